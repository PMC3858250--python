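"""Genome-wide univariate survival screening.

Each gene's expression is standardized on the screened samples (mean 0,
SD 1) and fitted against the outcome with either a cause-specific Cox model
(the competing event treated as censoring) or a Fine-Gray subdistribution
model.  Genes with Wald p below the significance threshold form the
selected set.  The standardized coefficient z = beta/se is what downstream
signature construction ranks and (in coefficient-weight mode) uses as gene
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SurvivalOutcome, outcomes_to_arrays
from .coxph import GeneScreenResult, screen_cox
from .finegray import screen_finegray

__all__ = [
    "ScreenOutput",
    "screen_genes",
    "compare_pvalue_sets",
    "results_to_frame",
    "zcut_for_p",
]

DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class ScreenOutput:
    results: list[GeneScreenResult]
    selected: list[str]          # gene ids with p < alpha, in input gene order
    excluded: list[str]          # zero-variance genes, reported not fitted
    alpha: float
    analysis: str

    def by_gene(self) -> dict[str, GeneScreenResult]:
        return {r.gene_id: r for r in self.results}


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Per-column (gene) standardization to mean 0, SD 1; zero-SD columns untouched."""
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def screen_genes(
    matrix: ExpressionMatrix,
    outcomes: Iterable[SurvivalOutcome],
    alpha: float = DEFAULT_ALPHA,
    analysis: str = "cox",
) -> ScreenOutput:
    """Fit one univariate model per gene and select at ``p < alpha``.

    Outcomes are aligned to the matrix by sample id; samples missing from
    either side are an error (screening on a partial cohort should be an
    explicit subsetting decision upstream).
    """
    outcomes = list(outcomes)
    ids, time, event, etype = outcomes_to_arrays(outcomes)
    by_id = dict(zip(ids, range(len(ids))))
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing or len(by_id) != matrix.n_samples:
        extra = sorted(set(by_id) - set(matrix.sample_ids))
        raise ValueError(
            "expression and outcome samples do not match: "
            f"missing outcomes for {missing[:5]}, outcomes without expression {extra[:5]}"
        )
    order = [by_id[s] for s in matrix.sample_ids]
    time, event, etype = time[order], event[order], etype[order]

    if analysis not in ("cox", "finegray"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")

    X = matrix.values.T  # samples x genes
    variable = np.ptp(X, axis=0) > 0
    excluded = [g for g, v in zip(matrix.gene_ids, variable) if not v]
    kept_ids = [g for g, v in zip(matrix.gene_ids, variable) if v]
    Xs = standardize_columns(X[:, variable])

    if analysis == "cox":
        results = screen_cox(Xs, time, event, kept_ids)
    else:
        results = screen_finegray(Xs, time, etype, kept_ids)
    selected = [r.gene_id for r in results if r.p < alpha and not r.degenerate]
    return ScreenOutput(
        results=results,
        selected=selected,
        excluded=excluded,
        alpha=alpha,
        analysis=analysis,
    )


def compare_pvalue_sets(
    results_a: Sequence[GeneScreenResult],
    results_b: Sequence[GeneScreenResult],
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-gene p-values between two screening runs.

    Used to check whether treating the competing event as censoring
    (cause-specific Cox) versus modelling it (Fine-Gray) materially changes
    the per-gene evidence; returns the correlation and the paired table for
    scatter plotting.
    """
    pa = {r.gene_id: r.p for r in results_a}
    pb = {r.gene_id: r.p for r in results_b}
    if set(pa) != set(pb):
        raise ValueError("the two result sets cover different gene universes")
    if len(pa) < 3:
        raise ValueError("need at least 3 genes to correlate p-values")
    genes = sorted(pa)
    table = pd.DataFrame(
        {"gene_id": genes, "p_a": [pa[g] for g in genes], "p_b": [pb[g] for g in genes]}
    )
    r, _ = stats.pearsonr(table["p_a"], table["p_b"])
    return float(r), table


def results_to_frame(output: ScreenOutput) -> pd.DataFrame:
    """Flat screening table (one row per fitted gene) for TSV export."""
    sel = set(output.selected)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in output.results],
            "beta": [r.beta for r in output.results],
            "se": [r.se for r in output.results],
            "z": [r.z for r in output.results],
            "p": [r.p for r in output.results],
            "analysis": [r.analysis for r in output.results],
            "selected": [r.gene_id in sel for r in output.results],
        }
    )


def zcut_for_p(p: float) -> float:
    """|z| threshold equivalent to a two-sided Wald p-value threshold."""
    return float(stats.norm.isf(p / 2.0))
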