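"""End-to-end orchestration: simulate/load -> normalize -> split -> screen
-> tune -> fit -> score -> validate, with a deterministic artifact directory.

The flow enforces the train/test discipline: the signature, its
normalization reference, and its dichotomization threshold are estimated on
training samples only and applied frozen to the test set; test outcomes are
touched only by the final validation stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as mio
from .cohort import SimulationConfig, simulate_cohort
from .containers import ClinicalRecord, ExpressionMatrix, SurvivalOutcome
from .normalize import apply_reference, log2_transform, quantile_normalize
from .screening import compare_pvalue_sets, results_to_frame, screen_genes
from .signature import DEFAULT_P_GRID, compute_mrs, cv_select_threshold, fit_signature
from .validation import build_report, split_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

VALID_ENDPOINTS = ("dss", "lrfs")


@dataclass(frozen=True)
class PipelineConfig:
    """Schema-validated configuration for one pipeline run.

    Either ``simulation`` (parameters for the synthetic-cohort generator) or
    the three input paths must be given.  ``normalization_mode``:
    ``frozen`` (normalize training samples, map test samples onto the frozen
    reference), ``joint`` (normalize the whole cohort before splitting), or
    ``none``.  ``input_scale``: ``log`` for already-log2 data, ``raw`` for
    intensities that need log2(value + offset) first.
    """

    endpoints: tuple[str, ...] = ("dss", "lrfs")
    simulation: dict | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    outcomes_paths: dict | None = None          # endpoint -> path
    normalization_mode: str = "frozen"
    input_scale: str = "log"
    log2_offset: float = 1.0
    alpha: float = 0.001
    cv_folds: int = 5
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    weight_mode: str = "pc1"
    split_seed: int = 0
    cv_seed: int = 0
    stratify_split_by_events: bool = False
    compare_competing_risks: bool = True

    def __post_init__(self) -> None:
        if not self.endpoints:
            raise ValueError("at least one endpoint required")
        bad = [e for e in self.endpoints if e not in VALID_ENDPOINTS]
        if bad:
            raise ValueError(f"unknown endpoints {bad}; valid: {VALID_ENDPOINTS}")
        if self.normalization_mode not in ("frozen", "joint", "none"):
            raise ValueError("normalization_mode must be frozen, joint or none")
        if self.input_scale not in ("log", "raw"):
            raise ValueError("input_scale must be 'log' or 'raw'")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.weight_mode not in ("pc1", "coef"):
            raise ValueError("weight_mode must be 'pc1' or 'coef'")
        has_sim = self.simulation is not None
        has_paths = self.expression_path is not None
        if has_sim == has_paths:
            raise ValueError("exactly one of 'simulation' or input paths must be given")
        if has_paths and (self.clinical_path is None or not self.outcomes_paths):
            raise ValueError("file input requires clinical_path and outcomes_paths")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("endpoints", "p_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["endpoints"] = list(self.endpoints)
        d["p_grid"] = list(self.p_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**config.simulation)
        cohort = simulate_cohort(sim)
        outcomes = {"dss": cohort.outcomes_dss, "lrfs": cohort.outcomes_lrfs}
        return cohort.expression, cohort.clinical, outcomes, cohort.truth
    expression = mio.read_expression(config.expression_path)
    outcomes = {}
    clinical = None
    for endpoint in config.endpoints:
        if endpoint not in (config.outcomes_paths or {}):
            raise ValueError(f"no outcomes path for endpoint {endpoint!r}")
        clinical, outs, _ = mio.read_clinical_outcomes(
            config.clinical_path,
            config.outcomes_paths[endpoint],
            expression.sample_ids,
        )
        outcomes[endpoint] = outs
    return expression, clinical, outcomes, None


def _normalize(
    config: PipelineConfig,
    expression: ExpressionMatrix,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
):
    """Apply the configured preprocessing; returns (matrix, reference|None)."""
    if config.input_scale == "raw":
        expression = log2_transform(expression, offset=config.log2_offset)
    if config.normalization_mode == "none":
        return expression, None
    if config.normalization_mode == "joint":
        normalized, ref = quantile_normalize(expression)
        return normalized, ref
    train = expression.subset_samples(list(train_ids))
    test = expression.subset_samples(list(test_ids))
    train_norm, ref = quantile_normalize(train)
    test_norm = apply_reference(test, ref)
    merged = ExpressionMatrix(
        expression.gene_ids,
        list(train_ids) + list(test_ids),
        np.hstack([train_norm.values, test_norm.values]),
    )
    return merged.subset_samples(expression.sample_ids), ref


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write the artifact directory; returns its path.

    On any stage failure a FAILED marker naming the stage and error is left
    next to whatever partial artifacts exist, and the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    chash = config.config_hash()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "artifacts": [],
    }

    def emit_json(obj: dict, name: str) -> None:
        obj = dict(obj)
        obj["config_hash"] = chash
        mio.write_json(obj, outdir / name)
        manifest["artifacts"].append(name)

    def note_file(name: str) -> None:
        manifest["artifacts"].append(name)

    try:
        stage = "load"
        expression, clinical, outcomes, truth = _load_inputs(config)
        mio.write_clinical(clinical, outdir / "clinical.csv")
        note_file("clinical.csv")
        for endpoint in config.endpoints:
            mio.write_outcomes(outcomes[endpoint], outdir / f"outcomes_{endpoint}.csv")
            note_file(f"outcomes_{endpoint}.csv")
        if truth is not None:
            emit_json({"planted_genes": truth}, "truth.json")

        stage = "split"
        strat = None
        if config.stratify_split_by_events:
            primary = outcomes[config.endpoints[0]]
            by_id = {o.sample_id: o.event for o in primary}
            strat = np.array([by_id[s] for s in expression.sample_ids])
        split = split_cohort(expression.sample_ids, config.split_seed, strat)
        emit_json(
            {"train_ids": list(split.train_ids), "test_ids": list(split.test_ids),
             "seed": split.seed},
            "split.json",
        )

        stage = "normalize"
        expression, ref = _normalize(config, expression, split.train_ids, split.test_ids)
        mio.write_expression(expression, outdir / "expression_normalized.tsv")
        note_file("expression_normalized.tsv")
        if ref is not None:
            mio.write_reference(ref, outdir / "quantile_reference.json")
            note_file("quantile_reference.json")

        train_matrix = expression.subset_samples(list(split.train_ids))
        test_matrix = expression.subset_samples(list(split.test_ids))
        by_id = {endpoint: {o.sample_id: o for o in outcomes[endpoint]}
                 for endpoint in config.endpoints}

        results = {}
        for endpoint in config.endpoints:
            train_out = [by_id[endpoint][s] for s in split.train_ids]
            test_out = [by_id[endpoint][s] for s in split.test_ids]

            stage = f"screen[{endpoint}]"
            screen = screen_genes(train_matrix, train_out, alpha=config.alpha, analysis="cox")
            frame = results_to_frame(screen)
            frame.to_csv(outdir / f"screening_{endpoint}_cox.tsv", sep="\t", index=False)
            note_file(f"screening_{endpoint}_cox.tsv")

            if endpoint == "lrfs" and config.compare_competing_risks:
                fg = screen_genes(train_matrix, train_out, alpha=config.alpha,
                                  analysis="finegray")
                results_to_frame(fg).to_csv(
                    outdir / "screening_lrfs_finegray.tsv", sep="\t", index=False
                )
                note_file("screening_lrfs_finegray.tsv")
                corr, table = compare_pvalue_sets(screen.results, fg.results)
                table.to_csv(outdir / "pvalue_comparison_lrfs.csv", index=False)
                note_file("pvalue_comparison_lrfs.csv")
                emit_json({"pearson_correlation": corr}, "pvalue_comparison_lrfs.json")

            stage = f"tune[{endpoint}]"
            zcut, cv_meta = cv_select_threshold(
                train_matrix,
                train_out,
                p_grid=config.p_grid,
                folds=config.cv_folds,
                weight_mode=config.weight_mode,
                seed=config.cv_seed,
            )

            stage = f"train[{endpoint}]"
            model = fit_signature(
                train_matrix,
                train_out,
                cutpoint=zcut,
                weight_mode=config.weight_mode,
                endpoint=endpoint,
                cv_metadata=cv_meta,
            )
            mio.write_model(model, outdir / f"model_{endpoint}.json")
            note_file(f"model_{endpoint}.json")

            stage = f"score[{endpoint}]"
            train_scores = compute_mrs(model, train_matrix)
            test_scores = compute_mrs(model, test_matrix)
            mio.write_scores(train_scores, outdir / f"scores_{endpoint}_train.csv")
            mio.write_scores(test_scores, outdir / f"scores_{endpoint}_test.csv")
            note_file(f"scores_{endpoint}_train.csv")
            note_file(f"scores_{endpoint}_test.csv")

            stage = f"validate[{endpoint}]"
            for cohort_name, scores, outs in (
                ("train", train_scores, train_out),
                ("test", test_scores, test_out),
                # frozen scheme applied to the entire cohort, as in the
                # combined-stratification analysis
                ("all", train_scores + test_scores, train_out + test_out),
            ):
                report = build_report(endpoint, cohort_name, scores, clinical, outs)
                emit_json(report.to_dict(), f"report_{endpoint}_{cohort_name}.json")
            results[endpoint] = model

        stage = "manifest"
        manifest["artifacts"] = sorted(set(manifest["artifacts"]))
        mio.write_json(manifest, outdir / "manifest.json")
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
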