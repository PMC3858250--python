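"""Clinical risk score, cohort splitting, and the validation report.

The clinical risk score (CRS) counts five adverse clinicopathological
factors (node-positive primary, disease-free interval < 12 months,
CEA > 200 ng/ml, multiple hepatic tumors, tumor > 5 cm); a sum >= 3 is high
risk.  Validation of a frozen molecular risk score (MRS) on held-out
samples reports Kaplan-Meier curves and log-rank tests by risk group,
concordance indices for MRS (continuous) and CRS, hazard ratios from a
multivariate Cox model with both scores, 3-year survival per group, and
the combined CRS+MRS three-group stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import ClinicalRecord, SurvivalOutcome, outcomes_to_arrays
from .coxph import cox_multivariate, cox_univariate
from .signature import RiskScore
from .survival import KMCurve, concordance_index, km_estimate, logrank_test, survival_at

__all__ = [
    "compute_crs",
    "split_cohort",
    "combine_risk_groups",
    "CohortSplit",
    "ValidationReport",
    "build_report",
]

CRS_HIGH_CUTOFF = 3
THREE_YEARS_MONTHS = 36.0


def compute_crs(record: ClinicalRecord) -> tuple[int, str]:
    """One point per adverse factor; total >= 3 is high risk."""
    score = sum(record.factors())
    return score, ("high" if score >= CRS_HIGH_CUTOFF else "low")


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


def split_cohort(
    sample_ids: Sequence[str], seed: int, stratify_events: np.ndarray | None = None
) -> CohortSplit:
    """Uniformly random 2:1 train:test partition (rounding toward train).

    With ``stratify_events`` (a 0/1 array aligned to ``sample_ids``) the 2:1
    ratio is applied within each event stratum.
    """
    sample_ids = [str(s) for s in sample_ids]
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a 2:1 split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    if stratify_events is None:
        perm = rng.permutation(n)
        test_idx = list(perm[: n // 3])
    else:
        stratify_events = np.asarray(stratify_events, dtype=int)
        for status in np.unique(stratify_events):
            idx = np.flatnonzero(stratify_events == status)
            perm = rng.permutation(idx)
            test_idx.extend(perm[: len(idx) // 3])
    test = set(test_idx)
    train_ids = tuple(s for i, s in enumerate(sample_ids) if i not in test)
    test_ids = tuple(s for i, s in enumerate(sample_ids) if i in test)
    return CohortSplit(train_ids=train_ids, test_ids=test_ids, seed=seed)


def combine_risk_groups(crs_class: str, mrs_class: str) -> str:
    """Three-way rule: both high -> high, both low -> low, otherwise intermediate."""
    for name, value in (("crs_class", crs_class), ("mrs_class", mrs_class)):
        if value not in ("high", "low"):
            raise ValueError(f"{name} must be 'high' or 'low', got {value!r}")
    if crs_class == "high" and mrs_class == "high":
        return "high"
    if crs_class == "low" and mrs_class == "low":
        return "low"
    return "intermediate"


def _curve_summary(curve: KMCurve) -> dict:
    s3, extrap = survival_at(curve, THREE_YEARS_MONTHS)
    return {
        "event_times": curve.event_times.tolist(),
        "at_risk": curve.at_risk.tolist(),
        "events": curve.events.tolist(),
        "survival": curve.survival.tolist(),
        "survival_3yr": s3,
        "survival_3yr_extrapolated": extrap,
    }


def _group_outcomes(
    outcomes: Sequence[SurvivalOutcome], labels: Mapping[str, str]
) -> dict[str, list[SurvivalOutcome]]:
    groups: dict[str, list[SurvivalOutcome]] = {}
    for o in outcomes:
        groups.setdefault(labels[o.sample_id], []).append(o)
    return groups


@dataclass(frozen=True)
class ValidationReport:
    endpoint: str
    cohort: str                   # "train" | "test" | "all"
    n_samples: int
    km_by_mrs_group: dict = field(default_factory=dict)
    logrank_mrs: dict = field(default_factory=dict)
    concordance_mrs: float = float("nan")
    concordance_crs: float = float("nan")
    multivariate: dict = field(default_factory=dict)
    combined_groups: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "cohort": self.cohort,
            "n_samples": self.n_samples,
            "km_by_mrs_group": self.km_by_mrs_group,
            "logrank_mrs": self.logrank_mrs,
            "concordance_mrs": self.concordance_mrs,
            "concordance_crs": self.concordance_crs,
            "multivariate": self.multivariate,
            "combined_groups": self.combined_groups,
            "notes": self.notes,
        }


def build_report(
    endpoint: str,
    cohort: str,
    scores: Sequence[RiskScore],
    clinical: Iterable[ClinicalRecord],
    outcomes: Iterable[SurvivalOutcome],
) -> ValidationReport:
    """Assemble every validation quantity for one cohort and endpoint.

    All inputs are per-sample and joined by sample id; every sample must
    appear in all three.  The multivariate Cox model enters CRS and MRS as
    binary high/low classes.
    """
    scores = list(scores)
    clinical = list(clinical)
    outcomes = list(outcomes)
    ids = [s.sample_id for s in scores]
    by_clin = {c.sample_id: c for c in clinical}
    by_out = {o.sample_id: o for o in outcomes}
    missing = [s for s in ids if s not in by_clin or s not in by_out]
    if missing:
        raise ValueError(f"missing clinical or outcome data for samples {missing[:5]}")
    clinical = [by_clin[s] for s in ids]
    outcomes = [by_out[s] for s in ids]
    notes: list[str] = []

    mrs_values = np.array([s.mrs for s in scores])
    mrs_class = {s.sample_id: s.group for s in scores}
    crs_class = {c.sample_id: compute_crs(c)[1] for c in clinical}

    # KM + log-rank by MRS group
    km_by_group = {}
    groups = _group_outcomes(outcomes, mrs_class)
    for label, members in sorted(groups.items()):
        km_by_group[label] = _curve_summary(km_estimate(members))
    if len(groups) >= 2:
        chi2, df, p = logrank_test([groups[k] for k in sorted(groups)])
        logrank_mrs = {"chi2": chi2, "df": df, "p": p}
    else:
        logrank_mrs = {}
        notes.append("all samples fell in one MRS group; log-rank not computed")

    # concordance: MRS continuous, CRS as 0-5 score
    c_mrs = concordance_index(mrs_values, outcomes)
    crs_scores = np.array([compute_crs(c)[0] for c in clinical], dtype=float)
    c_crs = concordance_index(crs_scores, outcomes)

    # multivariate Cox on the two binary classes
    X = np.column_stack(
        [
            [1.0 if crs_class[s] == "high" else 0.0 for s in ids],
            [1.0 if mrs_class[s] == "high" else 0.0 for s in ids],
        ]
    )
    multivariate = {}
    if np.ptp(X[:, 0]) > 0 and np.ptp(X[:, 1]) > 0:
        try:
            fit = cox_multivariate(X, outcomes, names=("crs_high", "mrs_high"))
            multivariate = fit.as_dict()
        except ValueError as exc:
            notes.append(f"multivariate Cox not computed: {exc}")
    else:
        notes.append("a risk class is constant; multivariate Cox not computed")

    # combined three-group stratification
    combined_label = {
        s: combine_risk_groups(crs_class[s], mrs_class[s]) for s in ids
    }
    combined = {}
    comb_groups = _group_outcomes(outcomes, combined_label)
    for label, members in comb_groups.items():
        combined[label] = _curve_summary(km_estimate(members))
        combined[label]["n"] = len(members)
    if len(comb_groups) >= 2:
        chi2, df, p = logrank_test([comb_groups[k] for k in sorted(comb_groups)])
        combined["logrank"] = {"chi2": chi2, "df": df, "p": p}

    return ValidationReport(
        endpoint=endpoint,
        cohort=cohort,
        n_samples=len(ids),
        km_by_mrs_group=km_by_group,
        logrank_mrs=logrank_mrs,
        concordance_mrs=float(c_mrs),
        concordance_crs=float(c_crs),
        multivariate=multivariate,
        combined_groups=combined,
        notes=notes,
    )
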