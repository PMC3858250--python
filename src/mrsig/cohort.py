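"""Synthetic cohorts with known prognostic ground truth.

Emulates the study design this pipeline targets: ~100 patients with
genome-wide log-scale expression, a handful of genes truly linked to hazard
through a proportional-hazards model, five binary adverse clinical factors
that also carry risk, independent censoring at a controllable rate, and —
for the liver-recurrence endpoint — a competing event (cancer death without
liver recurrence) affecting a controllable fraction of events.

Every draw is a pure function of (config, seed): each generation step uses
its own child generator derived from the config seed and a fixed stream tag,
so regenerating any component reproduces it bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .containers import (
    ClinicalRecord,
    CRS_FACTORS,
    ExpressionMatrix,
    SurvivalOutcome,
    outcomes_from_arrays,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_expression",
    "simulate_clinical",
    "simulate_outcomes",
    "simulate_cohort",
]

# Adverse-factor prevalences for (node_positive, dfi_lt_12mo, cea_gt_200,
# multiple_tumors, size_gt_5cm): the approximate frequencies seen in
# resected colorectal liver-metastasis cohorts.
DEFAULT_PREVALENCES = (0.59, 0.53, 0.08, 0.60, 0.23)

# fixed stream tags so each component draws from its own reproducible stream
_TAG_LATENT = 7
_TAG_EXPRESSION = 11
_TAG_CLINICAL = 23
_TAG_OUTCOME_DSS = 37
_TAG_OUTCOME_LRFS = 41


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    effect_size is the per-standard-deviation log hazard ratio of each
    planted prognostic gene; clinical_effect the log hazard ratio per
    adverse clinical factor; baseline_hazard is per month.
    """

    n_samples: int = 96
    n_genes: int = 1000
    n_prognostic: int = 20
    effect_size: float = 0.5
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.40
    competing_hazard_fraction: float = 0.15
    clinical_effect: float = 0.3
    noise_sd: float = 1.0
    latent_correlation: float = 0.3
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0 <= self.n_prognostic <= self.n_genes:
            raise ValueError("n_prognostic must lie in [0, n_genes]")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.competing_hazard_fraction < 1:
            raise ValueError("competing_hazard_fraction must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.latent_correlation <= 1:
            raise ValueError("latent_correlation must lie in (0, 1]")
        if len(self.prevalences) != len(CRS_FACTORS):
            raise ValueError(f"exactly {len(CRS_FACTORS)} factor prevalences required")
        if any(not 0 <= q <= 1 for q in self.prevalences):
            raise ValueError("factor prevalences must lie in [0, 1]")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, tag])


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth used to create it."""

    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    outcomes_dss: list[SurvivalOutcome]
    outcomes_lrfs: list[SurvivalOutcome]
    truth: dict[str, float]  # planted gene id -> true per-SD log hazard ratio
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(n)]


def prognostic_gene_ids(config: SimulationConfig) -> list[str]:
    """The first n_prognostic gene identifiers carry the planted signal."""
    return _gene_ids(config.n_genes)[: config.n_prognostic]


def _latent_factor(config: SimulationConfig) -> np.ndarray:
    """Per-sample latent prognostic axis shared by all planted genes.

    Drawn from its own stream so expression and outcome generation see the
    identical factor for a given config.
    """
    return config.rng(_TAG_LATENT).standard_normal(config.n_samples)


def simulate_expression(
    config: SimulationConfig, raw_intensities: bool = False
) -> ExpressionMatrix:
    """Draw a genes x samples matrix on a log2-like intensity scale.

    Each gene g is Gaussian around its own baseline level mu_g with standard
    deviation ``noise_sd``.  The planted prognostic genes are noisy reads of
    one shared per-sample latent axis u (correlation sqrt(latent_correlation)
    between each planted gene and u), the co-expression structure a
    first-principal-component signature presumes; hazard acts through u, and
    each planted gene's standardized expression then carries a marginal
    per-SD log hazard ratio of ``effect_size``.  With
    ``raw_intensities=True`` the same draw is returned exponentiated (2**x),
    emulating unlogged scanner intensities for exercising the
    log2 + quantile-normalization path.
    """
    rng = config.rng(_TAG_EXPRESSION)
    u = _latent_factor(config)
    mu = rng.normal(loc=7.5, scale=1.0, size=config.n_genes)
    z = rng.standard_normal((config.n_genes, config.n_samples))
    k, rho = config.n_prognostic, config.latent_correlation
    if k:
        z[:k] = np.sqrt(rho) * u[None, :] + np.sqrt(1.0 - rho) * z[:k]
    values = mu[:, None] + config.noise_sd * z
    if raw_intensities:
        values = np.exp2(values)
    return ExpressionMatrix(
        _gene_ids(config.n_genes), _sample_ids(config.n_samples), values
    )


def simulate_clinical(config: SimulationConfig) -> list[ClinicalRecord]:
    """Five independent Bernoulli adverse factors per sample."""
    rng = config.rng(_TAG_CLINICAL)
    draws = rng.random((config.n_samples, len(CRS_FACTORS))) < np.asarray(
        config.prevalences
    )
    return [
        ClinicalRecord(sample_id=s, **dict(zip(CRS_FACTORS, map(bool, row))))
        for s, row in zip(_sample_ids(config.n_samples), draws)
    ]


def _linear_predictor(
    expression: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    config: SimulationConfig,
) -> tuple[np.ndarray, dict[str, float]]:
    genes = prognostic_gene_ids(config)
    # each planted gene's standardized expression correlates sqrt(rho) with
    # the latent axis u; hazard effect_size/sqrt(rho) on u makes the marginal
    # per-SD log hazard ratio of every planted gene equal effect_size
    truth = {g: float(config.effect_size) for g in genes}
    lp = np.zeros(config.n_samples)
    if genes and config.effect_size != 0.0:
        u = _latent_factor(config)
        lp += (config.effect_size / np.sqrt(config.latent_correlation)) * u
    counts = np.array([sum(r.factors()) for r in clinical], dtype=float)
    lp += config.clinical_effect * counts
    return lp, truth


def _solve_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = target.

    For T ~ Exp(lambda_i) and C ~ Exp(c) independent, P(C < T_i) =
    c / (c + lambda_i); the mean over samples is monotone in c, so the root
    is bracketed and solved numerically.
    """
    if target == 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target

    lo, hi = 1e-12, 1.0
    while frac(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid targets
            break
    return float(optimize.brentq(frac, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_outcomes(
    expression: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    config: SimulationConfig,
    endpoint: str = "dss",
) -> list[SurvivalOutcome]:
    """Draw censored event times from the proportional-hazards truth.

    Event times are exponential with subject rate
    ``baseline_hazard * exp(linear predictor)``; censoring is independent
    exponential with its rate solved so the expected censored fraction equals
    ``censoring_rate``.  For the ``lrfs`` endpoint a Bernoulli
    ``competing_hazard_fraction`` subset of events is relabelled as the
    competing event (type 2), keeping event times fixed.
    """
    if endpoint not in ("dss", "lrfs"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if expression.n_samples != len(clinical):
        raise ValueError("expression columns and clinical records are misaligned")
    if expression.sample_ids != [r.sample_id for r in clinical]:
        raise ValueError("expression and clinical sample ids differ or are re-ordered")
    rng = config.rng(_TAG_OUTCOME_DSS if endpoint == "dss" else _TAG_OUTCOME_LRFS)
    lp, _ = _linear_predictor(expression, clinical, config)
    rates = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)
    c_rate = _solve_censoring_rate(rates, config.censoring_rate)
    t_cens = (
        rng.exponential(1.0 / c_rate, size=config.n_samples)
        if c_rate > 0
        else np.full(config.n_samples, np.inf)
    )
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)  # guard exact zeros
    etype = np.where(t_event <= t_cens, 1, 0)
    if endpoint == "lrfs" and config.competing_hazard_fraction > 0:
        events = np.flatnonzero(etype == 1)
        flip = rng.random(events.size) < config.competing_hazard_fraction
        etype[events[flip]] = 2
    return outcomes_from_arrays(expression.sample_ids, time, etype)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate expression, clinical factors, both endpoints, and the truth."""
    expression = simulate_expression(config)
    clinical = simulate_clinical(config)
    _, truth = _linear_predictor(expression, clinical, config)
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        outcomes_dss=simulate_outcomes(expression, clinical, config, "dss"),
        outcomes_lrfs=simulate_outcomes(expression, clinical, config, "lrfs"),
        truth=truth,
        config=config,
    )
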