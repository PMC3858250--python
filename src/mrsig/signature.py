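"""Construction of the molecular risk score (MRS) by supervised principal components.

The recipe: screen every gene for univariate survival association on the
training samples, keep the genes whose standardized coefficient magnitude
|z| clears a cutpoint tuned by cross-validation, extract the first
principal component of the selected-gene training submatrix, and use its
per-gene loadings as weights (alternatively the standardized Cox
coefficients themselves).  The score is oriented so that higher MRS means
higher hazard on the training data, and dichotomized at the exact training
median — both frozen into the model so scoring new samples re-estimates
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .containers import ExpressionMatrix, SurvivalOutcome, outcomes_to_arrays
from .coxph import GeneScreenResult, cox_score_statistic, cox_univariate
from .screening import screen_genes, zcut_for_p

__all__ = [
    "SignatureModel",
    "RiskScore",
    "rank_genes",
    "cv_select_threshold",
    "fit_signature",
    "compute_mrs",
    "DEFAULT_P_GRID",
]

# candidate |z| cutpoints bracket the p<0.001 operating point
DEFAULT_P_GRID = (1e-2, 10 ** -2.5, 1e-3, 10 ** -3.5, 1e-4)


@dataclass(frozen=True)
class SignatureModel:
    """A frozen molecular risk score.

    Everything needed to score a new sample lives here: the selected genes,
    their training centering/scaling, the weights, the orientation sign
    (+1/-1 so that higher score = higher hazard on training data), and the
    training-median threshold for the high/low dichotomy.
    """

    endpoint: str
    selected_genes: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    weight_mode: str            # "pc1" | "coef"
    orientation: int            # +1 or -1
    mrs_threshold: float
    analysis: str = "cox"
    cv_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.selected_genes)
        if k < 1:
            raise ValueError("a signature needs at least one gene")
        for name in ("center", "scale", "weights"):
            # contiguous copy: strided views (e.g. SVD columns) can change
            # BLAS summation order and break bitwise score reproducibility
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per selected gene")
            object.__setattr__(self, name, arr)
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")
        if self.weight_mode not in ("pc1", "coef"):
            raise ValueError("weight_mode must be 'pc1' or 'coef'")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "endpoint": self.endpoint,
            "selected_genes": list(self.selected_genes),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "weight_mode": self.weight_mode,
            "orientation": self.orientation,
            "mrs_threshold": self.mrs_threshold,
            "analysis": self.analysis,
            "cv_metadata": self.cv_metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported signature schema: {d.get('schema_version')}")
        return cls(
            endpoint=d["endpoint"],
            selected_genes=tuple(d["selected_genes"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            weight_mode=d["weight_mode"],
            orientation=int(d["orientation"]),
            mrs_threshold=float(d["mrs_threshold"]),
            analysis=d.get("analysis", "cox"),
            cv_metadata=d.get("cv_metadata", {}),
        )


@dataclass(frozen=True)
class RiskScore:
    sample_id: str
    mrs: float
    group: str  # "high" | "low"


def rank_genes(results: Sequence[GeneScreenResult]) -> list[GeneScreenResult]:
    """Order screening results by standardized coefficient magnitude |z|,
    descending; exact ties broken lexicographically by gene id."""
    if not results:
        raise ValueError("no screening results to rank")
    return sorted(results, key=lambda r: (-abs(r.z), r.gene_id))


def _raw_scores(
    model_genes: Sequence[str],
    center: np.ndarray,
    scale: np.ndarray,
    weights: np.ndarray,
    matrix: ExpressionMatrix,
) -> np.ndarray:
    sub = matrix.subset_genes(list(model_genes)).values  # genes x samples
    z = (sub - center[:, None]) / scale[:, None]
    return weights @ z


def _fit_unoriented(
    train_matrix: ExpressionMatrix,
    outcomes: Sequence[SurvivalOutcome],
    zcut: float,
    weight_mode: str,
    alpha_for_screen: float = 1.0,
    analysis: str = "cox",
):
    """Screen, select by |z| >= zcut, derive weights.  Returns None if no gene clears."""
    screen = screen_genes(train_matrix, outcomes, alpha=alpha_for_screen, analysis=analysis)
    chosen = [r for r in screen.results if not r.degenerate and abs(r.z) >= zcut]
    if not chosen:
        return None
    chosen = rank_genes(chosen)
    genes = [r.gene_id for r in chosen]
    sub = train_matrix.subset_genes(genes).values
    center = sub.mean(axis=1)
    scale = sub.std(axis=1)
    scale[scale == 0] = 1.0
    z = (sub - center[:, None]) / scale[:, None]
    if weight_mode == "pc1":
        # per-gene loadings of the leading singular direction of the
        # standardized genes x samples submatrix
        u, _, _ = np.linalg.svd(z, full_matrices=False)
        weights = u[:, 0]
    elif weight_mode == "coef":
        weights = np.array([r.z for r in chosen], dtype=float)
    else:
        raise ValueError("weight_mode must be 'pc1' or 'coef'")
    return genes, center, scale, weights, screen


def fit_signature(
    train_matrix: ExpressionMatrix,
    outcomes: Iterable[SurvivalOutcome],
    cutpoint: float,
    weight_mode: str = "pc1",
    endpoint: str = "dss",
    analysis: str = "cox",
    cv_metadata: dict | None = None,
) -> SignatureModel:
    """Fit the frozen signature at a given |z| cutpoint.

    Orientation is the sign of the Cox coefficient of the raw training score;
    the dichotomization threshold is the exact median of the oriented
    training scores.
    """
    outcomes = list(outcomes)
    fitted = _fit_unoriented(train_matrix, outcomes, cutpoint, weight_mode, analysis=analysis)
    if fitted is None:
        raise ValueError(
            f"no gene reaches |z| >= {cutpoint:.3f} on the training data; "
            "use a smaller cutpoint"
        )
    genes, center, scale, weights, _ = fitted
    raw = _raw_scores(genes, center, scale, weights, train_matrix)
    fit = cox_univariate(raw, _align(outcomes, train_matrix.sample_ids), gene_id="mrs")
    orientation = -1 if fit.beta < 0 else +1
    oriented = orientation * raw
    return SignatureModel(
        endpoint=endpoint,
        selected_genes=tuple(genes),
        center=center,
        scale=scale,
        weights=weights,
        weight_mode=weight_mode,
        orientation=orientation,
        mrs_threshold=float(np.median(oriented)),
        analysis=analysis,
        cv_metadata=cv_metadata or {},
    )


def compute_mrs(model: SignatureModel, matrix: ExpressionMatrix) -> list[RiskScore]:
    """Apply a frozen signature: linear combination of weighted, training-
    standardized expression, dichotomized at the frozen training median.

    Ties at the threshold go to the low-risk group.  Raises if any model
    gene is absent, listing the missing genes.
    """
    missing = [g for g in model.selected_genes if g not in matrix._gene_index]
    if missing:
        raise KeyError(f"matrix lacks signature genes: {missing}")
    raw = _raw_scores(model.selected_genes, model.center, model.scale, model.weights, matrix)
    mrs = model.orientation * raw
    return [
        RiskScore(sample_id=s, mrs=float(v), group="high" if v > model.mrs_threshold else "low")
        for s, v in zip(matrix.sample_ids, mrs)
    ]


def _align(
    outcomes: Sequence[SurvivalOutcome], sample_ids: Sequence[str]
) -> list[SurvivalOutcome]:
    by_id = {o.sample_id: o for o in outcomes}
    missing = [s for s in sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"outcomes missing for samples {missing[:5]}")
    return [by_id[s] for s in sample_ids]


def _stratified_folds(
    event: np.ndarray, k: int, rng: np.random.Generator, max_retries: int = 10
) -> np.ndarray:
    """Fold labels stratified by event status; every fold's training part
    must contain events.  Redraws up to ``max_retries`` times, then raises."""
    n = len(event)
    for _ in range(max_retries):
        labels = np.empty(n, dtype=int)
        for status in (0, 1):
            idx = np.flatnonzero(event == status)
            perm = rng.permutation(idx)
            labels[perm] = np.arange(len(perm)) % k
        ok = all((event[labels != f].sum() >= 2) for f in range(k))
        if ok:
            return labels
    raise ValueError("could not build folds with events in every training part")


def cv_select_threshold(
    train_matrix: ExpressionMatrix,
    outcomes: Iterable[SurvivalOutcome],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    folds: int = 5,
    weight_mode: str = "pc1",
    seed: int = 0,
    analysis: str = "cox",
) -> tuple[float, dict]:
    """Choose the screening cutpoint by K-fold cross-validation.

    For each candidate |z| cutpoint (given as equivalent p-value thresholds)
    genes are re-screened within each fold's training part, the signature
    fitted there, and held-out samples scored with the fold model (oriented
    by its fold-training Cox coefficient).  The held-out scores are pooled
    across folds into one pre-validated score vector per candidate, and the
    univariate Cox score statistic of that vector on the full training
    outcomes is the selection objective — pooling is markedly more stable
    than averaging five small per-fold statistics.  The cutpoint with the
    highest statistic wins; ties go to the stricter cutpoint.  Returns
    (zcut, cv_metadata).
    """
    outcomes = _align(list(outcomes), train_matrix.sample_ids)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not p_grid:
        raise ValueError("empty candidate grid")
    _, time, event, _ = outcomes_to_arrays(outcomes)
    rng = np.random.default_rng(seed)
    labels = _stratified_folds(event, folds, rng)

    cand = sorted(set(float(p) for p in p_grid), reverse=True)  # lenient -> strict
    zcuts = [zcut_for_p(p) for p in cand]
    n = train_matrix.n_samples
    prevalidated = np.zeros((len(cand), n))
    sizes_per_cand: list[list[int]] = [[] for _ in cand]
    for f in range(folds):
        tr = np.flatnonzero(labels != f)
        te = np.flatnonzero(labels == f)
        tr_ids = [train_matrix.sample_ids[i] for i in tr]
        te_ids = [train_matrix.sample_ids[i] for i in te]
        m_tr = train_matrix.subset_samples(tr_ids)
        m_te = train_matrix.subset_samples(te_ids)
        o_tr = [outcomes[i] for i in tr]
        for c, zc in enumerate(zcuts):
            fitted = _fit_unoriented(m_tr, o_tr, zc, weight_mode, analysis=analysis)
            if fitted is None:
                sizes_per_cand[c].append(0)
                continue  # held-out scores stay 0 (uninformative)
            genes, center, scale, weights, _ = fitted
            # orient with the fold-training coefficient so pooled scores
            # share a direction despite PC1 sign indeterminacy
            fold_scores = _raw_scores(genes, center, scale, weights, m_tr)
            if np.ptp(fold_scores) > 0:
                sign = cox_univariate(fold_scores, o_tr).beta
                orient = -1.0 if sign < 0 else 1.0
            else:
                orient = 1.0
            held = orient * _raw_scores(genes, center, scale, weights, m_te)
            # standardize per fold so folds contribute on a common scale
            if np.ptp(held) > 0:
                held = (held - held.mean()) / held.std()
            prevalidated[c, te] = held
            sizes_per_cand[c].append(len(genes))
    cv_stats = [
        cox_score_statistic(prevalidated[c], time, event)
        if np.ptp(prevalidated[c]) > 0
        else 0.0
        for c in range(len(cand))
    ]
    # argmax with ties to the strictest (largest) cutpoint
    best = max(range(len(cand)), key=lambda c: (cv_stats[c], zcuts[c]))
    metadata = {
        "folds": folds,
        "seed": seed,
        "weight_mode": weight_mode,
        "candidate_p": cand,
        "candidate_zcut": zcuts,
        "cv_statistic": cv_stats,
        "selected_gene_counts": sizes_per_cand,
        "chosen_p": cand[best],
        "chosen_zcut": zcuts[best],
    }
    return zcuts[best], metadata
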