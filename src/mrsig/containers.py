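"""Core in-memory containers shared across the pipeline.

The pipeline passes around three kinds of per-sample data: a genes x samples
expression matrix, censored survival outcomes (optionally with a competing
event type), and the five binary clinicopathological factors that make up
the clinical risk score (CRS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalOutcome",
    "ClinicalRecord",
    "QuantileReference",
    "outcomes_to_arrays",
    "outcomes_from_arrays",
    "CRS_FACTORS",
]

#: The five adverse factors of the clinical risk score, in canonical order.
CRS_FACTORS = (
    "node_positive",   # lymph-node-positive primary tumor
    "dfi_lt_12mo",     # disease-free interval < 12 months
    "cea_gt_200",      # preoperative serum CEA > 200 ng/ml
    "multiple_tumors", # more than one hepatic tumor
    "size_gt_5cm",     # largest tumor > 5 cm
)


class ExpressionMatrix:
    """Genes x samples matrix of real-valued (log-scale) expression.

    Gene and sample identifiers are unique, ordered strings; ``values`` is a
    float array of shape ``(n_genes, n_samples)`` with no missing entries.
    """

    __slots__ = ("gene_ids", "sample_ids", "values", "_gene_index")

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene "
                f"{gene_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
            )
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        idx = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples>"


@dataclass(frozen=True)
class SurvivalOutcome:
    """One sample's censored follow-up.

    ``event_type`` is 0 for censored, 1 for the endpoint event, and 2 for a
    competing event (cancer death without liver recurrence in the
    liver-recurrence analyses).  ``event`` is 1 iff ``event_type`` is 1, so
    cause-specific analyses can use it directly (the competing event is then
    censoring).
    """

    sample_id: str
    time: float
    event: int
    event_type: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.event_type is None:
            object.__setattr__(self, "event_type", int(self.event))
        if self.time <= 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be > 0, got {self.time}")
        if self.event_type not in (0, 1, 2):
            raise ValueError(f"sample {self.sample_id!r}: event_type must be 0, 1 or 2")
        if self.event != (1 if self.event_type == 1 else 0):
            raise ValueError(
                f"sample {self.sample_id!r}: event must be 1 iff event_type is 1"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    """The five binary CRS factors for one sample; all must be present."""

    sample_id: str
    node_positive: bool
    dfi_lt_12mo: bool
    cea_gt_200: bool
    multiple_tumors: bool
    size_gt_5cm: bool

    def factors(self) -> tuple[bool, ...]:
        return tuple(bool(getattr(self, f)) for f in CRS_FACTORS)


@dataclass(frozen=True)
class QuantileReference:
    """Frozen reference distribution from quantile normalization.

    ``distribution`` is the non-decreasing column-mean of per-sample sorted
    values from the training matrix; applying it to new samples maps each
    sample onto this distribution by rank without re-estimating anything.
    """

    distribution: np.ndarray
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        dist = np.asarray(self.distribution, dtype=float)
        if dist.ndim != 1:
            raise ValueError("reference distribution must be one-dimensional")
        if np.any(np.diff(dist) < 0):
            raise ValueError("reference distribution must be non-decreasing")
        object.__setattr__(self, "distribution", dist)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.distribution)


def outcomes_to_arrays(
    outcomes: Iterable[SurvivalOutcome],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Unpack outcomes into (ids, time, event, event_type) arrays."""
    outcomes = list(outcomes)
    ids = [o.sample_id for o in outcomes]
    time = np.array([o.time for o in outcomes], dtype=float)
    event = np.array([o.event for o in outcomes], dtype=int)
    etype = np.array([o.event_type for o in outcomes], dtype=int)
    return ids, time, event, etype


def outcomes_from_arrays(
    ids: Sequence[str], time: np.ndarray, event_type: np.ndarray
) -> list[SurvivalOutcome]:
    return [
        SurvivalOutcome(
            sample_id=str(s),
            time=float(t),
            event=1 if int(k) == 1 else 0,
            event_type=int(k),
        )
        for s, t, k in zip(ids, time, event_type)
    ]
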