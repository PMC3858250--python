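"""File formats: expression TSV, clinical/outcome CSV, JSON artifacts.

Conventions: expression is genes-in-rows TSV whose first column holds gene
ids and whose header row holds sample ids; clinical and outcome tables are
CSV with declared headers; models, references, reports and manifests are
JSON.  Readers validate aggressively and report coordinates, since silent
coercion of a malformed expression table corrupts everything downstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CRS_FACTORS,
    ClinicalRecord,
    ExpressionMatrix,
    QuantileReference,
    SurvivalOutcome,
)
from .signature import RiskScore, SignatureModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_outcomes",
    "write_outcomes",
    "read_clinical_outcomes",
    "write_model",
    "read_model",
    "write_reference",
    "read_reference",
    "write_scores",
    "read_scores",
    "write_json",
    "read_json",
]

OUTCOME_COLUMNS = ("sample_id", "time_months", "event", "event_type")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Parse a genes x samples TSV; rejects duplicates and non-numeric cells.

    A matrix that looks transposed (sample-like row ids vastly outnumbering
    columns is not detectable in general, but a duplicated header or blank
    cells are) is refused with coordinates rather than guessed at.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if frame.columns.duplicated().any():
        dupes = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValueError(f"{path.name}: duplicated sample ids {dupes}")
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"{path.name}: duplicated gene ids {dupes}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = frame.index[bad.to_numpy().argmax()]
            cell = frame[col][bad].iloc[0]
            raise ValueError(
                f"{path.name}: non-numeric or blank cell {cell!r} at "
                f"gene {gene!r}, sample {col!r} (row {int(bad.to_numpy().argmax()) + 2})"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, **{f: int(getattr(r, f)) for f in CRS_FACTORS}}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    frame = pd.read_csv(path)
    missing_cols = [c for c in ("sample_id", *CRS_FACTORS) if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing clinical columns {missing_cols}")
    records = []
    for i, row in frame.iterrows():
        for f in CRS_FACTORS:
            if pd.isna(row[f]):
                raise ValueError(
                    f"{path.name}: sample {row['sample_id']!r} is missing CRS "
                    f"factor {f!r}; incomplete clinical records are excluded upstream"
                )
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                **{f: bool(int(row[f])) for f in CRS_FACTORS},
            )
        )
    return records


def write_outcomes(outcomes: Iterable[SurvivalOutcome], path: str | Path) -> None:
    rows = [
        {
            "sample_id": o.sample_id,
            "time_months": o.time,
            "event": o.event,
            "event_type": o.event_type,
        }
        for o in outcomes
    ]
    pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS)).to_csv(path, index=False)


def read_outcomes(path: str | Path) -> list[SurvivalOutcome]:
    path = Path(path)
    frame = pd.read_csv(path)
    missing_cols = [c for c in OUTCOME_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing outcome columns {missing_cols}")
    outcomes = []
    for _, row in frame.iterrows():
        t = float(row["time_months"])
        if not np.isfinite(t) or t <= 0:
            raise ValueError(
                f"{path.name}: sample {row['sample_id']!r} has invalid "
                f"follow-up time {row['time_months']!r} (months must be positive)"
            )
        outcomes.append(
            SurvivalOutcome(
                sample_id=str(row["sample_id"]),
                time=t,
                event=int(row["event"]),
                event_type=int(row["event_type"]),
            )
        )
    return outcomes


def read_clinical_outcomes(
    clinical_path: str | Path,
    outcomes_path: str | Path,
    expression_sample_ids: Sequence[str] | None = None,
) -> tuple[list[ClinicalRecord], list[SurvivalOutcome], dict]:
    """Read both per-sample tables and align them to the expression samples.

    Returns (clinical, outcomes, exclusion_report); samples present in the
    tables but not the expression matrix (or vice versa) are listed in the
    report rather than silently dropped.
    """
    clinical = read_clinical(clinical_path)
    outcomes = read_outcomes(outcomes_path)
    report: dict = {"clinical_only": [], "outcomes_only": [], "expression_only": []}
    if expression_sample_ids is not None:
        expr = list(expression_sample_ids)
        cset = {c.sample_id for c in clinical}
        oset = {o.sample_id for o in outcomes}
        eset = set(expr)
        report["clinical_only"] = sorted(cset - eset)
        report["outcomes_only"] = sorted(oset - eset)
        report["expression_only"] = sorted(eset - (cset & oset))
        keep = [s for s in expr if s in cset and s in oset]
        by_c = {c.sample_id: c for c in clinical}
        by_o = {o.sample_id: o for o in outcomes}
        clinical = [by_c[s] for s in keep]
        outcomes = [by_o[s] for s in keep]
    return clinical, outcomes, report


def write_scores(scores: Iterable[RiskScore], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": s.sample_id, "mrs": s.mrs, "group": s.group} for s in scores]
    ).to_csv(path, index=False, float_format="%.12g")


def read_scores(path: str | Path) -> list[RiskScore]:
    frame = pd.read_csv(path)
    return [
        RiskScore(sample_id=str(r["sample_id"]), mrs=float(r["mrs"]), group=str(r["group"]))
        for _, r in frame.iterrows()
    ]


def write_model(model: SignatureModel, path: str | Path) -> None:
    write_json(model.to_dict(), path)


def read_model(path: str | Path) -> SignatureModel:
    return SignatureModel.from_dict(read_json(path))


def write_reference(ref: QuantileReference, path: str | Path) -> None:
    write_json(
        {"distribution": ref.distribution.tolist(), "provenance": list(ref.provenance)},
        path,
    )


def read_reference(path: str | Path) -> QuantileReference:
    d = read_json(path)
    return QuantileReference(
        distribution=np.asarray(d["distribution"], dtype=float),
        provenance=tuple(d["provenance"]),
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
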