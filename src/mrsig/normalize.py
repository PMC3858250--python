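"""Expression preprocessing: log2 transformation and quantile normalization.

Quantile normalization forces every sample (column) onto a common reference
distribution — the column-mean of per-sample sorted values — preserving each
sample's within-column rank order.  The reference can be frozen from the
training samples and applied unchanged to test samples, so that no test
information leaks into preprocessing.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, QuantileReference

__all__ = ["log2_transform", "quantile_normalize", "apply_reference"]


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; identifiers and shape preserved.

    ``offset`` guards raw intensities that can be zero (default 0 assumes
    strictly positive input and raises, naming the offending cell, if not).
    """
    shifted = matrix.values + offset
    if np.any(shifted <= 0):
        g, s = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"log2 undefined: value {matrix.values[g, s]!r} + offset {offset} "
            f"is not positive at gene {matrix.gene_ids[g]!r}, "
            f"sample {matrix.sample_ids[s]!r}"
        )
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, np.log2(shifted))


def _map_column_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace values by reference quantiles of matching rank; ties get the
    mean of the reference entries they span."""
    order = np.argsort(col, kind="stable")
    mapped = np.empty_like(ref)
    mapped[order] = ref
    # average reference values across tied input values
    sorted_vals = col[order]
    tie_starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    if len(tie_starts) < len(col):
        group_sizes = np.diff(np.r_[tie_starts, len(col)])
        group_means = np.add.reduceat(ref, tie_starts) / group_sizes
        mapped[order] = np.repeat(group_means, group_sizes)
    return mapped


def quantile_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, QuantileReference]:
    """Normalize all samples jointly; returns the matrix and the frozen reference."""
    if matrix.n_samples < 2:
        raise ValueError(
            "quantile normalization needs at least 2 samples "
            f"(got {matrix.n_samples})"
        )
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(matrix.n_samples):
        out[:, j] = _map_column_to_reference(values[:, j], reference)
    ref = QuantileReference(distribution=reference, provenance=tuple(matrix.sample_ids))
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out), ref


def apply_reference(
    matrix: ExpressionMatrix, ref: QuantileReference
) -> ExpressionMatrix:
    """Map each sample onto a frozen reference distribution by rank.

    Works for a single test sample; nothing is re-estimated from the data
    being normalized.
    """
    if len(ref) != matrix.n_genes:
        raise ValueError(
            f"reference length {len(ref)} does not match gene count {matrix.n_genes}"
        )
    out = np.empty_like(matrix.values)
    for j in range(matrix.n_samples):
        out[:, j] = _map_column_to_reference(matrix.values[:, j], ref.distribution)
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out)
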