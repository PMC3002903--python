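"""Reading/writing expression tables and cross-batch quantile normalization.

Matrices are plain TSV: first column gene ids, header row sample ids.
Condition maps are two-column TSV (sample_id, condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    MODE_LOG_EXPRESSION,
    ConditionMap,
    ExpressionMatrix,
    ParseError,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_condition_map",
    "write_condition_map",
    "quantile_normalize",
]


def read_matrix(path, mode: str = MODE_LOG_EXPRESSION) -> ExpressionMatrix:
    """Parse a gene × sample TSV into an :class:`ExpressionMatrix`.

    Rejects ragged rows, non-numeric cells and duplicate gene or sample ids,
    naming the offending row in the error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & frame.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        raise ParseError(f"{path}: non-numeric cell in row {gene!r}")
    if values.isna().to_numpy().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in row {gene!r}")
    return ExpressionMatrix.from_frame(values.astype(float), mode=mode)


def write_matrix(matrix: ExpressionMatrix, path, sig_digits: int = 6) -> None:
    """Write a matrix as TSV with `sig_digits` significant digits."""
    matrix.to_frame().to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")


def read_condition_map(path) -> ConditionMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] != 2:
        raise ParseError(f"{path}: condition map must have exactly two columns")
    sample_col, cond_col = frame.columns
    if frame[sample_col].duplicated().any():
        dup = frame[sample_col][frame[sample_col].duplicated()].iloc[0]
        raise ParseError(f"{path}: sample {dup!r} listed more than once")
    return ConditionMap(dict(zip(frame[sample_col], frame[cond_col])))


def write_condition_map(cmap: ConditionMap, path) -> None:
    pd.DataFrame(
        {"sample_id": list(cmap.assignments), "condition": list(cmap.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def quantile_normalize(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Quantile-normalize all samples across a list of batches.

    Every output sample is forced onto the common reference distribution: the
    across-sample mean of order statistics, pooled over all batches.  Gene
    identity within each sample is preserved.  Tied values within a sample
    receive the mean of the corresponding reference quantiles (fractional
    average ranks are linearly interpolated).

    All matrices must share the same gene set (same order) and be in
    ``log_expression`` mode.  A single pooled sample is returned unchanged.
    """
    if not matrices:
        raise ParseError("no matrices given")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise ParseError("matrices have mismatched gene sets")
    for m in matrices:
        if m.mode != MODE_LOG_EXPRESSION:
            raise ParseError("quantile normalization applies to log_expression mode only")

    pooled = np.hstack([m.values for m in matrices])  # genes × total samples
    n_genes, n_total = pooled.shape
    if n_total == 1:
        return [
            ExpressionMatrix(m.gene_ids, m.sample_ids, m.values.copy(), m.mode)
            for m in matrices
        ]
    reference = np.sort(pooled, axis=0).mean(axis=1)

    normalized = np.empty_like(pooled)
    positions = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_total):
        ranks = rankdata(pooled[:, j], method="average")
        normalized[:, j] = np.interp(ranks, positions, reference)

    out: list[ExpressionMatrix] = []
    col = 0
    for m in matrices:
        block = normalized[:, col : col + m.n_samples]
        col += m.n_samples
        out.append(ExpressionMatrix(m.gene_ids, m.sample_ids, block, m.mode))
    return out
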