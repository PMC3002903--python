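"""Screening genes unaffected by experimental conditions.

Distribution characterization only makes sense on genes whose expression was
not shifted by the study's conditions, so each gene is first tested across
conditions with the Kruskal-Wallis rank test; genes with p > 0.1 (a
deliberately liberal cutoff) are deemed unaffected and retained.  Genes are
further stratified against a noise floor — mean log expression above 6
(single-color) or absolute mean log ratio above 0.05 (two-color) — below
which measurements behave like optical/ratio noise with inflated higher
moments.  For two-color data an active-gene seed set can be expanded by
Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConditionMap, ExpressionMatrix, MODE_LOG_EXPRESSION

__all__ = [
    "ScreenResult",
    "kruskal_wallis",
    "screen_unaffected",
    "noise_floor_filter",
    "expand_active",
    "DEFAULT_ALPHA",
    "NOISE_FLOOR_LOG_EXPRESSION",
    "NOISE_FLOOR_LOG_RATIO",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
NOISE_FLOOR_LOG_EXPRESSION = 6.0
NOISE_FLOOR_LOG_RATIO = 0.05


@dataclass
class ScreenResult:
    """Per-gene screening outcome: KW statistic/p and the retained flag."""

    table: pd.DataFrame  # index gene; columns H, p_value, retained
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table.retained])


def kruskal_wallis(values_by_group) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All-identical data across groups gives H = 0, p = 1 (equal rank sums).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def screen_unaffected(
    matrix: ExpressionMatrix,
    conditions: ConditionMap,
    alpha: float = DEFAULT_ALPHA,
) -> ScreenResult:
    """Retain genes whose KW p-value across conditions exceeds `alpha`.

    With a single condition the test is undefined: everything is retained
    with a warning (p set to NaN).
    """
    groups = conditions.groups_for(matrix)
    gene_ids = matrix.gene_ids
    if len(groups) < 2:
        logger.warning(
            "single condition: Kruskal-Wallis undefined, retaining all %d genes",
            len(gene_ids),
        )
        table = pd.DataFrame(
            {"H": np.nan, "p_value": np.nan, "retained": True}, index=gene_ids
        )
        return ScreenResult(table=table, alpha=alpha)

    idx = list(groups.values())
    h = np.empty(len(gene_ids))
    p = np.empty(len(gene_ids))
    for i, row in enumerate(matrix.values):
        h[i], p[i] = kruskal_wallis([row[ix] for ix in idx])
    retained = p > alpha
    logger.info(
        "screen: %d/%d genes retained at alpha=%g", int(retained.sum()), len(gene_ids), alpha
    )
    table = pd.DataFrame({"H": h, "p_value": p, "retained": retained}, index=gene_ids)
    return ScreenResult(table=table, alpha=alpha)


def noise_floor_filter(
    means, mode: str = MODE_LOG_EXPRESSION, cutoff: float | None = None
) -> pd.DataFrame:
    """Partition genes into signal vs noise strata by the mean cutoff.

    Signal means strictly exceeding the cutoff (log_expression mode) or
    |mean| strictly exceeding it (log_ratio mode); a mean exactly at the
    cutoff falls in the noise stratum.  The partition is exhaustive and
    disjoint by construction.
    """
    if cutoff is None:
        cutoff = (
            NOISE_FLOOR_LOG_EXPRESSION
            if mode == MODE_LOG_EXPRESSION
            else NOISE_FLOOR_LOG_RATIO
        )
    means = pd.Series(means, dtype=float)
    level = means if mode == MODE_LOG_EXPRESSION else means.abs()
    signal = level > cutoff
    return pd.DataFrame({"mean": means, "signal": signal, "noise": ~signal})


def expand_active(
    matrix: ExpressionMatrix, seed_set, p_cut: float = 1e-5, chunk: int = 2048
) -> set[str]:
    """Expand an active-gene seed set by significant Pearson correlation.

    Returns the seed set plus every gene whose two-sided Pearson correlation
    p-value (t transform, n-2 df) with at least one seed gene is below
    `p_cut`.
    """
    seed_set = set(seed_set)
    if not seed_set:
        raise ValueError("empty seed set")
    unknown = seed_set - set(matrix.gene_ids)
    if unknown:
        raise ValueError(f"seed genes not in matrix: {sorted(unknown)[:5]}")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples for correlation p-values")

    x = matrix.values
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    norms[norms == 0.0] = np.inf  # constant genes correlate with nothing
    z = xc / norms[:, None]

    seed_idx = [i for i, g in enumerate(matrix.gene_ids) if g in seed_set]
    zs = z[seed_idx]

    # per-seed two-sided p threshold translated once into an |r| threshold
    t_crit = stats.t.isf(p_cut / 2.0, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)

    active = set(seed_set)
    for start in range(0, z.shape[0], chunk):
        block = z[start : start + chunk]
        r = np.abs(block @ zs.T)
        hits = np.where((r >= r_crit).any(axis=1))[0]
        active.update(matrix.gene_ids[start + i] for i in hits)
    return active
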