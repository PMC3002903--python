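"""Shared containers for expression matrices and sample→condition maps.

All expression values handled by this package are already on the log scale:
either log2 transcript measures from a single-color oligonucleotide platform
(``mode="log_expression"``) or log ratios against a common reference pool
from a two-color platform (``mode="log_ratio"``), which may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODE_LOG_EXPRESSION = "log_expression"
MODE_LOG_RATIO = "log_ratio"
VALID_MODES = (MODE_LOG_EXPRESSION, MODE_LOG_RATIO)


class ExprDistError(Exception):
    """Base error for this package."""


class ConfigError(ExprDistError):
    """Invalid configuration (bad proportions, empty conditions, ...)."""


class ParseError(ExprDistError):
    """Malformed input table."""


class DomainError(ExprDistError):
    """Data outside a distribution family's support."""


class DegenerateDataError(ExprDistError):
    """Zero-variance or otherwise degenerate data."""


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of log-scale expression values.

    Parameters
    ----------
    gene_ids, sample_ids : sequences of unique identifiers
    values : 2-D float array, shape ``(n_genes, n_samples)``
    mode : ``"log_expression"`` (single-color, log2 expression) or
        ``"log_ratio"`` (two-color, log ratio vs a common pool).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str = MODE_LOG_EXPRESSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.mode not in VALID_MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {VALID_MODES}")
        if self.values.ndim != 2:
            raise ParseError("expression values must be a 2-D gene × sample array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ParseError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ParseError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ParseError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value for gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str = MODE_LOG_EXPRESSION) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            mode=mode,
        )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class ConditionMap:
    """Assignment of each sample to an experimental condition label."""

    assignments: dict[str, str] = field(default_factory=dict)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.assignments.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def groups_for(self, matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
        """Column-index arrays per condition, validated against the matrix."""
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ConfigError(f"samples missing from condition map: {missing[:5]}")
        out: dict[str, list[int]] = {}
        for j, s in enumerate(matrix.sample_ids):
            out.setdefault(self.assignments[s], []).append(j)
        return {lab: np.asarray(ix, dtype=int) for lab, ix in out.items()}


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
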