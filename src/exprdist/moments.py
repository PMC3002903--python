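"""Product moments, sample L-moments and theoretical L-moment ratio curves.

Product moments use plug-in (1/n) estimators throughout, so the population
inequality between kurtosis K and skewness S,

    K >= S**2 + 1,

holds exactly for every sample, and the normal reference values are
skewness 0 and kurtosis 3 (kurtosis is reported raw, not excess).

Sample L-moments are Hosking's unbiased estimators via probability-weighted
moments of the order statistics:

    b_r = (1/n) * sum_i x_(i) * C(i-1, r) / C(n-1, r)

    l1 = b0
    l2 = 2 b1 - b0
    l3 = 6 b2 - 6 b1 + b0
    l4 = 20 b3 - 30 b2 + 12 b1 - b0

with the L-moment ratios tau3 = l3/l2 (L-skewness) and tau4 = l4/l2
(L-kurtosis).  On the (tau3, tau4) plane every two-parameter location-scale
family is a single point and every three-parameter family traces a curve;
plotting per-gene sample ratios against these curves identifies plausible
families for the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .datatypes import ExpressionMatrix

__all__ = [
    "MomentSummary",
    "product_moments",
    "sample_lmoments",
    "moment_table",
    "theoretical_lmoment_curve",
    "lmoment_point_families",
    "lmoment_curve_families",
    "kurtosis_lower_bound",
    "lmoment_tau4_lower_bound",
]


@dataclass
class MomentSummary:
    """Per-sample product- and L-moment summary."""

    n: int
    mean: float
    sd: float
    cv: float
    skewness: float
    kurtosis: float
    l1: float
    l2: float
    tau3: float
    tau4: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# product moments
# ---------------------------------------------------------------------------

def _product_moments_rows(x: np.ndarray):
    """Plug-in mean/sd/skew/kurt per row of a 2-D array."""
    n = x.shape[1]
    mean = x.mean(axis=1)
    dev = x - mean[:, None]
    m2 = (dev**2).mean(axis=1)
    m3 = (dev**3).mean(axis=1)
    m4 = (dev**4).mean(axis=1)
    sd = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, np.nan)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2, np.nan)
        cv = np.where(mean != 0, sd / mean, np.nan)
    return mean, sd, cv, skew, kurt


def product_moments(values) -> MomentSummary:
    """Plug-in product moments of one sample (n >= 4).

    Constant data is flagged degenerate: sd 0, skewness/kurtosis NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("product_moments needs a 1-D sample with n >= 4")
    mean, sd, cv, skew, kurt = (v[0] for v in _product_moments_rows(x[None, :]))
    l1, l2, tau3, tau4 = sample_lmoments(x)
    return MomentSummary(
        n=x.size,
        mean=float(mean),
        sd=float(sd),
        cv=float(cv),
        skewness=float(skew),
        kurtosis=float(kurt),
        l1=float(l1),
        l2=float(l2),
        tau3=float(tau3),
        tau4=float(tau4),
        degenerate=bool(sd == 0.0),
    )


# ---------------------------------------------------------------------------
# sample L-moments
# ---------------------------------------------------------------------------

def _lmoments_rows(x: np.ndarray):
    """Unbiased sample L-moments per row (rows sorted internally)."""
    n = x.shape[1]
    if n < 4:
        raise ValueError("sample L-moments through l4 need n >= 4")
    xs = np.sort(x, axis=1)
    i = np.arange(1, n + 1, dtype=float)
    w1 = (i - 1) / (n - 1)
    w2 = w1 * (i - 2) / (n - 2)
    w3 = w2 * (i - 3) / (n - 3)
    b0 = xs.mean(axis=1)
    b1 = (xs * w1).mean(axis=1)
    b2 = (xs * w2).mean(axis=1)
    b3 = (xs * w3).mean(axis=1)
    l1 = b0
    l2 = 2 * b1 - b0
    l3 = 6 * b2 - 6 * b1 + b0
    l4 = 20 * b3 - 30 * b2 + 12 * b1 - b0
    with np.errstate(divide="ignore", invalid="ignore"):
        tau3 = np.where(l2 > 0, l3 / np.where(l2 > 0, l2, 1.0), np.nan)
        tau4 = np.where(l2 > 0, l4 / np.where(l2 > 0, l2, 1.0), np.nan)
    return l1, l2, tau3, tau4


def sample_lmoments(values):
    """Return (l1, l2, tau3, tau4) for one sample (n >= 4).

    Constant data gives l2 = 0 with undefined (NaN) ratios.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    l1, l2, tau3, tau4 = (v[0] for v in _lmoments_rows(x[None, :]))
    return float(l1), float(l2), float(tau3), float(tau4)


def moment_table(matrix: ExpressionMatrix, block: int = 512) -> pd.DataFrame:
    """Per-gene :class:`MomentSummary` table for a whole matrix.

    Rows are processed in blocks of `block` genes to bound the temporaries
    on wide matrices.
    """
    x = matrix.values
    parts = [
        (_product_moments_rows(x[i : i + block]), _lmoments_rows(x[i : i + block]))
        for i in range(0, x.shape[0], block)
    ]
    mean, sd, cv, skew, kurt = (
        np.concatenate([p[0][j] for p in parts]) for j in range(5)
    )
    l1, l2, tau3, tau4 = (np.concatenate([p[1][j] for p in parts]) for j in range(4))
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "n": x.shape[1],
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "skewness": skew,
            "kurtosis": kurt,
            "l1": l1,
            "l2": l2,
            "tau3": tau3,
            "tau4": tau4,
            "degenerate": sd == 0.0,
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# theoretical L-moment ratio curves
# ---------------------------------------------------------------------------

lmoment_curve_families = ("GEV", "GLO", "GNO", "GPA", "PE3")
lmoment_point_families = ("EXP", "NOR", "GUM", "RAY", "UNI")


@lru_cache(maxsize=1)
def _gauss_nodes(n: int = 4096):
    nodes, weights = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (nodes + 1.0)  # map to (0,1)
    w = 0.5 * weights
    return u, w


def _lmoment_ratios_from_quantile(qfunc) -> tuple[float, float]:
    """(tau3, tau4) by Gauss-Legendre quadrature of a quantile function.

    lambda_r = int_0^1 Q(u) P*_{r-1}(u) du with shifted Legendre polynomials.
    """
    u, w = _gauss_nodes()
    q = qfunc(u)
    p1 = 2 * u - 1
    p2 = 6 * u**2 - 6 * u + 1
    p3 = 20 * u**3 - 30 * u**2 + 12 * u - 1
    l2 = np.sum(w * q * p1)
    l3 = np.sum(w * q * p2)
    l4 = np.sum(w * q * p3)
    return float(l3 / l2), float(l4 / l2)


def _gev_tau3(k: float) -> float:
    # shape convention: Q(u) = (1 - (-ln u)^k)/k ; k -> 0 is Gumbel
    a = -np.expm1(-k * np.log(3.0))
    b = -np.expm1(-k * np.log(2.0))
    return 2.0 * a / b - 3.0


def _gev_tau4(k: float) -> float:
    def g(m):
        return -np.expm1(-k * np.log(m))

    return (5.0 * g(4) - 10.0 * g(3) + 6.0 * g(2)) / g(2)


def _gno_ratios(k: float) -> tuple[float, float]:
    if abs(k) < 1e-9:
        return _lmoment_ratios_from_quantile(lambda u: stats.norm.ppf(u))

    def q(u):
        z = stats.norm.ppf(u)
        return -np.expm1(-k * z) / k

    return _lmoment_ratios_from_quantile(q)


def _pe3_ratios(alpha: float) -> tuple[float, float]:
    # gamma with shape alpha; mirroring handles negative skew
    return _lmoment_ratios_from_quantile(lambda u: stats.gamma.ppf(u, alpha))


_POINTS = {
    "EXP": (1.0 / 3.0, 1.0 / 6.0),
    "UNI": (0.0, 0.0),
}


def _point(family: str) -> tuple[float, float]:
    if family in _POINTS:
        return _POINTS[family]
    if family == "NOR":
        return _lmoment_ratios_from_quantile(stats.norm.ppf)
    if family == "GUM":
        return _lmoment_ratios_from_quantile(lambda u: -np.log(-np.log(u)))
    if family == "RAY":
        return _lmoment_ratios_from_quantile(lambda u: np.sqrt(-2.0 * np.log1p(-u)))
    raise ValueError(f"unknown point family {family!r}")


def theoretical_lmoment_curve(family: str, tau3_grid=None) -> pd.DataFrame:
    """(tau3, tau4) locus of a family on the L-moment ratio diagram.

    Three-parameter families (GEV, GLO, GNO, GPA, PE3) return a curve over
    `tau3_grid` (default: 41 points on the family's attainable range);
    location-scale/point families (EXP, NOR, GUM, RAY, UNI) return a single
    row, and `tau3_grid` must be omitted for them.
    """
    family = family.upper()
    if family in lmoment_point_families:
        if tau3_grid is not None:
            raise ValueError(f"{family} is a point on the diagram; no tau3 grid applies")
        t3, t4 = _point(family)
        return pd.DataFrame({"family": [family], "tau3": [t3], "tau4": [t4]})
    if family not in lmoment_curve_families:
        raise ValueError(f"unknown family {family!r}")

    if tau3_grid is None:
        lo, hi = {
            "GEV": (-0.3, 0.7),
            "GLO": (-0.7, 0.7),
            "GNO": (-0.7, 0.7),
            "GPA": (-0.2, 0.7),
            "PE3": (-0.7, 0.7),
        }[family]
        tau3_grid = np.linspace(lo, hi, 41)
    tau3_grid = np.asarray(tau3_grid, dtype=float)

    tau4 = np.empty_like(tau3_grid)
    for idx, t3 in enumerate(tau3_grid):
        tau4[idx] = _tau4_at(family, float(t3))
    return pd.DataFrame({"family": family, "tau3": tau3_grid, "tau4": tau4})


def _tau4_at(family: str, t3: float) -> float:
    if not -1.0 < t3 < 1.0:
        raise ValueError(f"tau3={t3} outside the attainable range (-1, 1)")
    if family == "GLO":
        return (1.0 + 5.0 * t3**2) / 6.0
    if family == "GPA":
        if t3 <= -1.0 / 3.0:
            raise ValueError(f"tau3={t3} unattainable for GPA (needs tau3 > -1/3)")
        return t3 * (1.0 + 5.0 * t3) / (5.0 + t3)
    if family == "GEV":
        k = brentq(lambda kk: _gev_tau3(kk) - t3, -0.99, 30.0, xtol=1e-12)
        return _gev_tau4(k)
    if family == "GNO":
        k = brentq(lambda kk: _gno_ratios(kk)[0] - t3, -8.0, 8.0, xtol=1e-10)
        return _gno_ratios(k)[1]
    if family == "PE3":
        if abs(t3) < 1e-10:
            return _point("NOR")[1]
        # negative skew is the mirrored gamma: same shape at |tau3|, same tau4
        a = brentq(
            lambda la: _pe3_ratios(np.exp(la))[0] - abs(t3),
            np.log(1e-3),
            np.log(1e6),
            xtol=1e-10,
        )
        return _pe3_ratios(np.exp(a))[1]
    raise ValueError(family)


# Hosking-style polynomial approximations, kept as an independent cross-check
# of the quadrature route (tests only).
_POLY_TAU4 = {
    "GNO": [0.12282, 0.0, 0.77518, 0.0, 0.12279, 0.0, -0.13638, 0.0, 0.11368],
    "PE3": [0.1224, 0.0, 0.30115, 0.0, 0.95812, 0.0, -0.57488, 0.0, 0.19383],
}


def _polynomial_tau4_approx(family: str, tau3) -> np.ndarray:
    coefs = _POLY_TAU4[family.upper()]
    t = np.asarray(tau3, dtype=float)
    return sum(c * t**p for p, c in enumerate(coefs))


# ---------------------------------------------------------------------------
# attainability bounds
# ---------------------------------------------------------------------------

def kurtosis_lower_bound(skewness) -> np.ndarray | float:
    """Minimal admissible kurtosis at a given skewness: K >= S**2 + 1."""
    s = np.asarray(skewness, dtype=float)
    out = s**2 + 1.0
    return float(out) if out.ndim == 0 else out


def lmoment_tau4_lower_bound(tau3) -> np.ndarray | float:
    """Minimal admissible L-kurtosis: tau4 >= (5 tau3**2 - 1) / 4."""
    t = np.asarray(tau3, dtype=float)
    out = (5.0 * t**2 - 1.0) / 4.0
    return float(out) if out.ndim == 0 else out
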