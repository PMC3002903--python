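"""Synthetic expression matrices with the moment structure the analysis assumes.

The generator emulates the statistical shape of GCRMA-normalized single-color
log2 expression (or two-color log-ratio) data:

* per-gene means drawn uniformly over a configurable range (default 6-14,
  the post-noise-floor range of single-color data);
* a linear trend of log10 CV on the mean, with lognormal jitter, matching
  the observed decreasing CV-vs-mean relationship;
* an optional quadratic kurtosis-skewness trend K = c0 + c1*S + c2*S**2;
* a noise stratum of genes below the mean floor with inflated dispersion and
  higher moments;
* condition-affected genes with between-condition location shifts;
* mixture-mode genes drawn from 2-3 component normal mixtures.

Per-gene draws come either from a configurable named distribution family,
moment-matched to the gene's target mean and SD, or — when a
kurtosis-skewness trend is requested — from a cubic-transform-of-normal
(Fleishman polynomial) family that moment-matches mean, SD, skewness and
kurtosis simultaneously.  A named family pins its kurtosis once the skewness
is fixed (a gamma always has K = 3 + 1.5 S**2), so only the cubic-normal
route can realize an arbitrary quadratic K(S) relation.

A ground-truth table accompanies every matrix so downstream stages are
testable without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, root
from scipy.special import gammaln
from scipy.stats import truncnorm as scipy_truncnorm

from .datatypes import (
    ConditionMap,
    ConfigError,
    ExpressionMatrix,
    MODE_LOG_EXPRESSION,
    MODE_LOG_RATIO,
    VALID_MODES,
)
from .screening import NOISE_FLOOR_LOG_EXPRESSION, NOISE_FLOOR_LOG_RATIO

__all__ = ["SyntheticSpec", "TruthTable", "generate", "fleishman_coefficients"]

EULER_GAMMA = 0.5772156649015329

NAMED_FAMILIES = (
    "normal",
    "lognormal",
    "logistic",
    "loglogistic",
    "weibull",
    "extreme_value",
    "gamma",
    "pareto",
)
REAL_SUPPORT_FAMILIES = ("normal", "logistic", "extreme_value")


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic study.

    Defaults emulate a single-color study of ~69 arrays in 3 conditions
    (strain-like groups) with the observed CV trend of brain tissue
    (log10 CV = -2.10 - 0.22 * mean); about 30% of genes sit below the
    noise floor and 40% respond to the conditions.
    """

    n_genes: int = 2000
    n_samples: int = 69
    mode: str = MODE_LOG_EXPRESSION
    condition_labels: dict[str, int] | list[str] | None = None
    family_weights: dict[str, float] = field(default_factory=lambda: {"normal": 1.0})
    cv_trend: tuple[float, float] = (-2.10, -0.22)
    kurt_skew_trend: tuple[float, float, float] | None = None
    noise_fraction: float = 0.3
    noise_floor: float | None = None
    affected_fraction: float = 0.4
    affected_effect: float = 1.0
    affected_effect_in_sd: bool = True
    mixture_fraction: float = 0.0
    seed: int = 0
    # scatter model (the observed trends constrain only the fitted lines,
    # not the scatter; these stand-ins are documented in docs/methods.md)
    mean_range: tuple[float, float] | None = None
    cv_jitter_sd: float = 0.1  # log10 units around the CV trend
    noise_cv_inflation: float = 3.0
    noise_mean_min: float = 2.0
    skew_sd: float = 0.6  # spread of target skewness under kurt_skew_trend
    kurt_jitter_sd: float = 0.3  # population-level jitter of K around the trend

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.condition_labels is None:
            self.condition_labels = _default_conditions(self.n_samples)
        if isinstance(self.condition_labels, (list, tuple)):
            counts: dict[str, int] = {}
            for lab in self.condition_labels:
                counts[str(lab)] = counts.get(str(lab), 0) + 1
            self.condition_labels = counts
        if self.noise_floor is None:
            self.noise_floor = (
                NOISE_FLOOR_LOG_EXPRESSION
                if self.mode == MODE_LOG_EXPRESSION
                else NOISE_FLOOR_LOG_RATIO
            )
        if self.mean_range is None:
            self.mean_range = (
                (self.noise_floor, 14.0)
                if self.mode == MODE_LOG_EXPRESSION
                else (self.noise_floor, 1.0)
            )
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigError("n_genes and n_samples must be positive")
        for name in ("noise_fraction", "affected_fraction", "mixture_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not self.family_weights:
            raise ConfigError("family_weights is empty")
        total = sum(self.family_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"family_weights sum to {total}, not 1")
        allowed = (
            REAL_SUPPORT_FAMILIES if self.mode == MODE_LOG_RATIO else NAMED_FAMILIES
        )
        for fam, w in self.family_weights.items():
            if w < 0:
                raise ConfigError(f"negative weight for family {fam!r}")
            if fam not in allowed:
                raise ConfigError(
                    f"family {fam!r} not usable in {self.mode} mode (allowed: {allowed})"
                )
        if not self.condition_labels:
            raise ConfigError("empty condition labels")
        if any(c < 1 for c in self.condition_labels.values()):
            raise ConfigError("every condition needs at least one sample")
        if sum(self.condition_labels.values()) != self.n_samples:
            raise ConfigError(
                f"condition sample counts sum to {sum(self.condition_labels.values())}, "
                f"but n_samples={self.n_samples}"
            )
        if self.affected_fraction + self.mixture_fraction > 1.0 + 1e-9:
            raise ConfigError("affected_fraction + mixture_fraction exceed 1")

    def condition_map(self) -> ConditionMap:
        sample_ids = _sample_ids(self.n_samples)
        labels: list[str] = []
        for lab, cnt in self.condition_labels.items():
            labels.extend([lab] * cnt)
        return ConditionMap(dict(zip(sample_ids, labels)))

    # -- config round trip --------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("cv_trend", "kurt_skew_trend", "mean_range"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


TruthTable = pd.DataFrame  # one row per gene; see generate() for columns


def _default_conditions(n_samples: int) -> dict[str, int]:
    k = 3 if n_samples >= 3 else n_samples
    base = n_samples // k
    counts = {f"cond{i + 1}": base for i in range(k)}
    counts[f"cond{k}"] += n_samples - base * k
    return counts


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Fleishman cubic-normal family
# ---------------------------------------------------------------------------

def _fleishman_system(coef, skew, exkurt):
    b, c, d = coef
    f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0
    f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - skew
    f3 = (
        24
        * (
            b * d
            + c**2 * (1 + b**2 + 28 * b * d)
            + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)
        )
        - exkurt
    )
    return [f1, f2, f3]


def fleishman_feasible_kurtosis(skew) -> np.ndarray | float:
    """Conservative lower raw-kurtosis boundary of the cubic-normal family.

    The exact boundary passes through K ~ 1.849 at zero skew and grows
    roughly as 1.60 * S**2; this floor (1.90 + 1.65 S**2) sits slightly
    inside it so the coefficient solve is always well-posed.
    """
    s = np.asarray(skew, dtype=float)
    out = 1.90 + 1.65 * s**2
    return float(out) if out.ndim == 0 else out


def fleishman_coefficients(skew: float, kurtosis: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) with a = -c of the cubic-normal transform
    Y = a + b Z + c Z^2 + d Z^3 matching (0, 1, skew, kurtosis)."""
    ex = kurtosis - 3.0
    inits = [
        (0.95, skew / 6.0, ex / 60.0),
        (1.0, 0.0, 0.0),
        (0.9, 0.2 * np.sign(skew or 1.0), 0.03),
        (1.2, 0.05 * np.sign(skew or 1.0), -0.08),
        (1.05, 0.03 * np.sign(skew or 1.0), -0.03),
        (0.7, 0.2 * np.sign(skew or 1.0), 0.15),
    ]
    for init in inits:
        sol = root(_fleishman_system, init, args=(skew, ex), method="hybr", tol=1e-12)
        if sol.success and np.max(np.abs(sol.fun)) < 1e-8:
            b, c, d = sol.x
            if b < 0:  # mirror-image branch; try another start
                continue
            return (-c, b, c, d)
    raise ConfigError(
        f"no cubic-normal transform for skew={skew:.3g}, kurtosis={kurtosis:.3g} "
        "(outside the feasible region)"
    )


# ---------------------------------------------------------------------------
# named-family moment matching
# ---------------------------------------------------------------------------

def _weibull_shape_from_cv(cv: float) -> float:
    def f(log_c):
        c = np.exp(log_c)
        return (
            np.exp(gammaln(1 + 2.0 / c) - 2 * gammaln(1 + 1.0 / c)) - 1.0 - cv**2
        )

    return float(np.exp(brentq(f, np.log(0.05), np.log(1e7), xtol=1e-12)))


def _fisk_b_from_cv(cv: float) -> float:
    # log-logistic with shape c = pi / b: cv^2 = tan(b)/b - 1, b in (0, pi/2)
    def f(b):
        return np.tan(b) / b - 1.0 - cv**2

    return float(brentq(f, 1e-9, np.pi / 2 - 1e-9, xtol=1e-15))


def _sample_named_family(rng, family: str, m, s, n: int) -> tuple[np.ndarray, dict]:
    """n draws from `family` with population mean m and sd s (both scalar)."""
    if family == "normal":
        return rng.normal(m, s, n), {"mu": m, "sigma": s}
    if family == "logistic":
        scale = s * np.sqrt(3.0) / np.pi
        return rng.logistic(m, scale, n), {"loc": m, "scale": scale}
    if family == "extreme_value":  # minimum-type Gumbel
        scale = s * np.sqrt(6.0) / np.pi
        loc = m + EULER_GAMMA * scale
        return loc - scale * rng.gumbel(0.0, 1.0, n), {"loc": loc, "scale": scale}
    if m <= 0:
        raise ConfigError(f"family {family!r} needs a positive target mean, got {m}")
    cv = s / m
    if family == "lognormal":
        sigma2 = np.log1p(cv**2)
        mu = np.log(m) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), n), {"mu_log": mu, "sigma_log": np.sqrt(sigma2)}
    if family == "gamma":
        shape = 1.0 / cv**2
        scale = m / shape
        return rng.gamma(shape, scale, n), {"shape": shape, "scale": scale}
    if family == "weibull":
        c = _weibull_shape_from_cv(cv)
        scale = m / np.exp(gammaln(1 + 1.0 / c))
        return scale * rng.weibull(c, n), {"shape": c, "scale": scale}
    if family == "pareto":
        alpha = 1.0 + np.sqrt(1.0 + 1.0 / cv**2)
        xm = m * (alpha - 1.0) / alpha
        return xm * (1.0 + rng.pareto(alpha, n)), {"alpha": alpha, "xm": xm}
    if family == "loglogistic":
        b = _fisk_b_from_cv(cv)
        c = np.pi / b
        scale = m * np.sin(b) / b
        u = rng.uniform(0.0, 1.0, n)
        return scale * (u / (1.0 - u)) ** (1.0 / c), {"shape": c, "scale": scale}
    raise ConfigError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# generate
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw one expression matrix plus its ground-truth table.

    Deterministic for a fixed spec (including its seed).  The truth table
    has one row per gene with columns: family, params (JSON), target mean /
    sd / skewness / kurtosis, n_components, and the affected / noise /
    mixture / degenerate flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, N = spec.n_genes, spec.n_samples
    gene_ids = _gene_ids(G)
    sample_ids = _sample_ids(N)
    log_ratio = spec.mode == MODE_LOG_RATIO

    # strata: noise is an independent flag; affected and mixture are disjoint
    perm = rng.permutation(G)
    n_noise = round(spec.noise_fraction * G)
    noise = np.zeros(G, dtype=bool)
    noise[perm[:n_noise]] = True
    perm2 = rng.permutation(G)
    n_aff = round(spec.affected_fraction * G)
    n_mix = round(spec.mixture_fraction * G)
    affected = np.zeros(G, dtype=bool)
    mixture = np.zeros(G, dtype=bool)
    affected[perm2[:n_aff]] = True
    mixture[perm2[n_aff : n_aff + n_mix]] = True

    # target means
    lo, hi = spec.mean_range
    means = rng.uniform(lo, hi, G)
    if log_ratio:
        means *= rng.choice([-1.0, 1.0], G)
        means[noise] = rng.uniform(-spec.noise_floor, spec.noise_floor, n_noise)
    else:
        means[noise] = rng.uniform(spec.noise_mean_min, spec.noise_floor, n_noise)

    # target CV along the trend (vs |mean| in log-ratio mode), with jitter
    a_cv, b_cv = spec.cv_trend
    level = np.abs(means) if log_ratio else means
    log_cv = a_cv + b_cv * level + rng.normal(0.0, spec.cv_jitter_sd, G)
    cvs = np.power(10.0, log_cv)
    cvs[noise] *= spec.noise_cv_inflation
    # log-ratio noise genes keep a floor-scale sd so a near-zero mean does
    # not collapse the row to a constant (ratio noise persists at mean 0)
    sd_level = np.maximum(level, spec.noise_floor / 2.0) if log_ratio else level
    sds = cvs * np.abs(sd_level)
    degenerate = sds < 1e-12

    # target shape: named families, or the cubic-normal trend family
    use_trend = spec.kurt_skew_trend is not None
    fam_names = list(spec.family_weights)
    fam_p = np.array([spec.family_weights[f] for f in fam_names])
    families = np.array(
        ["cubic_normal"] * G if use_trend else rng.choice(fam_names, G, p=fam_p),
        dtype=object,
    )
    families[mixture] = "normal_mixture"
    families[degenerate] = "constant"

    skew_t = np.full(G, np.nan)
    kurt_t = np.full(G, np.nan)
    if use_trend:
        c0, c1, c2 = spec.kurt_skew_trend
        skew_t = np.clip(rng.normal(0.0, spec.skew_sd, G), -1.3, 1.3)
        skew_t[noise] = np.clip(rng.normal(0.0, 2.0 * spec.skew_sd, n_noise), -2.5, 2.5)
        trend_k = c0 + c1 * skew_t + c2 * skew_t**2
        floor_k = fleishman_feasible_kurtosis(skew_t) + 0.02
        # symmetric truncation keeps E[K | S] exactly on the trend: the
        # jitter band is shrunk to the feasible head-room on both sides
        sigma = spec.kurt_jitter_sd
        if sigma > 0:
            half = np.clip(trend_k - floor_k, 1e-9, 3.0 * sigma)
            eps = scipy_truncnorm.rvs(
                -half / sigma, half / sigma, scale=sigma, size=G, random_state=rng
            )
        else:
            eps = np.zeros(G)
        kurt_t = np.maximum(trend_k + eps, floor_k)
        kurt_t[noise] += np.abs(rng.normal(0.0, 2.0, n_noise))

    values = np.empty((G, N))
    params_out: list[str] = []
    n_components = np.ones(G, dtype=int)

    for g in range(G):
        m, s = float(means[g]), float(sds[g])
        if degenerate[g]:
            values[g] = m
            params_out.append(json.dumps({"value": m}))
            continue
        if mixture[g]:
            k = int(rng.integers(2, 4))
            offsets = np.array([-1.5, 1.5]) if k == 2 else np.array([-2.0, 0.0, 2.0])
            comp_means = m + s * offsets
            comp_sd = 0.5 * s
            comp = rng.integers(0, k, N)
            values[g] = rng.normal(comp_means[comp], comp_sd)
            n_components[g] = k
            params_out.append(
                json.dumps({"means": comp_means.tolist(), "sd": comp_sd, "k": k})
            )
        elif use_trend:
            coef = fleishman_coefficients(float(skew_t[g]), float(kurt_t[g]))
            z = rng.standard_normal(N)
            y = coef[0] + coef[1] * z + coef[2] * z**2 + coef[3] * z**3
            values[g] = m + s * y
            params_out.append(json.dumps({"abcd": [round(v, 10) for v in coef]}))
        else:
            draws, pars = _sample_named_family(rng, str(families[g]), m, s, N)
            values[g] = draws
            params_out.append(json.dumps({k: float(v) for k, v in pars.items()}))

    # condition-dependent location shifts for affected genes
    cond_of = spec.condition_map().assignments
    labels = list(spec.condition_labels)
    col_level = np.array([labels.index(cond_of[s_]) for s_ in sample_ids], dtype=float)
    J = len(labels)
    if J > 1 and affected.any():
        centered = col_level / (J - 1) - 0.5  # spans exactly affected_effect
        eff = spec.affected_effect * (sds if spec.affected_effect_in_sd else np.ones(G))
        values[affected] += eff[affected, None] * centered[None, :]

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, spec.mode)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "family": families,
            "params": params_out,
            "mean": means,
            "sd": sds,
            "skewness": skew_t,
            "kurtosis": kurt_t,
            "n_components": n_components,
            "affected": affected,
            "noise": noise,
            "mixture": mixture,
            "degenerate": degenerate,
        }
    ).set_index("gene")
    return matrix, truth


def write_truth_table(truth: TruthTable, path) -> None:
    truth.to_csv(path, sep="\t")
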