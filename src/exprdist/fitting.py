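"""Maximum-likelihood fitting of candidate univariate families and normal
mixtures (EM).

Eight families are supported: normal, lognormal, logistic, log-logistic,
Weibull, extreme value (minimum-type Gumbel by default), gamma and Pareto.
The positive-support families (lognormal, log-logistic, Weibull, gamma,
Pareto) require strictly positive data, so in log-ratio mode — where values
can be negative — only normal, logistic and extreme value apply.

Closed forms are used where they exist (normal; lognormal/log-logistic via
the log transform; Pareto).  Gamma shape is solved by Newton iteration on
the profile log-likelihood; logistic, Weibull and Gumbel use scipy's
numerical MLE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import polygamma, psi

from .datatypes import DegenerateDataError, DomainError

__all__ = [
    "DistFamily",
    "FitResult",
    "MixtureFit",
    "fit_mle",
    "frozen_dist",
    "fit_mixture_em",
    "POSITIVE_SUPPORT",
    "REAL_SUPPORT",
]


class DistFamily(str, enum.Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    LOGISTIC = "logistic"
    LOGLOGISTIC = "loglogistic"
    WEIBULL = "weibull"
    EXTREME_VALUE = "extreme_value"
    GAMMA = "gamma"
    PARETO = "pareto"


POSITIVE_SUPPORT = frozenset(
    {
        DistFamily.LOGNORMAL,
        DistFamily.LOGLOGISTIC,
        DistFamily.WEIBULL,
        DistFamily.GAMMA,
        DistFamily.PARETO,
    }
)
REAL_SUPPORT = frozenset(
    {DistFamily.NORMAL, DistFamily.LOGISTIC, DistFamily.EXTREME_VALUE}
)


@dataclass
class FitResult:
    family: DistFamily
    params: dict[str, float]
    loglik: float
    n: int
    converged: bool = True


def _check(values: np.ndarray, family: DistFamily) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("fit_mle needs a 1-D sample with n >= 3")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("constant data: no scale to estimate")
    if family in POSITIVE_SUPPORT and np.min(x) <= 0.0:
        raise DomainError(f"{family.value} requires strictly positive data")
    return x


def fit_mle(values, family: DistFamily, max_type: bool = False) -> FitResult:
    """Maximum-likelihood fit of one family to one sample.

    Scale parameters use the 1/n (plug-in) convention where closed forms
    apply (e.g. the normal sigma-hat).  `max_type=True` switches the extreme
    value family from the default minimum-type Gumbel to the maximum type.
    """
    family = DistFamily(family)
    x = _check(values, family)
    n = x.size

    if family is DistFamily.NORMAL:
        mu, sigma = float(x.mean()), float(x.std())
        params = {"mu": mu, "sigma": sigma}
    elif family is DistFamily.LOGNORMAL:
        lx = np.log(x)
        params = {"mu_log": float(lx.mean()), "sigma_log": float(lx.std())}
    elif family is DistFamily.LOGISTIC:
        loc, scale = stats.logistic.fit(x)
        params = {"loc": float(loc), "scale": float(scale)}
    elif family is DistFamily.LOGLOGISTIC:
        loc, scale = stats.logistic.fit(np.log(x))
        params = {"mu_log": float(loc), "scale_log": float(scale)}
    elif family is DistFamily.WEIBULL:
        c, _, scale = stats.weibull_min.fit(x, floc=0.0)
        params = {"shape": float(c), "scale": float(scale)}
    elif family is DistFamily.EXTREME_VALUE:
        dist = stats.gumbel_r if max_type else stats.gumbel_l
        loc, scale = dist.fit(x)
        params = {"loc": float(loc), "scale": float(scale), "max_type": float(max_type)}
    elif family is DistFamily.GAMMA:
        params = _fit_gamma(x)
    elif family is DistFamily.PARETO:
        xm = float(x.min())
        alpha = n / float(np.sum(np.log(x / xm)))
        params = {"xm": xm, "alpha": alpha}
    else:  # pragma: no cover
        raise ValueError(family)

    fit = FitResult(family=family, params=params, loglik=0.0, n=n)
    fit.loglik = float(np.sum(frozen_dist(fit).logpdf(x)))
    fit.converged = np.isfinite(fit.loglik)
    return fit


def _fit_gamma(x: np.ndarray) -> dict[str, float]:
    """Gamma MLE: Newton iteration on the shape profile log-likelihood.

    Solves ln(k) - psi(k) = s with s = ln(mean) - mean(ln x), starting from
    the standard approximation k0 = (3 - s + sqrt((s-3)^2 + 24 s)) / (12 s).
    """
    s = float(np.log(x.mean()) - np.mean(np.log(x)))
    if s <= 0:  # numerically degenerate (near-constant data)
        raise DegenerateDataError("gamma profile degenerate: ln(mean) <= mean(ln x)")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(k) - psi(k) - s
        fprime = 1.0 / k - polygamma(1, k)
        step = f / fprime
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return {"shape": float(k), "scale": float(x.mean() / k)}


def frozen_dist(fit: FitResult):
    """scipy frozen distribution for a fit (cdf / rvs / logpdf)."""
    f, p = fit.family, fit.params
    if f is DistFamily.NORMAL:
        return stats.norm(p["mu"], p["sigma"])
    if f is DistFamily.LOGNORMAL:
        return stats.lognorm(p["sigma_log"], scale=np.exp(p["mu_log"]))
    if f is DistFamily.LOGISTIC:
        return stats.logistic(p["loc"], p["scale"])
    if f is DistFamily.LOGLOGISTIC:
        return stats.fisk(1.0 / p["scale_log"], scale=np.exp(p["mu_log"]))
    if f is DistFamily.WEIBULL:
        return stats.weibull_min(p["shape"], scale=p["scale"])
    if f is DistFamily.EXTREME_VALUE:
        dist = stats.gumbel_r if p.get("max_type", 0.0) else stats.gumbel_l
        return dist(p["loc"], p["scale"])
    if f is DistFamily.GAMMA:
        return stats.gamma(p["shape"], scale=p["scale"])
    if f is DistFamily.PARETO:
        return stats.pareto(p["alpha"], scale=p["xm"])
    raise ValueError(f)


# ---------------------------------------------------------------------------
# normal mixtures via EM
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        return stats.norm.cdf(z) @ self.weights

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        comp = stats.norm.logpdf(z) - np.log(self.sds) + np.log(self.weights)
        m = comp.max(axis=-1, keepdims=True)
        return (m + np.log(np.exp(comp - m).sum(axis=-1, keepdims=True))).squeeze(-1)


def fit_mixture_grouped_ml(
    counts: np.ndarray, edges: np.ndarray, k: int, init: "MixtureFit"
) -> "MixtureFit":
    """Fit a k-component normal mixture to binned counts by multinomial ML.

    This is the grouped-data route classically used for chi-square
    mixture comparisons: with parameters estimated from the same counts the
    statistic is asymptotically chi-square with df = bins - 1 - (3k - 1),
    which does not hold for ungrouped (EM) estimates.

    `edges` are bins+1 boundaries (outer ones may be +-inf); `init` supplies
    starting values (typically an ungrouped EM fit).
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    n = counts.sum()

    def unpack(theta):
        logits = np.concatenate([theta[: k - 1], [0.0]])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        means = theta[k - 1 : 2 * k - 1]
        sds = np.exp(theta[2 * k - 1 :])
        return w, means, sds

    def cell_probs(theta):
        w, means, sds = unpack(theta)
        cdf = stats.norm.cdf((edges[:, None] - means) / sds) @ w
        p = np.diff(cdf)
        return np.clip(p, 1e-300, 1.0)

    def negll(theta):
        return -np.sum(counts * np.log(cell_probs(theta)))

    theta0 = np.concatenate(
        [
            np.log(np.clip(init.weights[:-1] / init.weights[-1], 1e-8, 1e8)),
            init.means,
            np.log(np.maximum(init.sds, 1e-12)),
        ]
    )
    from scipy.optimize import minimize

    bounds = (
        [(-30.0, 30.0)] * (k - 1)
        + [(None, None)] * k
        + [(np.log(1e-8), np.log(1e8))] * k
    )
    res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    best = res.x if res.fun <= negll(theta0) else theta0
    w, means, sds = unpack(best)
    order = np.argsort(means)
    fit = MixtureFit(
        k=k,
        weights=w[order],
        means=means[order],
        sds=sds[order],
        loglik=float(-negll(best)),
        converged=bool(res.success or np.isfinite(res.fun)),
    )
    fit.cell_probs = cell_probs(best)  # type: ignore[attr-defined]
    fit.n = n  # type: ignore[attr-defined]
    return fit


def fit_mixture_em(
    values,
    k: int,
    n_restarts: int = 5,
    seed=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MixtureFit:
    """Fit a k-component normal mixture by EM with random restarts.

    Each restart initializes component means from k distinct data quantiles
    jittered by the rng, runs EM to a relative log-likelihood tolerance
    (`tol`), and the best-likelihood restart is returned.  Component sds are
    floored at 1e-6 of the data sd to avoid degenerate spikes.  k=1 reduces
    exactly to the normal MLE.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5 * k:
        raise ValueError(f"need n >= 5k = {5 * k} observations")
    n = x.size
    data_sd = float(x.std())
    if data_sd == 0.0:
        raise DegenerateDataError("constant data")
    sd_floor = 1e-6 * data_sd

    if k == 1:
        mu, sd = float(x.mean()), data_sd
        ll = float(np.sum(stats.norm.logpdf(x, mu, sd)))
        return MixtureFit(1, np.array([1.0]), np.array([mu]), np.array([sd]), ll, True, 0, [ll])

    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for restart in range(n_restarts):
        qs = np.linspace(0.5 / k, 1 - 0.5 / k, k) + rng.uniform(-0.2 / k, 0.2 / k, k)
        means = np.quantile(x, np.clip(qs, 0.0, 1.0))
        sds = np.full(k, data_sd / k + sd_floor)
        weights = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        path: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E step
            logc = (
                stats.norm.logpdf((x[:, None] - means) / sds)
                - np.log(sds)
                + np.log(weights)
            )
            m = logc.max(axis=1, keepdims=True)
            lse = m + np.log(np.exp(logc - m).sum(axis=1, keepdims=True))
            resp = np.exp(logc - lse)
            ll = float(lse.sum())
            path.append(ll)
            # M step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), sd_floor)
            if np.isfinite(ll) and ll - ll_prev <= tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        cand = MixtureFit(k, weights, means, sds, path[-1], converged, it, path)
        if best is None or cand.loglik > best.loglik:
            best = cand
    assert best is not None
    if not np.isfinite(best.loglik):
        best.converged = False
    return best
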