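"""Registry of the fitted lifetime models: NE-W and its nine competitors.

Each entry is a :class:`ModelSpec` bundling the model's parameter names,
cdf, log-density, and a deterministic data-driven starting point for the
optimizer.  All models live on x >= 0 with strictly positive parameters;
the alpha-power models additionally exclude a single degenerate parameter
value (alpha1 = 1 for APTW, alpha1 = e for Ex-APTW), which the numerics
handle by continuity / exclusion.

Registered names: ``new`` (NE-Weibull), ``weibull``, ``fwe`` (flexible
Weibull extension), ``aptw`` (alpha power transformed Weibull), ``mow``
(Marshall-Olkin Weibull), ``mw`` (modified/additive Weibull), ``exaptw``
(extended alpha power transformed Weibull), ``kuw`` (Kumaraswamy Weibull),
``bw`` (beta Weibull), ``lomax``, ``burr`` (Burr XII).

The Weibull kernel everywhere is F = 1 - exp(-gamma * x**alpha) (rate-like
gamma).  Lomax uses the scale form G = 1 - (1 + x/gamma)**(-alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

from .family import new_weibull

__all__ = [
    "ModelSpec",
    "REGISTRY",
    "get_model",
    "competitor_cdf",
    "competitor_pdf",
    "model_quantile",
    "weibull_lsq_init",
]


@dataclass(frozen=True)
class ModelSpec:
    """A parametric lifetime model as seen by the fitting machinery."""

    name: str
    param_names: tuple[str, ...]
    cdf: Callable[[np.ndarray, np.ndarray], np.ndarray]  # (params, x) -> G
    logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    init: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    support_low: float = 0.0

    @property
    def k(self) -> int:
        return len(self.param_names)

    def pdf(self, params, x):
        with np.errstate(over="ignore"):
            return np.exp(self.logpdf(params, x))

    def validate(self, params) -> np.ndarray:
        params = np.atleast_1d(np.asarray(params, dtype=float))
        if params.shape != (self.k,):
            raise ValueError(
                f"{self.name} expects {self.k} parameters {self.param_names}, "
                f"got {params.shape[0]}"
            )
        if not np.all(params > 0):
            raise ValueError(f"{self.name} parameters must all be > 0: {params}")
        return params


def _as_x(x):
    return np.asarray(x, dtype=float)


def _weib_F(alpha, gamma, x):
    return -np.expm1(-gamma * np.maximum(x, 0.0) ** alpha)


def _weib_logsf(alpha, gamma, x):
    return -gamma * np.maximum(x, 0.0) ** alpha


def _weib_logpdf(alpha, gamma, x):
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(alpha * gamma) + (alpha - 1.0) * np.log(x) - gamma * np.abs(x) ** alpha
    return np.where(x > 0, lp, -np.inf)


def _guard(x, values, fill=0.0):
    out = np.where(x > 0, values, fill)
    return out[()] if np.ndim(out) == 0 else out


# --- individual models --------------------------------------------------

def _new_cdf(p, x):
    return new_weibull(p[2], p[0], p[1]).cdf(_as_x(x))


def _new_logpdf(p, x):
    return new_weibull(p[2], p[0], p[1]).logpdf(_as_x(x))


def _weibull_cdf(p, x):
    x = _as_x(x)
    return _guard(x, _weib_F(p[0], p[1], x))


def _weibull_logpdf(p, x):
    return _weib_logpdf(p[0], p[1], _as_x(x))


def _fwe_cdf(p, x):
    alpha, sigma, gamma = p
    x = _as_x(x)
    with np.errstate(divide="ignore", over="ignore"):
        h = sigma * x * x - gamma * np.abs(x) ** (-alpha)
        val = -np.expm1(-np.exp(h))
    return _guard(x, val)


def _fwe_logpdf(p, x):
    alpha, sigma, gamma = p
    x = _as_x(x)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        h = sigma * x * x - gamma * np.abs(x) ** (-alpha)
        lp = np.log(2.0 * sigma * x + alpha * gamma * np.abs(x) ** (-alpha - 1.0)) + h - np.exp(h)
    return _guard(x, lp, -np.inf)


def _aptw_cdf(p, x):
    alpha1, alpha, gamma = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    la = np.log(alpha1)
    if abs(la) < 1e-10:  # continuity limit alpha1 -> 1: G -> F
        return _guard(x, F)
    return _guard(x, np.expm1(F * la) / np.expm1(la))


def _aptw_logpdf(p, x):
    alpha1, alpha, gamma = p
    x = _as_x(x)
    la = np.log(alpha1)
    lf = _weib_logpdf(alpha, gamma, x)
    if abs(la) < 1e-10:
        return lf
    F = _weib_F(alpha, gamma, x)
    # la / (alpha1 - 1) > 0 for every alpha1 != 1
    return _guard(x, lf + F * la + np.log(la / np.expm1(la)), -np.inf)


def _mow_cdf(p, x):
    alpha, gamma, sigma = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    return _guard(x, F / (sigma + (1.0 - sigma) * F))


def _mow_logpdf(p, x):
    alpha, gamma, sigma = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    lf = _weib_logpdf(alpha, gamma, x)
    return _guard(x, np.log(sigma) + lf - 2.0 * np.log(sigma + (1.0 - sigma) * F), -np.inf)


def _mw_cdf(p, x):
    alpha, gamma, theta = p
    x = _as_x(x)
    return _guard(x, -np.expm1(-theta * x - gamma * np.abs(x) ** alpha))


def _mw_logpdf(p, x):
    alpha, gamma, theta = p
    x = _as_x(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (
            np.log(theta + alpha * gamma * np.abs(x) ** (alpha - 1.0))
            - theta * x
            - gamma * np.abs(x) ** alpha
        )
    return _guard(x, lp, -np.inf)


_E = float(np.e)


def _exaptw_cdf(p, x):
    alpha1, alpha, gamma = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    with np.errstate(over="ignore"):
        val = (alpha1 ** F - np.exp(F)) / (alpha1 - _E)
    return _guard(x, val)


def _exaptw_logpdf(p, x):
    alpha1, alpha, gamma = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    lf = _weib_logpdf(alpha, gamma, x)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        num = alpha1 ** F * np.log(alpha1) - np.exp(F)
        lp = lf + np.log(num / (alpha1 - _E))
    return _guard(x, lp, -np.inf)


def _kuw_cdf(p, x):
    alpha, gamma, a, b = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    with np.errstate(divide="ignore"):
        val = -np.expm1(b * np.log1p(-np.abs(F) ** a))
    return _guard(x, val)


def _kuw_logpdf(p, x):
    alpha, gamma, a, b = p
    x = _as_x(x)
    logsf = _weib_logsf(alpha, gamma, x)
    sfw = np.exp(logsf)
    logF = np.log1p(-sfw)
    lf = _weib_logpdf(alpha, gamma, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        # log(1 - F^a); in the far tail 1 - F^a ~ a*sf, which stays finite
        # in log space after float F has rounded to 1
        log1mFa = np.where(
            sfw > 1e-15, np.log(-np.expm1(a * logF)), np.log(a) + logsf
        )
        lp = np.log(a * b) + lf + (a - 1.0) * logF + (b - 1.0) * log1mFa
    return _guard(x, lp, -np.inf)


def _bw_cdf(p, x):
    alpha, gamma, a, b = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    return _guard(x, special.betainc(a, b, F))


def _bw_logpdf(p, x):
    alpha, gamma, a, b = p
    x = _as_x(x)
    F = _weib_F(alpha, gamma, x)
    lf = _weib_logpdf(alpha, gamma, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (
            lf
            + (a - 1.0) * np.log(F)
            + (b - 1.0) * _weib_logsf(alpha, gamma, x)
            - special.betaln(a, b)
        )
    return _guard(x, lp, -np.inf)


def _lomax_cdf(p, x):
    alpha, gamma = p
    x = _as_x(x)
    return _guard(x, -np.expm1(-alpha * np.log1p(np.maximum(x, 0.0) / gamma)))


def _lomax_logpdf(p, x):
    alpha, gamma = p
    x = _as_x(x)
    lp = np.log(alpha / gamma) - (alpha + 1.0) * np.log1p(np.maximum(x, 0.0) / gamma)
    return _guard(x, lp, -np.inf)


def _burr_cdf(p, x):
    c, k = p
    x = _as_x(x)
    return _guard(x, -np.expm1(-k * np.log1p(np.maximum(x, 0.0) ** c)))


def _burr_logpdf(p, x):
    c, k = p
    x = _as_x(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(c * k) + (c - 1.0) * np.log(x) - (k + 1.0) * np.log1p(np.abs(x) ** c)
    return _guard(x, lp, -np.inf)


# --- starting points ------------------------------------------------------

def weibull_lsq_init(data: np.ndarray) -> tuple[float, float]:
    """Weibull (alpha, gamma) start from a least-squares fit of the
    empirical log-log survival: log(-log S_n(x)) = log gamma + alpha log x.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    p = (np.arange(1, n + 1) - 0.5) / n  # midpoint plotting positions
    keep = x > 0
    lx = np.log(x[keep])
    ly = np.log(-np.log1p(-p[keep]))
    if lx.size < 2 or np.ptp(lx) == 0:
        return 1.0, 1.0 / max(float(np.mean(x)), 1e-12)
    slope, intercept = np.polyfit(lx, ly, 1)
    alpha = float(np.clip(slope, 1e-3, 1e3))
    gamma = float(np.clip(np.exp(intercept), 1e-12, 1e12))
    return alpha, gamma


def _mk_init(fn):
    def init(data):
        return np.asarray(fn(np.asarray(data, dtype=float)), dtype=float)

    return init


def _init_new(d):
    # profile theta over a coarse grid at the Weibull-regression (a, gamma);
    # the likelihood ridge in (gamma, theta) makes a single theta=1 start
    # land in local optima on some samples
    a, g = weibull_lsq_init(d)
    with np.errstate(all="ignore"):
        lls = [
            (float(np.sum(new_weibull(th, a, g).logpdf(d))), th)
            for th in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
    best = max(ll for ll in lls if np.isfinite(ll[0]))
    return (a, g, best[1])


def _init_weibull(d):
    return weibull_lsq_init(d)


def _init_fwe(d):
    m = float(np.mean(d))
    return (1.0, 0.5 / (m * m + 1e-12), m)


def _init_aptw(d):
    a, g = weibull_lsq_init(d)
    return (2.0, a, g)


def _init_mow(d):
    a, g = weibull_lsq_init(d)
    return (a, g, 1.0)


def _init_mw(d):
    a, g = weibull_lsq_init(d)
    return (a, 0.5 * g, 0.5 / max(float(np.mean(d)), 1e-12))


def _init_exaptw(d):
    a, g = weibull_lsq_init(d)
    return (1.0, a, g)


def _init_kuw(d):
    a, g = weibull_lsq_init(d)
    return (a, g, 1.0, 1.0)


def _init_bw(d):
    a, g = weibull_lsq_init(d)
    return (a, g, 1.0, 1.0)


def _init_lomax(d):
    return (2.0, max(float(np.mean(d)), 1e-12))


def _init_burr(d):
    return (1.0, 1.0)


REGISTRY: dict[str, ModelSpec] = {
    s.name: s
    for s in [
        ModelSpec("new", ("alpha", "gamma", "theta"), _new_cdf, _new_logpdf, _mk_init(_init_new)),
        ModelSpec("weibull", ("alpha", "gamma"), _weibull_cdf, _weibull_logpdf, _mk_init(_init_weibull)),
        ModelSpec("fwe", ("alpha", "sigma", "gamma"), _fwe_cdf, _fwe_logpdf, _mk_init(_init_fwe)),
        ModelSpec("aptw", ("alpha1", "alpha", "gamma"), _aptw_cdf, _aptw_logpdf, _mk_init(_init_aptw)),
        ModelSpec("mow", ("alpha", "gamma", "sigma"), _mow_cdf, _mow_logpdf, _mk_init(_init_mow)),
        ModelSpec("mw", ("alpha", "gamma", "theta"), _mw_cdf, _mw_logpdf, _mk_init(_init_mw)),
        ModelSpec("exaptw", ("alpha1", "alpha", "gamma"), _exaptw_cdf, _exaptw_logpdf, _mk_init(_init_exaptw)),
        ModelSpec("kuw", ("alpha", "gamma", "a", "b"), _kuw_cdf, _kuw_logpdf, _mk_init(_init_kuw)),
        ModelSpec("bw", ("alpha", "gamma", "a", "b"), _bw_cdf, _bw_logpdf, _mk_init(_init_bw)),
        ModelSpec("lomax", ("alpha", "gamma"), _lomax_cdf, _lomax_logpdf, _mk_init(_init_lomax)),
        ModelSpec("burr", ("c", "k"), _burr_cdf, _burr_logpdf, _mk_init(_init_burr)),
    ]
}


def get_model(name: str) -> ModelSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


def competitor_cdf(name: str, params, x):
    spec = get_model(name)
    return spec.cdf(spec.validate(params), x)


def competitor_pdf(name: str, params, x):
    spec = get_model(name)
    return spec.pdf(spec.validate(params), x)


def model_quantile(name: str, params, p: float) -> float:
    """Numeric quantile for any registered model (bracketed root finding)."""
    spec = get_model(name)
    params = spec.validate(params)
    p = float(p)
    if not 0 <= p < 1:
        raise ValueError("quantile argument must lie in [0, 1)")
    if p == 0.0:
        return spec.support_low
    hi = 1.0
    while spec.cdf(params, hi) < p:
        hi *= 2.0
        if hi > 1e300:  # pragma: no cover
            raise RuntimeError("failed to bracket quantile")
    return float(
        optimize.brentq(lambda x: spec.cdf(params, x) - p, 0.0, hi, xtol=1e-12, rtol=1e-14)
    )
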