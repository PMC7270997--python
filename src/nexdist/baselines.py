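"""Baseline (parent) distributions that the NE-X generator extends.

A baseline is any absolutely continuous lifetime distribution with cdf
``F(x; xi)`` on ``[support_low, inf)``.  The generator only needs the cdf,
pdf and (ideally closed-form) quantile of the parent; everything else is
derived.  :class:`Weibull` is the parent used throughout, with the
rate-like parameterization ``F(x) = 1 - exp(-gamma * x**a)``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["Baseline", "Weibull"]


class Baseline:
    """Abstract parent distribution.

    Subclasses must implement :meth:`cdf` and :meth:`logpdf`; the remaining
    methods have generic (numeric) fallbacks.  Parameters are exposed through
    ``params`` as an ordered name -> value mapping.
    """

    name: str = "baseline"
    support_low: float = 0.0

    @property
    def params(self) -> dict[str, float]:
        raise NotImplementedError

    def cdf(self, x):
        raise NotImplementedError

    def logpdf(self, x):
        raise NotImplementedError

    def pdf(self, x):
        with np.errstate(over="ignore"):
            return np.exp(self.logpdf(x))

    def sf(self, x):
        return 1.0 - self.cdf(x)

    def logsf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.sf(x))

    def quantile_from_log_sf(self, log_sf):
        """Inverse of the log-survival function.

        Subclasses with a closed form should override; the fallback converts
        to probability space and loses resolution once exp(log_sf)
        underflows.
        """
        return self.quantile(-np.expm1(log_sf))

    def quantile(self, p):
        """Numeric inverse cdf by bracketed root finding.

        Used only when a subclass has no closed form.  The bracket is grown
        geometrically from the support lower end; tolerance is 1e-10 in
        probability (via ``xtol`` on a monotone cdf).
        """
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("quantile argument must lie in [0, 1)")

        def _scalar(pi: float) -> float:
            if pi == 0.0:
                return self.support_low
            lo = self.support_low
            hi = max(lo + 1.0, 1.0)
            while self.cdf(hi) < pi:
                hi = lo + 2.0 * (hi - lo)
                if hi > 1e300:  # pragma: no cover - pathological parent
                    raise RuntimeError("failed to bracket quantile")
            return optimize.brentq(
                lambda x: self.cdf(x) - pi, lo, hi, xtol=1e-12, rtol=1e-14
            )

        if p.ndim == 0:
            return _scalar(float(p))
        return np.array([_scalar(pi) for pi in p.ravel()]).reshape(p.shape)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"{type(self).__name__}({inner})"


class Weibull(Baseline):
    """Two-parameter Weibull parent, ``F(x) = 1 - exp(-gamma * x**a)``.

    Parameters
    ----------
    a : float
        Shape, > 0.
    gamma : float
        Rate-like scale, > 0 (multiplies ``x**a`` in the exponent; this is
        *not* scipy's ``scale`` convention).
    """

    name = "weibull"

    def __init__(self, a: float, gamma: float):
        a = float(a)
        gamma = float(gamma)
        if not (a > 0 and gamma > 0):
            raise ValueError("Weibull requires a > 0 and gamma > 0")
        self.a = a
        self.gamma = gamma

    @property
    def params(self) -> dict[str, float]:
        return {"a": self.a, "gamma": self.gamma}

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > 0, -np.expm1(-self.gamma * np.maximum(x, 0.0) ** self.a), 0.0)
        return out[()] if out.ndim == 0 else out

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > 0, np.exp(-self.gamma * np.maximum(x, 0.0) ** self.a), 1.0)
        return out[()] if out.ndim == 0 else out

    def logsf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x > 0, -self.gamma * np.maximum(x, 0.0) ** self.a, 0.0)
        return out[()] if out.ndim == 0 else out

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (
                np.log(self.a * self.gamma)
                + (self.a - 1.0) * np.log(x)
                - self.gamma * np.abs(x) ** self.a
            )
        out = np.where(x > 0, lp, -np.inf)
        return out[()] if out.ndim == 0 else out

    def quantile(self, p):
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("quantile argument must lie in [0, 1)")
        out = (-np.log1p(-p) / self.gamma) ** (1.0 / self.a)
        return out[()] if out.ndim == 0 else out

    def quantile_from_log_sf(self, log_sf):
        log_sf = np.asarray(log_sf, dtype=float)
        if np.any(log_sf > 0):
            raise ValueError("log survival must be <= 0")
        out = (-log_sf / self.gamma) ** (1.0 / self.a)
        return out[()] if out.ndim == 0 else out
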