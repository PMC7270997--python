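"""The NE-X generator: a one-parameter extension of any baseline cdf.

Given a parent distribution with cdf ``F`` and pdf ``f``, the extended
distribution has

    cdf       G(x) = 1 - [ (1 - F^2) / (1 - (1-theta) F^2) ]^theta
    pdf       g(x) = 2 theta^2 f F (1 - F^2)^(theta-1) / (1 - (1-theta) F^2)^(theta+1)
    survival  S(x) = [ (1 - F^2) / (1 - (1-theta) F^2) ]^theta

with extension parameter ``theta > 0``.  At ``theta = 1`` the family reduces
to the exponentiated family ``G = F^2`` (the maximum of two iid parent
draws).  The quantile is closed-form whenever the parent's is:

    x_q = F^{-1}( sqrt( (1 - w) / (1 - (1-theta) w) ) ),   w = (1-u)^(1/theta).

All powers are evaluated in log space (``log1p``/``expm1``) so that large
``theta`` and ``F`` near 1 do not overflow or cancel.
"""

from __future__ import annotations

import numpy as np

from .baselines import Baseline, Weibull

__all__ = [
    "NewExtended",
    "new_weibull",
    "nex_cdf",
    "nex_pdf",
    "nex_sf",
    "nex_hazard",
    "nex_quantile",
    "nex_sample",
]


class NewExtended:
    """NE-X distribution: ``baseline`` extended by ``theta > 0``.

    Parameters
    ----------
    theta : float
        Extension parameter, strictly positive.  Acts as both a scale- and
        shape-like parameter; the survival function is strictly decreasing
        in ``theta`` at every fixed ``x``.
    baseline : Baseline
        Parent distribution supplying ``F``, ``f`` and (optionally) a
        closed-form quantile.
    """

    def __init__(self, theta: float, baseline: Baseline):
        theta = float(theta)
        if not theta > 0:
            raise ValueError(f"theta must be > 0, got {theta}")
        self.theta = theta
        self.baseline = baseline

    @property
    def support_low(self) -> float:
        return self.baseline.support_low

    @property
    def params(self) -> dict[str, float]:
        out = dict(self.baseline.params)
        out["theta"] = self.theta
        return out

    # -- internal pieces ---------------------------------------------------

    def _log_A_B(self, x):
        """log(1-F^2) and log(1-(1-theta)F^2), the two factors of log S.

        1-F^2 = (1-F)(1+F) is taken through the baseline survival function
        so it never cancels; the second factor is bounded below by
        min(theta, 1) > 0 and is safe in ``log1p``.
        """
        F = np.asarray(self.baseline.cdf(x), dtype=float)
        logA = self.baseline.logsf(x) + np.log1p(F)
        logB = np.log1p(-(1.0 - self.theta) * F * F)
        return F, logA, logB

    # -- distribution functions -------------------------------------------

    def logsf(self, x):
        _, logA, logB = self._log_A_B(x)
        return self.theta * (logA - logB)

    def sf(self, x):
        """Survival function, computed directly in power form (no 1-cdf)."""
        return np.exp(self.logsf(x))

    def cdf(self, x):
        out = -np.expm1(self.logsf(x))
        return out[()] if np.ndim(out) == 0 else out

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        F, logA, logB = self._log_A_B(x)
        with np.errstate(divide="ignore"):
            lp = (
                np.log(2.0)
                + 2.0 * np.log(self.theta)
                + self.baseline.logpdf(x)
                + np.log(F)
                + (self.theta - 1.0) * logA
                - (self.theta + 1.0) * logB
            )
        out = np.where(x > self.support_low, lp, -np.inf)
        return out[()] if out.ndim == 0 else out

    def pdf(self, x):
        out = np.exp(self.logpdf(x))
        return out[()] if np.ndim(out) == 0 else out

    def hazard(self, x):
        """Hazard rate g/S; raises where the survival function is zero."""
        logsf = self.logsf(x)
        if np.any(np.isneginf(logsf)):
            raise ValueError("hazard undefined where the survival function is 0")
        out = np.exp(self.logpdf(x) - logsf)
        return out[()] if np.ndim(out) == 0 else out

    def ppf(self, u):
        """Quantile function on [0, 1).

        Uses the algebraic form F^2 = (1-w)/(1-(1-theta)w), w=(1-u)^(1/theta),
        which is regular at theta = 1 (where it collapses to F = sqrt(u)).
        """
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u >= 1)):
            raise ValueError("quantile argument must lie in [0, 1)")
        log_w = np.log1p(-u) / self.theta
        w = np.exp(log_w)
        one_minus_w = -np.expm1(log_w)
        log_denom = np.log1p(-(1.0 - self.theta) * w)
        F2 = one_minus_w * np.exp(-log_denom)
        # 1 - F^2 = theta*w/denom, so the parent's survival 1 - F is
        # available in log space even after F^2 has rounded to 1 (small
        # theta pushes w into the denormal range long before u reaches 1)
        log_1m_F2 = np.log(self.theta) + log_w - log_denom
        log_sf_parent = log_1m_F2 - np.log1p(np.sqrt(np.clip(F2, 0.0, 1.0)))
        out = self.baseline.quantile_from_log_sf(np.minimum(log_sf_parent, 0.0))
        return out[()] if isinstance(out, np.ndarray) and out.ndim == 0 else out

    def rvs(self, n: int, seed=None):
        """Draw ``n`` variates by inverse-transform sampling.

        Deterministic given ``seed`` (an int or a numpy Generator).  Uniform
        draws are confined to the open interval (0, 1): exact 0 (the only
        value ``Generator.random`` can hit) is redrawn.
        """
        n = int(n)
        if n < 0:
            raise ValueError("sample size must be >= 0")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        u = rng.random(n)
        while True:  # reject endpoints of the uniform draw
            bad = u <= 0.0
            if not bad.any():
                break
            u[bad] = rng.random(int(bad.sum()))
        return self.ppf(u)

    def median(self) -> float:
        return float(self.ppf(0.5))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NewExtended(theta={self.theta:g}, baseline={self.baseline!r})"


def new_weibull(theta: float, a: float, gamma: float) -> NewExtended:
    """The NE-W distribution: NE-X with a Weibull(a, gamma) parent."""
    return NewExtended(theta, Weibull(a, gamma))


# Thin functional aliases over the methods above.

def nex_cdf(model: NewExtended, x):
    return model.cdf(x)


def nex_pdf(model: NewExtended, x):
    return model.pdf(x)


def nex_sf(model: NewExtended, x):
    return model.sf(x)


def nex_hazard(model: NewExtended, x):
    return model.hazard(x)


def nex_quantile(model: NewExtended, u):
    return model.ppf(u)


def nex_sample(model: NewExtended, n: int, seed=None):
    return model.rvs(n, seed)
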