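"""Moments, descriptive measures and the mgf of NE-X models.

Adaptive quadrature is the canonical engine: the integration domain is
split at the distribution median and the upper piece is handled by
``scipy.integrate.quad``'s semi-infinite transformation.  A convergent
series representation in the kernel integrals K_{r,m} = ∫ x^r f F^m dx is
provided as an independent cross-check for integer theta (see
:func:`series_raw_moment` for why integer theta is required and why the
naive termwise expansion must be regrouped before it can be summed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import integrate

from .family import NewExtended

__all__ = [
    "MomentSummary",
    "QuadratureError",
    "raw_moment",
    "series_raw_moment",
    "kernel_integral",
    "describe",
    "mgf",
    "mgf_quadrature",
]

_QUAD_TOL = 1e-10


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature reports non-convergence."""


def _quad(fn, lo, hi, what: str) -> float:
    ret = integrate.quad(
        fn, lo, hi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200, full_output=1
    )
    val, err = ret[0], ret[1]
    if len(ret) > 3:  # quadpack flagged the integral; accept only small error
        if not (np.isfinite(val) and err <= 1e-8 * max(1.0, abs(val))):
            raise QuadratureError(
                f"quadrature failed for {what}: {ret[3]} (value={val!r}, abserr={err!r})"
            )
    return val


def _expectation(model: NewExtended, integrand, what: str) -> float:
    """∫ integrand(x) g(x) dx split at the median, tail to infinity."""
    med = model.median()
    lo = model.support_low

    def h(x):
        return integrand(x) * model.pdf(x)

    return _quad(h, lo, med, what) + _quad(h, med, np.inf, what)


def raw_moment(model: NewExtended, r: int) -> float:
    """r-th raw moment mu'_r = E[X^r] by adaptive quadrature."""
    r = int(r)
    if r < 0:
        raise ValueError("moment order must be >= 0")
    if r == 0:
        return 1.0
    return _expectation(model, lambda x: x**r, f"raw moment r={r}")


def kernel_integral(model: NewExtended, r: int, m: float) -> float:
    """K_{r,m} = ∫ x^r f(x) F(x)^m dx over the baseline support.

    Evaluated in probability space as ∫_0^1 Q_F(p)^r p^m dp, which is exact
    under the substitution p = F(x) and keeps the integrand bounded.
    """
    Qb = model.baseline.quantile
    return _quad(lambda p: Qb(p) ** r * p**m, 0.0, 1.0, f"K({r},{m})")


def _L_integral(model: NewExtended, r: int, m: float) -> float:
    # ∫ x^r f F (1-F^2)^m dx, in probability space; equals the finite
    # alternating sum  Σ_j (-1)^j C(m,j) K_{r,2j+1} when m is an integer.
    Qb = model.baseline.quantile
    return _quad(
        lambda p: Qb(p) ** r * p * (1.0 - p * p) ** m, 0.0, 1.0, f"L({r},{m})"
    )


def series_raw_moment(model: NewExtended, r: int, i_max: int = 60) -> float:
    """Series cross-check of :func:`raw_moment` for integer theta.

    The binomial expansion of (1-F^2)^(theta-1) that underlies the series
    representation terminates only when theta is a positive integer, so any
    other theta is rejected.  The textbook termwise double series — expand
    1/(1-(1-theta)F^2)^(theta+1) in powers of (1-theta)F^2 and integrate
    term by term — has terms growing like C(i+theta,theta)(theta-1)^i and
    diverges for theta >= 2; the expansion is therefore regrouped around the
    value the denominator takes at F = 1:

        1/(1+(theta-1)F^2)^(theta+1)
            = theta^-(theta+1) Σ_i C(i+theta, theta) rho^i (1-F^2)^i,
        rho = (theta-1)/theta < 1,

    which converges on the whole support and gives

        mu'_r = 2 theta^(1-theta) Σ_i C(i+theta, theta) rho^i L_{r, theta-1+i},
        L_{r,m} = ∫ x^r f F (1-F^2)^m dx.

    For integer theta each L is a finite alternating combination of the
    kernel integrals K_{r,m}; it is evaluated directly by quadrature to
    avoid binomial cancellation at large m.
    """
    theta = model.theta
    if abs(theta - round(theta)) > 1e-12 or theta < 1:
        raise ValueError(
            f"series expansion requires a positive integer theta, got {theta}"
        )
    theta = float(round(theta))
    r = int(r)
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    rho = (theta - 1.0) / theta
    total = 0.0
    for i in range(i_max + 1):
        coeff = np.exp(lgamma(i + theta + 1.0) - lgamma(theta + 1.0) - lgamma(i + 1.0))
        term = coeff * rho**i * _L_integral(model, r, theta - 1.0 + i)
        total += term
        if rho > 0 and i > 2 and abs(term) < 1e-14 * max(abs(total), 1.0):
            break
    return 2.0 * theta ** (1.0 - theta) * total


@dataclass(frozen=True)
class MomentSummary:
    """First four moments of a model, Tables-style descriptive measures."""

    params: dict[str, float]
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    raw_moments: tuple[float, float, float, float]  # mu'_1 .. mu'_4

    def to_row(self) -> dict[str, float]:
        """One CSV row: parameters, then Mean, Variance, Sk, Kur."""
        row = dict(self.params)
        row.update(
            Mean=self.mean, Variance=self.variance, Sk=self.skewness, Kur=self.kurtosis
        )
        return row


def describe(model: NewExtended) -> MomentSummary:
    """Mean, variance, skewness and kurtosis by direct quadrature.

    Central moments are integrated directly against (x - mean)^k rather
    than assembled from raw moments, which would cancel catastrophically
    for heavy-tailed parameter values.
    """
    raw = tuple(raw_moment(model, r) for r in range(1, 5))
    mean = raw[0]
    mu = [
        _expectation(model, lambda x, k=k: (x - mean) ** k, f"central moment {k}")
        for k in (2, 3, 4)
    ]
    variance = mu[0]
    if variance < 0:
        raise QuadratureError(f"negative variance from quadrature: {variance}")
    sk = mu[1] / variance**1.5
    kur = mu[2] / variance**2
    return MomentSummary(dict(model.params), mean, variance, sk, kur, raw)


def mgf(model: NewExtended, t: float, r_max: int = 25) -> float:
    """Moment generating function via the moment series Σ t^r mu'_r / r!.

    Terms are monitored; if the tail of the partial sum is still growing at
    ``r_max`` the series is deemed divergent for this ``t``.
    """
    t = float(t)
    if t == 0.0:
        return 1.0
    terms = [1.0]
    log_t = np.log(abs(t))
    for r in range(1, r_max + 1):
        mu_r = raw_moment(model, r)
        terms.append(np.sign(t) ** r * np.exp(r * log_t - lgamma(r + 1.0)) * mu_r)
    tail = np.abs(terms[-3:])
    if not (tail[-1] <= tail[0] and tail[-1] < 1e-6 * max(abs(sum(terms)), 1.0)):
        raise QuadratureError(
            f"moment series for mgf not converged at t={t}, r_max={r_max}"
        )
    return float(np.sum(terms))


def mgf_quadrature(model: NewExtended, t: float) -> float:
    """Direct-quadrature mgf ∫ e^{tx} g(x) dx (oracle for :func:`mgf`).

    The integrand is evaluated as exp(t x + log g(x)) so that a large
    exponential factor against an underflowing density never produces
    inf * 0.
    """
    med = model.median()

    def h(x):
        with np.errstate(over="ignore"):
            return np.exp(t * x + model.logpdf(x))

    what = f"mgf t={t}"
    return _quad(h, model.support_low, med, what) + _quad(h, med, np.inf, what)
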