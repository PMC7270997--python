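"""Model discrimination and goodness-of-fit measures.

AIC/BIC, and the Anderson-Darling (AD), Cramér-von Mises (CM) and
Kolmogorov-Smirnov (KS) distances between the fitted cdf and the empirical
cdf, with the KS p-value from the asymptotic Kolmogorov distribution.

All three distance statistics are computed with the *estimated* parameters
plugged into the fitted cdf, as is conventional in distribution-comparison
tables; the KS p-value therefore inherits the usual anti-conservative
plug-in convention (it is exact only for a fully specified null), which is
recorded in the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .competitors import get_model
from .inference import FitResult, fit_mle

__all__ = [
    "GoFReport",
    "information_criteria",
    "ad_stat",
    "cm_stat",
    "ks_stat",
    "gof_report",
    "compare_models",
    "comparison_table",
]


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2l and BIC = k log n - 2l."""
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return 2.0 * k - 2.0 * loglik, k * np.log(n) - 2.0 * loglik


def _check_sorted_probs(g, open_interval: bool) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("expected a nonempty 1-D vector of fitted cdf values")
    if np.any(np.diff(g) < 0):
        raise ValueError("fitted cdf values must be sorted ascending")
    if open_interval:
        if np.any((g <= 0) | (g >= 1)):
            raise ValueError("fitted cdf values must lie strictly inside (0, 1)")
    elif np.any((g < 0) | (g > 1)):
        raise ValueError("fitted cdf values must lie in [0, 1]")
    return g


def ad_stat(fitted_cdf_values) -> float:
    """Anderson-Darling statistic from sorted fitted cdf values G_(i).

    AD = -n - (1/n) Σ (2i-1) [log G_(i) + log(1 - G_(n-i+1))].
    """
    g = _check_sorted_probs(fitted_cdf_values, open_interval=True)
    n = g.size
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(g) + np.log1p(-g[::-1])))
    return float(-n - s / n)


def cm_stat(fitted_cdf_values) -> float:
    """Cramér-von Mises statistic 1/(12n) + Σ ((2i-1)/(2n) - G_(i))^2."""
    g = _check_sorted_probs(fitted_cdf_values, open_interval=False)
    n = g.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum(((2 * i - 1) / (2.0 * n) - g) ** 2))


def ks_stat(fitted_cdf_values) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and asymptotic p-value.

    D = max_i max( i/n - G_(i), G_(i) - (i-1)/n ), the sup distance between
    the right-continuous empirical cdf and the fitted cdf; the p-value is
    the Kolmogorov survival function at sqrt(n) D.
    """
    g = _check_sorted_probs(fitted_cdf_values, open_interval=False)
    n = g.size
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - g, g - (i - 1) / n)))
    return d, float(special.kolmogorov(np.sqrt(n) * d))


@dataclass
class GoFReport:
    """Per-model goodness-of-fit row plus plotting coordinates."""

    model_name: str
    k: int
    n: int
    fit: FitResult | None
    aic: float = float("nan")
    bic: float = float("nan")
    cm: float = float("nan")
    ad: float = float("nan")
    ks: float = float("nan")
    ks_pvalue: float = float("nan")
    error: str = ""
    pp_points: np.ndarray = field(default=None, repr=False)  # (empirical, fitted)
    km_points: np.ndarray = field(default=None, repr=False)  # (x, empirical survival)
    pvalue_convention: str = "plug-in (estimated parameters); anti-conservative"

    def to_row(self) -> dict:
        return {
            "Dist.": self.model_name,
            "AIC": self.aic,
            "BIC": self.bic,
            "CM": self.cm,
            "AD": self.ad,
            "KS": self.ks,
            "p value": self.ks_pvalue,
        }


def gof_report(fit: FitResult, data) -> GoFReport:
    """Assemble the full GoF report for one fitted model."""
    spec = get_model(fit.model_name)
    x = np.sort(np.asarray(data, dtype=float), kind="stable")
    n = x.size
    g = np.asarray(spec.cdf(fit.theta_hat, x), dtype=float)
    aic, bic = information_criteria(fit.loglik, spec.k, n)
    # keep the AD log arguments off the endpoints; float cdfs can round to 0/1
    g_ad = np.clip(g, 1e-300, 1.0 - 1e-16)
    i = np.arange(1, n + 1)
    d, p = ks_stat(np.clip(g, 0.0, 1.0))
    return GoFReport(
        model_name=fit.model_name,
        k=spec.k,
        n=n,
        fit=fit,
        aic=aic,
        bic=bic,
        cm=cm_stat(np.clip(g, 0.0, 1.0)),
        ad=ad_stat(g_ad),
        ks=d,
        ks_pvalue=p,
        pp_points=np.column_stack([i / (n + 1.0), g]),
        km_points=np.column_stack([x, 1.0 - i / n]),
    )


def compare_models(
    data,
    model_names,
    n_restarts: int = 3,
    seed=None,
) -> list[GoFReport]:
    """Fit each named model to ``data`` and report GoF measures.

    Rows are sorted by AIC ascending; a model whose fit fails contributes a
    row with NaN statistics and the error message rather than aborting the
    comparison.  Each model's restarts use an independent stream derived
    from ``seed`` and the model name, so adding a model to the list leaves
    the other rows identical.
    """
    x = np.asarray(data, dtype=float)
    reports = []
    for name in model_names:
        spec = get_model(name)  # fail fast on unknown names
        model_seed = np.random.SeedSequence(
            entropy=0 if seed is None else int(seed),
            spawn_key=tuple(ord(c) for c in name),
        )
        try:
            fit = fit_mle(name, x, n_restarts=n_restarts, seed=np.random.default_rng(model_seed))
            reports.append(gof_report(fit, x))
        except Exception as exc:  # recorded in-row, not fatal
            reports.append(
                GoFReport(model_name=name, k=spec.k, n=x.size, fit=None, error=str(exc))
            )
    reports.sort(key=lambda r: (np.isnan(r.aic), r.aic))
    return reports


def comparison_table(reports: list[GoFReport]) -> pd.DataFrame:
    """Serialize GoF reports to the standard comparison-table columns."""
    return pd.DataFrame([r.to_row() for r in reports])[
        ["Dist.", "AIC", "BIC", "CM", "AD", "KS", "p value"]
    ]
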