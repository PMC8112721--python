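"""Goodness-of-fit statistics and model-comparison criteria.

Given a sample and a fitted cdf, the classical order-statistic forms with
u_(i) = cdf(x_(i)) are

    KS:   D  = max_i max( i/n - u_(i), u_(i) - (i-1)/n )
    CVM:  W2 = 1/(12n) + sum_i [ u_(i) - (2i-1)/(2n) ]^2
    AD:   A2 = -n - (1/n) sum_i (2i-1) [ log u_(i) + log(1 - u_(n+1-i)) ]

By default (``modified=True``) CVM and AD are computed in the
Chen-Balakrishnan form used throughout the distribution-fitting literature
(e.g. R's AdequacyModel): the u_(i) are mapped through the standard normal
quantile, standardised, mapped back through the normal cdf, and the
small-sample factors W* = W2 (1 + 0.5/n), A* = A2 (1 + 0.75/n + 2.25/n^2)
are applied.  ``modified=False`` gives the plain forms above.  Parameters
are estimated on the same data the statistics are computed on (no
Lilliefors-type correction).

The KS p-value uses the asymptotic Kolmogorov distribution at sqrt(n) D by
default; the exact finite-n two-sided distribution is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "GofReport",
    "ks_statistic",
    "cvm_statistic",
    "ad_statistic",
    "aic",
    "pp_points",
    "ecdf",
    "gof_report",
]

_EPS = 1e-12


def _order_u(data, fitted_cdf) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least one observation")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contain non-finite values")
    u = np.sort(np.asarray(fitted_cdf(np.sort(x)), dtype=float))
    return u


def _normalise_u(u: np.ndarray) -> np.ndarray:
    """Chen-Balakrishnan normality transform of the fitted-cdf values."""
    uc = np.clip(u, _EPS, 1.0 - _EPS)
    y = stats.norm.ppf(uc)
    z = (y - y.mean()) / y.std(ddof=1)
    return stats.norm.cdf(z)


def ks_statistic(data, fitted_cdf, method: str = "asymptotic"):
    """Two-sided Kolmogorov-Smirnov statistic and p-value.

    ``method`` is "asymptotic" (Kolmogorov distribution at sqrt(n) D, the
    default) or "exact" (finite-n two-sided distribution).
    """
    u = _order_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    d = float(max(np.max(i / n - u), np.max(u - (i - 1) / n)))
    if method == "asymptotic":
        pvalue = float(special.kolmogorov(np.sqrt(n) * d))
    elif method == "exact":
        pvalue = float(stats.kstwo.sf(d, n))
    else:
        raise ValueError(f"method must be 'asymptotic' or 'exact', got {method!r}")
    return d, min(max(pvalue, 0.0), 1.0)


def cvm_statistic(data, fitted_cdf, modified: bool = True) -> float:
    """Cramer-von Mises statistic (W* by default, plain W2 otherwise)."""
    u = _order_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    v = _normalise_u(u) if modified else u
    w2 = 1.0 / (12.0 * n) + float(np.sum((v - (2.0 * i - 1.0) / (2.0 * n)) ** 2))
    return w2 * (1.0 + 0.5 / n) if modified else w2


def ad_statistic(data, fitted_cdf, modified: bool = True) -> float:
    """Anderson-Darling statistic (A* by default, plain A2 otherwise).

    Fitted-cdf values at 0 or 1 are clipped to [eps, 1-eps] with a warning
    (the statistic is otherwise undefined).
    """
    u = _order_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    v = _normalise_u(u) if modified else u
    if np.any(v <= 0.0) or np.any(v >= 1.0):
        warnings.warn(
            "fitted cdf values at 0 or 1 clipped for the Anderson-Darling statistic",
            RuntimeWarning,
            stacklevel=2,
        )
        v = np.clip(v, _EPS, 1.0 - _EPS)
    a2 = -n - float(np.mean((2.0 * i - 1.0) * (np.log(v) + np.log(1.0 - v[::-1]))))
    return a2 * (1.0 + 0.75 / n + 2.25 / n**2) if modified else a2


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion 2k - 2 loglik for k fitted parameters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def pp_points(data, fitted_cdf, position: str = "midpoint"):
    """Probability-probability pairs (empirical, theoretical) at the order
    statistics.  ``position`` picks the plotting convention: "midpoint" for
    (i - 0.5)/n (default) or "ecdf" for i/n."""
    u = _order_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    if position == "midpoint":
        emp = (i - 0.5) / n
    elif position == "ecdf":
        emp = i / n
    else:
        raise ValueError(f"position must be 'midpoint' or 'ecdf', got {position!r}")
    return emp, u


def ecdf(data):
    """Right-continuous empirical cdf of the sample, as a callable."""
    x = np.asarray(data, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("data contain non-finite values")
    return stats.ecdf(x).cdf.evaluate


@dataclass(frozen=True)
class GofReport:
    """CVM, AD, KS statistic with p-value, and AIC for one fitted model."""

    cvm: float
    ad: float
    ks: float
    ks_pvalue: float
    aic: float
    n: int
    model: str
    modified: bool = True

    def __str__(self) -> str:
        return (
            f"{self.model}: CVM={self.cvm:.4f}  AD={self.ad:.4f}  "
            f"KS={self.ks:.4f} (p={self.ks_pvalue:.4f})  AIC={self.aic:.4f}"
        )


def gof_report(
    data,
    fitted_cdf,
    loglik: float,
    k: int,
    model: str = "",
    modified: bool = True,
    ks_method: str = "asymptotic",
) -> GofReport:
    """Assemble the full goodness-of-fit report for one fitted model."""
    d, p = ks_statistic(data, fitted_cdf, method=ks_method)
    return GofReport(
        cvm=cvm_statistic(data, fitted_cdf, modified=modified),
        ad=ad_statistic(data, fitted_cdf, modified=modified),
        ks=d,
        ks_pvalue=p,
        aic=aic(loglik, k),
        n=int(np.asarray(data).size),
        model=model,
        modified=modified,
    )
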