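"""The transformed-Sin-Weibull (TSW) distribution in closed form.

TSW composes the transform with the Weibull cdf G(x) = 1 - exp(-alpha x^beta)
(alpha > 0 multiplies x^beta, a rate-like parameterisation: the conventional
scale is alpha**(-1/beta)).  Writing E = exp(-alpha x^beta), the cdf has two
equivalent printed forms,

    F(x) = sin((pi/2)(1-E)) - lam (pi/2)(1-E) cos((pi/2)(1-E))
         = cos((pi/2) E)    - lam (pi/2)(1-E) sin((pi/2) E),

and the second (used internally) avoids the cancellation of 1 - sin(.) when
G is close to 1, which matters for tail-accurate survival and hazard values.
The SW (sine-Weibull) model is the lam = 0 restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .family import TSG, make_baseline
from .transform import t_inverse, validate_lam

__all__ = [
    "TSWParams",
    "tsw_cdf",
    "tsw_sf",
    "tsw_pdf",
    "tsw_logpdf",
    "tsw_hrf",
    "tsw_quantile",
    "tsw_rvs",
    "as_tsg",
]

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class TSWParams:
    """Parameter triple (lam, alpha, beta) with lam in [0,1], alpha, beta > 0."""

    lam: float
    alpha: float
    beta: float

    def __post_init__(self):
        validate_lam(self.lam)
        if not (self.alpha > 0.0 and np.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive real, got {self.alpha!r}")
        if not (self.beta > 0.0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive real, got {self.beta!r}")

    def astuple(self) -> tuple[float, float, float]:
        return (self.lam, self.alpha, self.beta)


def _params(params) -> tuple[float, float, float]:
    if isinstance(params, TSWParams):
        return params.astuple()
    lam, alpha, beta = params
    return TSWParams(float(lam), float(alpha), float(beta)).astuple()


def _exp_tail(x, alpha, beta):
    """E = exp(-alpha x^beta) for x > 0, 1 at or below 0."""
    x = np.asarray(x, dtype=float)
    return np.exp(-alpha * np.clip(x, 0.0, None) ** beta)


def tsw_cdf(params, x):
    """TSW cdf; 0 for x <= 0."""
    lam, alpha, beta = _params(params)
    x = np.asarray(x, dtype=float)
    E = _exp_tail(x, alpha, beta)
    out = np.cos(_HALF_PI * E) - lam * _HALF_PI * (1.0 - E) * np.sin(_HALF_PI * E)
    out = np.where(x > 0.0, np.clip(out, 0.0, 1.0), 0.0)
    return out if out.ndim else float(out)


def tsw_sf(params, x):
    """TSW survival function, evaluated from its own closed form (not as
    1 - cdf) so the upper tail keeps relative precision for hazard rates."""
    lam, alpha, beta = _params(params)
    x = np.asarray(x, dtype=float)
    E = _exp_tail(x, alpha, beta)
    y = _HALF_PI * E
    # 1 - cos(y) = 2 sin^2(y/2): stable for small E (deep right tail)
    out = 2.0 * np.sin(0.5 * y) ** 2 + lam * _HALF_PI * (1.0 - E) * np.sin(y)
    out = np.where(x > 0.0, np.clip(out, 0.0, 1.0), 1.0)
    return out if out.ndim else float(out)


def tsw_pdf(params, x):
    """TSW pdf; 0 for x <= 0."""
    out = np.exp(tsw_logpdf(params, x))
    return out if np.ndim(out) else float(out)


def tsw_logpdf(params, x):
    """Log pdf, -inf off the support or where the density vanishes."""
    lam, alpha, beta = _params(params)
    x = np.asarray(x, dtype=float)
    xs = np.where(x > 0.0, x, 1.0)  # placeholder off-support
    t = xs**beta
    E = np.exp(-alpha * t)
    y = _HALF_PI * E
    bracket = lam * _HALF_PI * (1.0 - E) * np.cos(y) + (1.0 - lam) * np.sin(y)
    with np.errstate(divide="ignore"):
        out = (
            np.log(_HALF_PI * alpha * beta)
            + (beta - 1.0) * np.log(xs)
            - alpha * t
            + np.log(np.clip(bracket, 0.0, None))
        )
    out = np.where((x > 0.0) & (bracket > 0.0), out, -np.inf)
    return out if out.ndim else float(out)


def tsw_hrf(params, x):
    """TSW hazard rate pdf/sf; 0 for x <= 0, +inf where sf underflows."""
    x = np.asarray(x, dtype=float)
    f = np.asarray(tsw_pdf(params, x), dtype=float)
    s = np.asarray(tsw_sf(params, x), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > 0.0, f / np.where(s > 0.0, s, 1.0), np.inf)
    out = np.where(x > 0.0, out, 0.0)
    return out if out.ndim else float(out)


def tsw_quantile(params, p, tol: float = 1e-12):
    """Quantile Q(p) = (-log(1-u)/alpha)^(1/beta) with u = T_lam^{-1}(p)."""
    lam, alpha, beta = _params(params)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("tsw_quantile requires p in [0, 1]")
    u = np.asarray(t_inverse(p, lam, tol=tol), dtype=float)
    with np.errstate(divide="ignore"):
        out = (-np.log1p(-u) / alpha) ** (1.0 / beta)
    out = np.where(p == 0.0, 0.0, out)
    out = np.where(p == 1.0, np.inf, out)
    return out if out.ndim else float(out)


def tsw_rvs(params, n: int, seed):
    """Inverse-transform sampling; reproducible for a given ``seed`` (an int
    or a numpy Generator)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return np.asarray(tsw_quantile(params, u), dtype=float)


def as_tsg(params) -> TSG:
    """The same distribution as a generic family object over the Weibull
    baseline (used to cross-check the closed forms)."""
    lam, alpha, beta = _params(params)
    return TSG(lam, make_baseline("weibull", alpha, beta))
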