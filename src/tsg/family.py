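"""Generic TS-G distributions over an arbitrary baseline.

A TS-G distribution is obtained by composing the polynomial-trigonometric
transform with a baseline cdf G:

    F(x; lam, zeta) = T_lam[G(x; zeta)]
                    = sin((pi/2) G) - lam (pi/2) G cos((pi/2) G),

with pdf

    f(x; lam, zeta) = (pi/2) g(x; zeta)
                      { lam (pi/2) G sin((pi/2) G) + (1 - lam) cos((pi/2) G) }.

lam = 0 recovers the plain Sin-G family, F = sin((pi/2) G).  This module
holds the baseline contract and registry, the distribution object
(cdf/pdf/sf/hrf, quantile, sampling) and the family-level analytical
utilities: the mixture identity, stochastic-ordering gaps, the likelihood
ratio, tail-equivalence coefficients, pdf/hrf critical points, the
exponentiated-baseline series expansion and the stress-strength reliability
parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .transform import t_inverse, t_lambda, validate_lam

__all__ = [
    "Baseline",
    "TSG",
    "make_baseline",
    "register_baseline",
    "mixture_check",
    "ordering_gap",
    "f_star_cdf",
    "likelihood_ratio",
    "tail_coefficients",
    "pdf_critical_points",
    "hrf_critical_points",
    "SeriesCoefficients",
    "series_coefficients",
    "reliability",
]

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class Baseline:
    """Baseline distribution contract: cdf G, pdf g, quantile Q_G, support.

    ``cdf``/``pdf``/``ppf`` must be vectorised over x (resp. u).  ``support``
    is an (lower, upper) pair of extended reals; the cdf must run from 0 to 1
    across it.
    """

    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    pdf: Callable[[np.ndarray], np.ndarray]
    ppf: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    params: tuple = ()
    #: optional survival function 1 - cdf in a cancellation-free form; when
    #: given, family survival/hazard values keep relative precision deep in
    #: the upper tail
    sf: Callable[[np.ndarray], np.ndarray] | None = None


def _uniform(a: float = 0.0, b: float = 1.0) -> Baseline:
    if not b > a:
        raise ValueError("uniform baseline requires b > a")
    width = b - a
    return Baseline(
        name="uniform",
        cdf=lambda x: np.clip((np.asarray(x, dtype=float) - a) / width, 0.0, 1.0),
        pdf=lambda x: np.where(
            (np.asarray(x, dtype=float) >= a) & (np.asarray(x, dtype=float) <= b),
            1.0 / width,
            0.0,
        ),
        ppf=lambda u: a + width * np.asarray(u, dtype=float),
        support=(a, b),
        params=(a, b),
    )


def _exponential(rate: float = 1.0) -> Baseline:
    if not rate > 0:
        raise ValueError("exponential baseline requires rate > 0")
    return Baseline(
        name="exponential",
        cdf=lambda x: -np.expm1(-rate * np.clip(np.asarray(x, dtype=float), 0.0, None)),
        pdf=lambda x: np.where(
            np.asarray(x, dtype=float) > 0,
            rate * np.exp(-rate * np.clip(np.asarray(x, dtype=float), 0.0, None)),
            0.0,
        ),
        ppf=lambda u: -np.log1p(-np.asarray(u, dtype=float)) / rate,
        support=(0.0, np.inf),
        params=(rate,),
        sf=lambda x: np.exp(-rate * np.clip(np.asarray(x, dtype=float), 0.0, None)),
    )


def _weibull(alpha: float = 1.0, beta: float = 1.0) -> Baseline:
    # rate-like parameterisation: G(x) = 1 - exp(-alpha x^beta); alpha
    # multiplies x^beta (the usual "scale" is alpha**(-1/beta)).
    if not (alpha > 0 and beta > 0):
        raise ValueError("weibull baseline requires alpha > 0 and beta > 0")

    def cdf(x):
        x = np.clip(np.asarray(x, dtype=float), 0.0, None)
        return -np.expm1(-alpha * x**beta)

    def pdf(x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                x > 0,
                alpha * beta * x ** (beta - 1.0) * np.exp(-alpha * np.clip(x, 0.0, None) ** beta),
                0.0,
            )
        return out

    return Baseline(
        name="weibull",
        cdf=cdf,
        pdf=pdf,
        ppf=lambda u: (-np.log1p(-np.asarray(u, dtype=float)) / alpha) ** (1.0 / beta),
        support=(0.0, np.inf),
        params=(alpha, beta),
        sf=lambda x: np.exp(-alpha * np.clip(np.asarray(x, dtype=float), 0.0, None) ** beta),
    )


_REGISTRY: dict[str, Callable[..., Baseline]] = {
    "uniform": _uniform,
    "exponential": _exponential,
    "weibull": _weibull,
}


def register_baseline(name: str, factory: Callable[..., Baseline]) -> None:
    """Register a new baseline factory under ``name``."""
    _REGISTRY[name] = factory


def make_baseline(name: str, *params) -> Baseline:
    """Build a registered baseline ("uniform", "exponential", "weibull")."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown baseline {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(*params)


class TSG:
    """A TS-G distribution: transform parameter ``lam`` over a ``Baseline``.

    cdf(x) = T_lam(G(x)).  Quantiles compose the baseline quantile with the
    scalar transform inverse, Q(p) = Q_G(T_lam^{-1}(p)), and sampling is by
    inverse transform.
    """

    def __init__(self, lam: float, baseline: Baseline):
        self.lam = validate_lam(lam)
        self.baseline = baseline

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TSG(lam={self.lam}, baseline={self.baseline.name}{self.baseline.params})"

    def cdf(self, x):
        return t_lambda(self.baseline.cdf(x), self.lam)

    def pdf(self, x):
        G = np.asarray(self.baseline.cdf(x), dtype=float)
        g = np.asarray(self.baseline.pdf(x), dtype=float)
        y = _HALF_PI * G
        out = _HALF_PI * g * (self.lam * y * np.sin(y) + (1.0 - self.lam) * np.cos(y))
        return out if out.ndim else float(out)

    def sf(self, x):
        """Survival function, in a cancellation-free form.

        With e = 1 - G,  1 - F = 2 sin^2((pi/4) e) + lam (pi/2) G sin((pi/2) e),
        which keeps relative precision as G -> 1 whenever the baseline
        supplies its own tail-accurate survival function.
        """
        G = np.asarray(self.baseline.cdf(x), dtype=float)
        if self.baseline.sf is not None:
            e = np.asarray(self.baseline.sf(x), dtype=float)
        else:
            e = 1.0 - G
        out = 2.0 * np.sin(0.25 * np.pi * e) ** 2 + self.lam * _HALF_PI * G * np.sin(
            _HALF_PI * e
        )
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def hrf(self, x):
        """Hazard rate pdf/sf.  Where sf underflows to 0 the hazard is
        returned as +inf (with a warning), not silently clipped."""
        s = np.asarray(self.sf(x), dtype=float)
        f = np.asarray(self.pdf(x), dtype=float)
        if np.any(s == 0.0):
            warnings.warn(
                "hazard rate evaluated where the survival function underflows; "
                "returning +inf",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0.0, f / np.where(s > 0.0, s, 1.0), np.inf)
        return out if out.ndim else float(out)

    def quantile(self, p, tol: float = 1e-12):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
            raise ValueError("quantile requires p in [0, 1]")
        u = t_inverse(p, self.lam, tol=tol)
        out = np.asarray(self.baseline.ppf(u), dtype=float)
        lower, upper = self.baseline.support
        out = np.where(p == 0.0, lower, out)
        out = np.where(p == 1.0, upper, out)
        return out if out.ndim else float(out)

    def rvs(self, n: int, seed):
        """Draw ``n`` variates by inverse transform; ``seed`` is mandatory
        (an int or a numpy Generator) — there is no global random state."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        u = rng.uniform(size=n)
        return np.asarray(self.quantile(u), dtype=float)


def mixture_check(dist: TSG, x):
    """Evaluate the two-component mixture (1-lam) F(x; 0) + lam F(x; 1).

    Algebraically identical to ``dist.cdf(x)``; exposed so the identity can
    be checked numerically.
    """
    f0 = TSG(0.0, dist.baseline).cdf(x)
    f1 = TSG(1.0, dist.baseline).cdf(x)
    return (1.0 - dist.lam) * np.asarray(f0) + dist.lam * np.asarray(f1)


def ordering_gap(x, lam1, lam2, baseline: Baseline):
    """F(x; lam1) - F(x; lam2); nonnegative whenever lam2 >= lam1.

    Larger lam pushes the cdf down (first-order stochastic dominance of the
    lam2-distribution over the lam1-distribution).
    """
    return np.asarray(TSG(lam1, baseline).cdf(x)) - np.asarray(TSG(lam2, baseline).cdf(x))


def f_star_cdf(x, baseline: Baseline):
    """The bound cdf F*(x) = G(x) { 1 - cos((pi/2) G(x)) }.

    For lam <= 2/pi the TS-G cdf dominates it: F(x; lam) >= F*(x).  F* is the
    cdf of max(X, Y) for X ~ G and Y from the Cos-G family, independent.
    """
    G = np.asarray(baseline.cdf(x), dtype=float)
    return G * (1.0 - np.cos(_HALF_PI * G))


def likelihood_ratio(x, lam1, lam2, baseline: Baseline):
    """Ratio f(x; lam1) / f(x; lam2); nonincreasing in x when lam2 >= lam1."""
    num = np.asarray(TSG(lam1, baseline).pdf(x), dtype=float)
    den = np.asarray(TSG(lam2, baseline).pdf(x), dtype=float)
    if np.any(den <= 0.0):
        raise ZeroDivisionError("likelihood_ratio: pdf(x; lam2) vanishes at some x")
    out = num / den
    return out if out.ndim else float(out)


def tail_coefficients(lam):
    """Tail-equivalence coefficients ((pi/2)(1-lam), (pi^2/4) lam).

    As G -> 0, F ~ (pi/2)(1-lam) G; as G -> 1, 1 - F ~ (pi^2/4) lam (1 - G).
    """
    lam = validate_lam(lam)
    return (_HALF_PI * (1.0 - lam), (np.pi**2 / 4.0) * lam)


def _critical_points(logf: Callable[[float], float], bracket, grid: int):
    """Roots of d log f / dx on ``bracket`` by sign-change scan + bisection.

    The log-derivative is taken by central differences (the family's critical
    -point equations equate it to zero); each root is classified by the sign
    of the second log-derivative: max (< 0), min (> 0), inflection (~ 0).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not hi > lo:
        raise ValueError("bracket must satisfy lo < hi")
    h = 1e-6 * (hi - lo)

    def dlog(x):
        return (logf(x + h) - logf(x - h)) / (2.0 * h)

    xs = np.linspace(lo + 2 * h, hi - 2 * h, grid)
    vals = np.array([dlog(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(xs[i])
        elif a * b < 0.0:
            roots.append(brentq(dlog, xs[i], xs[i + 1], xtol=1e-12))
    out = []
    for r in roots:
        eta = (logf(r + h) - 2.0 * logf(r) + logf(r - h)) / h**2
        if eta < -1e-8:
            kind = "max"
        elif eta > 1e-8:
            kind = "min"
        else:
            kind = "inflection"
        out.append((float(r), kind))
    return out


def pdf_critical_points(dist: TSG, bracket, grid: int = 2048):
    """Interior critical points of the pdf, each labelled max/min/inflection.

    An empty list means no sign change of d log f / dx in the bracket (a
    monotone pdf there), which is not an error.
    """
    def logf(x):
        v = float(np.asarray(dist.pdf(x), dtype=float))
        return np.log(v) if v > 0.0 else -np.inf

    return _critical_points(logf, bracket, grid)


def hrf_critical_points(dist: TSG, bracket, grid: int = 2048):
    """Interior critical points of the hazard rate, labelled as for the pdf."""
    def logh(x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = float(np.asarray(dist.hrf(x), dtype=float))
        return np.log(v) if 0.0 < v < np.inf else -np.inf

    return _critical_points(logh, bracket, grid)


@dataclass(frozen=True)
class SeriesCoefficients:
    """Coefficients a_k of the exponentiated-baseline expansion.

    F(x) = sum_k a_k G(x)^(2k+1) with
    a_k = (pi/2)^(2k+1) (-1)^k [1 - lam (2k+1)] / (2k+1)!,
    and correspondingly f(x) = sum_k a_k v_{2k+1}(x) where v_gamma is the
    exponentiated-baseline pdf gamma g G^(gamma-1).  The terms decay
    factorially, so the truncation error is bounded by the first omitted
    term (stored as ``tail_bound``).
    """

    lam: float
    K: int
    a: np.ndarray = field(repr=False)
    tail_bound: float

    def cdf_series(self, G):
        """Reconstruct F from baseline-cdf values G via the truncated series."""
        G = np.asarray(G, dtype=float)
        k = np.arange(self.K + 1)
        powers = G[..., None] ** (2 * k + 1)
        return powers @ self.a


def series_coefficients(lam, K: int = 30) -> SeriesCoefficients:
    """Compute a_0..a_K of the expansion of the TS-G cdf in powers of G."""
    lam = validate_lam(lam)
    if K < 0:
        raise ValueError("K must be >= 0")
    k = np.arange(K + 2)
    gamma = 2 * k + 1
    from scipy.special import factorial

    a = _HALF_PI**gamma * (-1.0) ** k * (1.0 - lam * gamma) / factorial(gamma, exact=False)
    return SeriesCoefficients(lam=lam, K=K, a=a[: K + 1], tail_bound=abs(float(a[K + 1])))


def reliability(lam1, lam2) -> float:
    """Stress-strength reliability R = P(X2 < X1) for two TS-G variables
    sharing a baseline, R = 1/2 + (lam1 - lam2)(pi^2 - 4)/16.

    The baseline cancels: R depends on the two transform parameters only.
    """
    lam1 = validate_lam(lam1)
    lam2 = validate_lam(lam2)
    return 0.5 + (lam1 - lam2) * (np.pi**2 - 4.0) / 16.0
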