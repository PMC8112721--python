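"""Maximum likelihood for the TSW and SW models.

The log-likelihood of a complete sample x_1..x_n under the TSW density is

    l(lam, alpha, beta) = n log(pi/2) + sum log g(x_i; alpha, beta)
        + sum log{ lam (pi/2) G_i sin((pi/2) G_i) + (1-lam) cos((pi/2) G_i) },

with G_i = 1 - exp(-alpha x_i^beta) and g the Weibull pdf.  The score is
analytic: the lam-component is

    sum [ (pi/2) G_i sin((pi/2) G_i) - cos((pi/2) G_i) ] / bracket_i,

and the (alpha, beta) components combine the baseline log-pdf derivatives
with the chain-rule term

    (pi/2) dG_i/dzeta [ (2 lam - 1) sin((pi/2) G_i)
                        + lam (pi/2) G_i cos((pi/2) G_i) ] / bracket_i.

Optimisation is bounded quasi-Newton on (lam, log alpha, log beta) with lam
box-constrained to [0, 1], multi-started from a deterministic grid around a
Weibull-only fit.  Standard errors come from the observed information (the
negative Hessian of l at the MLE, by central differences on the
unconstrained scale, mapped back by the delta method).

The user-facing surface is statsmodels-shaped: ``TransformedSinWeibull(data)``
(or ``SineWeibull`` for the lam = 0 restriction) with ``.fit()`` returning a
``TSWResults`` carrying estimates, standard errors, log-likelihood, AIC,
observed information, diagnostics, a ``summary()`` table and ``gof()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .tsw import TSWParams, tsw_cdf

__all__ = [
    "loglik",
    "score",
    "fit_mle",
    "standard_errors",
    "FitError",
    "TransformedSinWeibull",
    "SineWeibull",
    "TSWResults",
]

_HALF_PI = np.pi / 2.0

MODELS = ("tsw", "sw")


class FitError(RuntimeError):
    """All optimisation starts failed; carries the per-start traces."""

    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces or []


def _validate_data(data) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    if np.any(x <= 0.0):
        raise ValueError("TSW/SW models require strictly positive data")
    return x


def loglik(data, lam, alpha, beta, model: str = "tsw") -> float:
    """Log-likelihood; -inf (not an exception) when the density vanishes at
    any observation, so optimisers can retreat."""
    x = np.asarray(data, dtype=float).ravel()
    if model == "sw" and lam != 0.0:
        raise ValueError("the SW model fixes lam = 0")
    if np.any(x <= 0.0) or not (alpha > 0 and beta > 0):
        return -np.inf
    with np.errstate(over="ignore"):
        t = x**beta
        E = np.exp(-alpha * t)
    y = _HALF_PI * E
    bracket = lam * _HALF_PI * (1.0 - E) * np.cos(y) + (1.0 - lam) * np.sin(y)
    if np.any(bracket <= 0.0):
        return -np.inf
    n = x.size
    return float(
        n * np.log(_HALF_PI)
        + n * (np.log(alpha) + np.log(beta))
        + np.sum((beta - 1.0) * np.log(x) - alpha * t)
        + np.sum(np.log(bracket))
    )


def score(data, lam, alpha, beta, model: str = "tsw") -> np.ndarray:
    """Analytic gradient of the log-likelihood.

    Returns (d/dlam, d/dalpha, d/dbeta) for "tsw", (d/dalpha, d/dbeta) for
    "sw".  Written in terms of E = exp(-alpha x^beta): with G = 1 - E,
    sin((pi/2)G) = cos((pi/2)E) and cos((pi/2)G) = sin((pi/2)E).
    """
    x = np.asarray(data, dtype=float).ravel()
    if model == "sw" and lam != 0.0:
        raise ValueError("the SW model fixes lam = 0")
    t = x**beta
    E = np.exp(-alpha * t)
    G = 1.0 - E
    y = _HALF_PI * E
    sinG = np.cos(y)   # sin((pi/2) G)
    cosG = np.sin(y)   # cos((pi/2) G)
    bracket = lam * _HALF_PI * G * sinG + (1.0 - lam) * cosG

    dl_dlam = np.sum((_HALF_PI * G * sinG - cosG) / bracket)

    # derivative of log bracket with respect to G
    trig = _HALF_PI * ((2.0 * lam - 1.0) * sinG + _HALF_PI * lam * G * cosG) / bracket
    logx = np.log(x)
    dG_da = t * E
    dG_db = alpha * t * logx * E
    dlogg_da = 1.0 / alpha - t
    dlogg_db = 1.0 / beta + logx * (1.0 - alpha * t)

    dl_da = np.sum(dlogg_da + trig * dG_da)
    dl_db = np.sum(dlogg_db + trig * dG_db)
    if model == "sw":
        return np.array([dl_da, dl_db])
    return np.array([dl_dlam, dl_da, dl_db])


def _weibull_start(x: np.ndarray) -> tuple[float, float]:
    """Starting (alpha, beta) from a plain Weibull fit of the data."""
    try:
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        if np.isfinite(c) and c > 0 and np.isfinite(scale) and scale > 0:
            return float(scale**-c), float(c)
    except Exception:
        pass
    # crude moment fallback
    m, s = float(np.mean(x)), float(np.std(x) + 1e-12)
    beta0 = max(0.1, min(20.0, (m / s) ** 1.086))
    alpha0 = 1.0 / np.mean(x**beta0)
    return alpha0, beta0


def _starts(x: np.ndarray, model: str, n_starts: int, seed) -> list[np.ndarray]:
    """Deterministic Latin-style start grid on (lam, log alpha, log beta),
    anchored at the Weibull-only fit; extra starts jitter the anchor."""
    a0, b0 = _weibull_start(x)
    la0, lb0 = np.log(a0), np.log(b0)
    if model == "sw":
        base = [np.array([la0, lb0])]
        grid = [np.array([la0 + da, lb0 + db]) for da, db in ((0.5, 0.0), (-0.5, 0.0), (0.0, 0.3))]
    else:
        lams = (0.05, 0.25, 0.5, 0.75, 0.95)
        base = [np.array([l, la0, lb0]) for l in lams]
        grid = []
        rng = np.random.default_rng(seed)
        while len(base) + len(grid) < max(n_starts, 1):
            jitter = rng.normal(scale=(0.1, 0.4, 0.2))
            cand = np.array([min(max(rng.uniform(), 0.0), 1.0), la0, lb0]) + jitter * np.array(
                [0.0, 1.0, 1.0]
            )
            cand[0] = float(np.clip(cand[0], 0.0, 1.0))
            grid.append(cand)
    return (base + grid)[: max(n_starts, 1)]


def _objective(theta: np.ndarray, x: np.ndarray, model: str):
    """Negative log-likelihood and gradient on the working scale
    (lam, log alpha, log beta) — or (log alpha, log beta) for SW."""
    if model == "sw":
        lam, (la, lb) = 0.0, theta
    else:
        lam, la, lb = theta
    alpha, beta = np.exp(la), np.exp(lb)
    ll = loglik(x, lam, alpha, beta)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(theta)
    g = score(x, lam, alpha, beta, model=model)
    if model == "sw":
        grad = -np.array([g[0] * alpha, g[1] * beta])
    else:
        grad = -np.array([g[0], g[1] * alpha, g[2] * beta])
    return -ll, grad


def fit_mle(
    data,
    model: str = "tsw",
    starts: int = 8,
    seed: int = 0,
    compute_se: bool = True,
    init=None,
) -> "TSWResults":
    """Fit the TSW (or SW) model by multi-start bounded maximum likelihood.

    Ties across converged starts are broken by log-likelihood, then by the
    smaller gradient norm.  Raises :class:`FitError` when no start converges.
    ``init`` replaces the start grid with a single given (lam, alpha, beta)
    starting point (local rather than multi-start optimisation).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    x = _validate_data(data)
    if model == "sw":
        bounds = [(None, None)] * 2
    else:
        bounds = [(0.0, 1.0), (None, None), (None, None)]

    if init is not None:
        lam0, a0, b0 = init.astuple() if isinstance(init, TSWParams) else map(float, init)
        if model == "sw":
            start_list = [np.array([np.log(a0), np.log(b0)])]
        else:
            start_list = [np.array([lam0, np.log(a0), np.log(b0)])]
    else:
        start_list = _starts(x, model, starts, seed)

    def _projected_gnorm(res) -> float:
        # KKT residual: at an active bound the gradient may legitimately
        # point out of the box
        if not np.all(np.isfinite(res.jac)):
            return np.inf
        g = np.array(res.jac, dtype=float)
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and res.x[i] <= lo + 1e-12:
                g[i] = min(g[i], 0.0)
            if hi is not None and res.x[i] >= hi - 1e-12:
                g[i] = max(g[i], 0.0)
        return float(np.max(np.abs(g)))

    traces = []
    best = None
    best_gnorm = np.inf
    best_conv = False
    for theta0 in start_list:
        res = minimize(
            _objective,
            theta0,
            args=(x, model),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(ftol=1e-14, gtol=1e-10, maxiter=2000),
        )
        gnorm = _projected_gnorm(res)
        # L-BFGS-B can abort the line search at machine-precision optima;
        # a small projected gradient certifies convergence regardless
        conv = bool(res.success) or gnorm < 1e-5
        traces.append(
            dict(start=list(map(float, theta0)), fun=float(res.fun), success=bool(res.success),
                 converged=conv, grad_norm=gnorm, message=str(res.message))
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10 or (
            abs(res.fun - best.fun) <= 1e-10 and gnorm < best_gnorm
        ):
            best, best_gnorm, best_conv = res, gnorm, conv
    if best is None or not np.isfinite(best.fun):
        raise FitError("all optimisation starts failed", traces=traces)

    if model == "sw":
        lam_hat = 0.0
        alpha_hat, beta_hat = np.exp(best.x)
    else:
        lam_hat = float(best.x[0])
        alpha_hat, beta_hat = np.exp(best.x[1]), np.exp(best.x[2])
    params = TSWParams(lam_hat, float(alpha_hat), float(beta_hat))
    llf = loglik(x, *params.astuple())

    result = TSWResults(
        model=model,
        params=params,
        llf=float(llf),
        nobs=int(x.size),
        data=x,
        converged=best_conv,
        trace=traces,
    )
    if compute_se:
        standard_errors(result)
    return result


def _observed_information(result: "TSWResults", rel_step: float = 1e-4) -> np.ndarray:
    """Observed information J = -Hessian of l at the MLE.

    Central differences on the working scale (lam, log alpha, log beta),
    mapped back to (lam, alpha, beta) with the delta method (the score is ~0
    at an interior MLE, so the curvature transforms as A^T H A with
    A = diag(1, 1/alpha, 1/beta)).
    """
    x = result.data
    model = result.model
    lam, alpha, beta = result.params.astuple()
    if model == "sw":
        theta = np.array([np.log(alpha), np.log(beta)])
        scale_back = np.diag([1.0 / alpha, 1.0 / beta])
    else:
        theta = np.array([lam, np.log(alpha), np.log(beta)])
        scale_back = np.diag([1.0, 1.0 / alpha, 1.0 / beta])

    def f(th):
        if model == "sw":
            return loglik(x, 0.0, np.exp(th[0]), np.exp(th[1]))
        return loglik(x, th[0], np.exp(th[1]), np.exp(th[2]))

    k = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    J_working = -H
    return scale_back.T @ J_working @ scale_back


def standard_errors(result: "TSWResults", rel_step: float = 1e-4) -> np.ndarray:
    """Fill in (and return) sqrt diag of the inverse observed information.

    A non-positive-definite information matrix is flagged
    (``result.se_flag``) instead of silently producing output; a lam-hat on
    the [0, 1] boundary sets ``result.boundary`` since the usual asymptotics
    do not apply there.
    """
    J = _observed_information(result, rel_step=rel_step)
    result.observed_info = J
    k = J.shape[0]
    bse = np.full(k, np.nan)
    flag = None
    try:
        eigvals = np.linalg.eigvalsh(J)
        if np.any(eigvals <= 0.0):
            flag = "observed information not positive definite"
        else:
            bse = np.sqrt(np.diag(np.linalg.inv(J)))
    except np.linalg.LinAlgError:
        flag = "observed information is singular"
    result.bse = bse
    result.se_flag = flag
    if result.model == "tsw":
        lam = result.params.lam
        result.boundary = bool(lam < 1e-6 or lam > 1.0 - 1e-6)
    return bse


@dataclass
class TSWResults:
    """Fit results: estimates, uncertainties, diagnostics.

    ``params`` is the full (lam, alpha, beta) triple (lam pinned to 0 for
    the SW model); ``bse`` aligns with the *fitted* parameters only
    (3 for TSW, 2 for SW).  ``aic`` = 2k - 2 llf with k = number of fitted
    parameters.
    """

    model: str
    params: TSWParams
    llf: float
    nobs: int
    data: np.ndarray = field(repr=False)
    converged: bool = True
    trace: list = field(default_factory=list, repr=False)
    observed_info: np.ndarray | None = field(default=None, repr=False)
    bse: np.ndarray | None = None
    se_flag: str | None = None
    boundary: bool = False

    @property
    def k_params(self) -> int:
        return 2 if self.model == "sw" else 3

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("alpha", "beta") if self.model == "sw" else ("lam", "alpha", "beta")

    @property
    def fitted_params(self) -> np.ndarray:
        p = self.params
        return np.array([p.alpha, p.beta]) if self.model == "sw" else np.array(p.astuple())

    @property
    def aic(self) -> float:
        from .gof import aic

        return aic(self.llf, self.k_params)

    def cdf(self, x):
        return tsw_cdf(self.params, x)

    def gof(self, modified: bool = True):
        """Goodness-of-fit report (CVM, AD, KS + p-value, AIC) on the
        training data at the fitted parameters."""
        from .gof import gof_report

        return gof_report(
            self.data, self.cdf, loglik=self.llf, k=self.k_params, model=self.model,
            modified=modified,
        )

    def summary(self) -> str:
        name = {"tsw": "Transformed-Sin-Weibull (TSW)", "sw": "Sine-Weibull (SW)"}[self.model]
        lines = [
            f"{name} maximum likelihood fit",
            f"  nobs: {self.nobs}    log-likelihood: {self.llf:.4f}    AIC: {self.aic:.4f}",
            f"  converged: {self.converged}" + ("    [lam on boundary]" if self.boundary else ""),
            "  " + "-" * 44,
            f"  {'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse if self.bse is not None else np.full(self.k_params, np.nan)
        for nm, est, se in zip(self.param_names, self.fitted_params, bse):
            lines.append(f"  {nm:<8}{est:>12.4f}{se:>12.4f}")
        if self.se_flag:
            lines.append(f"  note: {self.se_flag}")
        return "\n".join(lines)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Wald intervals; the lam interval is truncated to [0, 1]."""
        if self.bse is None:
            raise ValueError("standard errors unavailable")
        z = stats.norm.ppf(0.5 * (1.0 + level))
        est = self.fitted_params
        lo, hi = est - z * self.bse, est + z * self.bse
        if self.model == "tsw":
            lo[0], hi[0] = max(lo[0], 0.0), min(hi[0], 1.0)
        return np.column_stack([lo, hi])

    def to_report(self, gof: bool = True) -> dict:
        """Versioned machine-readable report (diffable against the printed
        comparison tables)."""
        rep = {
            "format": "tsg-report/1",
            "model": self.model,
            "nobs": self.nobs,
            "estimates": {n: float(v) for n, v in zip(self.param_names, self.fitted_params)},
            "ses": {
                n: (float(v) if v is not None and np.isfinite(v) else None)
                for n, v in zip(self.param_names, self.bse if self.bse is not None else [])
            },
            "loglik": float(self.llf),
            "aic": float(self.aic),
            "converged": self.converged,
            "boundary": self.boundary,
            "se_flag": self.se_flag,
        }
        if gof:
            g = self.gof()
            rep["gof"] = {
                "cvm": g.cvm, "ad": g.ad, "ks": g.ks, "ks_pvalue": g.ks_pvalue,
                "modified": g.modified,
            }
        return rep

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)


class TransformedSinWeibull:
    """Model object for the three-parameter TSW distribution.

    Parameters
    ----------
    data : array-like
        Strictly positive observations (complete sample), n >= 5.

    ``fit()`` runs multi-start bounded maximum likelihood and returns a
    :class:`TSWResults`.
    """

    model_name = "tsw"

    def __init__(self, data):
        self.data = _validate_data(data)

    @classmethod
    def from_dataframe(cls, df, column: str):
        return cls(np.asarray(df[column], dtype=float))

    def loglike(self, params) -> float:
        lam, alpha, beta = (
            params.astuple() if isinstance(params, TSWParams) else map(float, params)
        )
        if self.model_name == "sw":
            return loglik(self.data, 0.0, alpha, beta)
        return loglik(self.data, lam, alpha, beta)

    def score(self, params) -> np.ndarray:
        lam, alpha, beta = (
            params.astuple() if isinstance(params, TSWParams) else map(float, params)
        )
        return score(self.data, lam, alpha, beta, model=self.model_name)

    def fit(self, starts: int = 8, seed: int = 0, compute_se: bool = True) -> TSWResults:
        return fit_mle(
            self.data, model=self.model_name, starts=starts, seed=seed, compute_se=compute_se
        )


class SineWeibull(TransformedSinWeibull):
    """The lam = 0 restriction (two-parameter sine-Weibull model)."""

    model_name = "sw"

    def loglike(self, params) -> float:
        alpha, beta = map(float, params)
        return loglik(self.data, 0.0, alpha, beta)

    def score(self, params) -> np.ndarray:
        alpha, beta = map(float, params)
        return score(self.data, 0.0, alpha, beta, model="sw")
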