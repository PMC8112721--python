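"""The scalar polynomial-trigonometric transform at the heart of the TS-G family.

The transform is

    T_lam(x) = sin((pi/2) x) - lam (pi/2) x cos((pi/2) x),    x in [0, 1],

extended by 0 below 0 and 1 above 1, with lam in [0, 1].  For every such lam
it is a continuous cdf on [0, 1]; its curvature is controlled by lam: concave
for lam <= 1/3, convex for lam >= 1/2, and possibly neither in between.  The
star form

    T*_lam(u) = u - lam arcsin(u) sqrt(1 - u^2),    u in [0, 1],

satisfies T*_lam(sin((pi/2) x)) = T_lam(x), i.e. T_lam "convexifies (or not)"
the sine cdf while preserving the cdf properties.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "t_lambda",
    "t_lambda_deriv",
    "t_star",
    "t_inverse",
    "classify_shape",
    "validate_lam",
]

_HALF_PI = np.pi / 2.0

#: guaranteed curvature intervals for the transform parameter
CONCAVE_UPPER = 1.0 / 3.0
CONVEX_LOWER = 0.5


def validate_lam(lam: float) -> float:
    """Validate the transform parameter lam, returning it as a float.

    The cdf property of the transform is only proven for lam in [0, 1], so
    values outside are rejected rather than extrapolated.
    """
    lam = float(lam)
    if not np.isfinite(lam) or lam < 0.0 or lam > 1.0:
        raise ValueError(f"transform parameter lam must lie in [0, 1], got {lam!r}")
    return lam


def t_lambda(x, lam):
    """Evaluate the transform T_lam at ``x`` (scalar or array).

    Values below 0 map to 0 and above 1 to 1, so the result is a valid cdf
    on the real line.
    """
    lam = validate_lam(lam)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("t_lambda requires finite x")
    xc = np.clip(x, 0.0, 1.0)
    out = np.sin(_HALF_PI * xc) - lam * _HALF_PI * xc * np.cos(_HALF_PI * xc)
    # pin the endpoints exactly (cos(pi/2) is not exactly 0 in floating point)
    out = np.where(x >= 1.0, 1.0, np.where(x <= 0.0, 0.0, np.clip(out, 0.0, 1.0)))
    return out if out.ndim else float(out)


def t_lambda_deriv(x, lam, order: int = 1):
    """First or second derivative of T_lam on [0, 1].

    order=1:  (pi/2) [ (1-lam) cos((pi/2)x) + lam (pi/2) x sin((pi/2)x) ]  >= 0
    order=2:  (pi^2/4) [ (2 lam - 1) sin((pi/2)x) + lam (pi/2) x cos((pi/2)x) ]
    """
    lam = validate_lam(lam)
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order!r}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("derivatives of t_lambda are defined on [0, 1]")
    y = _HALF_PI * x
    if order == 1:
        out = _HALF_PI * ((1.0 - lam) * np.cos(y) + lam * y * np.sin(y))
    else:
        out = _HALF_PI**2 * ((2.0 * lam - 1.0) * np.sin(y) + lam * y * np.cos(y))
    return out if out.ndim else float(out)


def t_star(u, lam):
    """The star form T*_lam(u) = u - lam arcsin(u) sqrt(1 - u^2) on [0, 1]."""
    lam = validate_lam(lam)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0) or not np.all(np.isfinite(u)):
        raise ValueError("t_star requires u in [0, 1]")
    out = u - lam * np.arcsin(u) * np.sqrt(np.clip(1.0 - u * u, 0.0, None))
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def t_inverse(p, lam, tol: float = 1e-12):
    """Invert the transform: return x in [0, 1] with |T_lam(x) - p| <= tol.

    Uses bracketed bisection on [0, 1].  T_lam is continuous and strictly
    increasing on (0, 1), so bisection converges unconditionally; the interval
    is halved until its width drops below ``tol``.  Vectorised over ``p``.
    """
    lam = validate_lam(lam)
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("t_inverse requires p in [0, 1]")
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    lo = np.zeros_like(p)
    hi = np.ones_like(p)
    n_iter = max(1, int(np.ceil(np.log2(1.0 / tol))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = t_lambda(mid, lam) < p
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    # pin exact endpoints
    out = np.where(p == 0.0, 0.0, out)
    out = np.where(p == 1.0, 1.0, out)
    return float(out[0]) if scalar else out


def classify_shape(lam, grid_size: int = 512) -> str:
    """Classify the curvature of T_lam: "concave", "convex" or "neither".

    The intervals lam <= 1/3 (concave) and lam >= 1/2 (convex) are proven and
    short-circuited analytically.  In the open gap (1/3, 1/2) the second
    derivative is inspected on an interior uniform grid; a sign is only
    counted when it exceeds a 1e-10 deadband.
    """
    lam = validate_lam(lam)
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    if lam <= CONCAVE_UPPER:
        return "concave"
    if lam >= CONVEX_LOWER:
        return "convex"
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    d2 = t_lambda_deriv(grid, lam, order=2)
    deadband = 1e-10
    has_pos = bool(np.any(d2 > deadband))
    has_neg = bool(np.any(d2 < -deadband))
    if has_pos and has_neg:
        return "neither"
    if has_neg:
        return "concave"
    return "convex"
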