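"""Hill-equation variant for morphogen gradient profiles.

The gradient intensity ``m`` at normalized margin position ``z`` (either the
scaled axis ``x/L`` or the relative axis ``x/L_max``, both in [0, 1]) is
modeled as

    m(z) = a / (1 + (z/b)**c)

with amplitude ``a`` (intensity at the ventral pole, z = 0), half-maximum
position ``b`` (the curve always passes through ``(b, a/2)``) and steepness
exponent ``c``.  Note the exponent applies to the ratio ``z/b`` as a whole,
not to ``b`` alone.  The function is strictly decreasing on z > 0 for
positive parameters and admits the closed-form inverse

    z(m) = b * (a/m - 1)**(1/c),   0 < m < a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class HillFitError(RuntimeError):
    """Raised when the nonlinear least-squares fit cannot converge."""


@dataclass(frozen=True)
class HillParams:
    """Fitted parameters of the Hill variant plus goodness of fit.

    Attributes
    ----------
    a, b, c
        Amplitude, half-max position (fraction of the axis) and steepness.
    r_squared
        1 - SS_res/SS_tot on the training nodes; <= 1, may be negative for
        a fit worse than the constant model.
    axis
        Which position axis the fit was made on ("scaled" or "relative").
    n_points
        Number of non-missing nodes used.
    converged
        False if every restart of the optimizer failed; such params carry
        NaN values and are excluded from population statistics.
    """

    a: float
    b: float
    c: float
    r_squared: float = float("nan")
    axis: str = "scaled"
    n_points: int = 0
    converged: bool = True


# optimizer bounds: a in (0, 3], b in (0, 2], c in [0.5, 30]
_BOUNDS = ([1e-9, 1e-9, 0.5], [3.0, 2.0, 30.0])


def hill_eval(params: HillParams, z):
    """Evaluate the Hill variant at position(s) ``z`` >= 0."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("position z must be non-negative")
    out = params.a / (1.0 + (z / params.b) ** params.c)
    return float(out) if out.ndim == 0 else out


def hill_inverse(params: HillParams, m):
    """Invert the Hill variant: position at which intensity equals ``m``.

    Only intensities strictly inside (0, a) are attainable.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0) or np.any(m >= params.a):
        raise ValueError(f"intensity must lie strictly in (0, a={params.a})")
    out = params.b * (params.a / m - 1.0) ** (1.0 / params.c)
    return float(out) if out.ndim == 0 else out


def _hill(z, a, b, c):
    return a / (1.0 + (z / b) ** c)


def fit_hill(
    positions,
    intensities,
    axis: str = "scaled",
    n_restarts: int = 3,
    restart_jitter: float = 0.2,
    seed: int = 0,
) -> HillParams:
    """Fit the Hill variant to (position, intensity) nodes by least squares.

    Missing nodes (NaN intensity) are dropped pairwise; at least 4 finite
    nodes are required for the 3-parameter fit.  Initialization: a0 = max
    intensity, b0 = position of the node nearest a0/2, c0 = 4.  Because the
    steepness c is weakly identified on flat profiles, the fit is multi-start:
    the base start plus ``n_restarts`` starts with +/-20% jitter on b0 and c0;
    the converged solution with the lowest residual sum of squares wins.

    Raises
    ------
    HillFitError
        If no start converges.  Degenerate (constant) data typically either
        raises or returns r_squared <= 0; callers should treat both as a
        flat-fit condition.
    """
    z = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if z.shape != y.shape:
        raise ValueError("positions and intensities must have equal length")
    ok = np.isfinite(z) & np.isfinite(y)
    z, y = z[ok], y[ok]
    if z.size < 4:
        raise HillFitError(f"need >= 4 finite nodes, got {z.size}")

    a0 = float(np.max(y))
    if a0 <= 0:
        raise HillFitError("all intensities non-positive; nothing to fit")
    a0 = min(a0, _BOUNDS[1][0])
    b0 = float(z[np.argmin(np.abs(y - a0 / 2.0))])
    b0 = float(np.clip(b0, 1e-3, _BOUNDS[1][1]))
    c0 = 4.0

    rng = np.random.default_rng(seed)
    starts = [(a0, b0, c0)]
    for _ in range(n_restarts):
        jb = b0 * (1.0 + restart_jitter * rng.uniform(-1, 1))
        jc = c0 * (1.0 + restart_jitter * rng.uniform(-1, 1))
        starts.append(
            (
                a0,
                float(np.clip(jb, _BOUNDS[0][1], _BOUNDS[1][1])),
                float(np.clip(jc, _BOUNDS[0][2], _BOUNDS[1][2])),
            )
        )

    best = None
    best_ss = np.inf
    failures = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _hill, z, y, p0=p0, bounds=_BOUNDS, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # no convergence this start
            failures.append(str(exc))
            continue
        ss = float(np.sum((y - _hill(z, *popt)) ** 2))
        if ss < best_ss:
            best_ss, best = ss, popt

    if best is None:
        raise HillFitError(
            "Hill fit failed to converge after "
            f"{len(starts)} starts: {failures[:2]}"
        )

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_ss / ss_tot if ss_tot > 0 else -np.inf
    return HillParams(
        a=float(best[0]),
        b=float(best[1]),
        c=float(best[2]),
        r_squared=float(r2),
        axis=axis,
        n_points=int(z.size),
        converged=True,
    )
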