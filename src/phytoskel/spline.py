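"""Beta-spline blending and uniform-density resampling of skeleton axes.

Beta-splines generalize cubic B-splines with two shape parameters, a
*tension* ``t`` and a *skew* ``s``; they sit between approximation and
interpolation and are first- and second-order continuous for admissible
parameters.  At ``s = 1`` the four blending values active at any curve
parameter form a partition of unity for any tension, so spline points are
affine combinations of at most four nearby control points.

An axis of a skeleton tree is resampled to uniform point density by
evaluating its spline at ``N = max(2, ceil(d / d0))`` uniformly spaced
parameters, where ``d`` is the Euclidean distance between the axis
endpoints (mm) and ``d0`` the target inter-point spacing (mm).  The two
terminal samples are truncated (clamped) to the exact axis endpoints so
the resampled curve never overshoots the branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BetaSplineParams", "beta_blend", "evaluate_spline", "resample_axis"]


@dataclass(frozen=True)
class BetaSplineParams:
    """Shape parameters of the beta-spline and the resampling density.

    Parameters
    ----------
    t : float
        Tension (dimensionless).  Values in [5, 15] approximate skeleton
        branches well; default 10.
    s : float
        Skew (dimensionless).  Kept at 1 for smooth curves.
    d0 : float
        Target inter-point spacing of the resampled axis, mm.  Default 1.0.
    """

    t: float = 10.0
    s: float = 1.0
    d0: float = 1.0
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        delta = self.t + 2 * self.s**3 + 4 * self.s**2 + 4 * self.s + 2
        if not (delta > 0):
            raise ValueError(f"normalizer delta = {delta} must be positive")
        if not (self.d0 > 0):
            raise ValueError(f"d0 = {self.d0} must be positive")
        object.__setattr__(self, "delta", delta)


def beta_blend(v: float, params: BetaSplineParams | None = None) -> float:
    """Beta-spline blending function beta(v) on the support [-2, 2].

    Piecewise cubic in four unit intervals; zero outside [-2, 2] and C0 at
    the interval boundaries.  ``v`` is the offset ``n*u - i`` between the
    scaled curve parameter and a control-point index.
    """
    if params is None:
        params = BetaSplineParams()
    if not math.isfinite(v):
        raise ValueError("beta_blend: v must be finite")
    t, s, d = params.t, params.s, params.delta
    if v < -2.0 or v > 2.0:
        return 0.0
    if v <= -1.0:
        return (2.0 / d) * (2.0 + v) ** 3
    if v <= 0.0:
        return (
            (t + 4 * s + 4 * s**2)
            - 6 * (1 - s**2) * v
            - 3 * v**2 * (2 + t + 2 * s)
            - 2 * v**3 * (1 + t + s + s**2)
        ) / d
    if v <= 1.0:
        return (
            (t + 4 * s + 4 * s**2)
            - 6 * v * (s - s**3)
            - 3 * v**2 * (t + 2 * s**2 + 2 * s**3)
            + 2 * v**3 * (t + s + s**2 + s**3)
        ) / d
    return (2.0 / d) * s**3 * (2.0 - v) ** 3


def evaluate_spline(
    control_points: np.ndarray, u: float, params: BetaSplineParams | None = None
) -> np.ndarray:
    """Evaluate the beta-spline S(u), u in [0, 1], over the control polygon.

    S(u) = sum_i beta(n*u - i) * P_i over the index window
    floor(n*u) - 2 .. ceil(n*u) + 2, with out-of-range indices clamped to
    the terminal control points (repeat-endpoint convention).  Because the
    blending values form a partition of unity, S(u) is always an affine
    combination of control points.
    """
    if params is None:
        params = BetaSplineParams()
    P = np.asarray(control_points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("evaluate_spline needs at least 2 control points")
    n = P.shape[0] - 1
    x = n * float(u)
    lo = math.floor(x) - 2
    hi = math.ceil(x) + 2
    out = np.zeros(P.shape[1])
    for i in range(lo, hi + 1):
        w = beta_blend(x - i, params)
        if w != 0.0:
            out += w * P[min(max(i, 0), n)]
    return out


def resample_axis(
    axis_points: np.ndarray, params: BetaSplineParams | None = None
) -> np.ndarray:
    """Resample an axis polyline to uniform point density via its spline.

    The output has ``max(2, ceil(d / d0))`` points where ``d`` is the
    endpoint chord length (branch bending is deliberately ignored); the
    first and last output points are set exactly to the axis endpoints.
    """
    if params is None:
        params = BetaSplineParams()
    P = np.asarray(axis_points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("resample_axis needs at least 2 axis points")
    d = float(np.linalg.norm(P[-1] - P[0]))
    if d <= 0.0:
        raise ValueError("degenerate axis: coincident endpoints")
    n_out = max(2, math.ceil(d / params.d0))
    us = np.linspace(0.0, 1.0, n_out)
    out = np.array([evaluate_spline(P, u, params) for u in us])
    out[0] = P[0]
    out[-1] = P[-1]
    return out
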