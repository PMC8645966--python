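"""Closed-form receptive-profile models and roto-translation curve geometry.

This module collects the analytic objects the rest of the package fits,
generates, or integrates against:

* a Laplacian-of-Gaussian (LoG) profile — the classical model of the
  radially symmetric receptive profiles of LGN cells;
* a Gabor profile — the standard model of V1 simple-cell receptive
  profiles, parameterized by amplitude, center, orientation, anisotropic
  scales, spatial frequency and phase;
* the circular-arc integral curves of the vector fields
  X1 = (cos theta, sin theta, 0), X2 = (0, 0, 1) that generate the
  sub-Riemannian structure on R^2 x S^1 used to model association fields.

Filters live on a normalized square grid: a size-``s`` filter is evaluated
at ``x, y in linspace(-1, 1, s)``, with ``x`` the column index increasing
rightward and ``y`` the row index increasing downward.  All fitted length
scales (``sigma`` and friends) are reported in these normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoGParams",
    "GaborParams",
    "IntegralCurveParams",
    "filter_grid",
    "log_profile",
    "gabor_profile",
    "integral_curve",
    "CURVATURE_EPS",
]

#: below this |k| the integral curve uses the analytic straight-line limit,
#: avoiding catastrophic cancellation in sin(kt)/k and (1-cos(kt))/k.
CURVATURE_EPS = 1e-8


@dataclass(frozen=True)
class LoGParams:
    """Laplacian-of-Gaussian profile parameter (normalized grid units)."""

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive real, got {self.sigma!r}")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a translated, rotated, dilated Gabor profile.

    ``theta`` is the orientation of the carrier axis, pi-periodic and stored
    in [0, pi); ``phi`` is the phase in [-pi, pi] and determines the parity
    (even/odd) of the profile; ``f`` is the spatial frequency in cycles per
    normalized grid unit.
    """

    amplitude: float
    x0: float
    y0: float
    theta: float
    sigma_x: float
    sigma_y: float
    f: float
    phi: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if self.f <= 0:
            raise ValueError("frequency f must be positive")
        if not (0.0 <= self.theta < np.pi):
            raise ValueError("theta must lie in [0, pi)")
        if not (-np.pi <= self.phi <= np.pi):
            raise ValueError("phi must lie in [-pi, pi]")


@dataclass(frozen=True)
class IntegralCurveParams:
    """A circular-arc integral curve of X1 + k X2 on R^2 x S^1.

    ``k`` is the curvature; the curve starts at ``start = (x0, y0, theta0)``
    at t = 0 and is sampled on the strictly increasing ``t_grid``.
    """

    k: float
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 51))

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be a strictly increasing 1-D sequence")
        object.__setattr__(self, "t_grid", t)


def filter_grid(s: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized coordinate grid for a square ``s x s`` filter.

    Returns ``(X, Y)`` meshgrids with x in [-1, 1] increasing along columns
    and y in [-1, 1] increasing along rows (i.e. downward in image display).
    """
    if s < 1 or s % 2 == 0:
        raise ValueError("filter size must be a positive odd integer")
    c = np.linspace(-1.0, 1.0, s)
    return np.meshgrid(c, c)


def log_profile(x, y, params: LoGParams) -> np.ndarray:
    """Laplacian-of-Gaussian receptive profile.

    psi(x, y) = -1/(pi sigma^4) [1 - (x^2+y^2)/(2 sigma^2)] exp(-(x^2+y^2)/(2 sigma^2))

    At the origin this reduces to -1/(pi sigma^4); the profile is radially
    symmetric and integrates to zero over the plane.
    """
    s2 = params.sigma**2
    r2 = np.asarray(x, dtype=float) ** 2 + np.asarray(y, dtype=float) ** 2
    return -1.0 / (np.pi * s2**2) * (1.0 - r2 / (2.0 * s2)) * np.exp(-r2 / (2.0 * s2))


def gabor_profile(x, y, params: GaborParams) -> np.ndarray:
    """Gabor receptive profile with translation, rotation and dilation.

    The canonical profile ``A exp(-(x^2+y^2)/2) cos(2 pi f x + phi)`` is
    translated by (x0, y0), rotated by theta, and dilated by
    (sigma_x, sigma_y).  The carrier oscillates along the rotated x-axis, so
    ``theta`` is the direction of modulation (the stripes run orthogonally).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - params.x0
    dy = y - params.y0
    ct, st = np.cos(params.theta), np.sin(params.theta)
    # rotate into the filter frame, then dilate
    u = (ct * dx + st * dy) / params.sigma_x
    v = (-st * dx + ct * dy) / params.sigma_y
    envelope = np.exp(-(u**2 + v**2) / 2.0)
    carrier = np.cos(2.0 * np.pi * params.f * (ct * dx + st * dy) + params.phi)
    return params.amplitude * envelope * carrier


def integral_curve(params: IntegralCurveParams) -> np.ndarray:
    """Sample an integral curve of X1 + k X2 on the parameter grid.

    From the origin with theta0 = 0 the curve is the circular arc

        x(t) = sin(k t)/k,  y(t) = (1 - cos(k t))/k,  theta(t) = k t,

    a circle of radius 1/|k| through the origin tangent to the x-axis.
    General starts are obtained by translating and rotating that arc.  For
    |k| below :data:`CURVATURE_EPS` the analytic k -> 0 limit (a straight
    line) is used.

    Returns an array of shape ``(len(t_grid), 3)`` with columns (x, y, theta).
    """
    t = params.t_grid
    k = params.k
    if abs(k) < CURVATURE_EPS:
        xs, ys, ths = t.copy(), np.zeros_like(t), np.zeros_like(t)
    else:
        xs = np.sin(k * t) / k
        ys = (1.0 - np.cos(k * t)) / k
        ths = k * t
    x0, y0, th0 = params.start
    c, s = np.cos(th0), np.sin(th0)
    out = np.empty((t.size, 3))
    out[:, 0] = x0 + c * xs - s * ys
    out[:, 1] = y0 + s * xs + c * ys
    out[:, 2] = th0 + ths
    return out
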