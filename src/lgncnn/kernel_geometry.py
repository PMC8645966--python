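"""Geometry of the learned lateral connectivity kernel in R^2 x S^1.

The lateral kernel ``K(i, j, f, g)`` couples first-layer filters f and g at
a spatial displacement (i, j).  Once each filter has been assigned a center
and an orientation by its Gabor fit, the kernel can be re-indexed by
*relative position and orientation* — the natural coordinates of cortical
connectivity models.  This module performs that re-parameterization and the
downstream analyses:

* orientation-tuning (hypercolumn) profiles at zero displacement, where a
  Mexican-hat shape indicates excitation of similar orientations flanked by
  inhibition;
* a planar vector field obtained by projecting the orientation fiber down
  weighted by kernel strength;
* association fields as streamlines of that vector field, compared against
  the circular-arc integral curves of the roto-translation group by fitting
  the curvature parameter k.

Coordinate convention: kernel rows (index i) increase downward like image
rows, but all geometry here is done in mathematical axes.  A displacement
(i, j) maps to (x, y) = (j - r, r - i) and a fitted image-convention
orientation theta maps to (-theta) mod pi, so that theta is measured
counter-clockwise from +x everywhere in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .fitting import FitResult, Parity, classify_parity
from .rf_models import GaborParams, IntegralCurveParams, integral_curve

__all__ = [
    "ReparamKernel",
    "OrientationProfile",
    "PlanarVectorField",
    "AssociationField",
    "image_theta_to_math",
    "reparameterize",
    "hypercolumn_profile",
    "project_spatial",
    "vector_field",
    "streamlines",
    "default_seeds",
    "fit_arc",
    "fit_association_field",
]


def image_theta_to_math(theta: float | np.ndarray) -> float | np.ndarray:
    """Convert an orientation fitted in image coordinates (y down) to
    mathematical convention (y up, counter-clockwise from +x), pi-periodic."""
    return (-np.asarray(theta)) % np.pi


@dataclass
class ReparamKernel:
    """Lateral kernel re-indexed by relative position and orientation.

    ``values[i, j, a, b]`` couples the a-th and b-th retained filters (both
    axes sorted by orientation) at displacement (i, j), after shifting each
    (f, g) slice so that (i, j) = (0, 0) means the fitted filter centers
    coincide.  ``orientations`` are ascending in [0, pi), mathematical
    convention.  ``mass_loss`` is the total |mass| shifted off the support.
    """

    values: np.ndarray
    orientations: np.ndarray
    parity: Parity | None
    filter_indices: np.ndarray
    mass_loss: float

    @property
    def radius(self) -> int:
        return (self.values.shape[0] - 1) // 2


@dataclass
class OrientationProfile:
    """Zero-displacement kernel strength as a function of orientation."""

    theta_g: np.ndarray
    strength: np.ndarray
    theta_f: float


@dataclass
class PlanarVectorField:
    """Vector field on the displacement lattice, mathematical axes.

    Arrays are indexed [iy, ix] with x = ix - r and y = iy - r; the vector
    norm at each point equals the kernel maximum over the orientation fiber.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    mag: np.ndarray | None = None  # stored so the max_g law holds exactly

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy) if self.mag is None else self.mag


@dataclass
class AssociationField:
    """Streamlines of the projected field plus fitted circular-arc curvature."""

    curves: list[np.ndarray]
    seeds: list[np.ndarray]
    initial_orientations: list[float]
    k: list[float] = field(default_factory=list)
    mean_distance: list[float] = field(default_factory=list)


def _shift_slice(sl: np.ndarray, drow: int, dcol: int) -> tuple[np.ndarray, float]:
    """Integer-shift a 2-D slice with zero fill; returns (shifted, lost mass)."""
    out = np.zeros_like(sl)
    S = sl.shape[0]
    r0s, r1s = max(0, drow), min(S, S + drow)
    c0s, c1s = max(0, dcol), min(S, S + dcol)
    if r0s < r1s and c0s < c1s:
        out[r0s:r1s, c0s:c1s] = sl[r0s - drow : r1s - drow, c0s - dcol : c1s - dcol]
    lost = float(np.sum(np.abs(sl)) - np.sum(np.abs(out)))
    return out, lost


def reparameterize(
    K: np.ndarray,
    fits: list[FitResult],
    filter_size: int,
    split_parity: bool = True,
    exclude_complex: bool = True,
) -> dict[Parity | None, ReparamKernel]:
    """Re-index the lateral kernel by relative position and orientation.

    For every retained pair (f, g) the spatial slice ``K[:, :, f, g]`` is
    translated by the rounded difference of the fitted centers, so that a
    displacement of (0, 0) corresponds to coincident receptive-field
    centers; values shifted off the support are dropped (and accounted in
    ``mass_loss``), vacated cells are zero-filled.  Filter axes are then
    permuted to ascending orientation.  When ``split_parity`` the kernel is
    restricted to same-parity (f, g) pairs, one output per parity.

    A filter whose entry in ``fits`` is None (no usable fit) is excluded
    with a logged warning, as are "complex shape" filters when
    ``exclude_complex``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 4 or K.shape[0] != K.shape[1] or K.shape[2] != K.shape[3]:
        raise ValueError("K must have shape (S, S, n, n)")
    n = K.shape[2]
    if len(fits) != n:
        raise ValueError(f"need one fit entry per filter: {len(fits)} for n={n}")
    missing = [i for i, f in enumerate(fits) if f is None]
    if missing:
        logging.getLogger(__name__).warning(
            "excluding %d filter(s) without a fit: %s", len(missing), missing
        )

    half_px = (filter_size - 1) / 2.0
    keep = np.array(
        [
            f is not None and not (exclude_complex and f.complex_shape)
            for f in fits
        ],
        dtype=bool,
    )
    thetas = np.array(
        [
            image_theta_to_math(f.params.theta)
            if f is not None and isinstance(f.params, GaborParams)
            else 0.0
            for f in fits
        ]
    )
    # fitted centers in map pixels, (row, col) = (y0, x0) scaled from the
    # normalized [-1, 1] filter grid
    centers = np.array(
        [
            (f.params.y0 * half_px, f.params.x0 * half_px)
            if f is not None and isinstance(f.params, GaborParams)
            else (0.0, 0.0)
            for f in fits
        ]
    )
    parities = [
        classify_parity(f.params.phi)
        if f is not None and isinstance(f.params, GaborParams)
        else None
        for f in fits
    ]

    groups: dict[Parity | None, np.ndarray]
    if split_parity:
        groups = {
            p: np.flatnonzero([keep[i] and parities[i] is p for i in range(n)])
            for p in (Parity.EVEN, Parity.ODD)
        }
    else:
        groups = {None: np.flatnonzero(keep)}

    out: dict[Parity | None, ReparamKernel] = {}
    for par, idx in groups.items():
        if idx.size == 0:
            continue
        order = idx[np.argsort(thetas[idx], kind="stable")]
        m = order.size
        values = np.zeros((K.shape[0], K.shape[1], m, m))
        mass_loss = 0.0
        for a, fa in enumerate(order):
            for b, gb in enumerate(order):
                d = centers[gb] - centers[fa]
                drow, dcol = int(round(d[0])), int(round(d[1]))
                values[:, :, a, b], lost = _shift_slice(K[:, :, fa, gb], drow, dcol)
                mass_loss += lost
        out[par] = ReparamKernel(values, thetas[order], par, order, mass_loss)
    return out


def hypercolumn_profile(
    RK: ReparamKernel, f: int, smooth: bool = False, window: int = 5
) -> OrientationProfile:
    """Orientation-tuning profile within a hypercolumn.

    Restricts the kernel to zero displacement — filters sharing a retinal
    position — and reads the connection strength of reference filter ``f``
    to every other orientation.  Optional smoothing is a centered moving
    average (edges renormalized by the actual window coverage).
    """
    r = RK.radius
    strength = RK.values[r, r, f, :].astype(float)
    if smooth and window > 1:
        kern = np.ones(window)
        strength = np.convolve(strength, kern, mode="same") / np.convolve(
            np.ones_like(strength), kern, mode="same"
        )
    return OrientationProfile(RK.orientations.copy(), strength, float(RK.orientations[f]))


def project_spatial(RK: ReparamKernel, f: int, upsample: int = 1) -> np.ndarray:
    """Project the 3-D kernel around filter ``f`` onto the plane.

    Takes the maximum over the orientation fiber per spatial cell, then
    (optionally) upsamples with cubic spline interpolation for display.
    Rows are flipped to mathematical y-up orientation.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    proj = RK.values[:, :, f, :].max(axis=2)
    proj = np.flipud(proj)  # math convention: y grows upward
    if upsample > 1:
        proj = ndimage.zoom(proj, upsample, order=3)
    return proj


def vector_field(RK: ReparamKernel, f: int) -> PlanarVectorField:
    """Project the orientation fiber down to a planar vector field.

    At each displacement the direction is the normalized kernel-weighted sum
    of the unit vectors (cos theta_g, sin theta_g) and the magnitude is the
    kernel maximum over g.  Points where the weighted sum cancels (possible
    for antiparallel contributions) or where the maximum is non-positive get
    the zero vector; streamline integration terminates there.
    """
    r = RK.radius
    W = RK.values[:, :, f, :]  # (S, S, m) indexed (row, col, g)
    vg = np.stack([np.cos(RK.orientations), np.sin(RK.orientations)], axis=1)
    vec = W @ vg  # (S, S, 2)
    mx = W.max(axis=2)
    norm = np.hypot(vec[..., 0], vec[..., 1])
    ok = (norm > 1e-12) & (mx > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(ok, vec[..., 0] / norm, 0.0)
        uy = np.where(ok, vec[..., 1] / norm, 0.0)
    mag = np.where(ok, mx, 0.0)
    # flip rows to math y-up layout, indexed [iy, ix]
    vx = np.flipud(mag * ux)
    vy = np.flipud(mag * uy)
    coords = np.arange(-r, r + 1, dtype=float)
    X, Y = np.meshgrid(coords, coords)
    return PlanarVectorField(X, Y, vx, vy, np.flipud(mag).copy())


def _bilinear_aligned(
    vx: np.ndarray, vy: np.ndarray, fx: float, fy: float, heading: np.ndarray
) -> np.ndarray:
    """Bilinear sample of a pi-periodic direction field at fractional indices.

    The field encodes *orientations*, so neighboring lattice vectors may
    point in opposite senses (and inhibitory kernel weights can flip signs
    outright).  Each corner vector is first aligned with the current
    heading (flipped if its dot product with it is negative) and only then
    interpolated — the standard treatment when tracing streamlines through
    orientation data.
    """
    ny, nx = vx.shape
    x0, y0 = int(np.floor(fx)), int(np.floor(fy))
    x0 = min(max(x0, 0), nx - 2)
    y0 = min(max(y0, 0), ny - 2)
    tx, ty = fx - x0, fy - y0
    out = np.zeros(2)
    for dy_, dx_, w in (
        (0, 0, (1 - tx) * (1 - ty)),
        (0, 1, tx * (1 - ty)),
        (1, 0, (1 - tx) * ty),
        (1, 1, tx * ty),
    ):
        v = np.array([vx[y0 + dy_, x0 + dx_], vy[y0 + dy_, x0 + dx_]])
        if v @ heading < 0:
            v = -v
        out += w * v
    return out


def default_seeds(theta_f: float, n: int = 7, spacing: float = 0.5) -> list[np.ndarray]:
    """Seeds on the segment through (0, 0) perpendicular to theta_f."""
    normal = np.array([-np.sin(theta_f), np.cos(theta_f)])
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    return [t * normal for t in offsets]


def streamlines(
    V: PlanarVectorField,
    seeds: list[np.ndarray],
    theta_f: float = 0.0,
    step: float = 0.1,
    max_steps: int = 10_000,
    both_directions: bool = True,
) -> AssociationField:
    """Integrate streamlines of the direction field from each seed.

    Fixed-step 4th-order Runge-Kutta on the *normalized* field direction
    (so the step size is arc length), with heading-aligned bilinear
    interpolation between lattice points (see :func:`_bilinear_aligned`).
    Integration stops at the grid boundary or where the interpolated
    magnitude vanishes.  Each returned polyline starts at its seed; with
    ``both_directions`` a second, backward curve (initial orientation
    theta_f + pi) is emitted per seed.
    """
    xmin, xmax = float(V.x.min()), float(V.x.max())
    ymin, ymax = float(V.y.min()), float(V.y.max())
    mag = V.magnitude
    mag_tol = 1e-9 * max(mag.max(), 1e-30)

    def direction(p: np.ndarray, heading: np.ndarray) -> np.ndarray | None:
        if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
            return None
        v = _bilinear_aligned(V.vx, V.vy, p[0] - xmin, p[1] - ymin, heading)
        n = np.hypot(v[0], v[1])
        if n < mag_tol:
            return None
        return v / n

    def integrate(seed: np.ndarray, theta0: float) -> np.ndarray:
        heading = np.array([np.cos(theta0), np.sin(theta0)])
        pts = [np.asarray(seed, dtype=float)]
        p = pts[0]
        for _ in range(max_steps):
            k1 = direction(p, heading)
            if k1 is None:
                break
            k2 = direction(p + 0.5 * step * k1, heading)
            if k2 is None:
                break
            k3 = direction(p + 0.5 * step * k2, heading)
            if k3 is None:
                break
            k4 = direction(p + step * k3, heading)
            if k4 is None:
                break
            move = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            p = p + step * move
            heading = move / max(np.hypot(*move), 1e-30)
            if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
                break
            pts.append(p)
        return np.array(pts)

    curves, seed_list, orients = [], [], []
    for seed in seeds:
        seed = np.asarray(seed, dtype=float)
        if not (xmin <= seed[0] <= xmax and ymin <= seed[1] <= ymax):
            raise ValueError(f"seed {seed} lies outside the field grid")
        curves.append(integrate(seed, theta_f))
        seed_list.append(seed)
        orients.append(float(theta_f))
        if both_directions:
            curves.append(integrate(seed, theta_f + np.pi))
            seed_list.append(seed)
            orients.append(float(theta_f + np.pi))
    return AssociationField(curves, seed_list, orients)


def fit_arc(
    curve: np.ndarray,
    theta_f: float,
    k_bounds: tuple[float, float] = (-5.0, 5.0),
) -> tuple[float, float]:
    """Fit the curvature of a circular arc to a polyline.

    The candidate arcs are the integral curves of X1 + k X2 through the
    polyline's start point with initial orientation ``theta_f``; points are
    matched by arc length from the start (the arcs are unit-speed, so the
    arc parameter equals arc length).  Returns the curvature minimizing the
    mean Euclidean distance between matched points, and that distance.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 3:
        raise ValueError("curve must be an (N, 2) polyline with N >= 3")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dedup = np.concatenate([[True], np.diff(s) > 0])
    s, pts = s[dedup], curve[dedup]
    if s.size < 3:
        raise ValueError("curve is degenerate (coincident points)")
    start = (pts[0, 0], pts[0, 1], float(theta_f))

    def mean_dist(k: float) -> float:
        arc = integral_curve(IntegralCurveParams(k, start, s))
        return float(np.mean(np.linalg.norm(arc[:, :2] - pts, axis=1)))

    # the objective oscillates in k once the arc winds, so a coarse scan
    # locates the global basin before local refinement
    grid = np.linspace(k_bounds[0], k_bounds[1], 201)
    costs = [mean_dist(k) for k in grid]
    i = int(np.argmin(costs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        mean_dist, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
    )
    best_k, best_c = float(res.x), float(res.fun)
    if costs[i] < best_c:
        best_k, best_c = float(grid[i]), float(costs[i])
    return best_k, best_c


def fit_association_field(af: AssociationField, min_points: int = 3) -> AssociationField:
    """Fit an arc curvature to every streamline of an association field.

    Curves too short to constrain an arc get k = nan.  Fills the ``k`` and
    ``mean_distance`` lists in place and returns the field.
    """
    af.k, af.mean_distance = [], []
    for curve, th0 in zip(af.curves, af.initial_orientations):
        if curve.shape[0] < min_points:
            af.k.append(float("nan"))
            af.mean_distance.append(float("nan"))
            continue
        k, d = fit_arc(curve, th0)
        af.k.append(k)
        af.mean_distance.append(d)
    return af
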