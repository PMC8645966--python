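"""Fit analytic LoG / Gabor models to learned filters and organize the bank.

The prefilter of the network is compared against a Laplacian-of-Gaussian
(the classical LGN receptive-profile model) and the first-layer filters
against Gabor profiles (the classical V1 simple-cell model).  The fitted
Gabor parameters — center (x0, y0), orientation theta and phase phi — then
serve as coordinates for the geometric analysis of the lateral kernel.

Both fits are nonlinear least squares on the normalized filter grid (see
:mod:`lgncnn.rf_models`); fit quality is reported as the Pearson correlation
between the filter and the fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import optimize, stats

from .rf_models import GaborParams, LoGParams, filter_grid, gabor_profile, log_profile

__all__ = [
    "FitResult",
    "Parity",
    "fit_log",
    "fit_gabor",
    "fit_gabor_bank",
    "classify_parity",
    "sign_normalize_even",
    "order_by_orientation",
    "COMPLEX_SHAPE_THRESHOLD",
]

#: filters whose best fit correlates below this are flagged "complex shape"
#: and excluded from the kernel re-parameterization.
COMPLEX_SHAPE_THRESHOLD = 0.5


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting an analytic profile to one filter."""

    params: LoGParams | GaborParams
    amplitude_scale: float
    correlation: float
    p_value: float
    converged: bool

    @property
    def complex_shape(self) -> bool:
        return self.correlation < COMPLEX_SHAPE_THRESHOLD


class Parity(str, Enum):
    """Phase class of a Gabor profile: odd detects boundaries, even interiors."""

    ODD = "odd"
    EVEN = "even"


def _check_filter(filt: np.ndarray) -> np.ndarray:
    filt = np.asarray(filt, dtype=float)
    if filt.ndim != 2 or filt.shape[0] != filt.shape[1] or filt.shape[0] % 2 == 0:
        raise ValueError("filter must be a square, odd-sized 2-D array")
    if not np.all(np.isfinite(filt)):
        raise ValueError("filter contains non-finite values")
    return filt


def _correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant surface")
    r, p = stats.pearsonr(a.ravel(), b.ravel())
    return float(r), float(p)


def fit_log(filt: np.ndarray) -> FitResult:
    """Least-squares LoG fit over (sigma, amplitude scale).

    A free positive amplitude multiplier accompanies sigma because learned
    filters carry an arbitrary scale (batch normalization absorbs any fixed
    normalization); the reported sigma is unaffected by it.
    """
    filt = _check_filter(filt)
    X, Y = filter_grid(filt.shape[0])
    target = filt.ravel()

    def model(_, sigma, c):
        return c * log_profile(X, Y, LoGParams(sigma)).ravel()

    best = None
    for sigma0 in (0.1, 0.2, 0.4, 0.8):
        peak = log_profile(0.0, 0.0, LoGParams(sigma0))
        c0 = filt[filt.shape[0] // 2, filt.shape[1] // 2] / peak
        if c0 <= 0:
            c0 = max(np.max(np.abs(filt)) / abs(peak), 1e-12)
        try:
            popt, _ = optimize.curve_fit(
                model,
                None,
                target,
                p0=[sigma0, c0],
                bounds=([1e-3, 1e-12], [5.0, np.inf]),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((model(None, *popt) - target) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise RuntimeError("LoG fit failed to converge from all starts")
    sigma, c = best[1]
    params = LoGParams(float(sigma))
    surface = c * log_profile(X, Y, params)
    r, p = _correlate(filt, surface)
    return FitResult(params, float(c), r, p, True)


def _canonical_gabor(v: np.ndarray) -> GaborParams:
    """Map a raw parameter vector to the canonical Gabor parameterization.

    Uses the identities gabor(A<0) = gabor(|A|, phi + pi) and
    gabor(theta + pi, phi) = gabor(theta, -phi) to enforce A > 0,
    theta in [0, pi), phi in [-pi, pi].
    """
    A, x0, y0, theta, sx, sy, f, phi = (float(t) for t in v)
    if A < 0:
        A, phi = -A, phi + np.pi
    n = np.floor(theta / np.pi)
    theta = theta - n * np.pi
    if n % 2 != 0:
        phi = -phi
    theta = theta % np.pi
    phi = np.arctan2(np.sin(phi), np.cos(phi))  # wrap to (-pi, pi]
    if phi > np.pi:
        phi = np.pi
    return GaborParams(A, x0, y0, theta, sx, sy, f, phi)


def fit_gabor(filt: np.ndarray, n_refine: int = 12) -> FitResult:
    """Multi-start nonlinear least-squares Gabor fit.

    The objective is nonconvex in orientation, phase and frequency, so a
    coarse grid of starts (8 orientations x 4 phases x 3 frequencies) is
    screened by initial residual and the ``n_refine`` most promising starts
    are polished with bounded least squares.  The best fit by residual is
    returned with theta folded to [0, pi) and phi to [-pi, pi].

    The fitted frequency is capped at the grid Nyquist rate, (s - 1)/4
    cycles per normalized unit: on the sampling lattice a carrier is
    exactly indistinguishable from its reciprocal-lattice aliases, so
    without the cap the optimizer may return an aliased high-frequency
    solution with a spurious orientation.
    """
    filt = _check_filter(filt)
    s = filt.shape[0]
    X, Y = filter_grid(s)
    target = filt.ravel()
    scale = float(np.max(np.abs(filt)))
    if scale == 0:
        raise ValueError("cannot fit an all-zero filter")

    def residuals(v):
        # evaluated with raw theta/phi (any angle); canonicalized at the end
        A, x0, y0, theta, sx, sy, f, phi = v
        dx, dy = X - x0, Y - y0
        ct, st = np.cos(theta), np.sin(theta)
        u = (ct * dx + st * dy) / sx
        v2 = (-st * dx + ct * dy) / sy
        g = A * np.exp(-(u**2 + v2**2) / 2.0) * np.cos(2 * np.pi * f * (ct * dx + st * dy) + phi)
        return g.ravel() - target

    f_nyquist = (s - 1) / 4.0
    lo = [-np.inf, -1.0, -1.0, -np.pi, 0.05, 0.05, 0.05, -2 * np.pi]
    hi = [np.inf, 1.0, 1.0, 2 * np.pi, 3.0, 3.0, f_nyquist, 2 * np.pi]

    starts = []
    for theta0 in np.arange(8) * np.pi / 8:
        for phi0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
            for f0 in (0.5, 1.0, 2.0):
                starts.append(
                    [scale, 0.0, 0.0, theta0, 0.5, 0.5, min(f0, 0.95 * f_nyquist), phi0]
                )
    # cheap screening: rank starts by their initial residual
    order = np.argsort([np.sum(residuals(v) ** 2) for v in starts])

    best: tuple[float, np.ndarray] | None = None
    converged = False
    for idx in order[:n_refine]:
        try:
            sol = optimize.least_squares(
                residuals, starts[idx], bounds=(lo, hi), max_nfev=400
            )
        except ValueError:
            continue
        if best is None or sol.cost < best[0]:
            best = (float(sol.cost), sol.x)
            converged = bool(sol.success) or converged
    if best is None:
        raise RuntimeError("Gabor fit failed from every start")
    params = _canonical_gabor(best[1])
    surface = gabor_profile(X, Y, params)
    r, p = _correlate(filt, surface)
    return FitResult(params, 1.0, r, p, converged)


def fit_gabor_bank(weights: np.ndarray, **kwargs) -> list[FitResult]:
    """Fit every filter of an ``(n, s, s)`` bank; returns one result each."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 3:
        raise ValueError("expected a bank of shape (n_filters, s, s)")
    return [fit_gabor(w, **kwargs) for w in weights]


def classify_parity(phi: float) -> Parity:
    """Classify a Gabor phase as odd or even.

    Odd if pi/4 < |phi| <= 3pi/4, even otherwise (|phi| <= pi/4 or
    |phi| > 3pi/4).  The boundary |phi| = pi/4 goes to even and
    |phi| = 3pi/4 to odd, closing each interval from below; phases outside
    [-pi, pi] are wrapped first.  The rule depends on |phi| only.
    """
    phi = float(np.arctan2(np.sin(phi), np.cos(phi)))
    a = abs(phi)
    return Parity.ODD if np.pi / 4 < a <= 3 * np.pi / 4 else Parity.EVEN


def sign_normalize_even(filt: np.ndarray, fit: FitResult) -> np.ndarray:
    """Flip an even filter so its central lobe is positive.

    The "central lobe" sample is the filter value at the grid point nearest
    the fitted center (x0, y0).  Odd filters are returned unchanged.
    """
    filt = _check_filter(filt)
    params = fit.params
    if not isinstance(params, GaborParams):
        raise TypeError("sign normalization requires a Gabor fit")
    if classify_parity(params.phi) is not Parity.EVEN:
        return filt.copy()
    s = filt.shape[0]
    coords = np.linspace(-1.0, 1.0, s)
    col = int(np.argmin(np.abs(coords - params.x0)))
    row = int(np.argmin(np.abs(coords - params.y0)))
    return -filt if filt[row, col] < 0 else filt.copy()


def order_by_orientation(fits: list[FitResult]) -> np.ndarray:
    """Permutation sorting filters by fitted orientation, ascending in [0, pi).

    Stable for ties, so equal orientations keep their original order.
    """
    thetas = np.array([f.params.theta for f in fits])
    return np.argsort(thetas, kind="stable")
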