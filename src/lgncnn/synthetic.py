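"""Synthetic inputs with known ground truth for every pipeline stage.

Real runs of the full pipeline train on a natural-image dataset; these
generators stand in for each stage's input with analytically known
structure, so that fits, re-parameterizations and association fields can
be checked against ground truth without any download:

* Gabor filter banks with known parameters (emulating a learned first
  convolutional layer);
* Laplacian-of-Gaussian filters with known sigma (emulating the learned
  prefilter);
* a parametric *co-circular* lateral kernel whose orientation profile at
  zero displacement is a difference of Gaussians and whose spatial spread
  follows the co-circularity transport rule — the qualitative structure
  reported for edge co-occurrence statistics in natural images;
* labeled grayscale images of oriented contours (circular arcs of
  class-dependent curvature over 1/f background noise), a stand-in for a
  grayscale natural-image classification set with broad orientation
  statistics.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .rf_models import GaborParams, LoGParams, filter_grid, gabor_profile, log_profile

__all__ = [
    "SyntheticGaborBankSpec",
    "SyntheticKernelSpec",
    "SyntheticImageDatasetSpec",
    "OrientedImageDataset",
    "make_gabor_bank",
    "make_log_filter",
    "make_cocircular_kernel",
    "make_oriented_image_dataset",
    "to_grayscale",
    "save_dataset",
    "load_dataset",
    "load_cifar10_batches",
]


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGaborBankSpec:
    """Sampling ranges for a synthetic first-layer filter bank."""

    n: int = 64
    s: int = 7
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    center_range: tuple[float, float] = (-0.15, 0.15)
    # sharply orientation-tuned filters: envelope elongated along the
    # stripes (sigma_y > sigma_x) and a carrier fast enough to show a full
    # oscillation inside the envelope, yet below the 7-point grid Nyquist
    # (1.5 cycles/unit)
    sigma_x_range: tuple[float, float] = (0.3, 0.5)
    sigma_y_range: tuple[float, float] = (0.4, 0.7)
    f_range: tuple[float, float] = (0.9, 1.4)
    phi_range: tuple[float, float] = (-np.pi, np.pi)
    theta_mode: str = "uniform"  # "uniform" draws, or "even" spacing in [0, pi)
    noise_sd: float = 0.0  # i.i.d. Gaussian noise, as a fraction of the peak
    seed: int = 0


def make_gabor_bank(
    spec: SyntheticGaborBankSpec,
) -> tuple[np.ndarray, list[GaborParams]]:
    """Render a bank of Gabor filters with known parameters plus noise.

    Returns ``(weights, truth)`` where ``weights`` has shape (n, s, s) and
    ``truth`` holds the generating :class:`GaborParams` for each filter.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y = filter_grid(spec.s)
    if spec.theta_mode == "even":
        thetas = (np.arange(spec.n) * np.pi / spec.n) % np.pi
    elif spec.theta_mode == "uniform":
        thetas = rng.uniform(0.0, np.pi, spec.n)
    else:
        raise ValueError(f"unknown theta_mode {spec.theta_mode!r}")
    weights = np.empty((spec.n, spec.s, spec.s))
    truth: list[GaborParams] = []
    for i in range(spec.n):
        p = GaborParams(
            amplitude=rng.uniform(*spec.amplitude_range),
            x0=rng.uniform(*spec.center_range),
            y0=rng.uniform(*spec.center_range),
            theta=float(thetas[i]),
            sigma_x=rng.uniform(*spec.sigma_x_range),
            sigma_y=rng.uniform(*spec.sigma_y_range),
            f=rng.uniform(*spec.f_range),
            phi=rng.uniform(*spec.phi_range),
        )
        w = gabor_profile(X, Y, p)
        if spec.noise_sd > 0:
            w = w + rng.normal(0.0, spec.noise_sd * np.max(np.abs(w)), w.shape)
        weights[i] = w
        truth.append(p)
    return weights, truth


def make_log_filter(
    sigma: float, s: int = 11, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """LoG surface on the normalized s x s grid, plus optional noise."""
    X, Y = filter_grid(s)
    w = log_profile(X, Y, LoGParams(sigma))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd * np.max(np.abs(w)), w.shape)
    return w


# ---------------------------------------------------------------------------
# Co-circular lateral kernel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticKernelSpec:
    """Parametric co-circularity model of a lateral connectivity kernel.

    Orientations are n evenly spaced values in [0, pi), mathematical
    convention.  ``cocircularity`` in [0, 1] interpolates between purely
    collinear transport (0: preferred orientation constant along the axis)
    and full co-circular transport (1: orientation rotates at twice the
    polar angle, linking elements tangent to a common circle).

    The default n is odd: with an even count of evenly spaced orientations
    the antipodal orientation of the reference enters the projected vector
    field's weighted sum unpaired (pi-periodic wrap), slightly biasing the
    field directions and breaking its mirror symmetry.
    """

    n: int = 17
    r: int = 6
    spatial_decay: float = 2.5  # lambda, grid cells
    orientation_width: float = 0.35  # kappa, radians (excitatory lobe)
    inhibition_width_ratio: float = 2.0
    inhibition_amplitude: float = 0.5
    inhibition_range: float = 1.0  # grid cells; inhibition is short-range
    transverse_width: float = 1.5  # grid cells, collinearity concentration
    cocircularity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.spatial_decay, self.orientation_width, self.transverse_width):
            if v <= 0:
                raise ValueError("decay/width parameters must be positive")

    @property
    def orientations(self) -> np.ndarray:
        # cell-centered sampling of [0, pi): with odd n the middle
        # orientation is exactly pi/2, so the reference filter's axis is
        # vertical and reflections across it map the lattice to itself
        return (np.arange(self.n) + 0.5) * np.pi / self.n

    def dog_profile(self, delta: np.ndarray) -> np.ndarray:
        """The generator's angular difference-of-Gaussians tuning curve."""
        delta = (np.asarray(delta) + np.pi / 2) % np.pi - np.pi / 2
        k1 = self.orientation_width
        k2 = k1 * self.inhibition_width_ratio
        return np.exp(-(delta**2) / (2 * k1**2)) - self.inhibition_amplitude * np.exp(
            -(delta**2) / (2 * k2**2)
        )


def make_cocircular_kernel(spec: SyntheticKernelSpec) -> tuple[np.ndarray, dict]:
    """Build a lateral kernel K(i, j, f, g) with co-circular structure.

    K = spatial decay x angular tuning x transverse (collinearity)
    concentration.  The angular term compares theta_g to the co-circular
    transport of theta_f to the displacement point: a Gaussian excitatory
    lobe minus a broader inhibitory lobe whose amplitude decays over
    ``inhibition_range`` cells — inhibition is short-range, long-range
    coupling is excitatory, as in center-surround orientation interaction
    models.  At zero displacement the transport is the identity and the
    inhibition is at full strength, so the hypercolumn profile is exactly
    the generator's difference of Gaussians (a Mexican hat).  Rows follow
    the image convention (i increases downward, y = -i).

    Returns ``(K, truth)`` with the ground-truth description (orientations,
    spec) used by recovery tests.
    """
    n, r = spec.n, spec.r
    thetas = spec.orientations
    coords = np.arange(-r, r + 1)
    J, I = np.meshgrid(coords, coords)  # J: columns (x), I: rows
    Xd = J.astype(float)
    Yd = -I.astype(float)  # math convention
    K = np.zeros((2 * r + 1, 2 * r + 1, n, n))
    for fi, tf in enumerate(thetas):
        ct, st = np.cos(tf), np.sin(tf)
        u = ct * Xd + st * Yd  # along the preferred axis
        v = -st * Xd + ct * Yd  # transverse
        d2 = u**2 + v**2
        alpha = np.arctan2(v, u)
        alpha[r, r] = 0.0  # transport is the identity at zero displacement
        theta_star = tf + spec.cocircularity * 2.0 * alpha
        spatial = np.exp(-d2 / (2 * spec.spatial_decay**2))
        transverse = np.exp(-(v**2) / (2 * spec.transverse_width**2))
        inh_gain = spec.inhibition_amplitude * np.exp(
            -d2 / (2 * spec.inhibition_range**2)
        )
        k1 = spec.orientation_width
        k2 = k1 * spec.inhibition_width_ratio
        for gi, tg in enumerate(thetas):
            delta = (tg - theta_star + np.pi / 2) % np.pi - np.pi / 2
            angular = np.exp(-(delta**2) / (2 * k1**2)) - inh_gain * np.exp(
                -(delta**2) / (2 * k2**2)
            )
            K[:, :, fi, gi] = spatial * transverse * angular
    truth = {"orientations": thetas, "spec": spec}
    return K, truth


# ---------------------------------------------------------------------------
# Oriented-contour image dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImageDatasetSpec:
    """Labeled grayscale images of oriented contours over 1/f noise.

    Each class draws contour curvatures from its own range (absolute
    curvature in 1/pixel units; signs are random), so the label encodes the
    curvature regime.  Contour positions and orientations are uniform, so
    the orientation marginal is approximately uniform.
    """

    n_images: int = 1000
    size: int = 32
    n_classes: int = 2
    curvature_ranges: tuple[tuple[float, float], ...] = ((0.0, 0.02), (0.15, 0.30))
    contours_per_image: tuple[int, int] = (2, 4)
    contour_length_frac: float = 0.8  # arc length as a fraction of image size
    background_amplitude: float = 0.15
    contour_amplitude: float = 1.0
    line_width: float = 0.7  # Gaussian splat sd, pixels (1-2 px lines)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.curvature_ranges) != self.n_classes:
            raise ValueError("one curvature range per class required")


@dataclass
class OrientedImageDataset:
    images: np.ndarray  # (N, H, W) float32 in [0, 1]
    labels: np.ndarray  # (N,) int64
    contour_orientations: np.ndarray  # initial orientation of every contour
    spec: SyntheticImageDatasetSpec = field(repr=False, default=None)


def _pink_noise(rng: np.random.Generator, size: int) -> np.ndarray:
    """Zero-mean 1/f spatial noise, unit standard deviation."""
    white = rng.normal(size=(size, size))
    F = np.fft.fft2(white)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0
    img = np.real(np.fft.ifft2(F / radius))
    img -= img.mean()
    sd = img.std()
    return img / sd if sd > 0 else img


def _render_arc(
    canvas: np.ndarray,
    x0: float,
    y0: float,
    theta0: float,
    k: float,
    length: float,
    width: float,
    amplitude: float,
) -> None:
    """Accumulate an antialiased circular arc onto the canvas (rows = y down)."""
    size = canvas.shape[0]
    n_samp = max(8, int(4 * length))
    t = np.linspace(0.0, length, n_samp)
    if abs(k) < 1e-8:
        xs = x0 + t * np.cos(theta0)
        ys = y0 + t * np.sin(theta0)
    else:
        xs = x0 + (np.sin(k * t + theta0) - np.sin(theta0)) / k
        ys = y0 - (np.cos(k * t + theta0) - np.cos(theta0)) / k
    rad = max(1, int(np.ceil(3 * width)))
    for xc, yc in zip(xs, ys):
        cx, cy = int(round(xc)), int(round(yc))
        if not (-rad <= cx < size + rad and -rad <= cy < size + rad):
            continue
        x_lo, x_hi = max(0, cx - rad), min(size, cx + rad + 1)
        y_lo, y_hi = max(0, cy - rad), min(size, cy + rad + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi) - xc
        gy = np.arange(y_lo, y_hi) - yc
        splat = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * width**2))
        patch = canvas[y_lo:y_hi, x_lo:x_hi]
        np.maximum(patch, amplitude * splat, out=patch)


def make_oriented_image_dataset(spec: SyntheticImageDatasetSpec) -> OrientedImageDataset:
    """Generate the labeled oriented-contour dataset described by the spec."""
    rng = np.random.default_rng(spec.seed)
    images = np.empty((spec.n_images, spec.size, spec.size), dtype=np.float32)
    labels = rng.integers(0, spec.n_classes, spec.n_images)
    orientations: list[float] = []
    length = spec.contour_length_frac * spec.size
    for i in range(spec.n_images):
        img = spec.background_amplitude * _pink_noise(rng, spec.size)
        contours = np.zeros((spec.size, spec.size))
        lo, hi = spec.curvature_ranges[labels[i]]
        n_contours = rng.integers(spec.contours_per_image[0], spec.contours_per_image[1] + 1)
        for _ in range(n_contours):
            kmag = rng.uniform(lo, hi)
            k = kmag * rng.choice([-1.0, 1.0])
            theta0 = rng.uniform(0.0, 2 * np.pi)
            x0 = rng.uniform(0.1 * spec.size, 0.9 * spec.size)
            y0 = rng.uniform(0.1 * spec.size, 0.9 * spec.size)
            _render_arc(
                contours, x0, y0, theta0, k, length, spec.line_width,
                spec.contour_amplitude,
            )
            orientations.append(theta0 % np.pi)
        img = img + contours
        img -= img.min()
        peak = img.max()
        if peak > 0:
            img /= peak
        images[i] = img
    return OrientedImageDataset(
        images, labels.astype(np.int64), np.array(orientations), spec
    )


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luminance conversion with ITU-R BT.601 weights (0.299, 0.587, 0.114).

    Accepts (..., H, W, 3) or (3, H, W) arrays with values in [0, 1].
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim >= 3 and rgb.shape[-1] == 3:
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    elif rgb.ndim == 3 and rgb.shape[0] == 3:
        r, g, b = rgb[0], rgb[1], rgb[2]
    else:
        raise ValueError("expected a 3-channel RGB image")
    return 0.299 * r + 0.587 * g + 0.114 * b


# ---------------------------------------------------------------------------
# PNG + CSV dataset interface
# ---------------------------------------------------------------------------

def save_dataset(directory: str | Path, ds: OrientedImageDataset) -> None:
    """Write images as 8-bit grayscale PNGs with a CSV label manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
            name = f"img_{i:05d}.png"
            arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(directory / name)
            writer.writerow([name, int(lab)])


def load_cifar10_batches(directory: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load CIFAR-10 *binary-version* batches as grayscale arrays.

    Reads every ``*.bin`` file under ``directory`` (each record is one
    label byte followed by 3072 pixel bytes, channel-planar RGB 32x32),
    converts to luminance in [0, 1].  The data files must already be on
    disk — nothing is downloaded.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.bin"))
    if not files:
        raise FileNotFoundError(f"no CIFAR-10 .bin batches under {directory}")
    record = 1 + 3 * 32 * 32
    images, labels = [], []
    for path in files:
        raw = np.frombuffer(path.read_bytes(), dtype=np.uint8)
        if raw.size % record:
            raise ValueError(f"{path} is not a CIFAR-10 binary batch")
        raw = raw.reshape(-1, record)
        labels.append(raw[:, 0].astype(np.int64))
        rgb = raw[:, 1:].reshape(-1, 3, 32, 32).astype(np.float32) / 255.0
        images.append(to_grayscale(rgb.transpose(0, 2, 3, 1)).astype(np.float32))
    return np.concatenate(images), np.concatenate(labels)


def load_dataset(directory: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a PNG + CSV manifest dataset back into arrays in [0, 1]."""
    directory = Path(directory)
    names, labels = [], []
    with open(directory / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["filename"])
            labels.append(int(row["label"]))
    images = np.stack(
        [np.asarray(Image.open(directory / n), dtype=np.float32) / 255.0 for n in names]
    )
    return images, np.asarray(labels, dtype=np.int64)
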