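# Methods

`lgncnn` studies how geometric structure — rotational symmetry, orientation
selectivity, and association-field geometry — emerges in the early layers of
a convolutional network built in analogy with the first stages of the visual
pathway. This note records the models, the conventions, the numerical
choices, and what the synthetic experiments do and do not show.

## The network

The classifier is a standard convolutional stack over grayscale images with
two biologically motivated modifications.

**Prefilter (`l0`).** A single learned filter Ψ⁰ (default 11×11) convolved
over the input, followed by batch normalization and ReLU — an analogue of
the LGN stage, in which all cells share one radially symmetric receptive
profile. With 1/f-dominated input statistics, efficient-coding arguments
predict this filter whitens the input, i.e. becomes center-surround.
We quantify that by fitting a Laplacian of Gaussian

    ψ_LoG(x, y) = −1/(πσ⁴) · [1 − (x²+y²)/(2σ²)] · exp(−(x²+y²)/(2σ²)),

with a free positive amplitude multiplier (learned filters carry an
arbitrary scale — batch normalization absorbs any fixed normalization;
σ is unaffected by the multiplier) and reporting the Pearson correlation
between the filter and the fitted surface.

**Lateral connectivity on the first layer (`l1`).** The first convolutional
layer (default 64 filters of 7×7) carries a learned 4-D kernel
K(i, j, f, g) — spatial displacement (i, j) in {−r..r}², source/target
filter indices f, g — implementing one linear diffusion step on the
feedforward activation h = ReLU(BN(z)):

    h~ = ½ (h + K ∗ h),    (K ∗ h)(g, y, x) = Σ_f Σ_{i,j} K(i,j,f,g) h(f, y−i, x−j).

The step is linear in h, so two applications compose into a single step
driven by the *self-replicated* long-range kernel 2K + K∗K (exact in the
interior of the activation map; zero padding truncates diffusion paths
within r of the border). During joint training a Bernoulli mask drops 20%
of the kernel entries per update (DropConnect on the lateral weights,
inverted scaling, full kernel at evaluation).

**Remaining stack.** Ten convolutional layers (64…128 filters, sizes
7/5/3), each conv → batch-norm → ReLU with same-size zero padding, 2×2 max
pooling after layers 1, 4, 7 and 10, dropout (0.5) after the last
convolution, and three fully-connected layers (1000, 200, n_classes).
`unit_fraction` scales all filter counts and hidden widths; `depth`
truncates the convolutional stack — both used for capacity comparisons and
for desk-scale runs. We apply batch normalization *before* the ReLU in
every block and let the lateral step act on the normalized, rectified
activation; this keeps the diffusion step on a signal with stable scale.

**Training protocol.** Two phases: (1) all weights except K are trained
with the lateral step disabled entirely (h~ = h, not h/2 — a global ½
would only be absorbed by the next batch normalization); (2) K is
initialized uniformly in ±1/(n·S²) and *all* weights are trained jointly.
Both phases early-stop when validation accuracy has not improved for
`patience` epochs. Early stopping is by default purely a stopping rule
(final weights kept); `restore_best=True` reloads the best-validation
snapshot instead. The optimizer is SGD with momentum 0.9, weight decay
1e−4, batch 128, and a 90/10 train/validation split — these are
config-exposed defaults, not claims about any particular reference run.
The engine is a small NumPy implementation (im2col convolutions, manual
backpropagation) in `lgncnn.nnet`; it is exact but CPU-bound, so the
shipped experiments run at reduced scale (see below).

## Fitting the learned filters

First-layer filters are fitted by the eight-parameter Gabor model

    ψ(x, y) = A exp(−(u² /σ_x² + v²/σ_y²)/2) cos(2πf·u_raw + ϕ),

where (u, v) are the coordinates relative to the center (x₀, y₀), rotated
by θ and dilated by (σ_x, σ_y), and u_raw is the rotated (undilated)
coordinate along the carrier axis. Filters live on the normalized grid
x, y ∈ linspace(−1, 1, s), x rightward along columns, y downward along
rows; all lengths and frequencies are in these units. We fit σ_x and σ_y
separately and report both.

Numerical choices:

* **Multi-start.** The objective is nonconvex in (θ, ϕ, f); we screen a
  8×4×3 grid of orientation/phase/frequency starts by initial residual and
  polish the best 12 with bounded least squares.
* **Nyquist cap.** The fitted frequency is bounded by (s−1)/4 cycles per
  unit. On the sampling lattice a carrier is *exactly* indistinguishable
  from its reciprocal-lattice aliases; without the cap, noise can select an
  aliased solution with a spurious orientation.
* **Canonicalization.** A < 0 folds into ϕ + π; θ is reduced to [0, π)
  using ψ(θ+π, ϕ) = ψ(θ, −ϕ); ϕ is wrapped to [−π, π].
* **Parity.** A filter is odd if π/4 < |ϕ| ≤ 3π/4 and even otherwise.
  The boundaries (measure-zero in practice) close the lower interval:
  |ϕ| = π/4 is even, |ϕ| = 3π/4 odd. Even filters whose sampled central
  lobe (the grid point nearest the fitted center) is negative are negated
  for display.
* **Complex shapes.** Filters whose best fit correlates below 0.5 are
  flagged and excluded from the kernel re-parameterization (threshold
  exposed in config).

Known identifiability limits: filters whose envelope is small relative to
the carrier period (σ·f ≲ 0.3 periods) are nearly radially symmetric and
their orientation is weakly constrained; center shifts along the carrier
trade against phase, so parity labels of filters with |ϕ| near the class
boundaries can flip under noise. The recovery tests quantify both at 5%
noise.

## Kernel geometry

**Coordinate convention.** All geometry is done in mathematical axes: a
kernel displacement (i, j) maps to (x, y) = (j, −i) and an
image-convention orientation θ to (−θ) mod π, so θ is counter-clockwise
from +x everywhere downstream of the fits.

**Re-parameterization.** The kernel is split by filter parity, each (f, g)
spatial slice is translated by the rounded difference of fitted centers —
so (0, 0) means coincident receptive-field centers — and the filter axes
are permuted to ascending orientation. Shifts are integer (the support is
small and fitted centers carry sub-pixel noise); mass shifted off the
support is dropped and reported exactly as a `mass_loss` diagnostic.

**Hypercolumn profiles.** The (0, 0) spatial slice as a function of the
partner orientation θ_g. Optional smoothing is a centered moving average
(default window 5, renormalized at the edges). A Mexican-hat shape —
excitation at θ_g = θ_f flanked by inhibition — is the signature of
orientation-tuning sharpening by non-maximal suppression.

**Projected vector field.** At each displacement, direction = the
normalized kernel-weighted sum of unit vectors (cos θ_g, sin θ_g), and
magnitude = the kernel maximum over g. Antiparallel contributions can
cancel the weighted sum; such degenerate points (and non-positive maxima)
get the zero vector. The field is computed on the raw lattice; display
upsampling of the projection is interpolation only.

**Streamlines.** Fixed-step 4th-order Runge–Kutta on the normalized
direction (step = 0.1 cells, max 10⁴ steps), stopping at the grid boundary
or at degenerate vectors. Because the field encodes π-periodic
*orientations*, neighboring lattice vectors may point in opposite senses;
each corner vector is therefore aligned with the current heading (flipped
if the dot product is negative) before bilinear interpolation — the
standard treatment when tracing orientation data, without which the
interpolated field develops spurious vortices. Seeds default to 7 points
spaced 0.5 cells along the trans-axial segment through the origin; each
seed emits a forward and a backward curve (initial orientations θ_f and
θ_f + π).

**Arc fitting.** Streamlines are compared with the circular-arc integral
curves of the roto-translation structure,

    x = sin(kt)/k,  y = (1 − cos(kt))/k,  θ = kt

(straight-line limit used below |k| = 1e−8 to avoid cancellation),
translated/rotated to the curve's start with initial orientation θ_f.
The arcs are unit-speed, so points are matched by arc length from the
start. k minimizes the mean Euclidean distance between matched points:
a coarse scan of 201 values on [−5, 5] (the objective oscillates once an
arc winds) followed by bounded local refinement.

## Synthetic data

The generators provide ground truth for every stage; their defaults define
the study conditions.

* **Gabor bank** (`make_gabor_bank`): n filters on a 7×7 grid with
  amplitude 0.5–1.5, centers within ±0.15, σ_x 0.3–0.5, σ_y 0.4–0.7
  (envelopes elongated along the stripes — sharply orientation-tuned),
  frequency 0.9–1.4 (a full oscillation inside the envelope, below the
  grid Nyquist of 1.5), uniform phase, and i.i.d. Gaussian noise at a
  fraction of the peak (5% in the recovery experiments).
* **Co-circular kernel** (`make_cocircular_kernel`): a parametric model of
  orientation-selective lateral connectivity, K = spatial Gaussian decay
  (λ = 2.5 cells) × angular tuning × transverse concentration (width 1.5
  cells) along the reference axis. The angular term compares θ_g with the
  *co-circular transport* of θ_f to the displacement point (rotation by
  twice the polar angle; the `cocircularity` parameter interpolates to
  purely collinear transport), with a Gaussian excitatory lobe (κ = 0.35
  rad) minus a broader inhibitory lobe whose amplitude decays over ~1 cell
  — inhibition is short-range, long-range coupling excitatory, so the
  zero-displacement profile is exactly a difference of Gaussians while the
  projected vector field stays well defined. 17 orientations,
  cell-centered on [0, π): an odd count keeps the antipodal orientation
  paired in the vector sum, and the middle orientation is exactly π/2 so
  that reflections across the reference axis map the lattice to itself
  (making the curvature-antisymmetry test exact rather than approximate).
  This is a test object, not a fit to data and not a stochastic-process
  fundamental solution.
* **Oriented-contour images** (`make_oriented_image_dataset`): antialiased
  circular arcs (width ~1–2 px, arc length 0.8 × image size, uniform
  position and orientation) over 1/f background noise; the class label is
  the contour-curvature regime (defaults: |k| ∈ [0, 0.02] vs [0.15, 0.30]
  per pixel). The orientation marginal is approximately uniform (KS
  statistic < 0.1 against uniform). The 1/f background supplies the
  second-order statistics of natural images that drive center-surround
  whitening in the prefilter; what the images do *not* have is natural
  higher-order structure (textures, occlusion, lighting), so passing the
  training smoke test shows the mechanism operates, not that the learned
  filters match those trained on natural photographs.

## Desk-scale experiments

The shipped experiments (tests and `scripts/acceptance.py`) run the
training loop at reduced problem size: 1200 images of 24×24, two classes,
`unit_fraction` 0.25 (16 first-layer filters), two convolutional layers,
a 9×9 lateral kernel, 8 epochs per phase, learning rate 0.015, batch 64.
At this scale a run takes a few CPU-minutes, validation accuracy reaches
~0.6–0.75 (chance 0.5), and the prefilter's LoG correlation rises above
its value at random initialization — the correlation climbs through the
joint phase and is still far from the values reachable with full-scale
training on a natural-image dataset. Full-scale reproduction (CIFAR-10
grayscale, 64 filters, 800-epoch phases) is supported by the same code
paths via `ArchitectureConfig`/`TrainingConfig` defaults but is a
long-running computation left to the user.

## Limitations

* The NumPy engine is single-core and eager; it is meant for analysis
  fidelity and desk-scale training, not throughput.
* Vector averaging of π-periodic orientations is intrinsically
  sign-ambiguous; the heading-aligned integrator handles streamlines, but
  the displayed vector field retains the representative-angle convention.
* Integer center shifts discard sub-pixel alignment; the `mass_loss`
  diagnostic bounds the effect.
* Gabor parity near |ϕ| ∈ {π/4, 3π/4} and orientation of near-isotropic
  filters are weakly identifiable under noise; recovery rates are reported
  rather than assumed perfect.
* The general neural-field dynamics with nonlinear activation and decay is
  out of scope; only the single linear diffusion step above is modeled.
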