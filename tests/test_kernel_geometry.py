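"""Kernel re-parameterization, orientation profiles, fields, arc fits."""

import numpy as np
import pytest

import lgncnn as L
from lgncnn import kernel_geometry as kg
from lgncnn.fitting import FitResult
from lgncnn.rf_models import GaborParams


def _fits(thetas_math, centers=None, phi=0.0):
    centers = centers if centers is not None else [(0.0, 0.0)] * len(thetas_math)
    return [
        FitResult(
            GaborParams(1.0, cx, cy, (-th) % np.pi, 0.4, 0.5, 1.0, phi),
            1.0,
            0.95,
            1e-9,
            True,
        )
        for th, (cx, cy) in zip(thetas_math, centers)
    ]


class TestReparameterize:
    def test_zero_centers_is_pure_permutation(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        perm = RK.filter_indices
        assert np.array_equal(RK.values, K[:, :, perm][:, :, :, perm])
        assert RK.mass_loss == 0.0
        assert np.all(np.diff(RK.orientations) > 0)

    def test_center_offset_shifts_slice_and_zeroes_border(self):
        n, S = 2, 5
        rng = np.random.default_rng(0)
        K = rng.normal(size=(S, S, n, n))
        # filter 1 fitted one map pixel right of filter 0 (x0 = 1/3 on a
        # 7-point grid -> 1 px); slice (0, 1) shifts by one column
        fits = _fits([0.3, 0.6], centers=[(0.0, 0.0), (1.0 / 3.0, 0.0)])
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        slice01 = RK.values[:, :, 0, 1]
        assert np.allclose(slice01[:, 1:], K[:, :-1, 0, 1])
        assert np.all(slice01[:, 0] == 0.0)
        assert RK.mass_loss > 0.0

    def test_mass_loss_accounts_shifted_out_values(self):
        n, S = 2, 5
        K = np.ones((S, S, n, n))
        fits = _fits([0.3, 0.6], centers=[(0.0, 0.0), (1.0 / 3.0, 0.0)])
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        # two slices shift by one column (0,1) and (1,0): S cells each
        assert RK.mass_loss == pytest.approx(2 * S)

    def test_parity_split_partitions_filters(self):
        n, S = 4, 5
        rng = np.random.default_rng(1)
        K = rng.normal(size=(S, S, n, n))
        fits = _fits([0.1, 0.4], phi=0.0) + _fits([0.2, 0.5], phi=np.pi / 2)
        out = L.reparameterize(K, fits, filter_size=7)
        assert set(out) == {L.Parity.EVEN, L.Parity.ODD}
        assert sorted(out[L.Parity.EVEN].filter_indices) == [0, 1]
        assert sorted(out[L.Parity.ODD].filter_indices) == [2, 3]

    def test_complex_shape_filters_excluded(self):
        n, S = 3, 5
        K = np.zeros((S, S, n, n))
        fits = _fits([0.1, 0.4, 0.7])
        fits[1] = FitResult(fits[1].params, 1.0, 0.2, 0.5, True)  # poor fit
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        assert list(RK.filter_indices) == [0, 2]

    def test_wrong_fit_count_rejected(self):
        with pytest.raises(ValueError):
            L.reparameterize(np.zeros((5, 5, 3, 3)), _fits([0.1]), filter_size=7)

    def test_missing_fit_excluded_with_warning(self, caplog):
        import logging

        n, S = 3, 5
        K = np.zeros((S, S, n, n))
        fits = _fits([0.1, 0.4, 0.7])
        fits[1] = None
        with caplog.at_level(logging.WARNING, logger="lgncnn.kernel_geometry"):
            RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        assert list(RK.filter_indices) == [0, 2]
        assert any("without a fit" in r.message for r in caplog.records)


class TestHypercolumnProfile:
    def test_constant_kernel_gives_flat_profile(self):
        n, S = 5, 7
        K = np.ones((S, S, n, n))
        fits = _fits(np.linspace(0.1, 2.8, n))
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        prof = L.hypercolumn_profile(RK, 2)
        assert np.allclose(prof.strength, 1.0)

    def test_recovers_generator_mexican_hat(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        f_ref = spec.n // 2
        prof = L.hypercolumn_profile(RK, f_ref, smooth=False)
        dog = spec.dog_profile(prof.theta_g - prof.theta_f)
        r = np.corrcoef(prof.strength, dog)[0, 1]
        assert r > 0.99
        # peak at theta_g = theta_f, flanks negative
        assert prof.strength.argmax() == f_ref
        assert prof.strength.min() < 0

    def test_smoothing_preserves_length_and_reduces_roughness(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        raw = L.hypercolumn_profile(RK, 8, smooth=False)
        smooth = L.hypercolumn_profile(RK, 8, smooth=True, window=5)
        assert smooth.strength.shape == raw.strength.shape
        assert np.abs(np.diff(smooth.strength, 2)).sum() < np.abs(np.diff(raw.strength, 2)).sum()


class TestProjectSpatial:
    def test_single_entry_kernel_peaks_at_displacement(self):
        n, S = 3, 7
        K = np.zeros((S, S, n, n))
        K[1, 5, 0, 1] = 2.0  # i = -2 (rows down), j = +2
        fits = _fits([0.1, 0.5, 0.9])
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        proj = L.project_spatial(RK, 0, upsample=1)
        iy, ix = np.unravel_index(proj.argmax(), proj.shape)
        # math convention: y flipped, so i=1 -> y=+2 -> row index 5
        assert (iy, ix) == (5, 5)

    def test_upsample_one_is_identity_resampling(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        proj = L.project_spatial(RK, 8, upsample=1)
        assert proj.shape == (2 * spec.r + 1, 2 * spec.r + 1)

    def test_upsample_scales_grid(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        proj = L.project_spatial(RK, 8, upsample=4)
        assert proj.shape == (4 * (2 * spec.r + 1), 4 * (2 * spec.r + 1))


class TestVectorField:
    def test_magnitude_equals_max_over_orientations(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        V = L.vector_field(RK, 8)
        W = RK.values[:, :, 8, :]
        expect = np.flipud(W.max(axis=2))
        mask = V.magnitude > 0
        assert np.abs(V.magnitude[mask] - expect[mask]).max() < 1e-12

    def test_single_orientation_kernel_direction(self):
        n, S = 3, 5
        K = np.zeros((S, S, n, n))
        thetas = [0.3, np.pi / 4, 1.2]
        K[:, :, 0, 1] = 0.7  # only the theta = pi/4 target active
        fits = _fits(thetas)
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        V = L.vector_field(RK, 0)
        assert np.abs(V.vx - 0.7 * np.sqrt(2) / 2).max() < 1e-12
        assert np.abs(V.vy - 0.7 * np.sqrt(2) / 2).max() < 1e-12

    def test_equal_weights_bisect(self):
        # equal weight on theta=0 and theta=pi/2 -> 45 degree direction
        n, S = 2, 3
        K = np.zeros((S, S, n, n))
        K[:, :, 0, 0] = 1.0
        K[:, :, 0, 1] = 1.0
        fits = _fits([0.0, np.pi / 2])
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        V = L.vector_field(RK, 0)
        ang = np.arctan2(V.vy, V.vx)
        assert np.abs(ang - np.pi / 4).max() < 1e-12

    def test_antiparallel_cancellation_gives_zero_vector(self):
        # theta=0 and theta just below pi have near-antiparallel unit
        # vectors; build an exact cancellation with opposite-sign weights
        n, S = 2, 3
        K = np.zeros((S, S, n, n))
        K[:, :, 0, 0] = 1.0
        K[:, :, 0, 1] = -1.0  # same orientation, negative weight
        fits = _fits([0.0, 0.0])
        RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
        V = L.vector_field(RK, 0)
        assert np.all(V.vx == 0.0)
        assert np.all(V.vy == 0.0)


class TestStreamlines:
    def _uniform_field(self, r=5):
        coords = np.arange(-r, r + 1, dtype=float)
        X, Y = np.meshgrid(coords, coords)
        return kg.PlanarVectorField(X, Y, np.ones_like(X), np.zeros_like(X))

    def test_uniform_field_gives_straight_lines(self):
        V = self._uniform_field()
        af = L.streamlines(V, [np.array([0.0, 1.0])], theta_f=0.0, step=0.1, both_directions=False)
        curve = af.curves[0]
        assert np.abs(curve[:, 1] - 1.0).max() < 1e-12
        assert curve[-1, 0] > 4.5  # reached the boundary

    def test_rotation_field_gives_circles(self):
        k, r = 0.25, 6
        coords = np.arange(-r, r + 1, dtype=float)
        X, Y = np.meshgrid(coords, coords)
        V = kg.PlanarVectorField(X, Y, -(Y - 1 / k), X)
        af = L.streamlines(V, [np.array([0.0, 0.0])], theta_f=0.0, step=0.05, both_directions=False)
        radius = np.hypot(af.curves[0][:, 0], af.curves[0][:, 1] - 1 / k)
        assert np.abs(radius - 1 / k).max() / (1 / k) < 0.02

    def test_seed_outside_grid_rejected(self):
        V = self._uniform_field(3)
        with pytest.raises(ValueError):
            L.streamlines(V, [np.array([10.0, 0.0])])

    def test_curves_start_at_their_seeds(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        V = L.vector_field(RK, 8)
        tf = RK.orientations[8]
        seeds = L.default_seeds(tf, 5, 0.5)
        af = L.streamlines(V, seeds, theta_f=tf)
        for curve, seed in zip(af.curves, af.seeds):
            assert np.allclose(curve[0], seed)


class TestFitArc:
    @pytest.mark.parametrize("k", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_recovers_curvature_of_exact_arc(self, k):
        t = np.linspace(0.0, 2.0, 801)
        curve = L.integral_curve(L.IntegralCurveParams(k, (0.3, -0.2, 0.7), t))
        khat, dist = L.fit_arc(curve[:, :2], 0.7)
        assert abs(khat - k) < 1e-3
        assert dist < 1e-6

    def test_straight_line_gives_zero_curvature(self):
        x = np.linspace(0, 5, 200)
        curve = np.stack([x, np.zeros_like(x)], axis=1)
        khat, dist = L.fit_arc(curve, 0.0)
        assert abs(khat) < 1e-6
        assert dist < 1e-9

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            L.fit_arc(np.array([[0.0, 0.0], [1.0, 0.0]]), 0.0)
        with pytest.raises(ValueError):
            L.fit_arc(np.zeros((5, 2)), 0.0)  # coincident points


class TestAssociationFieldEndToEnd:
    def test_curvature_antisymmetric_across_axis(self, cocircular_setup):
        spec, K, truth, fits, RK = cocircular_setup
        f_ref = spec.n // 2
        tf = RK.orientations[f_ref]
        V = L.vector_field(RK, f_ref)
        af = L.streamlines(V, L.default_seeds(tf, 7, 0.5), theta_f=tf, both_directions=False)
        L.fit_association_field(af)
        ks = np.array(af.k)
        assert np.allclose(ks + ks[::-1], 0.0, atol=1e-6)
        assert abs(ks[len(ks) // 2]) < 1e-6  # on-axis curve is straight

    def test_curvature_grows_with_cocircularity(self):
        mean_abs = []
        for cc in (0.0, 1.0):
            spec = L.SyntheticKernelSpec(cocircularity=cc)
            K, truth = L.make_cocircular_kernel(spec)
            fits = _fits(truth["orientations"])
            RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
            tf = RK.orientations[spec.n // 2]
            V = L.vector_field(RK, spec.n // 2)
            af = L.streamlines(V, L.default_seeds(tf, 5, 0.5), theta_f=tf, both_directions=False)
            L.fit_association_field(af)
            mean_abs.append(np.nanmean(np.abs(af.k)))
        assert mean_abs[0] < 1e-6  # pure collinearity: straight lines
        assert mean_abs[1] > 0.05
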