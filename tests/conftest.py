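import numpy as np
import pytest

import lgncnn as L
from lgncnn.fitting import FitResult
from lgncnn.rf_models import GaborParams


@pytest.fixture(scope="session")
def cocircular_setup():
    """Synthetic co-circular kernel with matching ground-truth fits.

    The fits mirror the generator exactly: centers at the origin and
    image-convention orientations whose mathematical counterparts are the
    generator's orientation grid, so the re-parameterization is an exact
    round trip.
    """
    spec = L.SyntheticKernelSpec()
    K, truth = L.make_cocircular_kernel(spec)
    fits = [
        FitResult(
            GaborParams(1.0, 0.0, 0.0, (-th) % np.pi, 0.4, 0.5, 1.0, 0.0),
            1.0,
            0.99,
            1e-9,
            True,
        )
        for th in truth["orientations"]
    ]
    RK = L.reparameterize(K, fits, filter_size=7, split_parity=False)[None]
    return spec, K, truth, fits, RK


def make_analysis_bundle(seed=0):
    """Weight bundle whose filter bank and lateral kernel share ground truth.

    One even Gabor per kernel orientation (image-convention theta chosen so
    the fitted mathematical orientations reproduce the kernel's grid),
    centered at the origin, plus a lightly noisy LoG prefilter — so the
    full analysis chain should recover the generators' structure.
    """
    from lgncnn.rf_models import filter_grid, gabor_profile

    kspec = L.SyntheticKernelSpec()
    K, truth = L.make_cocircular_kernel(kspec)
    rng = np.random.default_rng(seed)
    X, Y = filter_grid(7)
    bank = np.stack(
        [
            gabor_profile(
                X,
                Y,
                GaborParams(
                    amplitude=rng.uniform(0.5, 1.5),
                    x0=0.0,
                    y0=0.0,
                    theta=float((-th) % np.pi),
                    sigma_x=rng.uniform(0.3, 0.5),
                    sigma_y=rng.uniform(0.4, 0.7),
                    f=rng.uniform(0.9, 1.4),
                    phi=rng.uniform(-0.1, 0.1),  # all even parity
                ),
            )
            for th in truth["orientations"]
        ]
    )
    psi0 = L.make_log_filter(0.184, s=11, noise_sd=0.02, seed=seed)
    return {"psi0": psi0, "l1_filters": bank, "K1": K}, kspec, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small oriented-contour dataset for fast training tests."""
    spec = L.SyntheticImageDatasetSpec(n_images=160, size=16, seed=11)
    return L.make_oriented_image_dataset(spec)
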