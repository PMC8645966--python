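"""Orchestration: run the full geometric analysis and the model comparison.

``run_analysis`` takes a weight bundle (prefilter, first-layer filter bank,
lateral kernel) and executes the whole analysis chain: LoG fit of the
prefilter, Gabor fits of the filter bank, parity split and orientation
ordering, kernel re-parameterization into R^2 x S^1, hypercolumn
orientation profiles, the projected vector field, association-field
streamlines, and circular-arc fits.  Results are returned as a structured
report and optionally written as CSV tables (the tested surface) and PNG
figures (side effects for inspection).

``compare_architectures`` trains the classical CNN, the LGN-CNN, and the
LGN-CNN with lateral connectivity across seeds and reports mean accuracy
with its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arch, fitting, kernel_geometry as kg
from .fitting import FitResult, Parity

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "compare_architectures"]


@dataclass
class AnalysisConfig:
    """Options of the analysis half (all stages deterministic)."""

    smooth_profile: bool = True
    smoothing_window: int = 5
    upsample: int = 10  # display upsampling of the kernel projection
    n_seeds: int = 7
    seed_spacing: float = 0.5  # grid cells, along the trans-axial segment
    step: float = 0.1  # streamline step, grid cells
    max_steps: int = 10_000
    arc_k_bounds: tuple[float, float] = (-5.0, 5.0)
    reference_parity: str = "even"
    make_figures: bool = False


@dataclass
class AnalysisReport:
    """All computed analysis outputs for one weight bundle."""

    log_fit: FitResult | None
    l1_filters: np.ndarray
    gabor_fits: list[FitResult]
    parities: list[Parity]
    order: np.ndarray
    reparam: dict | None
    reference_parity: Parity | None
    reference_filter: int | None
    profile: kg.OrientationProfile | None
    vector_field: kg.PlanarVectorField | None
    association_field: kg.AssociationField | None
    arc_table: pd.DataFrame | None
    grand_mean_distance: float | None
    provenance: dict = field(default_factory=dict)


def _gabor_table(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    order_index = np.empty(len(report.gabor_fits), dtype=int)
    order_index[report.order] = np.arange(len(report.order))
    for i, (fit, par) in enumerate(zip(report.gabor_fits, report.parities)):
        p = fit.params
        rows.append(
            {
                "filter": i,
                "amplitude": p.amplitude,
                "x0": p.x0,
                "y0": p.y0,
                "theta": p.theta,
                "sigma_x": p.sigma_x,
                "sigma_y": p.sigma_y,
                "f": p.f,
                "phi": p.phi,
                "correlation": fit.correlation,
                "p_value": fit.p_value,
                "parity": par.value,
                "order_index": int(order_index[i]),
                "complex_shape": fit.complex_shape,
            }
        )
    return pd.DataFrame(rows)


def run_analysis(
    bundle: dict, cfg: AnalysisConfig | None = None, outdir: str | Path | None = None
) -> AnalysisReport:
    """Execute the full analysis chain on a weight bundle.

    The bundle must contain ``l1_filters`` (n, s, s); ``psi0`` and ``K1``
    are optional — missing entries simply leave the corresponding report
    sections empty.  Deterministic given (bundle, config).
    """
    cfg = cfg or AnalysisConfig()
    if "l1_filters" not in bundle:
        raise KeyError("weight bundle is missing the 'l1_filters' entry")
    l1 = np.asarray(bundle["l1_filters"], dtype=float)

    log_fit = fitting.fit_log(np.asarray(bundle["psi0"], dtype=float)) if "psi0" in bundle else None

    gabor_fits = fitting.fit_gabor_bank(l1)
    parities = [fitting.classify_parity(f.params.phi) for f in gabor_fits]
    order = fitting.order_by_orientation(gabor_fits)

    reparam = None
    ref_par: Parity | None = None
    ref_idx: int | None = None
    profile = None
    V = None
    af = None
    arc_table = None
    grand = None
    if "K1" in bundle and bundle["K1"] is not None:
        K1 = np.asarray(bundle["K1"], dtype=float)
        reparam = kg.reparameterize(K1, gabor_fits, filter_size=l1.shape[1])
        want = Parity(cfg.reference_parity)
        if want in reparam:
            ref_par = want
        elif reparam:
            ref_par = next(iter(reparam))
        if ref_par is not None:
            RK = reparam[ref_par]
            # reference filter: median orientation of the retained group
            ref_idx = int(np.argsort(RK.orientations)[len(RK.orientations) // 2])
            profile = kg.hypercolumn_profile(
                RK, ref_idx, smooth=cfg.smooth_profile, window=cfg.smoothing_window
            )
            V = kg.vector_field(RK, ref_idx)
            theta_f = float(RK.orientations[ref_idx])
            seeds = kg.default_seeds(theta_f, cfg.n_seeds, cfg.seed_spacing)
            af = kg.streamlines(
                V, seeds, theta_f=theta_f, step=cfg.step, max_steps=cfg.max_steps
            )
            kg.fit_association_field(af)
            arc_table = pd.DataFrame(
                {
                    "curve": np.arange(len(af.curves)),
                    "seed_x": [s[0] for s in af.seeds],
                    "seed_y": [s[1] for s in af.seeds],
                    "initial_orientation": af.initial_orientations,
                    "n_points": [len(c) for c in af.curves],
                    "k": af.k,
                    "mean_distance": af.mean_distance,
                }
            )
            finite = np.asarray(af.mean_distance, dtype=float)
            finite = finite[np.isfinite(finite)]
            grand = float(finite.mean()) if finite.size else float("nan")

    report = AnalysisReport(
        log_fit=log_fit,
        l1_filters=l1,
        gabor_fits=gabor_fits,
        parities=parities,
        order=order,
        reparam=reparam,
        reference_parity=ref_par,
        reference_filter=ref_idx,
        profile=profile,
        vector_field=V,
        association_field=af,
        arc_table=arc_table,
        grand_mean_distance=grand,
        provenance={
            "n_filters": int(l1.shape[0]),
            "filter_size": int(l1.shape[1]),
            "has_psi0": "psi0" in bundle,
            "has_K1": "K1" in bundle and bundle["K1"] is not None,
        },
    )

    if outdir is not None:
        _write_report(report, Path(outdir), cfg)
    return report


def _write_report(report: AnalysisReport, outdir: Path, cfg: AnalysisConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _gabor_table(report).to_csv(outdir / "gabor_fits.csv", index=False)
    if report.log_fit is not None:
        pd.DataFrame(
            [
                {
                    "sigma": report.log_fit.params.sigma,
                    "amplitude_scale": report.log_fit.amplitude_scale,
                    "correlation": report.log_fit.correlation,
                    "p_value": report.log_fit.p_value,
                }
            ]
        ).to_csv(outdir / "log_fit.csv", index=False)
    if report.profile is not None:
        pd.DataFrame(
            {"theta_g": report.profile.theta_g, "strength": report.profile.strength}
        ).to_csv(outdir / "hypercolumn_profile.csv", index=False)
    if report.arc_table is not None:
        report.arc_table.to_csv(outdir / "association_field.csv", index=False)
    if cfg.make_figures:
        _write_figures(report, outdir, cfg)


def _write_figures(report: AnalysisReport, outdir: Path, cfg: AnalysisConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.profile is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(report.profile.theta_g, report.profile.strength, "b-")
        ax.axvline(report.profile.theta_f, color="gray", ls="--", lw=0.8)
        ax.set_xlabel(r"$\theta_g$ (rad)")
        ax.set_ylabel("connection strength")
        ax.set_title("Hypercolumn orientation profile")
        fig.tight_layout()
        fig.savefig(outdir / "hypercolumn_profile.png", dpi=150)
        plt.close(fig)

    if report.reparam is not None and report.reference_parity is not None:
        RK = report.reparam[report.reference_parity]
        proj = kg.project_spatial(RK, report.reference_filter, upsample=cfg.upsample)
        V = report.vector_field
        r = RK.radius
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(
            proj, extent=(-r, r, -r, r), origin="lower", cmap="gray_r"
        )
        ax.quiver(V.x, V.y, V.vx, V.vy, color="tab:blue", width=0.004)
        for curve in report.association_field.curves:
            if len(curve) > 1:
                ax.plot(curve[:, 0], curve[:, 1], "b-", lw=1.0)
        ax.set_title("Kernel projection, vector field and association field")
        fig.tight_layout()
        fig.savefig(outdir / "association_field.png", dpi=150)
        plt.close(fig)

    # filter gallery ordered by orientation (learned filter next to its fit)
    n = len(report.gabor_fits)
    if n:
        from .rf_models import filter_grid, gabor_profile

        X, Y = filter_grid(report.l1_filters.shape[1])
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        fig, axes = plt.subplots(rows, 2 * cols, figsize=(2.0 * cols, 1.1 * rows))
        axes = np.atleast_2d(axes)
        for ax in axes.ravel():
            ax.axis("off")
        for slot, idx in enumerate(report.order):
            fit = report.gabor_fits[idx]
            rr, cc = divmod(slot, cols)
            axes[rr, 2 * cc].imshow(report.l1_filters[idx], cmap="gray")
            axes[rr, 2 * cc + 1].imshow(gabor_profile(X, Y, fit.params), cmap="gray")
            axes[rr, 2 * cc].set_title(f"{fit.params.theta:.2f}", fontsize=6)
        fig.tight_layout()
        fig.savefig(outdir / "filters_vs_fits.png", dpi=120)
        plt.close(fig)


def compare_architectures(
    base_cfg: arch.ArchitectureConfig,
    dataset,
    train_cfg: arch.TrainingConfig,
    n_seeds: int = 2,
    image_size: int = 32,
) -> pd.DataFrame:
    """Train the three model variants across seeds; mean accuracy +/- SEM.

    Variants: classical CNN (no prefilter, no lateral kernel), LGN-CNN
    (prefilter only), and LGN-CNN with lateral connectivity.  All share the
    remaining architecture and the training protocol; only the seed varies
    within a variant.
    """
    if n_seeds < 2:
        raise ValueError("need at least two seeds for a standard error")
    from dataclasses import replace

    variants = {
        "classical_cnn": replace(base_cfg, use_l0=False, use_lateral=False),
        "lgn_cnn": replace(base_cfg, use_l0=True, use_lateral=False),
        "lgn_cnn_lateral": replace(base_cfg, use_l0=True, use_lateral=True),
    }
    rows = []
    for name, cfg in variants.items():
        accs = []
        for s in range(n_seeds):
            tc = replace(train_cfg, seed=train_cfg.seed + s)
            net = arch.build_network(cfg, image_size=image_size, seed=tc.seed)
            history = arch.train(net, dataset, tc)
            accs.append(max(history["val_acc"]))
        accs = np.asarray(accs)
        rows.append(
            {
                "model": name,
                "n_seeds": n_seeds,
                "mean_accuracy": float(accs.mean()),
                "sem": float(accs.std(ddof=1) / np.sqrt(n_seeds)),
            }
        )
    return pd.DataFrame(rows)
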