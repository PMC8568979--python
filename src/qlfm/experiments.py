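"""End-to-end synthetic experiments used for validation and benchmarking.

These functions wire the full pipeline together at desk scale: phantom ->
capture simulation -> realignment -> reconstruction -> metrics. They are
the programmatic equivalents of the instrument-characterisation bench
experiments (bead SBR in a scattering phantom; PSF calibration from a bead
image) and are reused by the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import calibrate_psf
from .config import OpticalConfig, ReconstructionOptions, preset_20x_na05
from .grid import MultiscaleGrid, analytic_resolution_model, build_grid
from .metrics import Roi, compute_sbr
from .phase_space import bin_views, realign
from .projection import psf_for_grid
from .psf import PSFSimulator
from .reconstruction import admm_reconstruct
from .synthetic import NoiseParams, make_bead_phantom, make_scattering_phantom, simulate_capture
from .zernike import zernike_wavefront

__all__ = ["SbrExperimentResult", "sbr_fold_change_experiment", "calibration_recovery_experiment"]


@dataclass
class SbrExperimentResult:
    sbr_complete: float
    sbr_incomplete: float
    fold_change: float
    n_beads: int
    details: dict


def _fine_subgrid(grid: MultiscaleGrid) -> MultiscaleGrid:
    fine = [s for s in grid.slabs if grid.factor(s) == 1]
    return MultiscaleGrid(
        slabs=tuple(fine),
        lens_pitch_sample=grid.lens_pitch_sample,
        num_lenses=grid.num_lenses,
    )


def _pick_background_center(grid: MultiscaleGrid, positions: np.ndarray) -> tuple[float, float, float]:
    """Corner of the fine field of view farthest from every bead (laterally)."""
    ny, nx = grid.num_lenses
    step0 = grid.lens_pitch_sample
    ry = 0.36 * ny * step0
    rx = 0.36 * nx * step0
    best, best_d = None, -1.0
    for sy in (-1, 1):
        for sx in (-1, 1):
            c = (0.0, sy * ry, sx * rx)
            d = np.min(np.hypot(positions[:, 1] - c[1], positions[:, 2] - c[2]))
            if d > best_d:
                best, best_d = c, d
    return best


def sbr_fold_change_experiment(
    seed: int = 42,
    config: OpticalConfig | None = None,
    n_beads: int = 10,
    bead_diameter: float = 2.0,
    bead_intensity: float = 60.0,
    scattering_level: float = 0.05,
    background_intensity: float = 25.0,
    fine_half_range: float = 60.0,
    full_half_range: float = 300.0,
    angular_bins: int = 5,
    peak_counts: float = 1000.0,
    opts: ReconstructionOptions | None = None,
) -> SbrExperimentResult:
    """Complete-space scattering model vs incomplete-space reconstruction.

    A seeded phantom (2-um beads near focus, smooth scattering potential,
    nonuniform out-of-focus background out to the coarse slabs) is imaged
    once with Poisson + read noise. The same realigned views are then
    reconstructed (a) on the fine slabs only with the scattering potential
    frozen at zero — the incomplete-space model — and (b) on the full
    multiscale grid with joint scattering updates. Reports the
    signal-to-background ratio of each (bead ROIs vs a sample-free region)
    and their fold change.
    """
    cfg = config or preset_20x_na05()
    opts = opts or ReconstructionOptions()
    model = analytic_resolution_model(cfg, full_half_range)
    model = replace(model, high_res_half_range=fine_half_range)
    grid = build_grid(-full_half_range, full_half_range, model, cfg)

    emission, potential, truth = make_scattering_phantom(
        grid,
        n_beads=n_beads,
        bead_diameter=bead_diameter,
        bead_intensity=bead_intensity,
        scattering_level=scattering_level,
        background_intensity=background_intensity,
        seed=seed,
    )
    sim_full = PSFSimulator(cfg)
    psf_capture = psf_for_grid(sim_full, grid)
    frame, _ = simulate_capture(
        emission,
        potential,
        psf_capture,
        cfg,
        noise=NoiseParams(poisson=True, read_sigma=1.6, peak_counts=peak_counts),
        seed=seed + 1,
    )
    views = bin_views(realign(frame), angular_bins)

    sim_b = sim_full.rebinned(angular_bins)
    grid_fine = _fine_subgrid(grid)
    psf_fine = psf_for_grid(sim_b, grid_fine)
    psf_all = psf_for_grid(sim_b, grid)

    rec_inc = admm_reconstruct(views, psf_fine, grid_fine, opts, with_scattering=False)
    rec_full = admm_reconstruct(views, psf_all, grid, opts, with_scattering=True)

    positions = truth["positions"]
    step0 = cfg.lens_pitch_sample
    dz_fine = grid_fine.slabs[0].axial_step
    rois = [
        Roi(center=tuple(p), extent=(1.2 * dz_fine, 2.2 * step0, 2.2 * step0))
        for p in positions
    ]
    bg_center = _pick_background_center(grid, positions)
    bg_roi = Roi(center=bg_center, extent=(1.2 * dz_fine, 2.2 * step0, 2.2 * step0))

    sbr_inc, _ = compute_sbr(rec_inc.emission, rois, bg_roi)
    sbr_full, _ = compute_sbr(rec_full.emission, rois, bg_roi)
    return SbrExperimentResult(
        sbr_complete=sbr_full,
        sbr_incomplete=sbr_inc,
        fold_change=sbr_full / sbr_inc,
        n_beads=n_beads,
        details={
            "grid_voxels": grid.voxel_count(),
            "misfit_complete": rec_full.misfit_history,
            "misfit_incomplete": rec_inc.misfit_history,
            "background_roi_center": bg_center,
        },
    )


def calibration_recovery_experiment(
    seed: int = 0,
    config: OpticalConfig | None = None,
    spherical: float = 0.5,
    astigmatism: float = 0.3,
    peak_counts: float | None = 1000.0,
    noise: bool = False,
    n_modes: int = 15,
    bead_depth: float = 30.0,
):
    """Recover known Zernike aberrations from a synthetic bead frame.

    Simulates an isolated sub-diffraction bead (moderately defocused, so
    its light spreads over many microlenses and the per-angle correlations
    carry slope information) through a system with ``spherical`` (Noll 11)
    and ``astigmatism`` (Noll 6) waves of aberration, then runs the
    phase-retrieval calibration loop against it.
    """
    cfg = config or preset_20x_na05()
    true_coeffs = np.zeros(11)
    true_coeffs[5] = astigmatism  # Noll 6
    true_coeffs[10] = spherical  # Noll 11
    wf_true = zernike_wavefront(true_coeffs)
    sim_true = PSFSimulator(cfg, wavefront=wf_true)

    from .grid import uniform_grid

    step0 = cfg.lens_pitch_sample
    grid = uniform_grid(
        bead_depth - 5.0, bead_depth + 5.0, 10.0, step0, cfg.num_lenses,
        lens_pitch_sample=step0, num_lenses=cfg.num_lenses,
    )
    psf_true = psf_for_grid(sim_true, grid)
    vol, _ = make_bead_phantom(grid, 0, 0.0, 1.0, seed=0)
    ic = (0, cfg.num_lenses[0] // 2, cfg.num_lenses[1] // 2)
    vol.slab_data[0][ic] = 1.0
    frame, _ = simulate_capture(
        vol,
        None,
        psf_true,
        cfg,
        noise=NoiseParams(poisson=noise, read_sigma=1.6 if noise else 0.0, peak_counts=peak_counts),
        seed=seed,
    )
    result = calibrate_psf(frame, cfg, bead_depth=bead_depth, n_modes=n_modes)
    rec = result.wavefront.zernike_coefficients
    return {
        "result": result,
        "true": {"astigmatism": astigmatism, "spherical": spherical},
        "recovered": {
            "astigmatism": float(rec[5]) if len(rec) > 5 else 0.0,
            "spherical": float(rec[10]) if len(rec) > 10 else 0.0,
        },
        "iterations": result.iterations,
        "converged": result.converged,
    }
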