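import numpy as np
import pytest

from qlfm import (
    MultiscaleVolume,
    PhaseSpaceViews,
    ReconstructionOptions,
    admm_reconstruct,
    analytic_resolution_model,
    build_grid,
    forward_project,
    make_bead_phantom,
    phase_space_deconvolve,
    scattered_intensity,
    ScatteringPotential,
    uniform_grid,
)
from qlfm.errors import ContractError
from qlfm.metrics import Roi, roi_mean
from qlfm.projection import ProjectionOperator, psf_for_grid
from qlfm.psf import PhaseSpacePSF
from qlfm.reconstruction import reconstruct_axial_scan, spiral_order
from qlfm.synthetic import _deposit_trilinear, _slab_of_depth


def _deposit(vol, pos, total):
    si = _slab_of_depth(vol.grid, pos[0])
    slab = vol.grid.slabs[si]
    yc, xc = vol.grid.lateral_coords(slab)
    _deposit_trilinear(vol.slab_data[si], slab.z_centers, yc, xc, pos, total)


def _centroid(vol):
    tz = ty = tx = tot = 0.0
    for slab, data in zip(vol.grid.slabs, vol.slab_data):
        yc, xc = vol.grid.lateral_coords(slab)
        zc = slab.z_centers
        tot += data.sum()
        tz += (data.sum(axis=(1, 2)) * zc).sum()
        ty += (data.sum(axis=(0, 2)) * yc).sum()
        tx += (data.sum(axis=(0, 1)) * xc).sum()
    return tz / tot, ty / tot, tx / tot


class TestSpiralOrder:
    def test_starts_at_centre_and_visits_all(self):
        order = spiral_order(5, 5)
        assert order[0] == (2, 2)
        assert sorted(order) == [(u, v) for u in range(5) for v in range(5)]


class TestPhaseSpaceDeconvolve:
    def test_noiseless_bead_centroid_recovered_within_half_sample(self, sim5, fine_grid, fine_psf):
        """Simulated single bead: reconstructed centroid within 0.5 lateral
        and 0.5 axial samples of the truth after 10 cycles."""
        vol, pos = make_bead_phantom(fine_grid, 1, 0.0, 100.0, seed=3)
        views = forward_project(vol, fine_psf)
        rec = phase_space_deconvolve(views, fine_psf, fine_grid, cycles=10)
        cz, cy, cx = _centroid(rec)
        slab = fine_grid.slabs[0]
        assert abs(cz - pos[0, 0]) < 0.5 * slab.axial_step
        assert abs(cy - pos[0, 1]) < 0.5 * slab.lateral_step
        assert abs(cx - pos[0, 2]) < 0.5 * slab.lateral_step

    def test_output_nonnegative_for_random_views(self, fine_grid, fine_psf, rng):
        views = rng.random((5, 5, 15, 15))
        rec = phase_space_deconvolve(views, fine_psf, fine_grid, cycles=4)
        assert all(np.all(a >= 0) for a in rec.slab_data)

    def test_poisson_loss_non_increasing_over_cycles(self, fine_grid, fine_psf, rng):
        vol, _ = make_bead_phantom(fine_grid, 3, 0.0, 50.0, seed=11)
        views = np.maximum(
            forward_project(vol, fine_psf) + 0.05 * rng.standard_normal((5, 5, 15, 15)), 0.0
        )
        hist = []
        phase_space_deconvolve(views, fine_psf, fine_grid, cycles=8, history=hist)
        assert len(hist) >= 1
        assert all(b <= a * (1 + 1e-9) for a, b in zip(hist, hist[1:]))

    def test_uniform_views_uniform_psf_give_flat_volume(self, desk_config):
        """No structure is invented: uniform data under a spatially uniform
        single-slab model reconstruct to a flat volume."""
        grid = uniform_grid(
            -5.0, 5.0, 10.0, desk_config.lens_pitch_sample, (9, 9),
            lens_pitch_sample=desk_config.lens_pitch_sample, num_lenses=(9, 9),
        )
        kern = np.full((3, 3, 1, 1), 1.0 / 9.0)
        psf = PhaseSpacePSF(
            config=desk_config, depth_list=np.array([0.0]), kernels=[kern],
            lateral_factors=[1], angular_bins=3,
        )
        views = np.ones((3, 3, 9, 9))
        rec = phase_space_deconvolve(views, psf, grid, cycles=5)
        data = rec.slab_data[0]
        assert data.std() / data.mean() < 1e-9

    def test_all_zero_views_warn_and_return_zero(self, fine_grid, fine_psf):
        with pytest.warns(UserWarning, match="all-zero"):
            rec = phase_space_deconvolve(np.zeros((5, 5, 15, 15)), fine_psf, fine_grid)
        assert rec.total() == 0.0


class TestAdmmReconstruct:
    def test_matches_deconvolution_when_no_scattering_in_truth(self, fine_grid, fine_psf):
        """With F_true = 0 the joint estimate agrees with plain phase-space
        deconvolution within 1% relative L2."""
        vol, _ = make_bead_phantom(fine_grid, 2, 0.0, 100.0, seed=5)
        views = forward_project(vol, fine_psf)
        opts = ReconstructionOptions()
        joint = admm_reconstruct(views, fine_psf, fine_grid, opts)
        plain = phase_space_deconvolve(views, fine_psf, fine_grid, opts)
        rel = (joint.emission - plain).norm() / plain.norm()
        assert rel <= 0.01

    def test_misfit_non_increasing_and_reported(self, fine_grid, fine_psf, rng):
        vol, _ = make_bead_phantom(fine_grid, 2, 0.0, 100.0, seed=6)
        F = ScatteringPotential(fine_grid, [np.full(fine_grid.slabs[0].shape, 0.02)])
        views = forward_project(vol + scattered_intensity(vol, F), fine_psf)
        opts = ReconstructionOptions(outer_iterations=4, inner_rl_iterations=5)
        res = admm_reconstruct(views, fine_psf, fine_grid, opts)
        assert len(res.misfit_history) >= 2
        assert all(
            b <= a + 1e-9 * abs(a) for a, b in zip(res.misfit_history, res.misfit_history[1:])
        )

    def test_both_unknowns_nonnegative(self, fine_grid, fine_psf, rng):
        views = rng.random((5, 5, 15, 15))
        res = admm_reconstruct(views, fine_psf, fine_grid, ReconstructionOptions(outer_iterations=2, inner_rl_iterations=3))
        assert all(np.all(a >= 0) for a in res.emission.slab_data)
        assert all(np.all(a >= 0) for a in res.potential.slab_data)


class TestAxialScan:
    @pytest.fixture(scope="class")
    def scan_setup(self, desk_config, sim5):
        model = analytic_resolution_model(desk_config, 300.0)
        # scan step ~ the high-resolution axial range, per the acquisition rule
        positions = [-17.5, 17.5]
        grid = build_grid(-60.0, 60.0, model, desk_config, scan_positions=positions)
        ops = [
            ProjectionOperator(psf_for_grid(sim5, grid, depth_shift=s), grid)
            for s in positions
        ]
        return model, positions, grid, ops

    def test_single_position_equals_snapshot_reconstruction(self, desk_config, sim5, fine_grid, fine_psf):
        model = analytic_resolution_model(desk_config, 300.0)
        vol, _ = make_bead_phantom(fine_grid, 1, 0.0, 80.0, seed=2)
        views = forward_project(vol, fine_psf)
        opts = ReconstructionOptions()
        a = reconstruct_axial_scan(
            [PhaseSpaceViews(views, desk_config)], [0.0], sim5, model, opts, grid=fine_grid
        )
        b = admm_reconstruct(views, fine_psf, fine_grid, opts)
        assert (a.emission - b.emission).norm() <= 1e-12 * max(b.emission.norm(), 1e-12)

    def test_bead_midway_between_scan_planes_is_unimodal(self, desk_config, sim5, scan_setup):
        """A bead halfway between two scan positions reconstructs with a
        single axial peak — no stitching seam."""
        model, positions, grid, ops = scan_setup
        vol = MultiscaleVolume.zeros(grid)
        _deposit(vol, (0.0, 0.0, 0.0), 100.0)
        frames = [PhaseSpaceViews(op.forward(vol), desk_config) for op in ops]
        res = reconstruct_axial_scan(frames, positions, sim5, model, grid=grid)
        zs, prof = [], []
        for slab, data in zip(grid.slabs, res.emission.slab_data):
            yc, xc = grid.lateral_coords(slab)
            iy, ix = np.argmin(np.abs(yc)), np.argmin(np.abs(xc))
            lo_y, lo_x = max(iy - 1, 0), max(ix - 1, 0)
            for iz, z in enumerate(slab.z_centers):
                zs.append(z)
                prof.append(data[iz, lo_y : iy + 2, lo_x : ix + 2].sum())
        order = np.argsort(zs)
        prof = np.asarray(prof)[order]
        zs = np.asarray(zs)[order]
        peak = int(np.argmax(prof))
        d = np.diff(prof)
        assert np.all(d[:peak] >= -1e-6 * prof.max())
        assert np.all(d[peak:] <= 1e-6 * prof.max())
        assert abs(zs[peak]) < 12.0

    def test_bead_intensities_uniform_across_scanned_depth(self, desk_config, sim5, scan_setup):
        """Identical beads spanning both scan ranges reconstruct with < 20%
        coefficient of variation in recovered brightness."""
        model, positions, grid, ops = scan_setup
        vol = MultiscaleVolume.zeros(grid)
        zb = np.linspace(-30.0, 30.0, 5)
        offsets = np.linspace(-10.0, 10.0, 5)
        for z, off in zip(zb, offsets):
            _deposit(vol, (z, off, -off), 100.0)
        frames = [PhaseSpaceViews(op.forward(vol), desk_config) for op in ops]
        res = reconstruct_axial_scan(frames, positions, sim5, model, grid=grid)
        peaks = np.array(
            [
                roi_mean(res.emission, Roi((z, off, -off), (30.0, 11.0, 11.0)))
                for z, off in zip(zb, offsets)
            ]
        )
        assert peaks.std() / peaks.mean() < 0.20

    def test_unsorted_scan_positions_rejected(self, desk_config, sim5):
        model = analytic_resolution_model(desk_config, 300.0)
        frames = [PhaseSpaceViews(np.zeros((5, 5, 15, 15)), desk_config)] * 2
        with pytest.raises(ContractError):
            reconstruct_axial_scan(frames, [30.0, -30.0], sim5, model)
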