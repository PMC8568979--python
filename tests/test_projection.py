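import numpy as np
import pytest

from qlfm import (
    MultiscaleGrid,
    MultiscaleVolume,
    backproject,
    forward_project,
    uniform_grid,
)
from qlfm.errors import ContractError
from qlfm.grid import Slab
from qlfm.projection import ProjectionOperator, psf_for_grid
from qlfm.psf import PhaseSpacePSF


def _toy_psf(config, grid, n_angles=3, ksize=5, seed=0):
    """Random synthetic kernels matched to a grid (for operator algebra tests)."""
    rng = np.random.default_rng(seed)
    depths, kernels, factors = [], [], []
    for slab in grid.slabs:
        q = grid.factor(slab)
        for z in slab.z_centers:
            depths.append(z)
            factors.append(q)
            kernels.append(rng.random((n_angles, n_angles, ksize, ksize)))
    return PhaseSpacePSF(
        config=config,
        depth_list=np.array(depths),
        kernels=kernels,
        lateral_factors=factors,
        angular_bins=n_angles,
    )


@pytest.fixture
def lens9_grid(desk_config):
    step0 = desk_config.lens_pitch_sample
    return uniform_grid(
        -15.0, 15.0, 10.0, step0, (9, 9), lens_pitch_sample=step0, num_lenses=(9, 9)
    )


class TestForwardProject:
    def test_zero_volume_gives_zero_views(self, lens9_grid, desk_config):
        psf = _toy_psf(desk_config, lens9_grid)
        views = forward_project(MultiscaleVolume.zeros(lens9_grid), psf)
        assert views.shape == (3, 3, 9, 9)
        assert np.all(views == 0)

    def test_unit_impulse_reproduces_translated_kernel(self, lens9_grid, desk_config):
        """A single voxel at (z0, y0, x0) projects to the depth-z0 kernels
        translated to the voxel's lens-grid position."""
        psf = _toy_psf(desk_config, lens9_grid)
        vol = MultiscaleVolume.zeros(lens9_grid)
        vol.slab_data[0][1, 4, 4] = 1.0  # grid centre
        views = forward_project(vol, psf)
        kern = psf.kernels[1]
        expected = np.zeros_like(views)
        expected[:, :, 2:7, 2:7] = kern  # 5x5 kernel centred at (4, 4)
        np.testing.assert_allclose(views, expected, atol=1e-12)

    def test_linearity(self, lens9_grid, desk_config, rng):
        psf = _toy_psf(desk_config, lens9_grid)
        a = MultiscaleVolume(lens9_grid, [rng.random(s.shape) for s in lens9_grid.slabs])
        b = MultiscaleVolume(lens9_grid, [rng.random(s.shape) for s in lens9_grid.slabs])
        fa, fb = forward_project(a, psf), forward_project(b, psf)
        fab = forward_project(a + b, psf)
        np.testing.assert_allclose(fab, fa + fb, rtol=1e-12, atol=1e-12 * fa.max())

    def test_matches_direct_triple_loop_sum(self, lens9_grid, desk_config, rng):
        """Oracle: brute-force summation over depth, source position and
        angle on a 9x9 lens grid with 3 depths and 3x3 angles."""
        psf = _toy_psf(desk_config, lens9_grid)
        vol = MultiscaleVolume(lens9_grid, [rng.random(s.shape) for s in lens9_grid.slabs])
        views = forward_project(vol, psf)

        data = vol.slab_data[0]
        nz, ny, nx = data.shape
        kh = 5 // 2
        direct = np.zeros((3, 3, 9, 9))
        for iz in range(nz):
            kern = psf.kernels[iz]
            for sy in range(ny):
                for sx in range(nx):
                    w = data[iz, sy, sx]
                    if w == 0:
                        continue
                    for iu in range(3):
                        for iv in range(3):
                            for ky in range(5):
                                for kx in range(5):
                                    oy, ox = sy + ky - kh, sx + kx - kh
                                    if 0 <= oy < 9 and 0 <= ox < 9:
                                        direct[iu, iv, oy, ox] += w * kern[iu, iv, ky, kx]
        assert np.abs(views - direct).max() / direct.max() < 1e-6

    def test_depth_mismatch_rejected(self, lens9_grid, desk_config):
        psf = _toy_psf(desk_config, lens9_grid)
        other = uniform_grid(
            -20.0, 20.0, 8.0, lens9_grid.lens_pitch_sample, (9, 9),
            lens_pitch_sample=lens9_grid.lens_pitch_sample, num_lenses=(9, 9),
        )
        with pytest.raises(ContractError):
            forward_project(MultiscaleVolume.zeros(other), psf)


class TestAdjoint:
    def test_zero_views_give_zero_volume(self, lens9_grid, desk_config):
        psf = _toy_psf(desk_config, lens9_grid)
        vol = backproject(np.zeros((3, 3, 9, 9)), psf, lens9_grid)
        assert vol.total() == 0.0

    def test_single_angle_impulse_backprojects_flipped_kernel(self, lens9_grid, desk_config):
        psf = _toy_psf(desk_config, lens9_grid)
        views = np.zeros((3, 3, 9, 9))
        views[1, 2, 4, 4] = 1.0
        vol = backproject(views, psf, lens9_grid)
        for iz in range(3):
            kern = psf.kernels[iz][1, 2]
            np.testing.assert_allclose(
                vol.slab_data[0][iz, 2:7, 2:7], kern[::-1, ::-1], atol=1e-12
            )

    @pytest.mark.parametrize("trial", range(10))
    def test_adjoint_dot_product_identity_on_multiscale_grid(self, desk_config, trial):
        """<forward(x), y> = <x, backproject(y)> on a mixed fine/coarse grid."""
        step0 = desk_config.lens_pitch_sample
        slabs = (
            Slab(-90.0, -30.0, 30.0, 4 * step0, (4, 4)),
            Slab(-30.0, 30.0, 15.0, step0, (15, 15)),
            Slab(30.0, 90.0, 30.0, 2 * step0, (8, 8)),
        )
        grid = MultiscaleGrid(slabs=slabs, lens_pitch_sample=step0, num_lenses=(15, 15))
        psf = _toy_psf(desk_config, grid, seed=trial)
        rng = np.random.default_rng(100 + trial)
        x = MultiscaleVolume(grid, [rng.random(s.shape) for s in grid.slabs])
        y = rng.random((3, 3, 15, 15))
        op = ProjectionOperator(psf, grid)
        lhs = float(np.sum(op.forward(x) * y))
        rhs = x.dot(op.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-5

    def test_per_angle_maps_sum_to_full_maps(self, lens9_grid, desk_config, rng):
        psf = _toy_psf(desk_config, lens9_grid)
        op = ProjectionOperator(psf, lens9_grid)
        x = MultiscaleVolume(lens9_grid, [rng.random(s.shape) for s in lens9_grid.slabs])
        full = op.forward(x)
        for iu in range(3):
            for iv in range(3):
                np.testing.assert_allclose(op.forward_angle(x, iu, iv), full[iu, iv], atol=1e-10)


class TestGridMatchedWavePsf:
    def test_forward_of_wave_psf_conserves_photons(self, sim5, fine_grid):
        """Projecting n photons through the energy-normalised PSF detects
        ~n photons (band-limit and window losses only)."""
        psf = psf_for_grid(sim5, fine_grid)
        vol = MultiscaleVolume.zeros(fine_grid)
        vol.slab_data[0][2, 7, 7] = 1000.0
        views = forward_project(vol, psf)
        assert 0.9 * 1000 < views.sum() < 1.01 * 1000
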