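import numpy as np
import pytest

from qlfm import (
    MultiscaleVolume,
    analytic_resolution_model,
    build_grid,
    fit_resolution_model,
    resample_between_grids,
    uniform_grid,
)
from qlfm.errors import ContractError
from qlfm.grid import downsample_lateral, resolution_model_from_psf, upsample_lateral


def _expo(z, a, b, g):
    return a * np.exp(b * np.abs(z)) + g


class TestResolutionFit:
    def test_exact_parameters_recovered(self):
        """Widths generated from (0.5, 0.02, 1.5) recover within 1%."""
        z = np.linspace(0, 250, 12)
        w = _expo(z, 0.5, 0.02, 1.5)
        model = fit_resolution_model(z, w, 3 * w)
        assert np.allclose(model.lateral_fit, (0.5, 0.02, 1.5), rtol=0.01)

    def test_constant_widths_degenerate_to_gamma_only(self):
        z = np.linspace(0, 100, 6)
        w = np.full_like(z, 2.5)
        model = fit_resolution_model(z, w, w)
        assert model.degenerate
        a, b, g = model.lateral_fit
        assert a == 0.0 and g == pytest.approx(2.5)

    def test_fit_anchors_resolution_at_focus(self):
        z = np.linspace(0, 200, 10)
        w = _expo(z, 1.2, 0.015, 2.0)
        model = fit_resolution_model(z, w, w)
        assert float(model.lateral(0.0)) == pytest.approx(w[0], rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ContractError):
            fit_resolution_model([0, 10, 20], [1, 2, 3], [1, 2, 3])

    def test_psf_derived_model_matches_sampling_floor_at_focus(self, desk_config, sim_full):
        """Self-calibrated resolution: R(0) is set by the lens-sampling
        floor and grows monotonically with depth."""
        model = resolution_model_from_psf(
            desk_config, simulator=sim_full, probe_depths=[0, 10, 20, 40, 60, 90]
        )
        r0 = float(model.lateral(0.0))
        assert 2.0 * desk_config.lens_pitch_sample <= r0 <= 3.5 * desk_config.lens_pitch_sample
        r = model.lateral([0.0, 30.0, 60.0, 90.0])
        assert np.all(np.diff(r) > 0)


class TestBuildGrid:
    def test_range_within_high_res_gives_single_finest_slab(self, desk_config):
        model = analytic_resolution_model(desk_config, 300.0)
        hr = model.high_res_half_range
        grid = build_grid(-0.8 * hr, 0.8 * hr, model, desk_config)
        assert len(grid.slabs) == 1
        assert grid.factor(grid.slabs[0]) == 1

    def test_slabs_tile_range_without_gaps(self, desk_config):
        model = analytic_resolution_model(desk_config, 300.0)
        grid = build_grid(-300.0, 300.0, model, desk_config)
        assert grid.z_min == pytest.approx(-300.0)
        assert grid.z_max == pytest.approx(300.0)
        for a, b in zip(grid.slabs[:-1], grid.slabs[1:]):
            assert a.z_end == pytest.approx(b.z_start)

    def test_steps_non_decreasing_away_from_focus(self, desk_config):
        model = analytic_resolution_model(desk_config, 300.0)
        grid = build_grid(-300.0, 300.0, model, desk_config)
        mids = [0.5 * (s.z_start + s.z_end) for s in grid.slabs]
        order = np.argsort(np.abs(mids))
        lat = [grid.slabs[i].lateral_step for i in order]
        ax = [grid.slabs[i].axial_step for i in order]
        assert all(b >= a - 1e-9 for a, b in zip(lat, lat[1:]))
        assert all(b >= a - 1e-6 for a, b in zip(ax, ax[1:]))

    def test_nyquist_invariant(self, desk_config):
        model = analytic_resolution_model(desk_config, 300.0)
        grid = build_grid(-300.0, 300.0, model, desk_config)
        for s in grid.slabs:
            mid = 0.5 * (s.z_start + s.z_end)
            assert s.lateral_step <= float(model.lateral(abs(mid))) / 2 + 1e-9

    def test_multiscale_grid_is_order_of_magnitude_smaller_than_dense(self, config_40x):
        """+-500 um at the x40/1.0 NA model: total voxel count <= 10% of a
        uniformly fine dense grid (complete-space modelling is what makes
        the memory budget work)."""
        import dataclasses

        cfg = dataclasses.replace(config_40x, num_lenses=(101, 101))
        model = analytic_resolution_model(cfg, 500.0)
        grid = build_grid(-500.0, 500.0, model, cfg)
        fine_ax = min(s.axial_step for s in grid.slabs)
        dense = int(round(1000.0 / fine_ax)) * 101 * 101
        assert grid.voxel_count() <= 0.10 * dense

    def test_voxel_count_decreases_with_faster_resolution_decay(self, desk_config):
        from qlfm.grid import ResolutionModel

        counts = []
        for beta in (0.005, 0.01, 0.02, 0.04):
            model = ResolutionModel(
                lateral_fit=(10.0, beta, 3.0),
                axial_fit=(30.0, beta, 9.0),
                high_res_half_range=40.0,
            )
            grid = build_grid(-400.0, 400.0, model, desk_config)
            counts.append(grid.voxel_count())
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_inverted_range_rejected(self, desk_config):
        model = analytic_resolution_model(desk_config, 300.0)
        with pytest.raises(ContractError):
            build_grid(50.0, -50.0, model, desk_config)


class TestLateralSamplingAdjoints:
    def test_up_down_are_adjoint(self, rng):
        x = rng.random((4, 4))
        y = rng.random((15, 15))
        up = upsample_lateral(x, 4, (15, 15))
        down = downsample_lateral(y, 4, (4, 4))
        assert float(np.sum(up * y)) == pytest.approx(float(np.sum(x * down)))


class TestResample:
    def test_identical_grids_identity(self, desk_config, rng):
        g = uniform_grid(-30, 30, 10.0, 5.0, (15, 15))
        vol = MultiscaleVolume(g, [rng.random(g.slabs[0].shape)])
        out = resample_between_grids(vol, g)
        np.testing.assert_array_equal(out.slab_data[0], vol.slab_data[0])

    def test_constant_field_stays_constant(self, desk_config):
        src = uniform_grid(-30, 30, 10.0, 5.0, (16, 16))
        dst = uniform_grid(-30, 30, 6.0, 5.0, (16, 16))
        vol = MultiscaleVolume(src, [np.full(src.slabs[0].shape, 3.0)])
        out = resample_between_grids(vol, dst)
        dens_src = 3.0 / src.slabs[0].voxel_volume
        expected = dens_src * dst.slabs[0].voxel_volume
        np.testing.assert_allclose(out.slab_data[0], expected, rtol=1e-9)

    def test_gaussian_blob_mass_preserved_down_and_up(self):
        """Numeric-integration oracle: the integral of a smooth blob
        survives a down- then up-sampling round trip within 1%."""
        fine = uniform_grid(-40, 40, 4.0, 2.0, (32, 32))
        coarse = uniform_grid(-40, 40, 8.0, 4.0, (16, 16))
        zc = fine.slabs[0].z_centers
        yc, xc = fine.lateral_coords(fine.slabs[0])
        zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
        blob = np.exp(-(zz**2 / 300 + yy**2 / 200 + xx**2 / 200))
        vol = MultiscaleVolume(fine, [blob])
        down = resample_between_grids(vol, coarse)
        back = resample_between_grids(down, fine)
        assert down.total() == pytest.approx(vol.total(), rel=0.01)
        assert back.total() == pytest.approx(vol.total(), rel=0.01)
        assert all(np.all(a >= 0) for a in back.slab_data)

    def test_uncovered_range_rejected(self, rng):
        src = uniform_grid(-30, 30, 10.0, 5.0, (8, 8))
        dst = uniform_grid(-10, 10, 10.0, 5.0, (8, 8))
        vol = MultiscaleVolume(src, [rng.random(src.slabs[0].shape)])
        with pytest.raises(ContractError):
            resample_between_grids(vol, dst)
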