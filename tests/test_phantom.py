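"""Unit tests of the speckle phantom and its deformation scenarios."""

import math
import warnings

import numpy as np
import pytest

from psoce import (
    DeformationScenario,
    PhantomConfig,
    ProcessingParams,
    apply_axial_displacement,
    make_cornea_phantom,
    make_scenario,
    simulate_timeseries,
)

from conftest import small_slab


class TestGeometryAndSpeckle:
    def test_noise_free_support_confined_to_band(self):
        cfg = small_slab(snr_db=math.inf)
        vol = make_cornea_phantom(cfg)
        tissue = cfg.tissue_mask()
        assert np.all(vol.amplitude[~tissue] == 0)
        assert (vol.amplitude[tissue] > 0).mean() > 0.95  # speckle may have rare nulls

    def test_uniform_band_nonzero_everywhere_inside(self):
        cfg = small_slab(scatterer_density=0.0)
        vol = make_cornea_phantom(cfg)
        tissue = cfg.tissue_mask()
        assert np.all(vol.amplitude[tissue] == 1.0)
        assert np.all(vol.amplitude[~tissue] == 0.0)

    def test_determinism_bit_identical(self):
        cfg = small_slab(seed=7, snr_db=25.0)
        a = make_cornea_phantom(cfg)
        b = make_cornea_phantom(cfg)
        assert np.array_equal(a.data, b.data)

    def test_curved_surfaces_follow_circle_equation(self):
        cfg = small_slab(n_x=64, n_y=3, curvature_radius=8000.0, snr_db=math.inf)
        vol = make_cornea_phantom(cfg)
        # analytic oracle: circle/column intersection
        x = (np.arange(cfg.n_x) - (cfg.n_x - 1) / 2) * cfg.pitch_x
        y = (np.arange(cfg.n_y) - (cfg.n_y - 1) / 2) * cfg.pitch_y
        r2 = x[:, None] ** 2 + y[None, :] ** 2
        sag = cfg.curvature_radius - np.sqrt(cfg.curvature_radius**2 - r2)
        ant_expected = (cfg.anterior_apex_depth + sag) / cfg.delta
        amp = vol.amplitude
        first = np.argmax(amp > 0, axis=0)
        assert np.all(np.abs(first - np.ceil(ant_expected)) <= 1)

    def test_cornea_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="does not fit"):
            small_slab(n_z=50, corneal_thickness=400.0)

    @pytest.mark.parametrize("bad", [dict(decorrelation=-0.1), dict(pitch_x=0.0), dict(snr_db=math.nan)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_slab(**bad)


class TestApplyDisplacement:
    def test_zero_displacement_is_identity(self, params):
        vol = make_cornea_phantom(small_slab())
        out = apply_axial_displacement(vol, 0.0, params)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_uniform_displacement_imposes_hand_computed_phase(self, params):
        vol = make_cornea_phantom(small_slab())
        U0 = 40e-9
        out = apply_axial_displacement(vol, U0, params)
        expected = 4 * np.pi * params.n_refr * U0 / params.lambda_mean
        tissue = vol.meta["tissue_mask"]
        dphi = np.angle(out.data[tissue] / vol.data[tissue])
        np.testing.assert_allclose(dphi, expected, atol=1e-12)

    def test_phase_only_preserves_amplitude_exactly(self, params, rng):
        vol = make_cornea_phantom(small_slab())
        U = 30e-9 * rng.standard_normal(vol.shape)
        out = apply_axial_displacement(vol, U, params)
        # amplitude preserved to the last ULP of the complex multiply
        np.testing.assert_allclose(np.abs(out.data), np.abs(vol.data), rtol=1e-15)

    def test_exceeding_wrap_bound_recorded_not_raised(self, params):
        vol = make_cornea_phantom(small_slab())
        out = apply_axial_displacement(vol, 2 * params.displacement_bound, params)
        assert out.meta.get("wrap_warning") is True

    def test_resample_mode_shifts_speckle(self, params):
        vol = make_cornea_phantom(small_slab())
        U0 = vol.delta  # exactly one pixel
        out = apply_axial_displacement(vol, U0, params, mode="resample")
        # amplitude pattern shifted down by one pixel inside the band interior
        np.testing.assert_allclose(
            np.abs(out.data[40:60]), np.abs(vol.data[39:59]), atol=1e-12
        )


class TestSimulateTimeseries:
    def test_zero_rate_scenario_is_static(self, params):
        cfg = small_slab()
        scen = make_scenario("isotonic", duration=5.0, frame_interval=60.0)
        frames, gt = simulate_timeseries(cfg, scen, params)
        assert len(frames) == 6
        assert np.all(gt.eps == 0)
        for f in frames[1:]:
            np.testing.assert_array_equal(f.data, frames[0].data)

    def test_constant_rate_cumulative_matches_closed_form(self, params):
        r = 5e-4  # per minute
        cfg = small_slab()
        scen = DeformationScenario(
            name="const", duration=10.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.full_like(np.asarray(d, float), r),
        )
        frames, gt = simulate_timeseries(cfg, scen, params)
        tissue_pairs = cfg.tissue_mask()[:-1] & cfg.tissue_mask()[1:]
        cum = gt.cumulative_strain(len(frames) - 1)
        np.testing.assert_allclose(cum[tissue_pairs], r * 10.0, rtol=1e-12)

    def test_ground_truth_gradient_consistency(self, params):
        cfg = small_slab()
        scen = make_scenario("hypertonic_deswelling", duration=5.0, frame_interval=60.0,
                             corneal_thickness=cfg.corneal_thickness)
        frames, gt = simulate_timeseries(cfg, scen, params)
        delta_m = cfg.delta * 1e-6
        for k in range(len(frames) - 1):
            dU = gt.U[k + 1] - gt.U[k]
            grad = np.diff(dU, axis=0) / delta_m
            np.testing.assert_allclose(grad, gt.eps[k], atol=1e-12)

    def test_cxl_negative_strain_confined_by_construction(self, params):
        cfg = small_slab()
        scen = make_scenario("cxl", duration=50.0, frame_interval=120.0,
                             corneal_thickness=cfg.corneal_thickness,
                             affected_depth=150.0, dropout_period=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            frames, gt = simulate_timeseries(cfg, scen, params)
        times = gt.times_min
        ant, post = cfg.surfaces_px()
        depth_um = (np.arange(cfg.n_z - 1)[:, None, None] + 0.5 - ant[None]) * cfg.delta
        for k in range(len(gt.eps)):
            neg = gt.eps[k] < 0
            if times[k + 1] <= scen.onset_time:
                assert not neg.any()
            else:
                assert np.all(depth_um[neg] <= scen.affected_depth + cfg.delta)

    def test_dropout_frames_marked_and_phase_randomized(self, params):
        cfg = small_slab()
        scen = make_scenario("cxl", duration=40.0, frame_interval=60.0,
                             corneal_thickness=cfg.corneal_thickness)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            frames, gt = simulate_timeseries(cfg, scen, params)
        assert gt.dropout_frames == [25, 30, 35, 40]
        k = gt.dropout_frames[0]
        assert frames[k].meta.get("dropout") is True
        # amplitude preserved, phase destroyed
        np.testing.assert_allclose(
            np.abs(frames[k].data), np.abs(frames[k - 1].data), rtol=0.5
        )

    def test_simulation_determinism(self, params):
        cfg = small_slab(seed=11, snr_db=25.0, decorrelation=0.05)
        scen = make_scenario("hypotonic_swelling", duration=3.0, frame_interval=60.0)
        f1, g1 = simulate_timeseries(cfg, scen, params)
        f2, g2 = simulate_timeseries(cfg, scen, params)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.data, b.data)
        assert np.array_equal(g1.U, g2.U)
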