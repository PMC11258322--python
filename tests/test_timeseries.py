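"""Unit tests of incremental series, accumulation and difference curves."""

import warnings

import numpy as np
import pytest

from psoce import (
    DeformationScenario,
    ProcessingParams,
    RegionSpec,
    StrainCurve,
    SurfaceModel,
    accumulate,
    depth_time_map,
    difference_curve,
    incremental_strain_series,
    make_scenario,
    regional_curve,
    simulate_timeseries,
)

from conftest import small_slab


def _simulate(scenario, cfg=None, params=None):
    cfg = cfg or small_slab()
    params = params or ProcessingParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frames, gt = simulate_timeseries(cfg, scenario, params)
    surf = SurfaceModel(
        anterior=frames[0].meta["anterior_px"],
        posterior=frames[0].meta["posterior_px"],
        delta_um=cfg.delta,
    )
    return cfg, frames, gt, surf


class TestIncrementalSeries:
    def test_identical_frames_give_zero_strain_maps(self, params):
        scen = make_scenario("isotonic", duration=4.0, frame_interval=60.0)
        cfg, frames, gt, surf = _simulate(scen)
        smaps = incremental_strain_series(frames, params)
        assert len(smaps) == len(frames) - 1
        for sm in smaps:
            assert sm.frame_valid
            np.testing.assert_allclose(sm.eps_zz[sm.mask], 0.0, atol=1e-12)

    def test_constant_rate_increments_match_ground_truth(self, params):
        r = 8e-4
        scen = DeformationScenario(
            name="const", duration=6.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.full_like(np.asarray(d, float), r),
        )
        cfg, frames, gt, surf = _simulate(scen)
        smaps = incremental_strain_series(frames, params)
        region = RegionSpec(band="full", lateral_halfwidth_x=150.0, lateral_halfwidth_y=1e6)
        curve = regional_curve(smaps, surf, region, cfg.pitch_x, cfg.pitch_y)
        np.testing.assert_allclose(curve.increments, r, rtol=0.1)

    def test_one_dropout_frame_invalidates_two_pairs(self, params):
        scen = DeformationScenario(
            name="drop", duration=8.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.zeros_like(np.asarray(d, float)),
            dropout_period=4.0, dropout_duration=1, dropout_end=4.5,
        )
        cfg, frames, gt, surf = _simulate(scen)
        assert gt.dropout_frames == [4]
        smaps = incremental_strain_series(frames, params)
        invalid = [k for k, sm in enumerate(smaps) if not sm.frame_valid]
        assert invalid == [3, 4]

    def test_unordered_timestamps_rejected(self, params):
        scen = make_scenario("isotonic", duration=2.0, frame_interval=60.0)
        cfg, frames, gt, surf = _simulate(scen)
        frames[1].timestamp = frames[0].timestamp
        with pytest.raises(ValueError, match="increasing"):
            incremental_strain_series(frames, params)


class TestAccumulate:
    def test_zero_increments_give_flat_curve(self):
        c = accumulate([0.0] * 5, [True] * 5, np.arange(1.0, 6.0))
        np.testing.assert_array_equal(c.cum_strain, 0.0)

    def test_constant_increment_arithmetic(self):
        s = 3e-4
        c = accumulate([s] * 10, [True] * 10, np.arange(1.0, 11.0))
        assert c.cum_strain[-1] == pytest.approx(100 * 10 * s)

    def test_invalid_increments_contribute_zero(self):
        inc = [1e-3, 1e-3, 1e-3, 1e-3]
        valid = [True, False, True, True]
        c = accumulate(inc, valid, [1.0, 2.0, 3.0, 4.0])
        assert c.cum_strain[-1] == pytest.approx(100 * 3e-3)

    def test_accumulation_is_additive_over_any_split(self):
        rng = np.random.default_rng(3)
        inc = rng.normal(0, 1e-3, 20)
        valid = rng.random(20) > 0.2
        t = np.arange(1.0, 21.0)
        full = accumulate(inc, valid, t)
        for split in (5, 11, 16):
            head = accumulate(inc[:split], valid[:split], t[:split])
            tail = accumulate(inc[split:], valid[split:], t[split:])
            assert full.cum_strain[-1] == pytest.approx(
                head.cum_strain[-1] + tail.cum_strain[-1], abs=1e-12
            )

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            accumulate([1.0], [True, False], [1.0, 2.0])


class TestTrackingAccuracy:
    def test_cumulative_strain_tracks_truth_within_fifth_of_a_point(self, params):
        # 80-min constant-rate swelling at SNR 20 dB
        r = 2e-4  # per minute
        cfg = small_slab(snr_db=20.0, decorrelation=0.02, seed=21)
        scen = DeformationScenario(
            name="const", duration=80.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.full_like(np.asarray(d, float), r),
        )
        cfg, frames, gt, surf = _simulate(scen, cfg)
        smaps = incremental_strain_series(frames, params)
        region = RegionSpec(band="full", lateral_halfwidth_x=200.0, lateral_halfwidth_y=1e6)
        curve = regional_curve(smaps, surf, region, cfg.pitch_x, cfg.pitch_y)
        truth_pct = 100 * r * 80.0
        assert abs(curve.cum_strain[-1] - truth_pct) < 0.2

    def test_linear_scenario_curve_is_linear_in_time(self, params):
        r = 3e-4
        cfg = small_slab(seed=4)  # noiseless
        scen = DeformationScenario(
            name="const", duration=30.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.full_like(np.asarray(d, float), r),
        )
        cfg, frames, gt, surf = _simulate(scen, cfg)
        smaps = incremental_strain_series(frames, params)
        region = RegionSpec(band="full", lateral_halfwidth_x=200.0, lateral_halfwidth_y=1e6)
        curve = regional_curve(smaps, surf, region, cfg.pitch_x, cfg.pitch_y)
        res = np.polyfit(curve.t, curve.cum_strain, 1, full=True)
        ss_res = res[1][0] if len(res[1]) else 0.0
        ss_tot = np.sum((curve.cum_strain - curve.cum_strain.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999


class TestDepthTimeMap:
    def test_static_scenario_columns_agree(self, params):
        scen = make_scenario("isotonic", duration=4.0, frame_interval=60.0)
        cfg, frames, gt, surf = _simulate(scen)
        smaps = incremental_strain_series(frames, params)
        dtm = depth_time_map(smaps, surf, lateral_window_um=300.0, pitch_x_um=cfg.pitch_x)
        assert dtm.M.shape[1] == len(smaps)
        np.testing.assert_allclose(dtm.M.compressed(), 0.0, atol=1e-12)

    def test_cxl_negative_region_confined_to_anterior_after_onset(self, params):
        cfg = small_slab(n_z=120, corneal_thickness=450.0, snr_db=30.0)
        scen = make_scenario("cxl", duration=45.0, frame_interval=120.0,
                             corneal_thickness=450.0, affected_depth=150.0,
                             onset_time=20.0, dropout_period=0.0)
        cfg, frames, gt, surf = _simulate(scen, cfg)
        smaps = incremental_strain_series(frames, params)
        dtm = depth_time_map(smaps, surf, lateral_window_um=600.0, pitch_x_um=cfg.pitch_x)
        strong_neg = (~np.ma.getmaskarray(dtm.M)) & (dtm.M.filled(0) < -2e-4)
        rows, cols = np.nonzero(strong_neg)
        assert strong_neg.any()
        # all strongly negative pixels postdate onset and stay in the anterior layer
        assert np.all(dtm.t[cols] >= scen.onset_time - 2.0)
        affected_rows = float(np.median(surf.anterior)) + scen.affected_depth / cfg.delta
        assert np.mean(rows <= affected_rows + 7) > 0.95

    def test_dropout_pairs_become_masked_stripes(self, params):
        scen = DeformationScenario(
            name="drop", duration=8.0, frame_interval=60.0,
            rate_profile=lambda d, t: np.zeros_like(np.asarray(d, float)),
            dropout_period=4.0, dropout_duration=1, dropout_end=4.5,
        )
        cfg, frames, gt, surf = _simulate(scen)
        smaps = incremental_strain_series(frames, params)
        dtm = depth_time_map(smaps, surf, lateral_window_um=300.0, pitch_x_um=cfg.pitch_x)
        mask = np.ma.getmaskarray(dtm.M)
        assert mask[:, 3].all() and mask[:, 4].all()
        # in-tissue rows of untouched pairs remain unmasked
        rows = slice(int(surf.anterior.max()) + 2, int(surf.posterior.min()) - 2)
        assert not mask[rows, 0].any()


class TestDifferenceCurve:
    def _curve(self, t, cum, label=""):
        inc = np.empty_like(np.asarray(cum, float))
        inc[0] = cum[0] / 100
        inc[1:] = np.diff(cum) / 100
        return StrainCurve(t=np.asarray(t, float), cum_strain=np.asarray(cum, float),
                           increments=inc, valid=np.ones(len(t), bool), label=label)

    def test_identical_curves_difference_is_zero(self):
        a = self._curve([1, 2, 3], [0.1, 0.2, 0.3], "a")
        d = difference_curve(a, a)
        np.testing.assert_allclose(d.cum_strain, 0.0, atol=1e-15)

    def test_different_grids_interpolated_with_shared_nodes_preserved(self):
        a = self._curve([0, 2, 4, 6], [0.0, 0.2, 0.4, 0.6], "a")
        b = self._curve([0, 3, 6], [0.0, 0.15, 0.3], "b")
        d = difference_curve(a, b)
        # at t=6 both curves are sampled exactly
        assert d.cum_strain[d.t == 6.0][0] == pytest.approx(0.6 - 0.3)

    def test_disjoint_ranges_rejected(self):
        a = self._curve([0, 1, 2], [0, 0.1, 0.2])
        b = self._curve([5, 6, 7], [0, 0.1, 0.2])
        with pytest.raises(ValueError, match="disjoint"):
            difference_curve(a, b)

    def test_cxl_minus_control_flat_then_negative(self, params):
        cfg = small_slab(n_z=120, corneal_thickness=450.0)
        region = RegionSpec(band="anterior", band_depth=150.0,
                            lateral_halfwidth_x=150.0, lateral_halfwidth_y=1e6)
        curves = {}
        for name, kwargs in [("control_swelling", {}),
                             ("cxl", dict(affected_depth=150.0, onset_time=20.0, dropout_period=0.0))]:
            scen = make_scenario(name, duration=45.0, frame_interval=120.0,
                                 corneal_thickness=450.0, **kwargs)
            cfg2, frames, gt, surf = _simulate(scen, cfg)
            smaps = incremental_strain_series(frames, params)
            curves[name] = regional_curve(smaps, surf, region, cfg.pitch_x, cfg.pitch_y, label=name)
        d = difference_curve(curves["cxl"], curves["control_swelling"])
        before = d.cum_strain[d.t <= 18.0]
        after = d.cum_strain[d.t >= 40.0]
        assert np.all(np.abs(before) < 0.25)
        assert np.all(after < -0.5)
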