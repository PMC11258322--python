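"""Unit tests of the windowed cross-correlation strain estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psoce import (
    ComplexVolume,
    ProcessingParams,
    apply_axial_displacement,
    axial_strain_map,
    complex_cross_correlation,
    displacement_map,
    make_cornea_phantom,
    quality_mask,
    strain_correlation,
)
from psoce.reference import naive_r, naive_w
from psoce.strain import interior_tissue_mask

from conftest import small_slab


def _vol(data: np.ndarray) -> ComplexVolume:
    return ComplexVolume(data=data, delta=4.48e-6, pitch_x=12e-6, pitch_y=120e-6)


def _speckle(shape, rng):
    return _vol(rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


class TestCrossCorrelation:
    def test_autocorrelation_has_zero_phase_and_unit_modulus(self, params, rng):
        c = _speckle((20, 20, 2), rng)
        W = complex_cross_correlation(c, c, params)
        assert W.valid.all()
        np.testing.assert_allclose(np.angle(W.data), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(W.data), 1.0, atol=1e-12)

    def test_global_phase_factor_reads_back_with_its_own_sign(self, params, rng):
        c1 = _speckle((16, 16, 1), rng)
        c2 = _vol(c1.data * np.exp(1j * np.pi / 3))
        W = complex_cross_correlation(c1, c2, params)
        np.testing.assert_allclose(np.angle(W.data), np.pi / 3, atol=1e-12)

    @pytest.mark.parametrize("shape,wz,wx", [((9, 9, 1), 3, 3), ((16, 16, 3), 3, 3), ((12, 10, 2), 2, 1)])
    def test_matches_naive_nested_loop_oracle(self, rng, shape, wz, wx):
        p = ProcessingParams(w_z=wz, w_x=wx)
        c1, c2 = _speckle(shape, rng), _speckle(shape, rng)
        W = complex_cross_correlation(c1, c2, p)
        np.testing.assert_allclose(W.data, naive_w(c1.data, c2.data, wz, wx), atol=1e-12)
        R = strain_correlation(W, p)
        np.testing.assert_allclose(R.data, naive_r(W.data, wz, wx), atol=1e-12)

    def test_shape_mismatch_rejected(self, params, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            complex_cross_correlation(_speckle((10, 8, 1), rng), _speckle((10, 9, 1), rng), params)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_unit_modulus_wherever_valid(self, seed):
        rng = np.random.default_rng(seed)
        p = ProcessingParams()
        W = complex_cross_correlation(_speckle((12, 12, 1), rng), _speckle((12, 12, 1), rng), p)
        assert np.allclose(np.abs(W.data[W.valid]), 1.0, atol=1e-12)
        assert np.all(W.data[~W.valid] == 0)


class TestDisplacement:
    def test_zero_phase_gives_zero_displacement(self, params, rng):
        c = _speckle((16, 16, 1), rng)
        dm = displacement_map(complex_cross_correlation(c, c, params), params)
        np.testing.assert_allclose(dm.U, 0.0, atol=1e-20)

    def test_pi_phase_gives_quarter_wavelength_over_n(self, params, rng):
        # ∠W = π ⇒ U = λ/(4n), the wrap-free bound
        c1 = _speckle((16, 16, 1), rng)
        c2 = _vol(c1.data * np.exp(1j * np.pi))
        dm = displacement_map(complex_cross_correlation(c1, c2, params), params)
        expected = params.lambda_mean / (4.0 * params.n_refr)
        np.testing.assert_allclose(np.abs(dm.U), expected, rtol=1e-10)

    def test_instrument_defaults(self, params):
        assert params.lambda_mean == pytest.approx(877.8e-9)
        assert params.n_refr == pytest.approx(1.375)
        assert params.delta == pytest.approx(4.48e-6)
        assert (params.w_z, params.w_x) == (3, 3)


class TestStrain:
    def test_constant_phase_gives_zero_strain(self, params, rng):
        c1 = _speckle((20, 16, 1), rng)
        c2 = _vol(c1.data * np.exp(1j * 0.7))
        R = strain_correlation(complex_cross_correlation(c1, c2, params), params)
        sm = axial_strain_map(R, params)
        np.testing.assert_allclose(sm.eps_zz[sm.mask], 0.0, atol=1e-15)

    @pytest.mark.parametrize("a", [0.05, -0.12, 0.4])
    def test_phase_ramp_recovers_closed_form_strain(self, params, a):
        # uniform-amplitude slab; imposed phase ramp a rad/pixel
        cfg = small_slab(scatterer_density=0.0)
        vol = make_cornea_phantom(cfg)
        z = np.arange(cfg.n_z)[:, None, None]
        shifted = _vol(vol.data * np.exp(1j * a * z))
        R = strain_correlation(complex_cross_correlation(vol, shifted, params), params)
        sm = axial_strain_map(R, params)
        core = interior_tissue_mask(cfg.tissue_mask(), params)
        expected = params.lambda_mean * a / (4 * np.pi * params.n_refr * params.delta)
        np.testing.assert_allclose(sm.eps_zz[core & sm.mask], expected, atol=1e-12)

    def test_ramp_beyond_pi_aliases_with_wrapped_sign(self, params):
        cfg = small_slab(scatterer_density=0.0)
        vol = make_cornea_phantom(cfg)
        z = np.arange(cfg.n_z)[:, None, None]
        a = np.pi * 1.02
        shifted = _vol(vol.data * np.exp(1j * a * z))
        sm = axial_strain_map(
            strain_correlation(complex_cross_correlation(vol, shifted, params), params), params
        )
        core = interior_tissue_mask(cfg.tissue_mask(), params)
        wrapped = a - 2 * np.pi  # ≈ −0.98π
        expected = params.lambda_mean * wrapped / (4 * np.pi * params.n_refr * params.delta)
        np.testing.assert_allclose(sm.eps_zz[core & sm.mask], expected, atol=1e-12)

    def test_too_few_axial_samples_rejected(self, params, rng):
        W = complex_cross_correlation(_speckle((7, 16, 1), rng), _speckle((7, 16, 1), rng), params)
        with pytest.raises(ValueError, match="axial samples"):
            strain_correlation(W, params)


class TestQualityMask:
    def test_noise_free_phantom_fully_valid_in_tissue(self, rng):
        cfg = small_slab()
        p = ProcessingParams(amp_threshold=0.0)
        vol = make_cornea_phantom(cfg)
        tissue = cfg.tissue_mask()
        mask, frame_valid = quality_mask(vol, vol, p, tissue)
        assert frame_valid
        assert mask[tissue].all()

    def test_phase_randomized_frame_flagged_invalid(self, rng):
        cfg = small_slab()
        p = ProcessingParams()
        vol = make_cornea_phantom(cfg)
        scrambled = _vol(np.abs(vol.data) * np.exp(1j * rng.uniform(-np.pi, np.pi, vol.shape)))
        _, frame_valid = quality_mask(vol, scrambled, p, cfg.tissue_mask())
        assert not frame_valid

    def test_all_zero_frame_fully_masked(self, params):
        cfg = small_slab()
        vol = make_cornea_phantom(cfg)
        zero = _vol(np.zeros(vol.shape, dtype=complex))
        mask, frame_valid = quality_mask(vol, zero, params, cfg.tissue_mask())
        assert not frame_valid
        assert not mask[cfg.tissue_mask()].any()
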