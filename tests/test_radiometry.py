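"""Radiometric calibration, Lambertian inversion, and band convolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lagoonwq.bands import PERUSAT1
from lagoonwq.radiometry import (
    AtmosphericTerms,
    RadiometricCalibration,
    Scene,
    SceneState,
    convolve_to_bands,
    dn_to_radiance,
    invert_surface_reflectance,
    radiance_to_dn,
    toa_radiance_forward,
    validate_correction,
)


def _scene(data, state=SceneState.DN):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = np.repeat(data[:, :, None], 4, axis=2)
    return Scene(data=data, state=state)


class TestDNConversion:
    def test_zero_dn_gives_bias(self):
        for convention in ("divide", "multiply"):
            cal = RadiometricCalibration(gain=2.0, bias=1.5, convention=convention)
            out = dn_to_radiance(_scene(np.zeros((2, 2))), cal)
            assert np.allclose(out.data, 1.5)
            assert out.state == SceneState.TOA_RADIANCE

    def test_divide_convention_arithmetic(self):
        cal = RadiometricCalibration(gain=2.0, bias=0.0, convention="divide")
        out = dn_to_radiance(_scene(np.full((1, 1), 100.0)), cal)
        assert np.allclose(out.data, 50.0)

    def test_multiply_convention_arithmetic(self):
        cal = RadiometricCalibration(gain=2.0, bias=0.0, convention="multiply")
        out = dn_to_radiance(_scene(np.full((1, 1), 100.0)), cal)
        assert np.allclose(out.data, 200.0)

    @pytest.mark.parametrize("convention", ["divide", "multiply"])
    def test_inverse_pair_exact_without_quantization(self, convention, rng):
        cal = RadiometricCalibration(
            gain=[3.0, 2.0, 1.5, 4.0], bias=[1.0, 0.5, 0.2, 0.0],
            convention=convention,
        )
        dn = rng.integers(0, 4096, size=(5, 5, 4)).astype(float)
        radiance = dn_to_radiance(_scene(dn), cal)
        back = radiance_to_dn(radiance, cal, quantize=False)
        assert np.allclose(back.data, dn, atol=1e-9)

    def test_quantized_round_trip_within_rounding(self, rng):
        cal = RadiometricCalibration(gain=10.0, bias=2.0)
        dn = rng.integers(0, 4096, size=(4, 4, 4)).astype(float)
        radiance = dn_to_radiance(_scene(dn), cal)
        back = radiance_to_dn(radiance, cal, quantize=True)
        assert np.array_equal(back.data, dn)

    def test_monotone_in_dn(self):
        cal = RadiometricCalibration(gain=2.0, bias=1.0)
        lo = dn_to_radiance(_scene(np.full((1, 1), 10.0)), cal).data
        hi = dn_to_radiance(_scene(np.full((1, 1), 11.0)), cal).data
        assert np.all(hi > lo)

    def test_wrong_state_rejected(self):
        cal = RadiometricCalibration(gain=1.0, bias=0.0)
        with pytest.raises(ValueError, match="DN"):
            dn_to_radiance(_scene(np.zeros((2, 2)), SceneState.TOA_RADIANCE), cal)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            RadiometricCalibration(gain=0.0, bias=0.0)


class TestLambertianModel:
    def test_zero_reflectance_gives_path_radiance(self, simple_terms):
        L = toa_radiance_forward(np.zeros(4), simple_terms)
        assert np.allclose(L, simple_terms.path_radiance)

    def test_unit_transfer_limit(self):
        terms = AtmosphericTerms(
            path_radiance=0.0, solar_irradiance=np.pi, gas_transmittance=1.0,
            total_transmittance=1.0, spherical_albedo=0.0,
        )
        rho = np.array([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(toa_radiance_forward(rho, terms), rho)

    def test_forward_numeric_oracle(self, simple_terms):
        # independent evaluation: L = L0 + (I0 Tg Tud / pi) * rho / (1 - S rho)
        expected = 20.0 + (1500.0 * 0.95 * 0.8 / np.pi) * 0.05 / (1.0 - 0.15 * 0.05)
        L = toa_radiance_forward(np.full(4, 0.05), simple_terms)
        assert np.allclose(L, expected, rtol=1e-14)

    def test_singularity_rejected(self):
        terms = AtmosphericTerms(
            path_radiance=0.0, solar_irradiance=1000.0, gas_transmittance=1.0,
            total_transmittance=1.0, spherical_albedo=0.5,
        )
        with pytest.raises(ValueError, match="singularity"):
            toa_radiance_forward(np.full(4, 2.0), terms)

    def test_radiance_at_l0_inverts_to_zero(self, simple_terms):
        sc = _scene(np.full((2, 2), 20.0), SceneState.TOA_RADIANCE)
        out = invert_surface_reflectance(sc, simple_terms)
        assert np.allclose(out.data, 0.0)
        assert out.state == SceneState.SURFACE_REFLECTANCE

    def test_zero_albedo_closed_form(self):
        terms = AtmosphericTerms(
            path_radiance=5.0, solar_irradiance=1200.0, gas_transmittance=0.9,
            total_transmittance=0.85, spherical_albedo=0.0,
        )
        L = 40.0
        sc = _scene(np.full((1, 1), L), SceneState.TOA_RADIANCE)
        out = invert_surface_reflectance(sc, terms)
        expected = np.pi * (L - 5.0) / (1200.0 * 0.9 * 0.85)
        assert np.allclose(out.data, expected, rtol=1e-14)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        rho=st.floats(0.0, 0.95),
        l0=st.floats(0.0, 50.0),
        i0=st.floats(500.0, 2000.0),
        tg=st.floats(0.5, 1.0),
        tud=st.floats(0.5, 1.0),
        s=st.floats(0.0, 0.4),
    )
    def test_invert_forward_identity(self, rho, l0, i0, tg, tud, s):
        terms = AtmosphericTerms(
            path_radiance=l0, solar_irradiance=i0, gas_transmittance=tg,
            total_transmittance=tud, spherical_albedo=s,
        )
        L = toa_radiance_forward(np.full(4, rho), terms)
        sc = _scene(np.broadcast_to(L, (1, 1, 4)), SceneState.TOA_RADIANCE)
        out = invert_surface_reflectance(sc, terms)
        assert np.allclose(out.data, rho, atol=1e-12)

    def test_negative_reflectance_flagged_not_zeroed(self, simple_terms):
        sc = _scene(np.full((2, 2), 19.0), SceneState.TOA_RADIANCE)  # below L0
        out = invert_surface_reflectance(sc, simple_terms)
        assert np.all(out.data < 0)
        assert out.clip_counts["negative"] == 16

    def test_clipping_counts_logged(self, simple_terms):
        huge = toa_radiance_forward(np.full(4, 0.99), simple_terms) * 10
        sc = _scene(np.broadcast_to(huge, (1, 1, 4)), SceneState.TOA_RADIANCE)
        out = invert_surface_reflectance(sc, simple_terms)
        assert out.clip_counts["clipped_high"] == 4
        assert np.all(out.data <= 1.0)


class TestBandConvolution:
    def test_flat_spectrum(self):
        wl = np.arange(400, 1000, 5.0)
        out = convolve_to_bands(wl, np.full_like(wl, 0.02))
        assert np.allclose(out, 0.02)

    def test_linear_spectrum_gives_midpoint_value(self):
        wl = np.arange(400, 1000, 1.0)
        rrs = 1e-4 * wl
        out = convolve_to_bands(wl, rrs)
        mids = [b.center for b in PERUSAT1]
        assert np.allclose(out, 1e-4 * np.array(mids), rtol=1e-12)

    def test_smooth_spectrum_matches_fine_quadrature(self):
        wl = np.arange(400, 1000, 2.0)
        rrs = 0.02 + 0.01 * np.sin(wl / 40.0)
        out = convolve_to_bands(wl, rrs)
        for i, band in enumerate(PERUSAT1):
            fine = np.linspace(band.wavelength_min, band.wavelength_max, 20001)
            expected = np.trapezoid(np.interp(fine, wl, rrs), fine) / (
                band.wavelength_max - band.wavelength_min
            )
            assert out[i] == pytest.approx(expected, abs=1e-6)

    def test_coverage_gap_names_band(self):
        wl = np.arange(500, 1000, 5.0)  # misses B1 start at 450
        with pytest.raises(ValueError, match="B1"):
            convolve_to_bands(wl, np.full_like(wl, 0.01))


class TestCorrectionValidation:
    def test_identical_pairs_zero_rmse(self, rng):
        spectra = rng.uniform(0.01, 0.1, size=(6, 4))
        out = validate_correction(spectra, spectra)
        assert out["rmse"] == 0.0

    def test_constant_offset(self, rng):
        ref = rng.uniform(0.01, 0.1, size=(5, 4))
        out = validate_correction(ref + 0.1, ref)
        assert out["rmse"] == pytest.approx(0.1, rel=1e-12)

    def test_matches_direct_formula(self, rng):
        img = rng.uniform(0, 0.2, size=(8, 4))
        ref = rng.uniform(0, 0.2, size=(8, 4))
        out = validate_correction(img, ref, per_band=True)
        assert out["rmse"] == pytest.approx(
            np.sqrt(np.mean((img - ref) ** 2)), rel=1e-12
        )
        assert out["rmse_per_band"] == pytest.approx(
            np.sqrt(np.mean((img - ref) ** 2, axis=0)), rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            validate_correction(np.zeros((3, 4)), np.zeros((2, 4)))
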