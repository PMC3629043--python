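"""Forward reflectance models and bandpass convolution."""

import numpy as np
import pytest

import waveopt as w
from waveopt.forward_model import (
    FWHM_TO_SIGMA,
    _boundary_parameter,
    diffusion_reflectance,
    diffusion_reflectance_annulus,
)
from waveopt.optics_core import OpticalProperties


def _props(mua, musp, grid=None):
    grid = grid or w.WavelengthGrid(450, 600, 25)
    return OpticalProperties(grid, np.full(grid.count, mua),
                             np.full(grid.count, musp))


class TestDiffusion:
    def test_reflectance_decreases_with_absorption(self):
        musp = np.full(7, 10.0)
        mua_low = np.full(7, 0.2)
        r_low = diffusion_reflectance(mua_low, musp, 0.2)
        r_high = diffusion_reflectance(mua_low + 0.5, musp, 0.2)
        assert np.all(r_high < r_low)

    def test_matches_independent_dipole_rederivation(self):
        # independent re-derivation of the extrapolated-boundary dipole
        # solution (fluence + flux detection), written out scalar-by-scalar
        mua, musp, rho, n_rel = 0.37, 9.3, 0.21, 1.4
        mut = mua + musp
        big_d = 1.0 / (3.0 * mut)
        mu_eff = np.sqrt(mua / big_d)
        z0 = 1.0 / mut
        r_eff = -1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        a_bc = (1 + r_eff) / (1 - r_eff)
        zb = 2.0 * a_bc * big_d
        r1 = np.hypot(z0, rho)
        r2 = np.hypot(z0 + 2 * zb, rho)
        flux = (z0 * (mu_eff + 1 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
                + (z0 + 2 * zb) * (mu_eff + 1 / r2)
                * np.exp(-mu_eff * r2) / r2 ** 2) / (4 * np.pi)
        fluence = (np.exp(-mu_eff * r1) / r1
                   - np.exp(-mu_eff * r2) / r2) / (4 * np.pi * big_d)
        expected = fluence / 4.0 + flux / 2.0
        got = diffusion_reflectance(np.array([mua]), np.array([musp]),
                                    rho, n_rel)[0]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_index_matched_boundary_parameter_is_one(self):
        assert _boundary_parameter(1.0) == 1.0
        assert _boundary_parameter(1.4) > 1.0

    def test_zero_musp_raises(self):
        with pytest.raises(ValueError):
            diffusion_reflectance(np.array([0.1]), np.array([0.0]), 0.1)

    def test_short_separation_warns_not_raises(self):
        with pytest.warns(UserWarning, match="transport mean free path"):
            diffusion_reflectance(np.array([0.1]), np.array([10.0]), 0.01)


class TestScaledMC:
    def test_zero_absorption_returns_baseline_weight_everywhere(
            self, photon_records):
        mua = np.zeros(5)
        musp = np.full(5, photon_records.baseline_mus)
        r = w.scaled_mc_reflectance(photon_records, mua, musp)
        expected = (photon_records.exit_weights.sum()
                    / (photon_records.n_launched
                       * photon_records.geometry.annulus_area_cm2()))
        np.testing.assert_allclose(r, expected, rtol=1e-12)

    def test_reproducible_given_seed(self):
        a = w.simulate_photon_records(n_photons=2000, seed=9)
        b = w.simulate_photon_records(n_photons=2000, seed=9)
        np.testing.assert_array_equal(a.path_lengths_cm, b.path_lengths_cm)

    def test_agrees_with_diffusion_in_validity_band(self, photon_records):
        # cross-model sanity: µa/µs' < 0.1 at the default separation,
        # 5-point absorption grid at the baseline scattering level
        musp = np.full(5, photon_records.baseline_mus)
        mua = np.linspace(0.1, 0.9, 5)
        r_mc = w.scaled_mc_reflectance(photon_records, mua, musp)
        r_diff = diffusion_reflectance_annulus(mua, musp,
                                               photon_records.geometry)
        assert np.all(np.abs(r_mc - r_diff) / r_diff < 0.15)


class TestForwardInterface:
    def test_unknown_model_raises(self):
        with pytest.raises(ValueError):
            w.forward_reflectance(_props(0.5, 10.0), model="beer_lambert")

    def test_scaled_mc_without_records_raises(self):
        with pytest.raises(ValueError):
            w.forward_reflectance(_props(0.5, 10.0), model="scaled_mc")

    def test_simulate_spectra_deterministic_and_shaped(self, basis):
        params = w.table1_fixture()[:2] * 2  # two identical pairs
        spectra = w.simulate_spectra(params, w.FULL_GRID, basis)
        assert len(spectra) == 4
        np.testing.assert_array_equal(spectra[0].values, spectra[2].values)
        assert all(np.all(s.values > 0) for s in spectra)

    def test_absorption_free_spectrum_shaped_by_scattering_only(self, basis):
        params = w.TissueParameters(0, 0, 0,
                                    w.ScatteringModel(amplitude_a=10.0,
                                                      exponent_b=1.0))
        s = w.simulate_spectra([params], w.FULL_GRID, basis)[0]
        # µa ≡ 0: reflectance should vary smoothly and monotonically the
        # way µs'(λ) does (decreasing µs' -> decreasing reflectance here)
        assert np.all(np.diff(s.values) < 0)


class TestConvolveBandpass:
    def test_zero_fwhm_is_identity(self, basis):
        s = w.simulate_spectra([w.table1_fixture()[0]], w.FULL_GRID, basis)[0]
        assert w.convolve_bandpass(s, 0.0) is s

    @pytest.mark.parametrize("fwhm", [1, 5, 10, 20, 50])
    def test_constant_spectrum_unchanged(self, fwhm):
        grid = w.WavelengthGrid(450, 600, 2.5)
        s = w.ReflectanceSpectrum(grid, np.full(grid.count, 3.3))
        out = w.convolve_bandpass(s, fwhm)
        np.testing.assert_allclose(out.values, 3.3, rtol=1e-12)
        assert out.fwhm_nm == fwhm

    def test_impulse_response_is_discretized_gaussian(self):
        # unit impulse on a 1 nm grid; FWHM 10 nm -> sigma 4.2466 nm
        grid = w.WavelengthGrid(450, 600, 1)
        values = np.zeros(grid.count)
        center = 75
        values[center] = 1.0
        out = w.convolve_bandpass(w.ReflectanceSpectrum(grid, values), 10.0)
        sigma = 10.0 * FWHM_TO_SIGMA
        assert sigma == pytest.approx(4.2466, abs=1e-4)
        half = int(np.floor(3 * sigma))
        offsets = np.arange(-half, half + 1, dtype=float)
        kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
        kernel /= kernel.sum()
        interior = slice(center - half, center + half + 1)
        np.testing.assert_allclose(out.values[interior], kernel, rtol=1e-9)

    def test_commutes_with_scalar_multiplication(self):
        grid = w.WavelengthGrid(450, 600, 2.5)
        rng = np.random.default_rng(3)
        values = rng.uniform(0.5, 2.0, grid.count)
        s = w.ReflectanceSpectrum(grid, values)
        scaled_then_convolved = w.convolve_bandpass(
            w.ReflectanceSpectrum(grid, 7.0 * values), 20.0).values
        convolved_then_scaled = 7.0 * w.convolve_bandpass(s, 20.0).values
        np.testing.assert_allclose(scaled_then_convolved,
                                   convolved_then_scaled, rtol=1e-12)

    def test_smoothness_never_decreases_with_fwhm(self, basis):
        # roughness on the grid interior (outside the widest kernel's
        # truncation zone, where renormalization perturbs the edges)
        grid = w.WavelengthGrid(400, 650, 1)
        s = w.simulate_spectra([w.table1_fixture()[4]], grid, basis)[0]
        fwhms = (0, 1, 5, 10, 20, 30, 40, 50)
        margin = int(3 * max(fwhms) * FWHM_TO_SIGMA) + 2
        interior = slice(margin, -margin)

        def roughness(values):
            return float(np.sum(np.diff(values[interior], n=2) ** 2))

        rough = [roughness(w.convolve_bandpass(s, f).values) for f in fwhms]
        assert all(b <= a + 1e-15 for a, b in zip(rough, rough[1:]))

    def test_custom_kernel_identity_and_validation(self):
        grid = w.WavelengthGrid(450, 600, 2.5)
        rng = np.random.default_rng(4)
        s = w.ReflectanceSpectrum(grid, rng.uniform(1, 2, grid.count))
        delta = w.convolve_bandpass(s, 5.0,
                                    kernel=lambda d: (d == 0).astype(float))
        np.testing.assert_allclose(delta.values, s.values)
        with pytest.raises(ValueError):
            w.convolve_bandpass(s, -1.0)


class TestPhotonRecordIO:
    def test_round_trip(self, tmp_path, photon_records):
        sub = w.PhotonRecordSet(photon_records.exit_weights[:50],
                                photon_records.path_lengths_cm[:50],
                                photon_records.baseline_mus, 1000,
                                photon_records.geometry)
        path = tmp_path / "records.csv"
        from waveopt.forward_model import load_photon_records, \
            save_photon_records
        save_photon_records(sub, path)
        loaded = load_photon_records(path)
        np.testing.assert_allclose(loaded.path_lengths_cm,
                                   sub.path_lengths_cm)
        assert loaded.baseline_mus == sub.baseline_mus
        assert loaded.geometry == sub.geometry
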