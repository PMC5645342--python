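"""Structure-factor transform, excitation spectra and wavelength ratios."""

import numpy as np
import pytest

from shgspec.dispersion import refractive_index, water
from shgspec.shg_model import (
    Chi2Profile,
    ExcitationSpectrum,
    GridSpec,
    build_profile,
    excitation_spectrum,
    fit_diameter,
    gouy_weight,
    normalize_to_reference,
    sample_structure_factor,
    structure_factor,
    wavelength_ratio,
)
from conftest import BAND_UM


def direct_transform(profile, wavelength, na, dk_values, n_medium=1.0):
    """Independent quadrature of the Gouy-weighted transform: explicit
    Riemann sum of chi2(z) exp(i dk z) / (1 + i zeta) over the grid."""
    z = profile.grid.z
    f = profile.values * gouy_weight(z, wavelength, na, n_medium)
    return np.array(
        [np.sum(f * np.exp(1j * dk * z)) * profile.grid.dz for dk in dk_values]
    )


def impulse_profile(grid=None, amplitude=1.0):
    grid = grid or GridSpec()
    values = np.zeros(grid.n_samples)
    values[grid.n_samples // 2] = amplitude  # z = 0 sample
    return Chi2Profile(grid=grid, values=values)


class TestGrid:
    def test_default_grid_arithmetic(self, default_grid):
        assert default_grid.sampling_rate == pytest.approx(85.33, abs=0.005)
        assert default_grid.delta_k_interval == pytest.approx(0.065, abs=5e-4)
        assert default_grid.delta_k_max == pytest.approx(268, abs=0.5)

    def test_z_axis_centred(self, default_grid):
        z = default_grid.z
        assert z[default_grid.n_samples // 2] == 0.0
        assert np.allclose(np.diff(z), default_grid.dz)


class TestBuildProfile:
    def test_centre_value_is_two(self, hamming_profile):
        # cosine peak (1) plus unit baseline window peak (1) at z = 0
        i0 = hamming_profile.grid.n_samples // 2
        assert hamming_profile.values[i0] == pytest.approx(2.0)

    def test_zero_outside_support(self, tophat_profile):
        z = tophat_profile.grid.z
        support = max(tophat_profile.diameter, tophat_profile.baseline_width) / 2
        assert np.all(tophat_profile.values[np.abs(z) > support] == 0.0)

    def test_oscillation_zero_mean_over_integer_periods(self, default_grid):
        # the polarity oscillation itself (no window) averages to zero
        p = build_profile("tophat", 0.46, 0.23, baseline_amplitude=0.0,
                          baseline_width=0.46)
        z = default_grid.z
        inside = np.abs(z) < 0.23  # exactly two periods
        # mean vanishes up to the sampling granularity of the period
        assert np.cos(2 * np.pi * z[inside] / 0.23).mean() == pytest.approx(0.0, abs=0.01)
        assert p.values[inside].mean() == pytest.approx(0.0, abs=0.01)

    def test_aliasing_period_rejected(self, default_grid):
        with pytest.raises(ValueError, match="alias"):
            build_profile("hamming", 0.45, 1.5 * default_grid.dz)

    def test_unknown_apodization(self):
        with pytest.raises(ValueError, match="apodization"):
            build_profile("triangle", 0.45, 0.23)


class TestGouyWeight:
    def test_plane_wave_limit(self):
        z = np.linspace(-5, 5, 11)
        assert np.allclose(gouy_weight(z, 0.92, 0.0, 1.33), 1.0)

    def test_focus_and_symmetry(self):
        assert gouy_weight(0.0, 0.92, 1.3, 1.33) == pytest.approx(1.0)
        wp = gouy_weight(1.7, 0.92, 1.3, 1.33)
        wm = gouy_weight(-1.7, 0.92, 1.3, 1.33)
        assert abs(wp) == pytest.approx(abs(wm))


class TestStructureFactor:
    def test_impulse_gives_flat_magnitude(self):
        sf = structure_factor(impulse_profile(), 0.9, na=1.3, n_medium=1.33)
        mags = np.abs(sf.G)
        assert np.allclose(mags, mags[0], rtol=1e-12)

    def test_tophat_matches_analytic_sinc(self):
        # plane-wave transform of a top-hat of width L is L*sinc(dk*L/2)
        L = 0.5
        p = build_profile("tophat", L, 0.23, baseline_amplitude=0.0)
        p = Chi2Profile(grid=p.grid, values=(np.abs(p.grid.z) <= L / 2).astype(float))
        sf = structure_factor(p, 0.9, na=0.0)
        dk = sf.delta_k_grid
        expected = L * np.sinc(dk * L / 2 / np.pi)
        # discretization error only: the top-hat edge is resolved to dz/2
        assert np.abs(np.abs(sf.G) - np.abs(expected)).max() < 2 * p.grid.dz

    def test_windowed_cosine_peaks_at_grating_momentum(self, water_model):
        p = build_profile("tophat", 0.5, 0.23, baseline_amplitude=0.0)
        sf = structure_factor(p, 0.9, na=0.0)
        pos = sf.delta_k_grid > 10
        peak_dk = sf.delta_k_grid[pos][np.argmax(np.abs(sf.G[pos]))]
        assert peak_dk == pytest.approx(2 * np.pi / 0.23, rel=0.02)

    def test_matches_direct_quadrature_at_nodes(self, hamming_profile, water_model):
        n = refractive_index(water_model, 0.86)
        sf = structure_factor(hamming_profile, 0.86, na=1.3, n_medium=n)
        rng = np.random.default_rng(7)
        idx = rng.integers(0, sf.delta_k_grid.size, size=10)
        oracle = direct_transform(
            hamming_profile, 0.86, 1.3, sf.delta_k_grid[idx], n_medium=n
        )
        assert np.allclose(sf.G[idx], oracle, rtol=1e-9, atol=1e-12)

    def test_conjugate_symmetry_plane_wave(self, tophat_profile):
        sf = structure_factor(tophat_profile, 0.9, na=0.0)
        dk = sf.delta_k_grid
        for k in (2.0, 15.0, 27.3):
            gp = sample_structure_factor(sf, k)
            gm = sample_structure_factor(sf, -k)
            assert gm == pytest.approx(np.conj(gp), rel=1e-9)
        assert np.abs(sf.G)[np.abs(dk) < 50].min() >= 0  # sanity

    def test_sample_at_node_is_exact(self, hamming_profile):
        sf = structure_factor(hamming_profile, 0.9, na=0.0)
        k = sf.delta_k_grid[4321]
        assert sample_structure_factor(sf, k) == pytest.approx(sf.G[4321], rel=1e-12)

    def test_sample_out_of_range(self, hamming_profile):
        sf = structure_factor(hamming_profile, 0.9, na=0.0)
        with pytest.raises(ValueError, match="unaliased"):
            sample_structure_factor(sf, 300.0)


class TestExcitationSpectrum:
    def test_impulse_inverse_fourth_power(self, water_model):
        # a point source has a flat G: the spectrum is a pure 1/lambda^4 fall
        spec = excitation_spectrum(
            impulse_profile(), BAND_UM, "epi", na=0.0, dispersion=water_model
        )
        expected = 1.0 / BAND_UM**4
        ratio = spec.S2 / spec.S2[0]
        assert np.allclose(ratio, expected / expected[0], rtol=1e-12)
        assert wavelength_ratio(spec, 0.92, 0.86) == pytest.approx(
            (0.86 / 0.92) ** 4, rel=1e-12
        )

    @pytest.mark.parametrize("profile_fixture", ["hamming_profile", "tophat_profile"])
    def test_forward_spectra_fall_monotonically(self, profile_fixture, request,
                                                water_model):
        p = request.getfixturevalue(profile_fixture)
        spec = excitation_spectrum(p, BAND_UM, "forward", na=1.3, dispersion=water_model)
        assert np.all(np.diff(spec.S2) < 0)

    def test_chi2_scaling_squares_intensity(self, hamming_profile, water_model):
        wl = np.array([0.86, 0.92])
        a = excitation_spectrum(hamming_profile, wl, "epi", dispersion=water_model)
        b = excitation_spectrum(
            hamming_profile.scaled(3.0), wl, "epi", dispersion=water_model
        )
        assert np.allclose(b.S2, 9.0 * a.S2, rtol=1e-12)
        assert wavelength_ratio(b, 0.92, 0.86) == pytest.approx(
            wavelength_ratio(a, 0.92, 0.86), rel=1e-12
        )

    def test_ratio_identity_and_zero_denominator(self, water_model):
        spec = excitation_spectrum(
            impulse_profile(), BAND_UM, "forward", na=0.0, dispersion=water_model
        )
        assert wavelength_ratio(spec, 0.9, 0.9) == pytest.approx(1.0)
        zero = ExcitationSpectrum(
            wavelengths=np.array([0.86, 0.92]),
            S2=np.array([0.0, 1.0]),
            direction="epi",
            na=0.0,
        )
        with pytest.raises(ZeroDivisionError):
            wavelength_ratio(zero, 0.92, 0.86)

    def test_forward_ratio_insensitive_epi_ratio_sensitive(self, water_model):
        # the structural discrimination mechanism: a 0.45 -> 0.5 um diameter
        # change barely moves the forward 920/860 ratio but reshapes the epi one
        ratios = {}
        for apod, diam in (("hamming", 0.45), ("tophat", 0.5)):
            p = build_profile(apod, diam, 0.23)
            for direction in ("forward", "epi"):
                spec = excitation_spectrum(p, BAND_UM, direction,
                                           dispersion=water_model)
                ratios[(diam, direction)] = wavelength_ratio(spec, 0.92, 0.86)
        assert abs(ratios[(0.5, "forward")] - ratios[(0.45, "forward")]) < 0.05
        assert abs(ratios[(0.5, "epi")] - ratios[(0.45, "epi")]) > 0.5


class TestNormalization:
    def test_reference_is_100(self, hamming_profile, water_model):
        spec = excitation_spectrum(hamming_profile, BAND_UM, "epi",
                                   dispersion=water_model)
        pct = normalize_to_reference(spec, 0.8)
        i = np.where(np.isclose(spec.wavelengths, 0.8))[0][0]
        assert pct.S2[i] == pytest.approx(100.0)

    def test_impulse_closed_form(self, water_model):
        spec = excitation_spectrum(
            impulse_profile(), np.array([0.8, 1.0]), "forward", na=0.0,
            dispersion=water_model,
        )
        pct = normalize_to_reference(spec, 0.8)
        assert pct.S2[1] == pytest.approx(100 * (0.8 / 1.0) ** 4, rel=1e-12)

    def test_scale_invariance(self, hamming_profile, water_model):
        wl = np.array([0.8, 0.9])
        spec = excitation_spectrum(hamming_profile, wl, "epi", dispersion=water_model)
        doubled = ExcitationSpectrum(
            wavelengths=wl, S2=2 * spec.S2, direction="epi", na=spec.na
        )
        assert np.allclose(
            normalize_to_reference(spec, 0.8).S2,
            normalize_to_reference(doubled, 0.8).S2,
        )


class TestDiameterRecovery:
    def test_grid_search_recovers_true_diameter(self, water_model):
        wl = BAND_UM
        truth = excitation_spectrum(
            build_profile("tophat", 0.50, 0.23), wl, "epi", dispersion=water_model
        )
        candidates = np.round(np.arange(0.40, 0.5501, 0.01), 3)
        best = fit_diameter(truth, candidates, "tophat", dispersion=water_model)
        assert abs(best - 0.50) <= 0.01
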