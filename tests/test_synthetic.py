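import numpy as np
import pytest

from oxiraman.bands import GaussianBand, default_band_library
from oxiraman.exceptions import CoverageError, SpectrumValidationError
from oxiraman.synthetic import (
    SyntheticDatasetSpec,
    generate_mixture_series,
    generate_pure_spectrum,
    generate_sers_dataset,
    generate_thz_series,
    generate_thz_spectrum,
    polynomial_baseline,
    wavenumber_axis,
)
from oxiraman.thz import DEOXY_TETRAD_SHIFT, TetradShift


class TestBandLibraryDefaults:
    """The default library must contain the assigned marker centers."""

    @pytest.mark.parametrize(
        "species, centers",
        [
            ("dGTP", {1123.0, 1485.0, 1575.0}),
            ("GTP", {1123.0, 1485.0, 1575.0}),
            ("8-oxo-dGTP", {1123.0, 1445.0, 1535.0, 1607.0}),
            ("8-oxo-GTP", {1123.0, 1445.0, 1535.0, 1607.0}),
            ("8-oxo-dATP", {620.0}),
            ("colloid", {240.0}),
        ],
    )
    def test_assigned_centers_present(self, library, species, centers):
        have = {b.center for b in library[species]}
        assert centers <= have

    def test_band_parameter_validation(self):
        with pytest.raises(ValueError):
            GaussianBand(1000.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            GaussianBand(1000.0, 8.0, -0.1)


class TestPureSpectrum:
    def test_single_band_is_exact_gaussian(self):
        band = GaussianBand(1000.0, 8.0, 2.0)
        lib = {"X": (band,)}
        s = generate_pure_spectrum("X", lib, axis=(900.0, 1100.0, 0.5),
                                   noise_sd=0.0, region=None)
        np.testing.assert_allclose(s.intensities, band.profile(s.wavenumbers), rtol=1e-12)
        assert s.wavenumbers[np.argmax(s.intensities)] == band.center

    def test_oxo_dgtp_maxima_at_assigned_centers(self, oxo_dgtp_noiseless):
        s = oxo_dgtp_noiseless
        for center in (1445.0, 1535.0, 1607.0):
            near = np.abs(s.wavenumbers - center) <= 10.0
            peak = s.wavenumbers[near][np.argmax(s.intensities[near])]
            assert abs(peak - center) <= 0.5  # one grid step

    def test_seed_determinism_and_noise_independence(self):
        a = generate_pure_spectrum("dGTP", noise_sd=0.02, seed=11)
        b = generate_pure_spectrum("dGTP", noise_sd=0.02, seed=11)
        c = generate_pure_spectrum("dGTP", noise_sd=0.02, seed=12)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        diff = a.intensities - c.intensities
        assert np.any(diff != 0)
        # difference is pure noise: zero mean within 4 standard errors
        assert abs(diff.mean()) < 4 * diff.std() / np.sqrt(diff.size)

    def test_unknown_species_and_narrow_axis_rejected(self, library):
        with pytest.raises(KeyError):
            generate_pure_spectrum("unobtainium", library)
        with pytest.raises(CoverageError):
            generate_pure_spectrum("dGTP", library, axis=(900.0, 1700.0, 0.5),
                                   region=None)


class TestMixtureSeries:
    def _series(self, concentrations, **kw):
        spec = SyntheticDatasetSpec(
            concentrations=concentrations, replicates=1, noise_sd=0.0,
            baseline=(), seed=0, **kw,
        )
        return generate_mixture_series(spec)

    def test_endpoints_reproduce_pure_components(self, library):
        _, spectra = self._series((0.0, 100.0))
        pure_a = generate_pure_spectrum("dGTP", library, noise_sd=0.0)
        pure_b = generate_pure_spectrum("8-oxo-dGTP", library, noise_sd=0.0)
        np.testing.assert_allclose(spectra[0].intensities, pure_a.intensities, atol=1e-14)
        np.testing.assert_allclose(spectra[1].intensities, pure_b.intensities, atol=1e-14)

    def test_marker_window_area_exactly_linear_in_fraction(self):
        conc = (0.0, 4.0, 8.0, 16.0)
        _, spectra = self._series(conc)
        areas = []
        for s in spectra:
            m = np.abs(s.wavenumbers - 1535.0) <= 25.0
            areas.append(np.trapezoid(s.intensities[m], s.wavenumbers[m]))
        coeffs, diag = np.polynomial.polynomial.polyfit(
            np.array(conc), np.array(areas), 1, full=True
        )
        assert diag[0][0] < 1e-16  # residual of the linear fit

    def test_c0_contamination_raises_marker_intensity_at_zero(self):
        _, clean = self._series((0.0,))
        _, contaminated = self._series((0.0,), c0_pct=0.5)
        i = np.argmin(np.abs(clean[0].wavenumbers - 1535.0))
        assert contaminated[0].intensities[i] > clean[0].intensities[i]

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(SpectrumValidationError, match="empty"):
            SyntheticDatasetSpec(concentrations=())


class TestThzSeries:
    def test_centers_follow_shift_model(self):
        model = DEOXY_TETRAD_SHIFT
        _, spectra = generate_thz_series([0.0, 100.0], model=model)
        for s, expected in zip(spectra, (model.nu0, model.frequency(100.0))):
            peak = s.wavenumbers[np.argmax(s.intensities)]
            assert abs(peak - expected) <= 0.25
        assert abs(model.frequency(100.0) - model.nu_oxo) < 1e-4  # asymptote

    def test_band_below_zero_rejected(self):
        low = TetradShift(nu0=40.0, nu_oxo=15.0, rate=6.0)
        with pytest.raises(CoverageError, match="below 0"):
            generate_thz_series([100.0], model=low)

    def test_spectrum_tagged_thz(self):
        s = generate_thz_spectrum("dGTP")
        assert s.region == "thz"
        assert s.wavenumbers.min() < 100.0


class TestSersDataset:
    def test_colloid_band_present_in_every_spectrum(self):
        spectra, _ = generate_sers_dataset(seed=5)
        for s in spectra:
            near = np.abs(s.wavenumbers - 240.0) <= 40.0
            peak = s.wavenumbers[near][np.argmax(s.intensities[near])]
            assert abs(peak - 240.0) <= 5.0

    def test_noiseless_endpoint_is_dg_plus_colloid(self, library):
        spectra, _ = generate_sers_dataset(
            [0.0], enhancement_cv=0.0, noise_sd=0.0, baseline=(), seed=0
        )
        wn = spectra[0].wavenumbers
        expected = np.zeros_like(wn)
        for b in library["dG"] + library["colloid"]:
            expected += b.profile(wn)
        np.testing.assert_allclose(spectra[0].intensities, expected, atol=1e-14)

    def test_noiseless_gainless_dataset_spans_two_dimensions(self):
        from oxiraman.preprocess import unit_vector_normalize

        spectra, _ = generate_sers_dataset(
            list(range(0, 101, 10)), enhancement_cv=0.0, noise_sd=0.0, seed=0
        )
        X = np.vstack(
            [unit_vector_normalize(s).intensities for s in spectra]
        )
        sv = np.linalg.svd(X, compute_uv=False)
        assert sv[2] / sv[0] < 1e-10  # two pure components only

    def test_negative_enhancement_cv_rejected(self):
        with pytest.raises(SpectrumValidationError):
            generate_sers_dataset(enhancement_cv=-0.1)


def test_axis_and_baseline_helpers():
    ax = wavenumber_axis(300.0, 1800.0, 0.5)
    assert ax[0] == 300.0 and ax[-1] == 1800.0
    assert np.allclose(np.diff(ax), 0.5)
    base = polynomial_baseline(ax, (1.0, 2.0))
    assert base[0] == 1.0 and np.isclose(base[-1], 3.0)
    assert np.all(polynomial_baseline(ax, ()) == 0)
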