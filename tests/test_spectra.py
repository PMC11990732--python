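"""Data model, I/O round-trips and the inner-filter correction."""

import numpy as np
import pytest

from quenchbind import (
    EmissionSpectrum,
    SimConfig,
    TitrationSeries,
    extract_quench_curve,
    inner_filter_correct,
    read_titration,
    simulate_titration,
    write_titration,
)
from quenchbind.spectra import parabolic_peak, series_meta


def make_spectrum(conc=0.0, intensities=None, wl=None, **kw):
    wl = np.arange(300.0, 321.0) if wl is None else wl
    if intensities is None:
        intensities = np.exp(-0.5 * ((wl - 310.0) / 5.0) ** 2) * 100
    defaults = dict(
        excitation_wavelength=295.0, temperature=298.0, quencher_conc=conc
    )
    defaults.update(kw)
    return EmissionSpectrum(wavelengths=wl, intensities=intensities, **defaults)


class TestInnerFilterCorrection:
    @pytest.mark.parametrize(
        "F, a_ex, a_em, expected",
        [
            (100.0, 0.0, 0.0, 100.0),  # zero absorbance is the identity
            (100.0, 0.1, 0.1, 100.0 * 10**0.1),  # = 125.8925...
            (50.0, 0.2, 0.0, 50.0 * 10**0.1),  # mean-of-absorbances exponent
        ],
    )
    def test_pointwise_values(self, F, a_ex, a_em, expected):
        assert inner_filter_correct(F, a_ex, a_em) == pytest.approx(expected, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError, match="absorbance"):
            inner_filter_correct(10.0, -0.1, 0.0)

    def test_correction_is_multiplicative_and_order_independent(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 50, 20)
        b = rng.uniform(0, 50, 20)
        summed = inner_filter_correct(a + b, 0.13, 0.07)
        separate = inner_filter_correct(a, 0.13, 0.07) + inner_filter_correct(b, 0.13, 0.07)
        np.testing.assert_allclose(summed, separate, rtol=1e-12)


class TestValidation:
    def test_non_monotone_wavelengths_rejected(self):
        wl = np.array([300.0, 302.0, 301.0, 303.0])
        with pytest.raises(ValueError, match="increasing"):
            make_spectrum(wl=wl, intensities=np.ones(4))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="finite and non-negative"):
            make_spectrum(intensities=np.full(21, -1.0))

    def test_series_requires_zero_concentration_first(self):
        spectra = [make_spectrum(conc=1e-6), make_spectrum(conc=2e-6)]
        with pytest.raises(ValueError, match="zero quencher"):
            TitrationSeries(spectra=spectra, protein_conc=1.6e-6, temperature=298.0)

    def test_series_requires_shared_grid(self):
        s0 = make_spectrum(conc=0.0)
        s1 = make_spectrum(conc=1e-6, wl=np.arange(301.0, 322.0))
        with pytest.raises(ValueError, match="wavelength grid"):
            TitrationSeries(spectra=[s0, s1], protein_conc=1.6e-6, temperature=298.0)


class TestTitrationIO:
    def test_round_trip_preserves_series(self, tmp_path, static_series):
        series, _ = static_series
        csv, meta = tmp_path / "t.csv", tmp_path / "t.yaml"
        write_titration(series, csv, meta_path=meta)
        back = read_titration(csv, meta)
        assert back.protein_conc == series.protein_conc
        assert back.temperature == series.temperature
        np.testing.assert_allclose(back.wavelengths, series.wavelengths)
        np.testing.assert_allclose(back.concentrations, series.concentrations)
        for a, b in zip(back.spectra, series.spectra):
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_meta_concentration_count_must_match_columns(self, tmp_path, static_series):
        series, _ = static_series
        csv = tmp_path / "t.csv"
        write_titration(series, csv)
        meta = series_meta(series)
        meta["quencher_concs_M"] = meta["quencher_concs_M"][:-1]
        with pytest.raises(ValueError, match="concentrations"):
            read_titration(csv, meta)

    def test_missing_wavelength_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("index,intensity_00\n1,2\n2,3\n3,4\n")
        with pytest.raises(ValueError, match="wavelength"):
            read_titration(
                p,
                {
                    "protein_conc_M": 1.6e-6,
                    "quencher_concs_M": [0.0],
                    "temperature_K": 298,
                    "excitation_nm": 295,
                },
            )


class TestQuenchCurveExtraction:
    def test_peak_mode_recovers_generator_band_center(self):
        # off-grid band center: parabolic interpolation must find it sub-grid
        series, _ = simulate_titration(SimConfig(band_center=337.3))
        wl_peak, _ = parabolic_peak(series.wavelengths, series.spectra[0].intensities)
        assert wl_peak == pytest.approx(337.3, abs=0.05)
        curve = extract_quench_curve(series, mode="peak")
        assert curve.F0 > 0 and curve.F[0] == curve.F0

    def test_identical_spectra_give_unit_ratio(self):
        spectra = [make_spectrum(conc=c) for c in (0.0, 1e-6, 2e-6)]
        series = TitrationSeries(spectra=spectra, protein_conc=1.6e-6, temperature=298.0)
        curve = extract_quench_curve(series)
        np.testing.assert_allclose(curve.F / curve.F0, 1.0, rtol=1e-12)

    def test_fixed_mode_matches_grid_interpolation(self, static_series):
        series, _ = static_series
        curve = extract_quench_curve(series, mode="fixed", wavelength=360.0)
        expected = [s.intensity_at(360.0) for s in series.spectra]
        np.testing.assert_allclose(curve.F, expected, rtol=1e-12)

    def test_fixed_mode_outside_grid_rejected(self, static_series):
        series, _ = static_series
        with pytest.raises(ValueError, match="outside"):
            extract_quench_curve(series, mode="fixed", wavelength=500.0)

    def test_noise_free_quenching_is_monotone(self, static_series):
        series, _ = static_series
        curve = extract_quench_curve(series)
        assert np.all(np.diff(curve.F) < 0)
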