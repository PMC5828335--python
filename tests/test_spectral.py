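"""Fundamental-frequency estimation and amplitude summaries."""

import numpy as np
import pytest

import corvib as cv
from corvib.errors import NoHarmonicError

FS = 1000.0 / 0.23


class TestFundamental:
    def test_pure_sine_short_window(self, rng):
        """48 samples of a 400 Hz sine: padded-bin estimate within 15 Hz."""
        t = np.arange(48) / FS
        x = np.sin(2 * np.pi * 400.0 * t + 0.7)
        f0, res = cv.fundamental_frequency(x, FS)
        assert f0 == pytest.approx(400.0, abs=15.0)
        assert res == pytest.approx(FS / 48)

    def test_constant_trace(self):
        with pytest.raises(NoHarmonicError, match="no harmonic"):
            cv.fundamental_frequency(np.ones(50), FS)

    def test_dominant_component_wins(self):
        t = np.arange(64) / FS
        x = 3.0 * np.sin(2 * np.pi * 300.0 * t) + 1.0 * np.sin(2 * np.pi * 600.0 * t)
        f0, _ = cv.fundamental_frequency(x, FS)
        assert f0 == pytest.approx(300.0, abs=20.0)

    def test_scale_and_offset_invariance(self, rng):
        t = np.arange(60) / FS
        x = np.sin(2 * np.pi * 500.0 * t)
        f0, _ = cv.fundamental_frequency(x, FS)
        f1, _ = cv.fundamental_frequency(7.3 * x + 42.0, FS)
        assert f0 == f1

    def test_gap_interpolation_and_refusal(self):
        t = np.arange(60) / FS
        x = np.sin(2 * np.pi * 400.0 * t)
        few = x.copy()
        few[10:14] = np.nan
        f0, _ = cv.fundamental_frequency(few, FS)
        assert f0 == pytest.approx(400.0, abs=20.0)
        many = x.copy()
        many[5:35] = np.nan
        with pytest.raises(cv.CorvibError):
            cv.fundamental_frequency(many, FS)


class TestAmplitude:
    def test_sine_peak_to_peak(self):
        t = np.linspace(0, 1, 500)
        assert cv.amplitude_all_harmonics(2.5 * np.sin(2 * np.pi * 5 * t)) == (
            pytest.approx(5.0, rel=1e-3)
        )

    def test_constant_is_zero(self):
        assert cv.amplitude_all_harmonics(np.full(10, 3.3)) == 0.0

    def test_multi_harmonic_exceeds_first_harmonic(self):
        """With several harmonics the full peak-to-peak exceeds any single one."""
        t = np.arange(200) / FS
        first = np.sin(2 * np.pi * 300.0 * t)
        x = first + 0.8 * np.sin(2 * np.pi * 600.0 * t + 1.0) \
            + 0.6 * np.sin(2 * np.pi * 900.0 * t + 2.0)
        assert cv.amplitude_all_harmonics(x) >= cv.amplitude_all_harmonics(first) * 0.95


class TestSummaries:
    def test_identical_cases_zero_sd(self, quarter_result):
        _, _, res = quarter_result
        table = cv.summarize_cases([res.spectra] * 10)
        assert len(table) == 4
        row = table.set_index("vibration_type").loc["quarter"]
        assert row["frequency_sd_hz"] == 0.0
        assert row["n_cases"] == 10

    def test_two_case_hand_arithmetic(self, quarter_result):
        import copy

        _, _, res = quarter_result
        a = copy.deepcopy(res.spectra)
        b = copy.deepcopy(res.spectra)
        a["quarter"]["fundamental_hz"] = 300.0
        b["quarter"]["fundamental_hz"] = 500.0
        row = (
            cv.summarize_cases([a, b])
            .set_index("vibration_type")
            .loc["quarter"]
        )
        assert row["frequency_mean_hz"] == pytest.approx(400.0)
        assert row["frequency_sd_hz"] == pytest.approx(141.42, abs=0.01)

    def test_simulated_population_recovered(self, rng):
        """10 phantoms with frequencies drawn around 400 Hz: the mean/SD of
        the recovered fundamentals match the draw within sampling error."""
        freqs = np.round(rng.normal(400.0, 60.0, size=10) / 2) * 2
        freqs = np.clip(freqs, 250, 900)
        recovered = []
        for f in freqs:
            spec = cv.default_spec(
                vibrations=(
                    cv.VibrationSpec("quarter_left", float(f), 2.0, 0.0),
                    cv.VibrationSpec("quarter_right", float(f), 2.0, np.pi),
                ),
            )
            truth = cv.synthesize_contour(spec)
            res = cv.analyze_contours(
                cv.contour_series_from_matrix(truth.contour), spec.calibration
            )
            recovered.append(res.spectra["quarter"]["fundamental_hz"])
        recovered = np.array(recovered, dtype=float)
        assert np.abs(recovered - freqs).max() <= 25.0
        assert recovered.mean() == pytest.approx(freqs.mean(), abs=10.0)
        assert recovered.std(ddof=1) == pytest.approx(freqs.std(ddof=1), rel=0.25)
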