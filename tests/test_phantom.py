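"""Phantom generator: determinism, truth consistency, end-to-end recovery."""

import dataclasses

import numpy as np
import pytest

import corvib as cv


class TestSynthesis:
    def test_default_shapes_and_peak_timing(self, default_truth):
        assert default_truth.contour.shape == (576, 140)
        peak = int(np.argmax(default_truth.depth_px))
        assert 60 <= peak <= 80  # mid-sequence

    def test_zero_spec_constant_contour(self):
        truth = cv.synthesize_contour(cv.static_spec())
        assert np.ptp(truth.contour, axis=1).max() == 0.0

    def test_injected_vibration_spectrum(self):
        """The truth trace of a 400 Hz injection peaks at 400 Hz."""
        spec = cv.quarter_vibration_spec()
        truth = cv.synthesize_contour(spec)
        trace = truth.vibration_traces[0]
        f0, _ = cv.fundamental_frequency(trace, 1000.0 / spec.dt_ms)
        assert f0 == pytest.approx(400.0, abs=20.0)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError, match="inconsistent spec"):
            cv.default_spec(
                depth_mm=0.0,
                vibrations=(cv.VibrationSpec("peak_left", 400.0, 2.0),),
            )
        with pytest.raises(ValueError, match="inconsistent spec"):
            cv.default_spec(vibrations=(cv.VibrationSpec("nowhere", 400.0, 2.0),))

    def test_spec_file_round_trip(self, tmp_path):
        spec = cv.quarter_vibration_spec(seed=5)
        (tmp_path / "s.json").write_text(
            __import__("json").dumps(spec.to_dict())
        )
        back = cv.PhantomSpec.from_file(tmp_path / "s.json")
        assert back == spec


class TestRendering:
    def test_seed_determinism(self, default_truth):
        a = cv.render_sequence(default_truth)
        b = cv.render_sequence(default_truth)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_distinct_seeds_differ_only_in_noise(self, default_truth):
        spec2 = dataclasses.replace(cv.default_spec(), seed=99)
        a = cv.render_sequence(default_truth)
        b = cv.render_sequence(default_truth, spec2)
        assert not np.array_equal(a.frames, b.frames)
        # noise-free renders are identical whatever the seed
        clean1 = dataclasses.replace(cv.default_spec(), noise_sd=0.0, speckle_count=0, seed=1)
        clean2 = dataclasses.replace(clean1, seed=2)
        c = cv.render_sequence(default_truth, clean1)
        d = cv.render_sequence(default_truth, clean2)
        np.testing.assert_array_equal(c.frames, d.frames)

    def test_frame_geometry(self, default_render):
        assert default_render.frames.shape == (140, 200, 576)
        assert default_render.frames.dtype == np.uint8

    def test_clean_render_detector_agreement(self, clean_render):
        truth, seq = clean_render
        contours = cv.detect_contour_sequence(seq)
        assert np.abs(contours.values - truth.contour).max() <= 0.25


class TestRecovery:
    def test_quarter_vibration_recovery(self, quarter_result):
        spec, truth, res = quarter_result
        q = res.spectra["quarter"]
        assert q["fundamental_hz"] == pytest.approx(400.0, abs=20.0)
        p2p = np.nanmax(res.traces.quarter_vib) - np.nanmin(res.traces.quarter_vib)
        assert p2p == pytest.approx(4.0, abs=1.0)

    def test_peak_vibration_recovery(self, peak_result):
        spec, truth, res = peak_result
        p = res.spectra["peak"]
        assert p["fundamental_hz"] == pytest.approx(350.0, abs=20.0)
        # antiphase amplitude a on both peaks -> trace maximum 2a
        assert np.nanmax(res.traces.peak_vib) == pytest.approx(6.0, abs=1.0)

    def test_in_phase_quarter_cancellation(self):
        spec = cv.default_spec(
            vibrations=(
                cv.VibrationSpec("quarter_left", 400.0, 2.0, 0.0),
                cv.VibrationSpec("quarter_right", 400.0, 2.0, 0.0),
            ),
        )
        truth = cv.synthesize_contour(spec)
        res = cv.analyze_contours(
            cv.contour_series_from_matrix(truth.contour), spec.calibration
        )
        assert np.nanmax(res.traces.quarter_vib) <= 1.0

    def test_recovery_degrades_monotonically_with_noise(self):
        """Contour RMS error never improves when render noise grows."""
        rms = []
        for sd in (0.0, 6.0, 14.0):
            spec = cv.default_spec(noise_sd=sd, speckle_count=0, seed=7)
            truth = cv.synthesize_contour(spec)
            seq = cv.render_sequence(truth, spec)
            c = cv.detect_contour_sequence(seq)
            rms.append(float(np.sqrt(np.mean((c.values - truth.contour) ** 2))))
        assert rms[0] <= rms[1] <= rms[2]

    def test_end_to_end_report_structure(self, tmp_path):
        rep = cv.end_to_end_recovery(cv.drift_spec())
        assert rep["n_d"]["max_abs_err_cols"] <= 2.0
        assert abs(rep["cutoff"]["recovered_at_peak"][0] - 200) <= 2
        assert abs(rep["cutoff"]["recovered_at_peak"][1] - 370) <= 2
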