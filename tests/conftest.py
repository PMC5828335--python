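"""Shared fixtures: phantoms are rendered once per session where possible."""

import dataclasses

import numpy as np
import pytest

import corvib as cv


@pytest.fixture(scope="session")
def nominal_cal():
    return cv.Calibration(rows=200, cols=576)


@pytest.fixture(scope="session")
def default_truth():
    return cv.synthesize_contour(cv.default_spec())


@pytest.fixture(scope="session")
def default_render(default_truth):
    return cv.render_sequence(default_truth)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, blur-free, evenly lit phantom."""
    return dataclasses.replace(
        cv.default_spec(),
        blur_sigma=0.0, noise_sd=0.0, speckle_count=0, gain_range=(1.0, 1.0),
    )


@pytest.fixture(scope="session")
def clean_render(clean_spec):
    truth = cv.synthesize_contour(clean_spec)
    return truth, cv.render_sequence(truth, clean_spec)


@pytest.fixture(scope="session")
def drift_result():
    """Full pipeline run on the drifting compact-dent phantom."""
    spec = cv.drift_spec()
    truth = cv.synthesize_contour(spec)
    seq = cv.render_sequence(truth, spec)
    res = cv.analyze_sequence(seq, cv.AnalysisParams(dt_ms=spec.dt_ms))
    return spec, truth, res


@pytest.fixture(scope="session")
def quarter_result():
    spec = cv.quarter_vibration_spec()
    truth = cv.synthesize_contour(spec)
    seq = cv.render_sequence(truth, spec)
    res = cv.analyze_sequence(seq, cv.AnalysisParams(dt_ms=spec.dt_ms))
    return spec, truth, res


@pytest.fixture(scope="session")
def peak_result():
    spec = cv.peak_vibration_spec()
    truth = cv.synthesize_contour(spec)
    seq = cv.render_sequence(truth, spec)
    res = cv.analyze_sequence(seq, cv.AnalysisParams(dt_ms=spec.dt_ms))
    return spec, truth, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
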