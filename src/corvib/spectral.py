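"""Spectral summaries of the vibration traces.

Each vibration trace lives on the short inter-applanation window (typically
~50 samples at 4347.8 Hz), so the Rayleigh resolution is coarse (~90 Hz).
The fundamental is taken as the dominant spectral bin above the band split
(the analysed signals are the >100 Hz components): traces are mean-
subtracted, Hann-windowed and zero-padded to >= 4096 points, which
interpolates the spectrum but cannot beat the Rayleigh limit — the
resolution is therefore reported alongside every estimate.

Frequencies are estimated on the *signed* difference traces (e.g.
``m_fl - m_fr``): rectifying to the absolute trace would double the
apparent fundamental.  Amplitudes are the peak-to-peak excursion of the
trace as defined (all harmonics together), which for multi-harmonic
vibrations exceeds the first-harmonic amplitude alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientFramesError, NoHarmonicError
from .io import Calibration
from .vibrations import VibrationTraces

#: trace keys summarised for the four vibration types
VIBRATION_TYPES = ("peak", "quarter", "max_deformation", "cutoff")


def _fill_gaps(x: np.ndarray, max_gap_frac: float) -> np.ndarray:
    ok = np.isfinite(x)
    if not ok.any():
        raise NoHarmonicError("no harmonic: empty trace")
    if (~ok).mean() > max_gap_frac:
        raise InsufficientFramesError(
            f"insufficient frames: {(~ok).sum()}/{x.size} gaps in trace"
        )
    if ok.all():
        return x
    idx = np.arange(x.size)
    out = x.copy()
    out[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return out


def fundamental_frequency(
    trace: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] | None = None,
    pad_to: int = 4096,
    max_gap_frac: float = 0.3,
) -> tuple[float, float]:
    """Frequency (Hz) of the dominant spectral bin within ``band``.

    Returns ``(fundamental_hz, resolution_hz)`` where the resolution is the
    Rayleigh limit ``fs / n_samples`` of the un-padded window.  Gaps
    (flagged frames) are linearly interpolated; more than ``max_gap_frac``
    gaps refuse.  Invariant to trace scaling and mean offset.
    """
    x = np.asarray(trace, dtype=float)
    ok = np.flatnonzero(np.isfinite(x))
    if ok.size == 0:
        raise NoHarmonicError("no harmonic: empty trace")
    x = _fill_gaps(x[ok[0] : ok[-1] + 1], max_gap_frac)  # trim to analysis span
    n = x.size
    if n < 8:
        raise InsufficientFramesError(f"insufficient frames: trace length {n} < 8")
    if np.ptp(x) == 0:
        raise NoHarmonicError("no harmonic: constant trace")
    x = x - x.mean()
    w = np.hanning(n)
    nfft = int(pad_to)
    while nfft < n:
        nfft *= 2
    spec = np.abs(np.fft.rfft(x * w, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    if band is None:
        band = (100.0, fs_hz / 2.0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise NoHarmonicError("no harmonic: empty analysis band")
    k = int(np.argmax(spec[sel]))
    return float(freqs[sel][k]), fs_hz / n


def amplitude_all_harmonics(trace: np.ndarray) -> float:
    """Peak-to-peak excursion of a trace over the analysis interval."""
    x = np.asarray(trace, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientFramesError("insufficient frames: trace length < 2")
    return float(np.max(x) - np.min(x))


def summarize_traces(
    traces: VibrationTraces,
    calibration: Calibration,
    dt_ms: float,
    band: tuple[float, float] | None = None,
) -> dict:
    """Per-vibration-type spectral summary of one case.

    Row-axis amplitudes (peak, quarter) are reported in um, column-axis
    amplitudes (maximum-deformation, cutoff) in mm, mirroring the mixed
    units of the acquisition geometry.
    """
    fs = 1000.0 / dt_ms
    ph_um = calibration.pixel_height_um
    pw_mm = calibration.pixel_width_mm
    signed = {
        "peak": traces.m_kl - traces.m_kr,
        "quarter": traces.m_fl - traces.m_fr,
        "max_deformation": traces.n_d,
        "cutoff": traces.n_bl - traces.n_br,
    }
    amplitude = {
        "peak": ("um", lambda: amplitude_all_harmonics(traces.peak_vib) * ph_um),
        "quarter": ("um", lambda: amplitude_all_harmonics(traces.quarter_vib) * ph_um),
        "max_deformation": ("mm", lambda: amplitude_all_harmonics(traces.n_d) * pw_mm),
        "cutoff": ("mm", lambda: amplitude_all_harmonics(traces.cutoff_vib) * pw_mm),
    }
    out: dict = {
        "analysis_interval": {
            "A_p1_frame": traces.ap.frame1,
            "A_p2_frame": traces.ap.frame2,
            "A_p1_ms": traces.ap.t1_ms,
            "A_p2_ms": traces.ap.t2_ms,
        }
    }
    for key in VIBRATION_TYPES:
        entry: dict = {}
        n_ok = int(np.isfinite(signed[key]).sum())
        entry["n_samples"] = n_ok
        try:
            f0, res = fundamental_frequency(signed[key], fs, band=band)
            entry["fundamental_hz"] = f0
            entry["resolution_hz"] = res
        except (NoHarmonicError, InsufficientFramesError) as exc:
            entry["fundamental_hz"] = None
            entry["resolution_hz"] = None
            entry["note"] = str(exc)
        units, amp = amplitude[key]
        try:
            entry["amplitude"] = amp()
        except InsufficientFramesError as exc:
            entry["amplitude"] = None
            entry["note"] = str(exc)
        entry["units"] = units
        out[key] = entry
    return out


def summarize_cases(cases: list[dict]) -> pd.DataFrame:
    """Mean +- SD of frequency and amplitude across cases, per vibration type.

    ``cases`` are per-case dicts from :func:`summarize_traces`; the result is
    a four-row table (one per vibration type).
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to summarize")
    rows = []
    for key in VIBRATION_TYPES:
        freqs = np.array(
            [c[key]["fundamental_hz"] for c in cases if c[key]["fundamental_hz"] is not None],
            dtype=float,
        )
        amps = np.array(
            [c[key]["amplitude"] for c in cases if c[key]["amplitude"] is not None],
            dtype=float,
        )
        units = cases[0][key]["units"]
        rows.append(
            {
                "vibration_type": key,
                "axis": "Y" if units == "um" else "X",
                "n_cases": len(freqs),
                "frequency_mean_hz": freqs.mean() if freqs.size else np.nan,
                "frequency_sd_hz": freqs.std(ddof=1) if freqs.size > 1 else np.nan,
                "amplitude_mean": amps.mean() if amps.size else np.nan,
                "amplitude_sd": amps.std(ddof=1) if amps.size > 1 else np.nan,
                "amplitude_units": units,
            }
        )
    return pd.DataFrame(rows)
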