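"""End-to-end analysis driver: frames (or contours) in, trace bundle out."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .applanation import ApplanationPair, applanations_from_times, detect_applanations
from .contour import ContourParams, ContourSeries, detect_contour_sequence
from .decompose import DecomposedSignals, decompose
from .io import Calibration, ImageSequence, write_contour_csv, write_traces
from .spectral import summarize_traces
from .vibrations import VibrationTraces, compute_vibration_traces


@dataclass
class AnalysisParams:
    """Tunable parameters of a run (defaults follow the nominal acquisition)."""

    dt_ms: float = 0.23
    p_r: float = 2.0
    cutoff_hz: float = 100.0
    edge_cols: int = 10
    window_mm: float = 3.0
    contour: ContourParams = field(default_factory=ContourParams)
    ap1_ms: float | None = None  # device-supplied override
    ap2_ms: float | None = None

    def validated(self) -> "AnalysisParams":
        for name in ("dt_ms", "p_r", "cutoff_hz", "window_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_cols < 1:
            raise ValueError("edge_cols must be >= 1")
        return self


@dataclass
class AnalysisResult:
    """Everything one run produces, stage by stage."""

    contours: ContourSeries
    decomp: DecomposedSignals
    ap: ApplanationPair
    traces: VibrationTraces
    spectra: dict
    calibration: Calibration
    params: AnalysisParams


def analyze_contours(
    contours: ContourSeries,
    calibration: Calibration,
    params: AnalysisParams | None = None,
) -> AnalysisResult:
    """Run the pipeline from a pre-extracted contour matrix."""
    params = (params or AnalysisParams()).validated()
    fs = 1000.0 / params.dt_ms
    decomp = decompose(
        contours, fs_hz=fs, cutoff_hz=params.cutoff_hz, edge_cols=params.edge_cols
    )
    if params.ap1_ms is not None and params.ap2_ms is not None:
        ap = applanations_from_times(
            params.ap1_ms, params.ap2_ms, params.dt_ms, decomp.n_frames
        )
    else:
        ap = detect_applanations(
            decomp, calibration, params.dt_ms,
            window_mm=params.window_mm, p_r=params.p_r,
        )
    traces = compute_vibration_traces(decomp, ap, p_r=params.p_r)
    spectra = summarize_traces(traces, calibration, params.dt_ms)
    return AnalysisResult(
        contours=contours, decomp=decomp, ap=ap, traces=traces,
        spectra=spectra, calibration=calibration, params=params,
    )


def analyze_sequence(
    seq: ImageSequence, params: AnalysisParams | None = None
) -> AnalysisResult:
    """Run the full pipeline from an image sequence."""
    params = (params or AnalysisParams()).validated()
    contours = detect_contour_sequence(seq, params.contour)
    return analyze_contours(contours, seq.calibration, params)


def contour_series_from_matrix(values: np.ndarray) -> ContourSeries:
    """Wrap a (columns x frames) row-coordinate matrix as a ContourSeries."""
    values = np.asarray(values, dtype=float)
    return ContourSeries(values=values, valid_mask=np.isfinite(values))


def write_result_bundle(
    result: AnalysisResult, outdir: str | Path, write_contours: bool = True
) -> Path:
    """Write traces.csv, spectral.json (and contours.csv) to ``outdir``.

    Output is deterministic: identical inputs and parameters produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_traces(
        result.traces, result.calibration, outdir / "traces.csv",
        dt_ms=result.params.dt_ms,
    )
    (outdir / "spectral.json").write_text(
        json.dumps(result.spectra, indent=2, sort_keys=True) + "\n"
    )
    if write_contours:
        write_contour_csv(result.contours.values, outdir / "contours.csv")
    return outdir


def plot_result(result: AnalysisResult, path: str | Path) -> None:
    """Diagnostic four-panel plot of the vibration traces (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(result.traces.n_frames) * result.params.dt_ms
    ph_um = result.calibration.pixel_height_um
    pw_mm = result.calibration.pixel_width_mm
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    panels = [
        ("peak vibration", result.traces.peak_vib * ph_um, "um"),
        ("quarter vibration", result.traces.quarter_vib * ph_um, "um"),
        ("max deformation position", (result.traces.n_d + 1) * pw_mm, "mm"),
        ("cutoff vibration", result.traces.cutoff_vib * pw_mm, "mm"),
    ]
    for ax, (title, y, unit) in zip(axes.ravel(), panels):
        ax.plot(t, y, lw=1)
        for tms in (result.ap.t1_ms, result.ap.t2_ms):
            ax.axvline(tms, color="r", ls="--", lw=0.8)
        ax.set_title(title)
        ax.set_ylabel(unit)
        ax.set_xlabel("t [ms]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
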