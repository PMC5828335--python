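"""Image-sequence and contour I/O plus physical calibration.

A Corvis-style acquisition is a stack of grayscale cross-sectional frames,
nominally 200x576 px covering 3.3 x 9.05 mm, recorded every 0.23 ms.  The
loader accepts a directory of single-frame images (lexicographic order) or a
video file; frames are converted to 8-bit luminance.  Row-axis (vertical)
quantities are reported in micrometres, column-axis (lateral) quantities in
millimetres.

Conventions
-----------
* Frame index ``i`` is 1-based in every user-facing report and file
  (``t = (i - 1) * dt``); in-memory arrays are 0-based.
* Image rows count downward from the top of the frame; the corneal apex has
  a *small* row coordinate and an indentation *increases* the row value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    InvalidCalibrationError,
    NoFramesError,
    ShapeMismatchError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .vibrations import VibrationTraces

_IMAGE_SUFFIXES = (".jpg", ".jpeg", ".png", ".tif", ".tiff", ".bmp")
_VIDEO_SUFFIXES = (".avi", ".mp4", ".mov", ".mkv")

#: Column order of the per-frame trace table (contract shared with the CLI).
TRACE_COLUMNS = [
    "i", "t_ms",
    "m_kl", "n_kl", "m_kr", "n_kr",
    "n_d", "n_fl", "n_fr", "m_fl", "m_fr", "n_bl", "n_br",
    "peak_vib_px", "peak_vib_um",
    "quarter_vib_px", "quarter_vib_um",
    "maxdef_vib_mm", "cutoff_vib_mm",
    "delta_px", "lambda_rad", "beta_rad",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of the imaging field.

    Parameters
    ----------
    rows, cols
        Frame size in pixels.
    field_height_mm, field_width_mm
        Physical extent spanned by the rows / columns.  Defaults follow the
        nominal Corvis geometry (3.3 x 9.05 mm for 200 x 576 px, i.e. a
        16.5 x 15.7 um pixel).
    """

    rows: int
    cols: int
    field_height_mm: float = 3.3
    field_width_mm: float = 9.05

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise InvalidCalibrationError("invalid calibration: rows/cols must be positive")
        if self.field_height_mm <= 0 or self.field_width_mm <= 0:
            raise InvalidCalibrationError("invalid calibration: field size must be positive")

    @property
    def pixel_height_um(self) -> float:
        """um spanned by one row step (exact quotient, no rounding)."""
        return self.field_height_mm / self.rows * 1000.0

    @property
    def pixel_width_um(self) -> float:
        """um spanned by one column step."""
        return self.field_width_mm / self.cols * 1000.0

    @property
    def pixel_width_mm(self) -> float:
        return self.field_width_mm / self.cols


def pixel_size(calibration: Calibration) -> tuple[float, float]:
    """Return ``(pixel_height_um, pixel_width_um)``.

    For the nominal geometry this is (16.5, 15.712...) um; the lateral value
    is conventionally quoted rounded to 15.7 um.
    """
    return calibration.pixel_height_um, calibration.pixel_width_um


def frame_time(i: int, dt_ms: float) -> float:
    """Acquisition time of 1-based frame ``i``: ``(i - 1) * dt_ms``."""
    if i < 1:
        raise ValueError(f"invalid index: frame index must be >= 1, got {i}")
    return (i - 1) * dt_ms


@dataclass
class ImageSequence:
    """Stack of grayscale frames with timing and pixel calibration.

    ``frames`` has shape ``(n_frames, M rows, N cols)`` with 8-bit
    intensities.  ``dt_ms`` is the inter-frame interval.
    """

    frames: np.ndarray
    dt_ms: float
    calibration: Calibration = field(repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeMismatchError("shape mismatch: frames must be a (F, M, N) stack")
        if self.frames.shape[1] < 20 or self.frames.shape[2] < 20:
            raise ShapeMismatchError("shape mismatch: frames must be at least 20x20")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if (self.calibration.rows, self.calibration.cols) != self.frames.shape[1:]:
            raise InvalidCalibrationError(
                "invalid calibration: does not match frame shape "
                f"{self.frames.shape[1:]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz (1000 / dt_ms); 0.23 ms -> 4347.8 Hz."""
        return 1000.0 / self.dt_ms

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def load_sequence(
    path: str | Path,
    dt_ms: float = 0.23,
    calibration: Calibration | None = None,
) -> ImageSequence:
    """Load a directory of frames (or a video file) as an :class:`ImageSequence`.

    Directory frames are taken in lexicographic filename order, which is the
    acquisition order for exports named with zero-padded indices.  Color
    inputs are converted to luminance.  When ``calibration`` is omitted the
    nominal 3.3 x 9.05 mm field is assumed.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise NoFramesError(f"no frames: no image files in {path}")
        imgs = [_to_gray(np.asarray(iio.imread(f))) for f in files]
    elif path.suffix.lower() in _VIDEO_SUFFIXES:
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # no video backend available
            raise NoFramesError(
                f"no frames: cannot decode video {path.name} "
                f"(no video plugin available: {exc})"
            ) from exc
        imgs = [_to_gray(np.asarray(f)) for f in np.asarray(raw)]
        if not imgs:
            raise NoFramesError(f"no frames: empty video {path}")
    elif path.exists():
        imgs = [_to_gray(np.asarray(iio.imread(path)))]
    else:
        raise NoFramesError(f"no frames: {path} does not exist")

    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"shape mismatch: frame shapes {sorted(shapes)}")
    frames = np.stack(imgs)
    if calibration is None:
        calibration = Calibration(rows=frames.shape[1], cols=frames.shape[2])
    return ImageSequence(frames=frames, dt_ms=dt_ms, calibration=calibration)


# ---------------------------------------------------------------------------
# contour matrices


def write_contour_csv(values: np.ndarray, path: str | Path) -> None:
    """Write a (columns x frames) contour matrix.

    Layout: one row per frame, header ``frame, col_1..col_N``; values are
    row coordinates in pixels.
    """
    values = np.asarray(values, dtype=float)
    n_cols, n_frames = values.shape
    df = pd.DataFrame(values.T, columns=[f"col_{n + 1}" for n in range(n_cols)])
    df.insert(0, "frame", np.arange(1, n_frames + 1))
    df.to_csv(path, index=False, float_format="%.10g")


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Read a contour CSV back to a (columns x frames) float matrix."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("col_")]
    if not cols:
        raise NoFramesError(f"no frames: {path} has no contour columns")
    return df[cols].to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# trace tables


def traces_to_frame(
    traces: "VibrationTraces", calibration: Calibration, dt_ms: float
) -> pd.DataFrame:
    """Per-frame trace table with 1-based frame/column indices and physical units."""
    ph_um = calibration.pixel_height_um
    pw_mm = calibration.pixel_width_mm
    F = traces.n_frames
    idx = np.arange(1, F + 1)

    def col1(a: np.ndarray) -> np.ndarray:  # 0-based column -> 1-based
        return a + 1

    df = pd.DataFrame(
        {
            "i": idx,
            "t_ms": (idx - 1) * dt_ms,
            "m_kl": traces.m_kl,
            "n_kl": col1(traces.n_kl),
            "m_kr": traces.m_kr,
            "n_kr": col1(traces.n_kr),
            "n_d": col1(traces.n_d),
            "n_fl": col1(traces.n_fl),
            "n_fr": col1(traces.n_fr),
            "m_fl": traces.m_fl,
            "m_fr": traces.m_fr,
            "n_bl": col1(traces.n_bl),
            "n_br": col1(traces.n_br),
            "peak_vib_px": traces.peak_vib,
            "peak_vib_um": traces.peak_vib * ph_um,
            "quarter_vib_px": traces.quarter_vib,
            "quarter_vib_um": traces.quarter_vib * ph_um,
            "maxdef_vib_mm": col1(traces.n_d) * pw_mm,
            "cutoff_vib_mm": traces.cutoff_vib * pw_mm,
            "delta_px": traces.delta,
            "lambda_rad": traces.lam,
            "beta_rad": traces.beta,
        }
    )
    return df[TRACE_COLUMNS]


def write_traces(
    traces: "VibrationTraces",
    calibration: Calibration,
    path: str | Path,
    dt_ms: float = 0.23,
    spectra: dict | None = None,
) -> Path:
    """Write the per-frame trace CSV (+ optional JSON sidecar of spectra).

    Frames outside the analysis interval carry empty cells.  Returns the CSV
    path; the sidecar (if any) is written next to it with suffix
    ``.spectra.json``.
    """
    path = Path(path)
    df = traces_to_frame(traces, calibration, dt_ms)
    df.to_csv(path, index=False, float_format="%.10g")
    if spectra is not None:
        sidecar = path.with_suffix(".spectra.json")
        sidecar.write_text(json.dumps(spectra, indent=2, sort_keys=True) + "\n")
    return path


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV written by :func:`write_traces`."""
    return pd.read_csv(path)
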