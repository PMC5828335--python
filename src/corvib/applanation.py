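"""Applanation detection.

The air puff flattens the cornea twice: on the way in (A_p1) and on the way
out (A_p2).  The vibration metrics are defined only between the two.  The
tonometer reports applanation times itself; when analysing raw sequences we
detect them from contour flatness:

``flatness(i)`` = RMS residual of a straight-line fit to the corrected
contour over a central window (default 3 mm).  The residual is large while
the cornea is curved (either way) and minimal at the flattening instants, so
A_p1 is the flatness minimum before the frame of maximal central deformation
and A_p2 the minimum after it.  Flatness is evaluated on the sub-cutoff band
plus the baseline shape, so >100 Hz vibrations cannot jitter the argmin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import DecomposedSignals
from .errors import NoDeformationEventError
from .io import Calibration


@dataclass
class ApplanationPair:
    """First/second applanation (frame-quantized).

    ``idx1``/``idx2`` are 0-based frame indices (internal convention);
    ``frame1``/``frame2`` and ``t1_ms``/``t2_ms`` are the 1-based user-facing
    values.
    """

    idx1: int
    idx2: int
    dt_ms: float
    flatness: np.ndarray
    peak_idx: int

    @property
    def frame1(self) -> int:
        return self.idx1 + 1

    @property
    def frame2(self) -> int:
        return self.idx2 + 1

    @property
    def t1_ms(self) -> float:
        return self.idx1 * self.dt_ms

    @property
    def t2_ms(self) -> float:
        return self.idx2 * self.dt_ms

    def interior(self) -> range:
        """0-based frames strictly between the applanations."""
        return range(self.idx1 + 1, self.idx2)


def _central_window(n_cols: int, calibration: Calibration, window_mm: float) -> slice:
    half = int(round(window_mm / 2.0 / calibration.pixel_width_mm))
    c = n_cols // 2
    return slice(max(0, c - half), min(n_cols, c + half + 1))


def flatness_metric(profiles: np.ndarray) -> np.ndarray:
    """RMS residual of a least-squares line fit, per frame.

    ``profiles``: (columns x frames).
    """
    n = profiles.shape[0]
    x = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, profiles, rcond=None)
    resid = profiles - X @ coef
    return np.sqrt(np.mean(resid**2, axis=0))


def detect_applanations(
    decomp: DecomposedSignals,
    calibration: Calibration,
    dt_ms: float,
    window_mm: float = 3.0,
    p_r: float = 2.0,
) -> ApplanationPair:
    """Locate A_p1 and A_p2 from contour flatness.

    Raises
    ------
    NoDeformationEventError
        If the deformation never exceeds ``p_r`` anywhere (static sequence).
    """
    if np.nanmax(np.abs(decomp.L_d)) < p_r:
        raise NoDeformationEventError(
            f"no deformation event: max |L_d| < p_r = {p_r}"
        )
    win = _central_window(decomp.L_d.shape[0], calibration, window_mm)
    smooth_contour = decomp.L_L[win, :] + decomp.baseline[win, None]
    flat = flatness_metric(smooth_contour)
    peak = int(np.argmax(decomp.L_L[win, :].max(axis=0)))
    if peak < 2 or peak > decomp.n_frames - 3:
        raise NoDeformationEventError(
            "no deformation event: indentation peak at the sequence edge"
        )
    idx1 = int(np.argmin(flat[:peak]))
    idx2 = peak + 1 + int(np.argmin(flat[peak + 1 :]))
    return ApplanationPair(
        idx1=idx1, idx2=idx2, dt_ms=dt_ms, flatness=flat, peak_idx=peak
    )


def applanations_from_times(
    t1_ms: float, t2_ms: float, dt_ms: float, n_frames: int
) -> ApplanationPair:
    """Build an :class:`ApplanationPair` from device-supplied times (override path)."""
    idx1 = int(round(t1_ms / dt_ms))
    idx2 = int(round(t2_ms / dt_ms))
    if not 0 < idx1 < idx2 < n_frames - 1:
        raise ValueError("applanation times out of order or outside the sequence")
    return ApplanationPair(
        idx1=idx1, idx2=idx2, dt_ms=dt_ms,
        flatness=np.full(n_frames, np.nan), peak_idx=(idx1 + idx2) // 2,
    )
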