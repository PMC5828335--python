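"""Decomposition of contour motion into eye reaction, deformation and bands.

The measured outer contour L_w(n, i) mixes three things: the resting corneal
shape, a rigid vertical displacement of the whole eye in reaction to the air
puff, and the actual corneal deformation.  The split is:

* ``L_q(i)`` — eyeball reaction: mean vertical displacement (relative to
  frame 1) of the outermost image columns on each side, which show sclera
  rather than deforming cornea (rigid-shift proxy);
* ``L_c(n, i) = L_w(n, i) - L_q(i)`` — contour corrected for eye motion;
* ``L_d(n, i) = L_c(n, i) - L_c(n, 1)`` — deformation relative to the
  baseline frame, in image-row orientation: an indentation *increases* L_d,
  the lateral peaks appear as *minima*;
* ``L_L`` / ``L_H`` — deformation below / above the 100 Hz cutoff.  The low
  band is a zero-net-phase (forward-backward) 4th-order Butterworth low-pass
  per column; the high band is defined as the exact residual
  ``L_H = L_d - L_L`` so the split conserves the signal identically.

The recordings are short (~140 samples, only ~6 cutoff periods), so filter
edge transients matter.  Reflection padding turns the tail of an oscillation
into a step (odd) or a kink (even) and smears spurious low-frequency energy
tens of samples into the window; each column is therefore extended by
autoregressive (Burg) extrapolation, which continues both the slow
deformation pulse and any sustained vibration across the window edges, and
the forward-backward filter runs on the extended signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .contour import ContourSeries
from .errors import InsufficientFramesError


@dataclass
class DecomposedSignals:
    """Components of contour motion (all arrays are columns x frames, px)."""

    L_d: np.ndarray
    L_q: np.ndarray  # per frame
    L_c: np.ndarray
    L_L: np.ndarray
    L_H: np.ndarray
    cutoff_hz: float
    fs_hz: float

    @property
    def baseline(self) -> np.ndarray:
        """Resting contour (frame 1 of the corrected series)."""
        return self.L_c[:, 0]

    @property
    def n_frames(self) -> int:
        return self.L_d.shape[1]


def separate_eye_reaction(
    contours: ContourSeries, edge_cols: int = 10
) -> np.ndarray:
    """Rigid vertical eye displacement per frame, from the scleral margins.

    Averages the row displacement (relative to frame 1) of the ``edge_cols``
    outermost *valid* columns on each side, then averages left and right.
    Columns that failed detection in any frame are skipped in favour of the
    nearest valid ones (with a warning).
    """
    N = contours.n_cols
    if not 1 <= edge_cols <= N // 4:
        raise ValueError(f"edge_cols must be in [1, {N // 4}]")
    vals = contours.values
    always_valid = contours.valid_mask.all(axis=1)
    order_left = np.arange(N)
    order_right = order_left[::-1]
    left = [n for n in order_left if always_valid[n]][:edge_cols]
    right = [n for n in order_right if always_valid[n]][:edge_cols]
    if len(left) < edge_cols or len(right) < edge_cols:
        # not enough detected columns anywhere: use interpolated edges
        left = list(range(edge_cols))
        right = list(range(N - edge_cols, N))
    if max(left) >= edge_cols or min(right) < N - edge_cols:
        warnings.warn(
            "invalid edge columns; falling back to nearest valid columns",
            stacklevel=2,
        )
    disp = vals - vals[:, :1]
    return 0.5 * (disp[left].mean(axis=0) + disp[right].mean(axis=0))


def compute_deformation(
    contours: ContourSeries, L_q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected contour and deformation: ``L_c = L_w - L_q``, ``L_d = L_c - L_c(:,1)``."""
    vals = contours.values
    if vals.shape[1] != np.asarray(L_q).shape[0]:
        raise ValueError("contours and L_q frame counts differ")
    L_c = vals - np.asarray(L_q)[None, :]
    L_d = L_c - L_c[:, :1]
    return L_d, L_c


def _burg_coeffs(x: np.ndarray, order: int) -> np.ndarray:
    """Burg AR coefficients ``a`` (prediction ``x[t] = -sum a[k] x[t-1-k]``...

    ...with ``a`` returned in ascending-lag order ``a[0]..a[order-1]``).
    The Burg recursion keeps all reflection coefficients in [-1, 1], so the
    fitted model is stable and the extrapolation bounded.
    """
    f = x.copy()
    b = x.copy()
    a = np.zeros(0)
    for m in range(order):
        ff = f[m + 1 :]
        bb = b[m:-1]
        den = ff @ ff + bb @ bb
        k = -2.0 * (ff @ bb) / den if den > 0 else 0.0
        a = np.concatenate([a, [0.0]])
        a = a + k * np.concatenate([a[:-1][::-1], [1.0]])
        f, b = ff + k * bb, bb + k * ff
    return a


def _ar_extrapolate(x: np.ndarray, npad: int, order: int) -> np.ndarray:
    """Forward AR extrapolation of ``x`` by ``npad`` samples."""
    a = _burg_coeffs(x, order)
    ext = np.concatenate([x, np.zeros(npad)])
    n = x.size
    rev = a[::-1]
    for t in range(n, n + npad):
        ext[t] = -(rev @ ext[t - order : t])
    return ext[n:]


def center_deformation(
    L_d: np.ndarray, margin_cols: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Remove residual rigid motion from the deformation signal.

    The scleral-edge estimate of L_q is itself uncertain by a fraction of a
    pixel, which leaves a small per-frame constant in L_d.  The median of
    the outermost ``margin_cols`` columns on each side (undeformed margins)
    estimates that constant; subtracting it makes every downstream vibration
    metric exactly independent of per-frame rigid offsets, because the
    estimator is equivariant: shifting a frame by ``c`` shifts the estimate
    by ``c``.

    Returns ``(L_d_centered, offset_per_frame)``.
    """
    L_d = np.asarray(L_d, dtype=float)
    N = L_d.shape[0]
    if margin_cols is None:
        margin_cols = max(1, N // 20)
    offset = np.median(
        np.concatenate([L_d[:margin_cols], L_d[-margin_cols:]], axis=0), axis=0
    )
    return L_d - offset[None, :], offset


def split_frequency(
    L_d: np.ndarray, fs_hz: float, cutoff_hz: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split deformation into sub- and super-cutoff bands.

    Zero net phase shift is required so that vibration timing is not skewed:
    the low-pass runs forward and backward.  Each column is first extended on
    both sides by Burg AR extrapolation (module docstring), which suppresses
    the edge transients reflection padding would leave on these short
    windows.  The high band is the exact complement ``L_H = L_d - L_L``.
    """
    L_d = np.atleast_2d(np.asarray(L_d, dtype=float))
    F = L_d.shape[1]
    if F < 8:
        raise InsufficientFramesError(f"insufficient frames: {F} < 8")
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    npad = min(4 * F, int(3 * fs_hz / cutoff_hz))
    order = min(24, F // 3)
    L_L = np.empty_like(L_d)
    for j in range(L_d.shape[0]):
        col = L_d[j]
        fwd = _ar_extrapolate(col, npad, order)
        bwd = _ar_extrapolate(col[::-1], npad, order)[::-1]
        ext = np.concatenate([bwd, col, fwd])
        L_L[j] = signal.sosfiltfilt(sos, ext, padlen=0)[npad : npad + F]
    return L_L, L_d - L_L


def decompose(
    contours: ContourSeries,
    fs_hz: float,
    cutoff_hz: float = 100.0,
    edge_cols: int = 10,
) -> DecomposedSignals:
    """Full decomposition of a contour series (Fig.-2-style split)."""
    L_q = separate_eye_reaction(contours, edge_cols=edge_cols)
    L_d, L_c = compute_deformation(contours, L_q)
    L_d, offset = center_deformation(L_d)
    L_q = L_q + offset  # residual rigid motion belongs to the eye reaction
    L_c = L_c - offset[None, :]
    L_L, L_H = split_frequency(L_d, fs_hz, cutoff_hz)
    return DecomposedSignals(
        L_d=L_d, L_q=L_q, L_c=L_c, L_L=L_L, L_H=L_H,
        cutoff_hz=cutoff_hz, fs_hz=fs_hz,
    )
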