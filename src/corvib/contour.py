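"""Outer corneal contour extraction.

Each cross-sectional frame shows the cornea as a bright band on a dark,
unevenly lit background, contaminated by isolated bright pixels.  The
detector scans column by column:

1. the frame is lightly Gaussian-smoothed;
2. each column is binarized at an adaptive threshold — a fraction of that
   column's own dynamic range, which makes the result insensitive to smooth
   illumination gain;
3. only pixels belonging to the largest 8-connected bright component (the
   cornea) are kept, which removes speckle and smaller spurious blobs;
4. the outer (topmost) edge row of the component is refined to sub-pixel
   precision by linearly interpolating the half-amplitude crossing of the
   smoothed column profile.

Plain global thresholding (including Otsu) fails on these images because of
the illumination gradient; an Otsu mode is nevertheless kept as a fallback
for clean synthetic frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ContourUnreliableError, NoCorneaFoundError
from .io import ImageSequence

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass(frozen=True)
class ContourParams:
    """Detection settings.

    threshold_frac
        Adaptive per-column threshold as a fraction of the column's dynamic
        range (default 0.3).
    smooth_sigma
        Gaussian pre-smoothing along rows, in pixels.
    lateral_sigma
        Pre-smoothing across columns; kept smaller than ``smooth_sigma`` so
        that sloped contour segments are not displaced laterally.
    min_contrast
        Minimum column dynamic range (intensity units) for a column to be
        considered at all.
    min_object_px
        Bright components smaller than this are treated as noise.
    median_width
        Width of the optional per-frame median filter across columns
        (0 disables); suppresses single-column outliers.
    max_invalid_frac
        Maximum tolerated fraction of failed columns per frame.
    method
        ``"adaptive"`` (default) or ``"otsu"`` (global threshold fallback for
        clean, evenly lit frames).
    """

    threshold_frac: float = 0.3
    smooth_sigma: float = 1.0
    lateral_sigma: float = 0.5
    min_contrast: float = 30.0
    min_object_px: int = 20
    median_width: int = 3
    max_invalid_frac: float = 0.2
    method: str = "adaptive"


@dataclass
class ContourSeries:
    """Outer contour L_w(n, i): row coordinate per column per frame.

    ``values`` has shape (N columns, n_frames); fractional rows allowed.
    ``valid_mask`` marks columns where detection succeeded before gap
    interpolation.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _largest_component(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Largest 8-connected True component; ties broken to the upper one."""
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = int(np.max(sizes))
    if best < min_size:
        return np.zeros_like(mask)
    cand = np.flatnonzero(sizes == best) + 1
    if len(cand) > 1:
        # equal sizes: keep the component with the smaller mean row
        rows = ndimage.center_of_mass(mask, labels, index=cand)
        cand = [cand[int(np.argmin([r for r, _ in rows]))]]
    return labels == cand[0]


def detect_outer_contour(
    frame: np.ndarray, params: ContourParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect the outer corneal edge in one frame.

    Returns ``(contour, valid)``: per-column sub-pixel row coordinates (NaN
    where detection failed) and the validity mask.

    Raises
    ------
    NoCorneaFoundError
        If no column yields a candidate (e.g. an all-black frame).
    """
    if params is None:
        params = ContourParams()
    frame = np.asarray(frame, dtype=float)
    M, N = frame.shape
    img = (
        ndimage.gaussian_filter(
            frame, (params.smooth_sigma, params.lateral_sigma), mode="nearest"
        )
        if params.smooth_sigma > 0
        else frame
    )

    cmin = img.min(axis=0)
    cmax = img.max(axis=0)
    rng = cmax - cmin
    contrast_ok = rng > params.min_contrast

    if params.method == "otsu":
        from skimage.filters import threshold_otsu

        thr = np.full(N, threshold_otsu(img))
    else:
        thr = cmin + params.threshold_frac * rng
    mask = (img >= thr[None, :]) & contrast_ok[None, :]

    comp = _largest_component(mask, params.min_object_px)
    has = comp.any(axis=0)
    valid = has & contrast_ok
    if not valid.any():
        raise NoCorneaFoundError("no cornea found")

    top = np.argmax(comp, axis=0)  # first True row per column (0 where none)

    # Sub-pixel: half-amplitude crossing of the smoothed profile near `top`.
    # The local plateau (inside the band) and background are estimated from
    # short row windows around the detected edge.
    offs = np.arange(-5, 4)
    rows = np.clip(top[None, :] + offs[:, None], 0, M - 1)
    win = img[rows, np.arange(N)[None, :]]  # (len(offs), N)
    plateau = img[
        np.clip(top[None, :] + np.arange(1, 8)[:, None], 0, M - 1),
        np.arange(N)[None, :],
    ].max(axis=0)
    level = cmin + 0.5 * (plateau - cmin)

    below = win <= level[None, :]
    rises = below[:-1] & ~below[1:]  # crossing between offs[k] and offs[k+1]
    any_rise = rises.any(axis=0)
    # last rising crossing per column = the one adjacent to the band edge
    k = rises.shape[0] - 1 - np.argmax(rises[::-1], axis=0)
    cols = np.arange(N)
    lo = win[k, cols]
    hi = win[k + 1, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(hi > lo, (level - lo) / (hi - lo), 0.0)
    contour = np.where(any_rise, top + offs[k] + frac, top.astype(float))
    # samples live at pixel centers: a row sample is the average over
    # [m, m+1), so the interpolated crossing sits half a pixel above the
    # physical edge position
    contour = np.clip(contour + 0.5, 0, M - 1)
    contour[~valid] = np.nan
    return contour, valid


def _fill_gaps(contour: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid columns (edge-extended)."""
    if valid.all():
        return contour
    cols = np.arange(contour.size)
    out = contour.copy()
    out[~valid] = np.interp(cols[~valid], cols[valid], contour[valid])
    return out


def detect_contour_sequence(
    seq: ImageSequence, params: ContourParams | None = None
) -> ContourSeries:
    """Detect the outer contour in every frame of a sequence.

    Gaps are interpolated linearly across columns; a width-3 median filter
    (configurable) suppresses single-column outliers.

    Raises
    ------
    ContourUnreliableError
        If any frame has more than ``max_invalid_frac`` failed columns; the
        message names the (1-based) frame.
    """
    if params is None:
        params = ContourParams()
    F = seq.n_frames
    N = seq.shape[1]
    values = np.empty((N, F))
    valid = np.empty((N, F), dtype=bool)
    for i in range(F):
        contour, v = detect_outer_contour(seq.frames[i], params)
        if (~v).mean() > params.max_invalid_frac:
            raise ContourUnreliableError(
                f"contour unreliable in frame {i + 1}: "
                f"{(~v).sum()}/{N} columns failed"
            )
        contour = _fill_gaps(contour, v)
        if params.median_width and params.median_width > 1:
            contour = ndimage.median_filter(
                contour, size=params.median_width, mode="nearest"
            )
        values[:, i] = contour
        valid[:, i] = v
    return ContourSeries(values=values, valid_mask=valid)


def clean_params() -> ContourParams:
    """Settings suited to clean synthetic renders (no speckle filtering needed)."""
    return replace(ContourParams(), min_contrast=10.0)
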