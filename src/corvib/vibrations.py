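"""The four corneal vibration metrics, the error bound and the angles.

All quantities are evaluated frame by frame, strictly between the two
applanations, on the deformation signal in image-row orientation (an
indentation increases L_d; the lateral peaks are *minima* of L_d):

* **peak vibration** ``|m_kl - m_kr|`` — difference of the topmost contour
  points in the left and right image halves (``m_kl = min L_d`` over columns
  1..N/2, mirrored on the right).  Being a left-right difference it is
  independent of rigid eye motion.
* **quarter vibration** ``|m_fl - m_fr|`` — the >cutoff band L_H sampled at
  the two quarter columns ``n_fl``/``n_fr`` halfway between each peak and
  the maximum-deformation column.
* **maximum-deformation vibration** ``n_d(i)`` — lateral wander of the
  deepest-indentation column.  ``n_d`` is bootstrapped from the global
  argmax of the low band L_L and refined once by the restricted argmax of
  L_d over (n_fl, n_fr) (the definition is circular; one fixed-point
  iteration resolves it deterministically).
* **cutoff vibration** ``|n_bl - n_br|`` — motion of the junction columns
  where the deformed contour departs from the resting one by more than the
  binarization threshold ``p_r`` (2 px by default).

The per-frame error bound is ``delta = 1 / (number of columns with
L_d > p_r)``, saturating at 1 px when no column exceeds the threshold.
The instantaneous quarter-segment orientation is
``lambda = atan2(m_fl - m_fr, n_fl - n_fr)`` (pixel units on both axes) and
``beta`` its running sum over the analysis interval.

Ties in every argmin/argmax are broken to the leftmost column; for odd N the
middle column belongs to the left half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .applanation import ApplanationPair
from .decompose import DecomposedSignals


@dataclass
class VibrationTraces:
    """Per-frame traces (NaN outside the analysis interval).

    Column indices (``n_*``) are stored 0-based as floats; the I/O layer
    reports them 1-based.
    """

    m_kl: np.ndarray
    n_kl: np.ndarray
    m_kr: np.ndarray
    n_kr: np.ndarray
    n_d: np.ndarray
    n_fl: np.ndarray
    n_fr: np.ndarray
    m_fl: np.ndarray
    m_fr: np.ndarray
    n_bl: np.ndarray
    n_br: np.ndarray
    delta: np.ndarray
    lam: np.ndarray
    beta: np.ndarray
    ap: ApplanationPair = field(repr=False)

    @property
    def n_frames(self) -> int:
        return self.m_kl.shape[0]

    @property
    def peak_vib(self) -> np.ndarray:
        """|m_kl - m_kr| per frame, px."""
        return np.abs(self.m_kl - self.m_kr)

    @property
    def quarter_vib(self) -> np.ndarray:
        """|m_fl - m_fr| per frame, px."""
        return np.abs(self.m_fl - self.m_fr)

    @property
    def cutoff_vib(self) -> np.ndarray:
        """|n_bl - n_br| per frame, columns."""
        return np.abs(self.n_bl - self.n_br)


# ---------------------------------------------------------------------------
# elementary operations


def peak_positions(l_d: np.ndarray) -> tuple[float, int, float, int]:
    """Topmost contour points of the two halves of one frame.

    Returns ``(m_kl, n_kl, m_kr, n_kr)``: the minima of L_d over columns
    0..N//2-1 and N//2..N-1 (0-based) with their leftmost argmin columns.
    A flat half returns its central column.
    """
    l_d = np.asarray(l_d, dtype=float)
    N = l_d.size
    half = (N + 1) // 2  # odd N: middle column belongs to the left half
    left, right = l_d[:half], l_d[half:]
    if np.ptp(left) == 0:
        n_kl = half // 2
    else:
        n_kl = int(np.argmin(left))
    if np.ptp(right) == 0:
        n_kr = half + (N - half) // 2
    else:
        n_kr = half + int(np.argmin(right))
    return float(l_d[n_kl]), n_kl, float(l_d[n_kr]), n_kr


def quarter_points(n_kl: int, n_kr: int, n_d: int) -> tuple[int, int]:
    """Quarter columns: floor midpoints between each peak and ``n_d``.

    Requires ``n_kl < n_d < n_kr``.  The floor midpoint is invariant under a
    common 0-/1-based shift of its endpoints, so reported 1-based values are
    consistent with the internal 0-based ones.
    """
    if not n_kl < n_d < n_kr:
        raise ValueError(f"ordering violated: need n_kl < n_d < n_kr, got "
                         f"{n_kl}, {n_d}, {n_kr}")
    return (n_kl + n_d) // 2, (n_kr + n_d) // 2


def max_deformation_position(
    l_d: np.ndarray, l_L: np.ndarray, n_kl: int, n_kr: int
) -> int:
    """Column of maximal deformation for one frame.

    Bootstraps from the global argmax of the low band ``l_L`` (deepest
    indentation, robust to >cutoff noise), derives the quarter columns, then
    re-evaluates the argmax of ``l_d`` restricted to [n_fl, n_fr]; one
    refinement iteration.  Leftmost tie-break throughout.
    """
    l_d = np.asarray(l_d, dtype=float)
    l_L = np.asarray(l_L, dtype=float)
    n_d = int(np.argmax(l_L))
    for _ in range(2):  # bootstrap evaluation + one refinement
        if not n_kl < n_d < n_kr:
            break
        n_fl, n_fr = quarter_points(n_kl, n_kr, n_d)
        seg = l_d[n_fl : n_fr + 1]
        n_d = n_fl + int(np.argmax(seg))
    return n_d


def quarter_vibration(
    L_H: np.ndarray, n_fl: int, n_fr: int, i: int
) -> tuple[float, float, float]:
    """High-band values at the quarter columns and their absolute difference."""
    m_fl = float(L_H[n_fl, i])
    m_fr = float(L_H[n_fr, i])
    return m_fl, m_fr, abs(m_fl - m_fr)


def cutoff_points(
    l_d: np.ndarray, p_r: float = 2.0, margin_cols: int = 0
) -> tuple[int, int]:
    """Junction columns where the contour departs from its resting position.

    ``n_bl`` is the last column (scanning left to center) before the first
    deviation ``|L_d| > p_r``; ``n_br`` the mirrored first sub-threshold
    column on the right.  With ``margin_cols > 0`` the deviation is
    referenced to the median of the outermost columns on each side ("the
    original position" as seen in the undeformed margins), which makes the
    junction columns exactly independent of any residual per-frame rigid
    offset.  Raises ``ValueError`` when the whole frame is sub-threshold or
    the deformed region touches an image edge.
    """
    l_d = np.asarray(l_d, dtype=float)
    ref = 0.0
    if margin_cols > 0:
        ref = float(np.median(np.r_[l_d[:margin_cols], l_d[-margin_cols:]]))
    dev = np.abs(l_d - ref)
    exceed = np.flatnonzero(dev > p_r)
    if exceed.size == 0:
        raise ValueError("whole frame sub-threshold")
    N = dev.size
    half = (N + 1) // 2
    n_bl = int(exceed[0]) - 1
    n_br = int(exceed[-1]) + 1
    if n_bl < 0 or n_br > N - 1:
        raise ValueError("deformation reaches the image edge")
    if n_bl >= half or n_br < half:
        raise ValueError("deformation confined to one image half")
    return n_bl, n_br


def measurement_error(l_d: np.ndarray, p_r: float = 2.0) -> float:
    """Per-frame error bound delta in px.

    The deformation map is binarized at ``p_r`` (strictly greater); delta is
    the reciprocal of the above-threshold column count, or 1 px when the
    count is zero (no deformation: the position estimate is only good to the
    +-1 px digitization).
    """
    if p_r <= 0:
        raise ValueError("p_r must be positive")
    count = int(np.sum(np.asarray(l_d, dtype=float) > p_r))
    return 1.0 / count if count else 1.0


def vibration_angle(m_fl: float, m_fr: float, n_fl: float, n_fr: float) -> float:
    """Orientation of the quarter-point segment, atan2(dm, dn) in (-pi, pi].

    Both arguments are in pixel units (mixed-axis angle); with identical
    points the angle is defined as 0.
    """
    dm = m_fl - m_fr
    dn = n_fl - n_fr
    if dm == 0 and dn == 0:
        return 0.0
    return math.atan2(dm, dn)


def cumulative_angle(lam: np.ndarray) -> np.ndarray:
    """Running sum of lambda over the analyzed frames.

    NaN (undefined) frames contribute 0 and stay NaN in the output.
    """
    lam = np.asarray(lam, dtype=float)
    filled = np.where(np.isfinite(lam), lam, 0.0)
    beta = np.cumsum(filled)
    beta[~np.isfinite(lam)] = np.nan
    return beta


def peak_quarter_correlation(
    peak_vib: np.ndarray, quarter_vib: np.ndarray
) -> float:
    """Pearson correlation of the peak and quarter traces over common frames."""
    a = np.asarray(peak_vib, dtype=float)
    b = np.asarray(quarter_vib, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("undefined correlation: fewer than 3 common frames")
    if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        raise ValueError("undefined correlation: constant trace")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


# ---------------------------------------------------------------------------
# per-sequence driver


def compute_vibration_traces(
    decomp: DecomposedSignals,
    ap: ApplanationPair,
    p_r: float = 2.0,
) -> VibrationTraces:
    """Evaluate every trace for the frames strictly between the applanations.

    Frames violating an ordering precondition (no indentation between the
    peaks, deformation sub-threshold, ...) are left as gaps (NaN) in the
    affected traces; ``delta`` is always defined.
    """
    F = decomp.n_frames
    nan = lambda: np.full(F, np.nan)
    tr = {k: nan() for k in (
        "m_kl", "n_kl", "m_kr", "n_kr", "n_d", "n_fl", "n_fr",
        "m_fl", "m_fr", "n_bl", "n_br", "delta", "lam",
    )}

    for i in ap.interior():
        ld = decomp.L_d[:, i]
        tr["delta"][i] = measurement_error(ld, p_r)

        m_kl, n_kl, m_kr, n_kr = peak_positions(ld)
        tr["m_kl"][i], tr["n_kl"][i] = m_kl, n_kl
        tr["m_kr"][i], tr["n_kr"][i] = m_kr, n_kr

        n_d = max_deformation_position(ld, decomp.L_L[:, i], n_kl, n_kr)
        if n_kl < n_d < n_kr and ld[n_d] > 0:
            tr["n_d"][i] = n_d
            n_fl, n_fr = quarter_points(n_kl, n_kr, n_d)
            tr["n_fl"][i], tr["n_fr"][i] = n_fl, n_fr
            m_fl, m_fr, _ = quarter_vibration(decomp.L_H, n_fl, n_fr, i)
            tr["m_fl"][i], tr["m_fr"][i] = m_fl, m_fr
            tr["lam"][i] = vibration_angle(m_fl, m_fr, n_fl, n_fr)

        try:
            n_bl, n_br = cutoff_points(ld, p_r, margin_cols=max(1, ld.size // 20))
        except ValueError:
            pass
        else:
            tr["n_bl"][i], tr["n_br"][i] = n_bl, n_br

    beta = cumulative_angle(tr["lam"])
    return VibrationTraces(ap=ap, beta=beta, **tr)
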