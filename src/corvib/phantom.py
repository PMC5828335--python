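"""Ground-truthed synthetic air-puff deformation sequences.

The phantom emulates the acquisition geometry of a Scheimpflug air-puff
recording (200 x 576 px over 3.3 x 9.05 mm, 140 frames every 0.23 ms) with a
fully parameterized, analytically known contour:

``contour(n, i) = baseline(n) + eye_reaction(i) + indentation(n, i) + vibrations(n, i)``

* *baseline* — circular arc (apex up) with a physiological radius;
* *indentation* — central Gaussian dent with optional lateral peak lobes
  (the "W" morphology of a deformed cornea), a raised-cosine depth pulse in
  time, optional lateral drift of the dent center, and a compact support
  window so the deformation has known end columns;
* *eye reaction* — rigid vertical shift with a slow monotone ramp;
* *vibrations* — localized sinusoids (>100 Hz) riding on the peaks, the
  quarter points or the whole contour, gated so they are active only while
  the cornea is substantially deformed.

Rendering draws an anti-aliased bright band of configurable thickness below
the contour, then applies a smooth illumination gain field, Gaussian blur,
additive noise and isolated bright-pixel speckle, quantized to 8 bit.  All
randomness comes from one seed; the same seed reproduces the byte-identical
sequence.

Every injected quantity (contour, eye shift, applanation frames, dent-center
trajectory, per-vibration traces, deformation support) is stored in
:class:`PhantomTruth`, so the entire measurement pipeline can be validated
without clinical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import Calibration, ImageSequence, write_contour_csv


@dataclass(frozen=True)
class VibrationSpec:
    """One injected vibration.

    ``location`` is one of ``peak_left``, ``peak_right``, ``quarter_left``,
    ``quarter_right``, ``whole_contour``; locations track the (possibly
    drifting) dent center.  Amplitude is in px (row axis), ``sigma_px`` the
    lateral Gaussian footprint.
    """

    location: str
    frequency_hz: float
    amplitude_px: float
    phase_rad: float = 0.0
    sigma_px: float = 12.0


_LOCATIONS = ("peak_left", "peak_right", "quarter_left", "quarter_right", "whole_contour")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic sequence (geometry, motion, render).

    Spatial parameters are physical (mm) where the measurement reports
    physical units; the defaults reproduce a realistic single-puff recording
    of a healthy eye.
    """

    rows: int = 200
    cols: int = 576
    n_frames: int = 140
    dt_ms: float = 0.23
    field_height_mm: float = 3.3
    field_width_mm: float = 9.05

    # baseline arc
    apex_row: float = 60.0
    radius_mm: float = 7.8

    # indentation
    center_col: float = 285.0
    drift_mm: float = 0.0
    sigma_mm: float = 1.1
    depth_mm: float = 0.6
    pulse_start: int = 25
    pulse_end: int = 115
    peak_offset_mm: float = 1.73
    peak_ratio: float = 0.6
    peak_sigma_mm: float = 0.47
    support_cols: tuple[int, int] = (120, 456)
    support_ramp_px: float = 20.0

    # eye reaction
    eye_reaction_px: float = 6.0
    eye_start: int = 40
    eye_rise: int = 70

    # vibrations
    vibrations: tuple[VibrationSpec, ...] = ()
    vib_gate: tuple[float, float] = (0.3, 0.45)  # depth fractions on/full

    # rendering
    band_px: float = 35.0
    blur_sigma: float = 0.8
    noise_sd: float = 4.0
    speckle_count: int = 40
    gain_range: tuple[float, float] = (0.7, 1.0)
    seed: int = 17

    def __post_init__(self) -> None:
        fs = 1000.0 / self.dt_ms
        for v in self.vibrations:
            if v.location not in _LOCATIONS:
                raise ValueError(f"inconsistent spec: unknown location {v.location!r}")
            if v.frequency_hz >= fs / 2:
                raise ValueError("inconsistent spec: vibration above Nyquist")
            if v.amplitude_px >= self.band_px:
                raise ValueError("inconsistent spec: amplitude exceeds band thickness")
            if v.location != "whole_contour" and self.depth_mm <= 0:
                raise ValueError(
                    "inconsistent spec: localized vibration without indentation"
                )

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            rows=self.rows, cols=self.cols,
            field_height_mm=self.field_height_mm,
            field_width_mm=self.field_width_mm,
        )

    def mm_to_cols(self, mm: float) -> float:
        return mm / self.calibration.pixel_width_mm

    def mm_to_rows(self, mm: float) -> float:
        return mm * 1000.0 / self.calibration.pixel_height_um

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vibrations"] = [dataclasses.asdict(v) for v in self.vibrations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        vibs = tuple(VibrationSpec(**v) for v in d.pop("vibrations", ()))
        for key in ("support_cols", "vib_gate", "gain_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(vibrations=vibs, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class PhantomTruth:
    """Everything the generator knows about a synthesized sequence."""

    spec: PhantomSpec = field(repr=False)
    contour: np.ndarray  # (cols x frames) including vibrations
    contour_novib: np.ndarray  # baseline + eye + indentation only
    eye_reaction: np.ndarray  # per frame, px
    depth_px: np.ndarray  # dent depth trajectory, px
    center_trace: np.ndarray  # dent center column per frame (float)
    n_d_trace: np.ndarray  # argmax column of the indentation per frame
    applanation_frames: tuple[int, int]  # 0-based
    support: tuple[int, int]  # columns outside which deformation is 0
    vibration_traces: list[np.ndarray]  # a*sin(...)*gate per injected vibration

    @property
    def calibration(self) -> Calibration:
        return self.spec.calibration


def _support_window(spec: PhantomSpec, n: np.ndarray) -> np.ndarray:
    s0, s1 = spec.support_cols
    ramp = spec.support_ramp_px
    w = np.zeros_like(n, dtype=float)
    inside = (n > s0) & (n < s1)
    w[inside] = 1.0
    if ramp > 0:
        up = inside & (n <= s0 + ramp)
        w[up] = 0.5 * (1 - np.cos(np.pi * (n[up] - s0) / ramp))
        dn = inside & (n >= s1 - ramp)
        w[dn] = np.minimum(w[dn], 0.5 * (1 - np.cos(np.pi * (s1 - n[dn]) / ramp)))
    return w


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def synthesize_contour(spec: PhantomSpec) -> PhantomTruth:
    """Build the analytic contour and all ground-truth traces."""
    N, F = spec.cols, spec.n_frames
    n = np.arange(N, dtype=float)
    i = np.arange(F, dtype=float)
    t_ms = i * spec.dt_ms
    cal = spec.calibration

    # baseline circular arc, apex up (small rows at the center)
    R = spec.mm_to_cols(spec.radius_mm)  # radius in column units
    dx = n - (N - 1) / 2.0
    sag_cols = R - np.sqrt(np.maximum(R**2 - dx**2, 0.0))
    # convert sagitta from column units to row units (anisotropic pixels)
    sag_rows = sag_cols * cal.pixel_width_um / cal.pixel_height_um
    baseline = spec.apex_row + sag_rows

    # depth pulse (raised cosine) and drifting center
    depth_px = np.zeros(F)
    p0, p1 = spec.pulse_start, spec.pulse_end
    depth_peak = spec.mm_to_rows(spec.depth_mm)
    if p1 > p0 and depth_peak > 0:
        ph = np.clip((i - p0) / (p1 - p0), 0.0, 1.0)
        depth_px = depth_peak * 0.5 * (1 - np.cos(2 * np.pi * ph))
        depth_px[(i <= p0) | (i >= p1)] = 0.0
    drift_cols = spec.mm_to_cols(spec.drift_mm)
    center = spec.center_col + drift_cols * np.clip(
        (i - p0) / max(p1 - p0, 1), 0.0, 1.0
    )

    # spatial indentation profile per frame
    sig_c = spec.mm_to_cols(spec.sigma_mm)
    sig_p = spec.mm_to_cols(spec.peak_sigma_mm)
    d_off = spec.mm_to_cols(spec.peak_offset_mm)
    W = _support_window(spec, n)
    dn = n[:, None] - center[None, :]  # (N, F)
    shape = np.exp(-(dn**2) / (2 * sig_c**2))
    if spec.peak_ratio > 0:
        shape = shape - spec.peak_ratio * (
            np.exp(-((dn - d_off) ** 2) / (2 * sig_p**2))
            + np.exp(-((dn + d_off) ** 2) / (2 * sig_p**2))
        )
    indent = depth_px[None, :] * shape * W[:, None]

    # eye reaction: slow monotone raised-cosine ramp (rigid shift)
    ramp = np.clip((i - spec.eye_start) / max(spec.eye_rise, 1), 0.0, 1.0)
    eye = spec.eye_reaction_px * 0.5 * (1 - np.cos(np.pi * ramp))

    # vibration gate from the depth trajectory
    lo, hi = spec.vib_gate
    gate = (
        _smoothstep((depth_px / depth_peak - lo) / max(hi - lo, 1e-9))
        if depth_peak > 0
        else np.zeros(F)
    )

    vib_total = np.zeros((N, F))
    vib_traces: list[np.ndarray] = []
    offsets = {
        "peak_left": -d_off,
        "peak_right": +d_off,
        "quarter_left": -d_off / 2.0,
        "quarter_right": +d_off / 2.0,
    }
    for v in spec.vibrations:
        osc = v.amplitude_px * np.sin(
            2 * np.pi * v.frequency_hz * t_ms / 1000.0 + v.phase_rad
        ) * gate
        vib_traces.append(osc)
        if v.location == "whole_contour":
            spatial = W[:, None]
        else:
            loc = center + offsets[v.location]
            spatial = np.exp(
                -((n[:, None] - loc[None, :]) ** 2) / (2 * v.sigma_px**2)
            ) * W[:, None]
        vib_total += osc[None, :] * spatial

    contour_novib = baseline[:, None] + eye[None, :] + indent
    contour = contour_novib + vib_total

    # truth n_d: argmax column of the (vibration-free) indentation
    n_d_trace = np.argmax(indent, axis=0).astype(float)
    n_d_trace[depth_px <= 0] = np.nan

    # applanation truth: zero crossings of the central quadratic curvature
    # of baseline + indentation (eye shift is rigid and irrelevant)
    win = slice(N // 2 - 80, N // 2 + 81)
    x = np.arange(win.stop - win.start, dtype=float)
    Xd = np.column_stack([np.ones_like(x), x, x**2])
    coef, *_ = np.linalg.lstsq(Xd, baseline[win, None] + indent[win, :], rcond=None)
    curv = coef[2]
    peak = int(np.argmax(depth_px)) if depth_peak > 0 else F // 2
    a1 = a2 = -1
    sign = np.sign(curv)
    for k in range(1, peak + 1):
        if sign[k] <= 0 <= sign[k - 1]:
            a1 = k if abs(curv[k]) < abs(curv[k - 1]) else k - 1
            break
    for k in range(F - 1, peak, -1):
        if sign[k - 1] <= 0 <= sign[k]:
            a2 = k - 1 if abs(curv[k - 1]) < abs(curv[k]) else k
            break

    return PhantomTruth(
        spec=spec,
        contour=contour,
        contour_novib=contour_novib,
        eye_reaction=eye,
        depth_px=depth_px,
        center_trace=center,
        n_d_trace=n_d_trace,
        applanation_frames=(a1, a2),
        support=spec.support_cols,
        vibration_traces=vib_traces,
    )


def _gain_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth deterministic illumination gain in ``gain_range``."""
    lo, hi = spec.gain_range
    m = np.arange(spec.rows)[:, None] / spec.rows
    n = np.arange(spec.cols)[None, :] / spec.cols
    f = 0.5 + 0.5 * np.cos(2 * np.pi * (0.55 * n + 0.25 * m - 0.35))
    return lo + (hi - lo) * f


def render_sequence(truth: PhantomTruth, spec: PhantomSpec | None = None) -> ImageSequence:
    """Render frames from a truth contour (deterministic under the spec seed)."""
    if spec is None:
        spec = truth.spec
    M, N, F = spec.rows, spec.cols, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    gain = _gain_field(spec)
    rows = np.arange(M, dtype=float)[:, None]
    frames = np.empty((F, M, N), dtype=np.uint8)
    for k in range(F):
        y = truth.contour[:, k][None, :]
        cov = np.clip(np.minimum(rows + 1, y + spec.band_px) - np.maximum(rows, y), 0, 1)
        img = 255.0 * cov * gain
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        for _ in range(spec.speckle_count):
            # isolated bright pixels, kept clear of the corneal band
            for _try in range(20):
                r = int(rng.integers(0, M))
                c = int(rng.integers(0, N))
                yc = truth.contour[c, k]
                if r < yc - 4 or r > yc + spec.band_px + 4:
                    img[r, c] = float(rng.uniform(180, 255))
                    break
        frames[k] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageSequence(frames=frames, dt_ms=spec.dt_ms, calibration=spec.calibration)


def write_phantom(
    truth: PhantomTruth, seq: ImageSequence, outdir: str | Path
) -> Path:
    """Write frames (PNG), truth.json and contour_truth.csv to ``outdir``."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k in range(seq.n_frames):
        iio.imwrite(outdir / f"frame_{k + 1:04d}.png", seq.frames[k])
    write_contour_csv(truth.contour, outdir / "contour_truth.csv")
    payload = {
        "spec": truth.spec.to_dict(),
        "applanation_frames_1based": [f + 1 for f in truth.applanation_frames],
        "support_cols": list(truth.support),
        "eye_reaction_px": truth.eye_reaction.tolist(),
        "depth_px": truth.depth_px.tolist(),
        "center_trace": truth.center_trace.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# canonical study specs


def default_spec(**overrides) -> PhantomSpec:
    """Baseline deformation phantom without injected vibrations."""
    return replace(PhantomSpec(), **overrides)


def _quarter_pair(freq: float = 400.0, amp: float = 2.0) -> tuple[VibrationSpec, ...]:
    return (
        VibrationSpec("quarter_left", freq, amp, 0.0),
        VibrationSpec("quarter_right", freq, amp, np.pi),
    )


def _peak_pair(freq: float = 350.0, amp: float = 3.0) -> tuple[VibrationSpec, ...]:
    # a peak vibration moves the whole peak lobe: its lateral footprint
    # matches the lobe width
    lobe_sigma = PhantomSpec().mm_to_cols(PhantomSpec().peak_sigma_mm)
    return (
        VibrationSpec("peak_left", freq, amp, 0.0, sigma_px=lobe_sigma),
        VibrationSpec("peak_right", freq, amp, np.pi, sigma_px=lobe_sigma),
    )


def quarter_vibration_spec(**overrides) -> PhantomSpec:
    """Antiphase 400 Hz / 2 px vibrations at the two quarter columns."""
    return replace(PhantomSpec(), vibrations=_quarter_pair(), **overrides)


def peak_vibration_spec(**overrides) -> PhantomSpec:
    """Antiphase 350 Hz / 3 px vibrations riding on the two lateral peaks."""
    return replace(PhantomSpec(), vibrations=_peak_pair(), **overrides)


def vibration_recovery_spec(**overrides) -> PhantomSpec:
    """Quarter (400 Hz / 2 px) and peak (350 Hz / 3 px) vibrations together.

    With both types present their spectra overlap spatially (the broad peak
    lobes reach the quarter columns), as in real recordings; for clean
    single-type recovery use :func:`quarter_vibration_spec` or
    :func:`peak_vibration_spec`.
    """
    vibs = _quarter_pair() + _peak_pair()
    return replace(PhantomSpec(), vibrations=vibs, **overrides)


def drift_spec(**overrides) -> PhantomSpec:
    """Compact single dent drifting 0.3 mm, for n_d / cutoff-point recovery.

    No lateral peak lobes; deformation strictly confined to columns
    (200, 370) with a steep 5 px ramp.
    """
    kw = dict(
        center_col=275.0,
        drift_mm=0.3,
        sigma_mm=0.71,
        depth_mm=0.74,
        peak_ratio=0.0,
        support_cols=(200, 370),
        support_ramp_px=5.0,
        noise_sd=2.0,
        speckle_count=0,
    )
    kw.update(overrides)
    return replace(PhantomSpec(), **kw)


def translation_spec(**overrides) -> PhantomSpec:
    """Rigid eye motion only (no indentation): exercises L_q separation."""
    kw = dict(depth_mm=0.0, eye_reaction_px=8.0, speckle_count=0)
    kw.update(overrides)
    return replace(PhantomSpec(), **kw)


def static_spec(**overrides) -> PhantomSpec:
    """No motion at all."""
    kw = dict(depth_mm=0.0, eye_reaction_px=0.0)
    kw.update(overrides)
    return replace(PhantomSpec(), **kw)


def end_to_end_recovery(spec: PhantomSpec, seed: int | None = None) -> dict:
    """Render -> detect -> decompose -> applanations -> vibrations -> spectra.

    Returns a report of injected vs. recovered quantities per vibration, the
    applanation comparison, the n_d tracking error and (when the deformation
    has compact support) the recovered cutoff columns.
    """
    from .pipeline import AnalysisParams, analyze_sequence

    if seed is not None:
        spec = replace(spec, seed=seed)
    truth = synthesize_contour(spec)
    seq = render_sequence(truth, spec)
    params = AnalysisParams(dt_ms=spec.dt_ms)
    res = analyze_sequence(seq, params)

    report: dict = {
        "applanations": {
            "truth_frames": [f + 1 for f in truth.applanation_frames],
            "detected_frames": [res.ap.frame1, res.ap.frame2],
        },
        "vibrations": [],
    }

    interior = np.array(list(res.ap.interior()))
    nd = res.traces.n_d[interior]
    ok = np.isfinite(nd)
    nd_err = np.abs(nd[ok] - truth.n_d_trace[interior][ok])
    report["n_d"] = {
        "max_abs_err_cols": float(nd_err.max()) if nd_err.size else None,
        "n_frames": int(ok.sum()),
    }

    peak_frame = int(np.argmax(truth.depth_px))
    if peak_frame in interior:
        n_bl = res.traces.n_bl[peak_frame]
        n_br = res.traces.n_br[peak_frame]
        report["cutoff"] = {
            "support_cols": list(truth.support),
            "recovered_at_peak": [
                float(n_bl) if np.isfinite(n_bl) else None,
                float(n_br) if np.isfinite(n_br) else None,
            ],
        }

    summaries = res.spectra
    by_type = {"quarter": ("quarter_left", "quarter_right"),
               "peak": ("peak_left", "peak_right")}
    for vtype, locs in by_type.items():
        injected = [v for v in spec.vibrations if v.location in locs]
        if not injected:
            continue
        entry = summaries[vtype]
        trace = (res.traces.quarter_vib if vtype == "quarter" else res.traces.peak_vib)
        finite = trace[np.isfinite(trace)]
        report["vibrations"].append(
            {
                "type": vtype,
                "injected_hz": injected[0].frequency_hz,
                "injected_amplitude_px": injected[0].amplitude_px,
                "recovered_hz": entry["fundamental_hz"],
                "resolution_hz": entry["resolution_hz"],
                "recovered_p2p_px": float(np.max(finite) - np.min(finite))
                if finite.size
                else None,
            }
        )
    return report
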