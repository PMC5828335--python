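# Methods

This note records what `corvib` computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open.

## Acquisition model and conventions

The input is a stack of grayscale cross-sections of the cornea during an
air-puff intraocular-pressure measurement: nominally 140 frames of
200 × 576 px spanning 3.3 × 9.05 mm (16.5 µm per row, 15.7 µm per column),
sampled every 0.23 ms (4347.8 Hz).  Frame index `i` is 1-based in every
user-facing report (`t = (i − 1)·dt`); arrays are 0-based internally.
Image rows count downward from the top: the corneal apex has a small row
coordinate, an indentation increases the row value, and the lateral peaks
of the deformed cornea appear as *minima* of the deformation signal.  Row-
axis (vertical, Y) quantities are reported in µm, column-axis (lateral, X)
quantities in mm, matching the anisotropic pixel.

## Outer contour detection

The cornea is a bright band on a dark, unevenly lit background with
isolated bright-pixel speckle.  Global thresholds (including Otsu's) fail
under the illumination gradient, so the detector works column-wise:

1. Gaussian pre-smoothing, σ = 1.0 px along rows and 0.5 px across columns.
   The lateral σ is deliberately the smaller: isotropic smoothing displaces
   sloped contour segments laterally (up to ~0.25 px at the flank slopes of
   a deformed cornea), whereas row-dominant smoothing does not.
2. Per-column binarization at `column min + 0.3 × column dynamic range`.
   Because the threshold is relative to each column's own range, a smooth
   multiplicative gain field cancels almost exactly (measured: ≤ 0.5 px
   contour shift under a 0.6–1.0 gain).  Columns with dynamic range below
   30 intensity units are marked invalid.
3. Only the largest 8-connected bright component is kept (ties broken to
   the upper component); components smaller than 20 px are noise.  This
   removes speckle and any smaller spurious blob.
4. Sub-pixel refinement: the half-amplitude crossing of the smoothed column
   profile near the component's top edge, located by linear interpolation
   between the bracketing samples, plus 0.5 px because samples sit at pixel
   centers (a row sample integrates over [m, m+1)).

Gaps (invalid columns) are interpolated linearly across columns; a width-3
median filter (on by default) suppresses single-column outliers.  A frame
with > 20 % invalid columns aborts the run with the frame named.  On
phantom renders the detector is unbiased with ≤ 0.25 px worst-case error on
clean frames and ~0.03 px RMS under nominal noise.

## Motion decomposition

The eyeball reaction L_q(i) is modeled as a rigid vertical shift, estimated
as the mean displacement (relative to frame 1) of the 10 outermost valid
columns on each side — image margins show sclera, which translates but does
not deform.  This is a deliberate simplification of multi-component
eyeball-reaction models; it recovers pure translations to < 0.1 px on
phantoms and is insensitive to central indentation.  After subtracting L_q
and the resting contour, a residual per-frame constant (the error of the
L_q estimate itself) is removed by subtracting the median of the outermost
5 % of columns per side.  That estimator is equivariant under per-frame
offsets, which makes every vibration metric downstream *exactly*
independent of residual rigid motion — the property that motivates
defining the peak vibration as a left–right difference in the first place.

### Frequency-band split

Deformation is split at 100 Hz into L_L (slow indentation morphology) and
L_H (vibrations); the split is applied to L_d (the arrows in the source
block diagram are ambiguous between L_d and L_c; the two differ only by the
static resting shape, which carries no temporal frequency content).  L_L is
a 4th-order Butterworth low-pass run forward and backward (zero net phase
shift, so vibration timing is not skewed); L_H := L_d − L_L is the exact
complement, so conservation holds to machine precision by construction.

Edge handling matters on these short windows (140 samples ≈ 6 cutoff
periods).  Reflection padding turns the tail of a sustained oscillation
into an endpoint step (odd) or kink (even) whose low-frequency content
leaks far into the window: a full-window 400 Hz test tone leaks 97 % (odd)
or 16 % (even) of its amplitude into L_L near the edges.  Each column is
therefore extended on both sides by autoregressive extrapolation (Burg
method, order min(24, F/3), pad 3 cutoff periods) before filtering; the
Burg recursion keeps all reflection coefficients in [−1, 1], so the
extrapolation is stable.  Measured leakage: 0.01 % for a 400 Hz tone into
L_L, 0.4 % for a 50 Hz tone into L_H, zero cross-correlation lag.  The
cost is that the filter becomes (weakly) data-dependent, which is why
rigid-offset independence is guaranteed upstream by the margin re-centering
rather than by filter linearity.

## Applanation detection

The vibration metrics are defined between the two applanations (momentary
central flattenings).  Devices report applanation times themselves and the
override `--ap1-ms/--ap2-ms` accepts them; for raw sequences the package
detects them: flatness(i) = RMS residual of a straight-line fit to the
corrected contour over the central 3 mm window, evaluated on the sub-100 Hz
band plus the resting shape (so >100 Hz vibrations cannot jitter the
argmin); A_p1 is the flatness minimum before the frame of maximal central
deformation, A_p2 the minimum after it.  Applanations are frame-quantized.
On phantoms the detected frames match the curvature-zero truth within one
frame, and time-reversing the sequence swaps them as it should.  A
sequence whose deformation never exceeds p_r raises "no deformation
event".

## Vibration metrics

All metrics are evaluated per frame strictly inside (A_p1, A_p2); ties in
every argmin/argmax go to the leftmost column; for odd N the middle column
belongs to the left half.

* **Peak**: m_kl = min of L_d over the left half-columns, m_kr mirrored;
  trace |m_kl − m_kr| (px and µm).
* **Maximum deformation** n_d: the definition is circular (n_d is an
  argmax over the quarter window, which depends on n_d).  Resolved by
  bootstrapping from the global argmax of L_L — the low band is the right
  signal for locating the indentation, being free of vibration ripple —
  followed by one fixed-point refinement with the restricted argmax of
  L_d over [n_fl, n_fr].  Deterministic; frames where the ordering
  n_kl < n_d < n_kr fails or no positive deformation exists are gaps.
* **Quarter**: n_fl = ⌊(n_kl + n_d)/2⌋, n_fr = ⌊(n_kr + n_d)/2⌋ (floor;
  the floor midpoint is invariant under a common 0/1-based shift, so
  internal and reported indices agree); m_f• = L_H(n_f•, i); trace
  |m_fl − m_fr|.
* **Cutoff**: n_bl is the column just left of the first |L_d| > p_r
  exceedance (scanning left→center), n_br mirrored; trace |n_bl − n_br|
  (columns and mm).  The printed min-of-difference formulation yields a
  value, not a column; the junction-point reading is implemented.  The
  deviation is referenced to the median of the outermost 5 % columns
  (≈ 0 on centered data), which keeps the junction columns exactly
  offset-independent.  Frames entirely sub-threshold, or whose deformation
  reaches an image edge, are gaps — this is by construction the metric
  most sensitive to noise near the applanations.
* **Error bound** δ = 1/#{n : L_d(n, i) > p_r}, saturating at 1 px when
  the set is empty: with no deformation the position estimate is only good
  to the ±1 px digitization, and the error shrinks as the deformed area
  (hence the contour slope) grows.  p_r defaults to 2 px.
* **Angles**: λ = atan2(m_fl − m_fr, n_fl − n_fr) with both arguments in
  pixel units (a mixed-axis angle; converting the axes to physical units
  would change it — the pixel convention is the default and is stated in
  the output header), λ := 0 when both differences vanish; β is the
  running sum of λ over the analysis interval (undefined frames
  contribute 0).

## Spectral summaries

Traces are short (~50–65 samples between applanations), so the Rayleigh
limit is ~70–90 Hz and is always reported alongside the estimate.  The
fundamental is the dominant spectral bin above the 100 Hz split, computed
on the gap-interpolated (> 30 % gaps: refuse), mean-subtracted,
Hann-windowed trace zero-padded to ≥ 4096 points.  Frequencies are
estimated on the *signed* difference traces (m_fl − m_fr, …): rectifying
to the absolute trace first would double the apparent fundamental.
Amplitudes are the peak-to-peak excursion of the trace as defined — all
harmonics together, which for multi-harmonic vibrations exceeds the first
harmonic alone — in µm for Y-axis metrics, mm for X-axis metrics.
Multi-case tables report mean and SD (ddof = 1) per vibration type.

## 3-D reconstruction

The contour is swept about a vertical symmetry axis (default: the
maximum-deformation column of the displayed frame) through θ ∈ [−π/2, π/2]:
a point at lateral distance r maps to (r cos θ, r sin θ) keeping its depth,
which on a regular (n, w) grid is the inverse map z(x, w) = contour(axis ±
ρ), ρ = √((x−axis)² + w²), linearly interpolated; left-side points fill
x ≤ axis and right-side points the rest, so asymmetric contours remain
asymmetric.  The w = 0 slice reproduces the measured contour exactly and
the surface is mirror-symmetric in w by construction.  The raw measured
contour is swept, not a smoothed fit.  Export: gridded CSV or OBJ mesh.

## Phantom generator

The phantom is the package's study bench; its defaults are chosen once to
emulate a realistic single-puff recording of a healthy eye:

| parameter | default | why |
|---|---|---|
| geometry | 200 × 576 px, 3.3 × 9.05 mm, 140 frames, 0.23 ms | nominal acquisition |
| baseline arc | apex row 60, radius 7.8 mm | physiological anterior curvature |
| indentation | Gaussian, σ 1.1 mm, peak depth 0.6 mm, raised-cosine pulse frames 25–115 | deformation amplitudes ~0.5–1 mm over ~20 ms |
| peak lobes | ±1.73 mm offset, ratio 0.6, σ 0.47 mm | the "W" morphology with raised lateral peaks |
| support window | columns (120, 456), 20 px cosine ramp | deformation has finite lateral extent with known end columns |
| eye reaction | 6 px slow monotone ramp from frame 40 | rigid recoil, sub-100 Hz |
| vibrations | per-spec list: location (peak/quarter/whole), f, a, φ, footprint σ 12 px (peak locations: lobe-sized footprint) | >100 Hz oscillations ride on the deformation; gated to ~the inter-applanation window via the depth trajectory |
| render | band 35 px, blur σ 0.8, noise SD 4, 40 speckles, gain 0.7–1.0 | Scheimpflug-like band, uneven lighting, sensor noise, isolated bright pixels |

Named study specs: `quarter_vibration_spec` (antiphase 400 Hz / 2 px at
the quarter columns), `peak_vibration_spec` (antiphase 350 Hz / 3 px on
the peak lobes), `drift_spec` (compact single dent, support (200, 370)
with a steep 5 px ramp, drifting 0.3 mm — the n_d- and cutoff-recovery
bench), `translation_spec`, `static_spec`.  Applanation truth is the
zero crossing of the central quadratic curvature of the vibration-free
contour (eye shift excluded as rigid); speckles are placed at least 4 rows
clear of the band so they stay isolated; all randomness flows from one
seed and a fixed seed reproduces byte-identical frames.

What the phantom does *not* emulate — and hence what passing tests do not
show about clinical data: viscoelastic corneal mechanics (the indentation
shape is prescribed, not simulated), specular highlights and eyelash
shadows, multi-component eyeball reaction (rotation, axial motion),
patient-specific contour asymmetry, and the proprietary device's own
photometric normalization.  Recovery tolerances on phantoms (frequency
±20 Hz, amplitudes ±1 px, junction columns ±2, n_d ±2 columns) measure the
pipeline's algorithmic fidelity, not clinical accuracy.

## Numerical and interface choices

* Problem sizes: the test suite and examples run full 140-frame,
  200 × 576 sequences end to end (~1–2 s per pipeline run); nothing is
  scaled down.
* Degenerate inputs: all-black frame → "no cornea found"; static sequence
  → "no deformation event"; constant trace → "no harmonic"; flat half →
  the half's central column, flagged.
* AVI input requires an imageio video backend; without one the loader
  raises an informative error.  Directory-of-frames (JPG/PNG/TIF) and
  contour-CSV inputs are always available; the phantom writes lossless
  PNG so round trips are bit-exact.
* Outputs are deterministic: identical input and parameters give
  byte-identical CSV/JSON.
* The proprietary `.U12` archive format is out of scope.

## Known limitations

* The eye-reaction proxy absorbs any true corneal motion that happens to
  be common to both margins; on strongly decentered puffs the margins may
  contain deforming cornea.
* Cutoff columns are frame-quantized and threshold-sensitive near the
  applanations (shallow deformation), so the cutoff trace has the largest
  variance of the four — consistent with its role as the least robust
  metric.
* With ~50–65 usable frames, two vibrations closer than the Rayleigh limit
  are not separable; the reported `resolution_hz` makes this explicit.
* β sums λ only between the applanations, where its inputs are defined.
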