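"""Full vibration analysis of a synthetic air-puff sequence.

Generates a ground-truthed phantom with antiphase 400 Hz / 2 px vibrations
at the quarter columns, renders it to 140 grayscale frames (200 x 576 px,
0.23 ms spacing), runs contour detection -> decomposition -> applanation
detection -> vibration traces -> spectra, and compares the recovered numbers
with what was injected.
"""

import numpy as np

import corvib as cv

spec = cv.quarter_vibration_spec()
truth = cv.synthesize_contour(spec)
seq = cv.render_sequence(truth, spec)
res = cv.analyze_sequence(seq, cv.AnalysisParams(dt_ms=spec.dt_ms))

a1t, a2t = (f + 1 for f in truth.applanation_frames)
print(f"applanations: detected frames {res.ap.frame1}/{res.ap.frame2} "
      f"({res.ap.t1_ms:.2f}/{res.ap.t2_ms:.2f} ms), truth {a1t}/{a2t}")

q = res.spectra["quarter"]
p2p = np.nanmax(res.traces.quarter_vib) - np.nanmin(res.traces.quarter_vib)
print(f"quarter vibration: fundamental {q['fundamental_hz']:.0f} Hz "
      f"(resolution +-{q['resolution_hz']:.0f} Hz), injected 400 Hz")
print(f"quarter vibration peak-to-peak: {p2p:.2f} px "
      f"({p2p * res.calibration.pixel_height_um:.1f} um); "
      f"antiphase 2 px injections add to 4 px")

r = cv.peak_quarter_correlation(res.traces.peak_vib, res.traces.quarter_vib)
print(f"peak-quarter Pearson correlation over the analysis interval: {r:.2f} "
      f"(near zero here: only quarter vibrations were injected; in clinical "
      f"recordings peak vibrations follow quarter vibrations and correlate)")

# The fundamental sits at the injected frequency even though the Rayleigh
# resolution of the ~60-frame inter-applanation window is ~70 Hz: zero
# padding interpolates the spectral peak position.
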