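"""Heart rate from a noisy probability curve with the confidence gate.

Builds a heartbeat-probability curve with strong true beats plus weak
spurious maxima, then shows that the confidence-gated detector ignores the
spurious ones while a naive peak count does not.
"""

import numpy as np
from scipy.signal import find_peaks

from hbpnet import DetectionConfig, HbpMap, peak_refine_hr

rng = np.random.default_rng(0)
fps, spacing = 30.0, 25                     # true rate: 72 bpm
T = 600
v = np.zeros(T)
true_peaks = np.arange(10, T - 5, spacing)
v[true_peaks] = 0.95
v[true_peaks - 1] = v[true_peaks + 1] = 0.5
spurious = rng.choice([i for i in range(3, T - 3)
                       if np.abs(true_peaks - i).min() > 3], 8, replace=False)
v[spurious] = rng.uniform(0.3, 0.65, 8)     # weak, sub-threshold maxima

hbp = HbpMap(v, fps)
naive = fps * 60 / np.mean(np.diff(find_peaks(v)[0]))
est = peak_refine_hr(hbp, DetectionConfig(confidence=0.7, fps=fps))
print(f"true rate:                    {fps * 60 / spacing:.1f} bpm")
print(f"naive peak counting:          {naive:.1f} bpm")
print(f"confidence-gated (0.7):       {est.bpm:.1f} bpm "
      f"from {est.n_intervals} intervals")
print("\nWeak maxima below the confidence threshold clear the interval"
      "\nregister, so both intervals flanking them are excluded instead of"
      "\ncorrupting the mean — the estimate is unchanged by the noise.")
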