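"""Decompose one 200 ms window into intrinsic mode functions.

EMD splits a window X(t) into oscillatory modes plus a residual,
X(t) = sum_i IMF_i(t) + rf(t), ordered from highest to lowest frequency.
The per-mode energy ratios E_IMFi = sum(IMF_i^2)/E_total * 100% say where
the window's energy lives; averaged over many windows they pick the
"competent" IMF used for detection.
"""

import numpy as np

from pamdetect.audio import SampledSignal
from pamdetect.emd import decompose, reconstruct
from pamdetect.features import energy_summary

fs = 4800.0
t = np.arange(960) / fs
# a 13 Hz call tone plus a 150 Hz interferer
x = np.sin(2 * np.pi * 13 * t) + 0.8 * np.sin(2 * np.pi * 150 * t)
window = SampledSignal(index=0, start_time=0.0, samples=x, fs=fs)

dec = decompose(window)
summary = energy_summary(dec)

print(f"modes extracted:  {dec.n_imfs}")
for i, ratio in enumerate(summary.imf_ratios, start=1):
    print(f"  IMF{i}: {ratio:6.2f}% of window energy")
print(f"  residual: {summary.residual_ratio:.2f}%")

err = np.max(np.abs(reconstruct(dec) - x))
print(f"reconstruction error: {err:.2e}  (additivity is exact by construction)")
# IMF1 should carry the 150 Hz component (~39% of energy at amplitude 0.8)
# and IMF2 the 13 Hz call (~61%).
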