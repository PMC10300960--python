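"""Marginal frequency distribution and main-band location of one mode.

The Hilbert transform gives each mode an instantaneous frequency; binning
the squared amplitude by that frequency and normalising by the window's
total energy yields the marginal frequency (MF) distribution — the % of
window energy per 1 Hz bin. Averaged over windows and thresholded, it
locates the main frequency band (contiguous above-threshold bins around
the peak) and the enclosing round-number main frequency domain used by
the ESD and CESED detectors.
"""

import numpy as np

from pamdetect.audio import segment
from pamdetect.emd import decompose
from pamdetect.features import energy_summary, segment_marginals
from pamdetect.hht import average_marginal, band_summary
from pamdetect.synth import Zone, generate

labelled = generate(
    seed=1,
    total_duration=20.0,
    zones=(Zone(name="A", start_s=0.0, end_s=20.0, center_freq=39.0, on_fraction=0.4),),
)
windows = segment(labelled.recording, 200.0)
decs = [decompose(w) for w in windows]

marginals = [m for m in segment_marginals(decs, i=1) if m is not None]
avg = average_marginal(marginals)
band = band_summary(avg, threshold_pct=0.3)

print(f"windows analysed:     {len(marginals)}")
print(f"peak frequency:       {band.peak_freq:.0f} Hz (highest average energy ratio)")
print(f"main frequency band:  {band.main_band} Hz (bins >= 0.3%)")
print(f"main frequency domain:{band.main_domain} Hz (rounded analysis range)")
top = np.argsort(avg.energy_ratio)[::-1][:5]
print("top bins (Hz -> %):  ",
      {int(avg.bins[k]): round(float(avg.energy_ratio[k]), 2) for k in sorted(top)})
# With the default layout the first mode peaks in the A-call band near
# 39 Hz, mirroring the structure of real blue-whale recordings.
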