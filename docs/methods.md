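# Methods

## Pipeline overview

The detector treats a recording as a sequence of fixed-duration windows
(default 200 ms) and makes an independent binary decision per window. The
stages are: segmentation → empirical mode decomposition (EMD) → Hilbert
marginal-frequency analysis → feature extraction (ERD/ESD/ESED/CESED) →
threshold detection with ROC evaluation. All stages are deterministic;
randomness enters only through the synthetic-data generator's seed.

## Empirical mode decomposition

Sifting uses natural cubic splines through the local maxima and minima.
Boundary handling mirrors the two outermost extrema of each kind across
the window ends; end samples that protrude beyond the outermost extrema
are treated as extrema themselves so the envelopes always enclose the
signal. A mode is accepted when the normalised squared difference between
successive sift iterates falls below `sd_threshold` (default 0.2, the
usual Cauchy-type criterion), with a hard cap of 100 sift iterations.
Decomposition stops when the residual has fewer than three extrema (i.e.
is monotonic or constant) or when `max_imfs` is reached. Windows that are
constant or all zero decompose to zero IMFs with the residual equal to the
input; non-finite samples are rejected.

Two properties are contractual and tested rather than assumed: the
decomposition is exactly additive (components sum back to the input to
floating-point accuracy), and modes come out ordered from high to low mean
instantaneous frequency on separable mixtures. Plateau extrema are counted
once, at the downstream end of the flat stretch.

No detrending or windowing is applied before sifting; any trend is
absorbed by the residual.

## Hilbert spectral analysis

The instantaneous frequency (IF) of a mode is the central difference of
the unwrapped analytic-signal phase (one-sided at the window ends) over
2π. Negative IF values — a known artefact of the finite-window Hilbert
transform — are clamped to 0 and counted; the 0 Hz bin collects them and
is excluded from all band logic and entropy ranges, which keeps the
energy bookkeeping exact without letting artefacts influence band
location.

Marginal spectra use 1 Hz bins over [0, fs/2]: every sample contributes
its squared amplitude to the bin containing its IF, and bin totals are
divided by the window's total energy (×100). By construction the spectrum
of mode *i* sums to that mode's energy ratio — this mass-conservation
identity ties the spectral layer to the energy-characteristics layer and
is asserted to 1e-6 in the tests.

A practical accuracy note: for a pure 39 Hz tone in a 200 ms window
(about 8 cycles), spectral leakage of the windowed transform produces a
slow IF ripple, so roughly 91% (not all) of the energy lands within
±1 Hz of the nominal bin; the peak bin itself is exact. Reflection-based
signal extension and smoothed phase derivatives were evaluated and did
not improve this, so the plain windowed transform is kept.

The band summary thresholds the *average* marginal spectrum across
windows (threshold in %, default 0.3): the main frequency band is the
contiguous above-threshold run containing the global peak (lowest
frequency wins peak ties), and the main frequency domain is the smallest
range (1, k·50 Hz) covering every above-threshold bin. If nothing
crosses the threshold the pipeline falls back to the full band and flags
the result.

## Features and their conventions

All entropies are in nats (natural logarithm), with 0·ln 0 := 0.

- **ERD**: the chosen mode's energy ratio (%). Windows lacking that mode
  score 0 and are flagged.
- **ESD**: highest marginal-spectrum bin (%) inside the main domain.
- **ESED**: −Σ P ln P with P = (bin energy)/E_total over a configurable
  frequency range (default: the full band [1, fs/2]). P intentionally
  sums to less than one — the divisor is the *whole window's* energy, not
  the in-range energy of the chosen mode. That deviation from a proper
  probability distribution is what motivates CESED, so the formula is
  implemented literally rather than renormalised. One consequence worth
  knowing: the usual bound H ≤ ln K over K bins holds only for K ≥ 3;
  for K < 3 the per-bin maximum of −p ln p = 1/e binds instead (for
  K = 2 the sharp bound is 2/e ≈ 0.736 > ln 2).
- **CESED**: within the main domain only, bin energies are min-max
  scaled (the minimum bin maps to 0, the maximum to 1), renormalised to a
  probability vector, and measured by entropy. Min-max scaling removes
  offset and gain, so CESED depends only on the *shape* of the in-domain
  spectrum — it is invariant under E → αE + β (tested). A flat or empty
  in-domain spectrum carries no information; the feature is defined as 0
  and flagged rather than risking a division by zero.

The competent IMF (CIMF) is the mode position with the highest average
energy ratio over all windows (top-2 reported; ties break toward the
lower index). Missing positions contribute 0% to the average.

## Detection and evaluation

Decisions use strict inequalities: value > cutoff (or < cutoff under the
`low_is_positive` polarity). Threshold rules: feature median;
median + M·MAD (MAD = median absolute deviation — a median-centric
deviation measure consistent with a Chebyshev-style margin rule); a fixed
value; or the ROC-optimal cutoff, defined as the candidate whose
(FPR, TPR) minimises the Euclidean distance to the perfect corner (0, 1),
ties resolved toward higher TPR then lower FPR. Candidates are every
distinct observed value plus one cutoff beyond each extreme, which
realises every achievable partition — equivalent to an exhaustive
midpoint search (tested against one).

The ROC sweeps distinct observed values bracketed by sentinels so the
curve always contains (0, 0) and (1, 1); tied values share one point.
AUC is the trapezoidal area, which equals the Mann–Whitney rank
statistic (concordant pairs + half ties over P·N) — the equality is
asserted to 1e-12 against a brute-force oracle and cross-checked against
scikit-learn. Undefined rates (empty class) are reported as 0 rather
than raised. Reported percentages are rounded half-up to two decimals.

### Detector polarity

Which side of the cutoff means "call" is a property of the data, not of
the features. For the energy features high values mark calls by
definition. For the entropy features the direction depends on call
structure: a tonal call concentrates the in-domain spectrum and *lowers*
the entropy, while pulsed or multiband calls (as in real blue-whale
A calls) spread energy and raise it. On this package's synthetic tonal
calls the measured direction is low-entropy-means-call, so the pipeline
default is `low_is_positive` for ESED/CESED and `high_is_positive` for
ERD/ESD; both directions are available via configuration, and the AUC of
one polarity is one minus the AUC of the other (absent ties).

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure of an archival blue-whale excerpt:
100 s at 4800 Hz, a 50 s zone of 39 Hz calls then a 50 s zone of 13 Hz
calls, 200 ms windows (500 in total), and per-zone call occupancies of
0.36 and 0.34 so the truth has exactly 175 call windows against 325
noise-only windows. Calls are amplitude-modulated tone bursts 1–5 s long
(raised-cosine ramps over 10% of each end to avoid spectral splatter;
shallow 0.5 Hz AM), snapped to the window grid so the ≥50%-overlap
labelling rule is exact by construction. Call amplitude defaults to 1.0
against noise of standard deviation 0.3 — a moderate, clearly imperfect
operating point at which no detector is near-perfect.

The background is Gaussian noise low-pass filtered at 50 Hz (4th-order
Butterworth), emulating the low-frequency-dominated ambient field of
deep-ocean hydrophone recordings. This matters structurally: per-window
energy ratios are scale-free, so with broadband white noise the
highest-frequency noise mode would win the competent-IMF vote at *any*
signal-to-noise ratio and the analysis mode would never carry the calls —
a configuration real low-frequency recordings do not show. With the
low-pass default the synthetic pipeline reproduces the structure seen in
real data: the first two modes are competent, the first peaks in the
A-call band near 39 Hz, the second near 13 Hz, and the main domain is
1–50 Hz. White noise remains available (`noise_cutoff_hz=None`), as do
arbitrary zone layouts.

What passing tests on this data establish: the pipeline's bookkeeping,
contracts and ranking behaviour under controlled conditions — including
that the concentrated entropy detector (CESED) out-ranks the energy-ratio
and plain-entropy detectors by AUC across independent seeds. What it does
not establish: performance on real recordings, whose calls are pulsed,
frequency-modulated and harmonically rich, whose noise is nonstationary,
and whose entropy-feature polarity can therefore be the reverse of the
synthetic one. Ocean propagation, click trains and multi-channel arrays
are out of scope.

## Numerical and degenerate-case choices

- Envelope splines need two maxima and two minima; otherwise the window
  is treated as fully sifted.
- Zero-energy windows: all ratios and features are defined as 0 and
  flagged rather than raising, so one silent window cannot abort a long
  recording's analysis.
- Peak ties in band location go to the lowest frequency; CIMF ties to the
  lower mode index; ROC-optimal ties to higher TPR, then lower FPR.
- Segmentation drops a trailing remainder shorter than one window, and
  windows never overlap (hop = window length).
- Problem sizes in the test suite and acceptance script: single 960-sample
  windows for the decomposition/spectral contracts, a 10 s / 50-window
  recording for feature and CLI tests, and ten full 100 s / 500-window
  recordings for the end-to-end ranking claim, which a sign test over
  seeds turns into a significance statement.
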