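# pamdetect

Detection of marine mammal vocalizations in passive acoustic monitoring
(PAM) recordings by empirical mode decomposition and Hilbert
spectral-entropy features.

Low-frequency baleen-whale calls (e.g. blue-whale A and B calls at tens of
Hz) sit in nonstationary, low-frequency-dominated ambient noise where
fixed-kernel time-frequency methods trade off badly between time and
frequency resolution. This package implements a detection pipeline that
sidesteps that trade-off: each fixed-length window of the recording is
decomposed adaptively into intrinsic mode functions (IMFs), the energy of
the informative mode is mapped onto frequency through the Hilbert
transform's instantaneous frequency, and scalar features of that energy
distribution are thresholded into per-window call/no-call decisions. It is
aimed at bioacousticians and PAM tool builders who want a transparent,
fully scriptable detector with ROC-based evaluation built in.

## Method

For a window `X(t)`, EMD gives `X(t) = Σᵢ IMFᵢ(t) + rf(t)` with total
energy `E_total = Σᵢ Σₜ IMFᵢ²(t) + Σₜ rf²(t)`. The analytic signal
`IMFᵢ(t) + j·HT[IMFᵢ](t) = Aᵢ(t)·e^{jθᵢ(t)}` yields the instantaneous
frequency `Fᵢ(t) = (1/2π)·dθᵢ/dt`; binning `IMFᵢ²(t)` by `Fᵢ(t)` and
normalising by `E_total` gives the marginal frequency distribution
`MFᵢ(f)` (% of window energy per 1 Hz bin). The mode with the highest
average energy ratio across windows is the *competent IMF* (CIMF); the
contiguous span of its average spectrum above a threshold is the *main
frequency band*, and the enclosing round-number range the *main frequency
domain* `(a, b)`.

Four per-window features are computed on the chosen mode `i`:

- **ERD** — energy ratio distribution: `E_IMFᵢ = Σₜ IMFᵢ²(t)/E_total·100%`.
- **ESD** — energy spectrum distribution: `max_{f∈(a,b)} MFᵢ(f)`.
- **ESED** — energy spectrum entropy distribution:
  `Hᵢ = −Σⱼ Pᵢⱼ ln Pᵢⱼ` (nats) with `Pᵢⱼ = Eᵢⱼ/E_total` over a frequency
  range; `P` is deliberately *not* renormalised to sum to one.
- **CESED** — concentrated energy spectrum entropy distribution: inside
  the main domain, energies are min-max scaled,
  `Sᵢⱼ = (Eᵢⱼ − min E)/(max E − min E)`, renormalised to a probability
  vector `Pᵢⱼ = Sᵢⱼ/Σⱼ Sᵢⱼ`, and `CHᵢ = −Σⱼ Pᵢⱼ ln Pᵢⱼ`.

A window is declared a call when its feature crosses a cutoff — the
feature median, median + M·MAD, a fixed value, or the ROC-optimal cutoff
(the threshold whose (FPR, TPR) lies closest to (0, 1)). Evaluation
reports confusion counts, TPR/FPR, the ROC curve, trapezoidal AUC, and
accuracy/precision/recall/F1.

A synthetic-data module generates labelled two-zone recordings (39 Hz and
13 Hz call bursts over low-frequency ambient noise) so the whole pipeline
is testable without any field data.

## Worked example

```sh
python examples/04_detect_and_evaluate.py
```

generates a 100 s labelled synthetic recording (500 windows, 175 calls),
picks the competent IMF automatically, and prints:

```
competent IMFs by average energy ratio: (1, 2); analysing IMF1
main domain: (1.0, 50.0) Hz

detector rule           cutoff    TPR%    FPR%     AUC     F1%
erd      median         58.701   69.71   39.38  0.7136   57.41
erd      roc_optimal    70.525   61.14   18.77  0.7136   62.39
esd      median          8.177   76.57   35.69  0.7580   63.06
esd      roc_optimal    10.619   69.14   17.85  0.7580   68.36
esed     median          2.073   49.71   50.15  0.5407   40.94
esed     roc_optimal     2.261   70.86   62.46  0.5407   49.40
cesed    median          2.981   80.00   33.85  0.8105   65.88
cesed    roc_optimal     2.830   72.57   22.46  0.8105   67.73
```

Reading the table: the first mode's average spectrum peaks in the A-call
band, so detection runs on IMF1 over the 1–50 Hz main domain. AUC ranks
the detectors independently of any cutoff — the concentrated entropy
feature (CESED, 0.81) separates call from noise windows best, and the
ROC-optimal rule cuts the false-alarm rate roughly in half relative to
the median rule at a modest cost in recall. The other examples
(`examples/01`–`03`) walk through synthesis, a single-window
decomposition, and the marginal-spectrum/band machinery.

The same pipeline is available from the shell:

```sh
pamdetect simulate --outdir run/
pamdetect detect --input run/recording.wav --labels run/labels.csv --outdir run/
pamdetect evaluate --features run/features.csv --labels run/labels.csv --outdir run/
```

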