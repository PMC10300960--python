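"""Hilbert spectral analysis of intrinsic mode functions.

For each IMF the analytic signal ``IMF_i(t) + j·HT[IMF_i](t) = A_i(t)·exp(j·theta_i(t))``
gives an instantaneous frequency ``F_i(t) = (1/2pi)·d(theta_i)/dt``. Binning the
squared IMF amplitude by the instantaneous frequency of each sample, and
normalising by the total window energy, yields the marginal frequency (MF)
distribution — the per-frequency energy ratio (%) of that IMF. Averaging MF
distributions across windows and thresholding locates the main frequency
band (contiguous above-threshold bins around the peak) and the main
frequency domain (the enclosing round-number analysis range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _hilbert

__all__ = [
    "AnalyticSeries",
    "MarginalSpectrum",
    "TimeFrequencyEnergy",
    "BandSummary",
    "analytic",
    "marginal",
    "average_marginal",
    "band_summary",
    "hilbert_spectrum",
]


@dataclass(frozen=True)
class AnalyticSeries:
    """Amplitude, unwrapped phase and instantaneous frequency of one IMF.

    ``n_clamped`` counts samples whose raw instantaneous frequency was
    negative and was clamped to 0; ``undefined`` marks an all-zero input
    for which no meaningful frequency exists.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray
    fs: float
    n_clamped: int = 0
    undefined: bool = False


@dataclass(frozen=True)
class MarginalSpectrum:
    """Per-frequency-bin energy ratio (% of total window energy) of one IMF.

    ``bins`` holds bin-centre frequencies ``k·bin_width`` for k = 0..K;
    bin 0 collects samples with clamped/undefined instantaneous frequency
    and is excluded from band logic.
    """

    bins: np.ndarray
    energy_ratio: np.ndarray
    imf_index: int = 0

    def __post_init__(self) -> None:
        if self.bins.size != self.energy_ratio.size:
            raise ValueError("bins and energy_ratio must have equal length")


@dataclass(frozen=True)
class TimeFrequencyEnergy:
    """Hilbert time-frequency energy grid E_i(t, f) for one IMF.

    ``grid[f_bin, t]`` is raw per-sample energy; dividing by ``normalizer``
    (the window's total energy) gives the normalised Hilbert spectrum.
    """

    grid: np.ndarray
    bins: np.ndarray
    bin_width: float
    normalizer: float


@dataclass(frozen=True)
class BandSummary:
    """Peak frequency, main band and main domain of an averaged spectrum."""

    peak_freq: float
    main_band: tuple[float, float] | None
    main_domain: tuple[float, float] | None
    threshold: float
    empty: bool = False


def analytic(imf: np.ndarray, fs: float) -> AnalyticSeries:
    """Analytic signal of one IMF via the Hilbert transform.

    The instantaneous frequency is the central difference of the unwrapped
    phase (one-sided at the ends) divided by 2*pi; negative values are
    clamped to 0 and counted.
    """
    x = np.asarray(imf, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for Hilbert analysis")
    if not np.any(x):
        z = np.zeros(x.size)
        return AnalyticSeries(amplitude=z, phase=z, inst_freq=z, fs=fs, undefined=True)
    z = _hilbert(x)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    inst_freq = np.gradient(phase) * fs / (2.0 * np.pi)
    negative = inst_freq < 0
    n_clamped = int(np.count_nonzero(negative))
    if n_clamped:
        inst_freq = np.where(negative, 0.0, inst_freq)
    return AnalyticSeries(
        amplitude=amplitude, phase=phase, inst_freq=inst_freq, fs=fs, n_clamped=n_clamped
    )


def _bin_grid(fs: float, bin_width: float) -> np.ndarray:
    n_bins = int(np.floor(fs / 2.0 / bin_width)) + 1
    return np.arange(n_bins) * bin_width


def _bin_indices(ana: AnalyticSeries, n_bins: int, bin_width: float) -> np.ndarray:
    idx = np.rint(ana.inst_freq / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def marginal(
    imf: np.ndarray,
    ana: AnalyticSeries,
    e_total: float,
    bin_width: float = 1.0,
    imf_index: int = 0,
) -> MarginalSpectrum:
    """Marginal frequency distribution of one IMF.

    Each sample contributes its squared amplitude ``IMF_i(t)^2`` to the bin
    containing its instantaneous frequency; bin totals are expressed as a
    percentage of ``e_total`` (the whole window's energy), so the spectrum
    sums to that IMF's energy ratio, not to 100%.
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    x = np.asarray(imf, dtype=float)
    bins = _bin_grid(ana.fs, bin_width)
    energy = np.zeros(bins.size)
    if np.any(x):
        idx = _bin_indices(ana, bins.size, bin_width)
        energy = np.bincount(idx, weights=x * x, minlength=bins.size)
    return MarginalSpectrum(
        bins=bins, energy_ratio=energy / e_total * 100.0, imf_index=imf_index
    )


def average_marginal(spectra: list[MarginalSpectrum]) -> MarginalSpectrum:
    """Element-wise mean of marginal spectra sharing one bin grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    bins = spectra[0].bins
    for s in spectra[1:]:
        if s.bins.size != bins.size or not np.allclose(s.bins, bins):
            raise ValueError("bin grids differ between spectra")
    mean = np.mean([s.energy_ratio for s in spectra], axis=0)
    return MarginalSpectrum(bins=bins, energy_ratio=mean, imf_index=spectra[0].imf_index)


def band_summary(avg: MarginalSpectrum, threshold_pct: float, domain_step: float = 50.0) -> BandSummary:
    """Locate the peak bin, main band and main domain of an averaged spectrum.

    The main band is the maximal contiguous run of bins at or above
    ``threshold_pct`` that contains the global peak (lowest frequency wins
    peak ties); the main domain is the smallest range ``(1, k·domain_step)``
    covering every above-threshold bin. Bin 0 (clamped/undefined
    instantaneous frequency) is excluded throughout.
    """
    if avg.bins.size < 2:
        raise ValueError("spectrum has no nonzero-frequency bins")
    ratios = avg.energy_ratio[1:]
    freqs = avg.bins[1:]
    peak_pos = int(np.argmax(ratios))  # argmax returns the first (lowest-frequency) tie
    peak_freq = float(freqs[peak_pos])
    above = ratios >= threshold_pct
    if not above.any():
        return BandSummary(
            peak_freq=peak_freq, main_band=None, main_domain=None,
            threshold=threshold_pct, empty=True,
        )
    # contiguous run of above-threshold bins containing the peak
    lo = peak_pos
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_pos
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    if not above[peak_pos]:  # peak below threshold: use the first run instead
        run_starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
        lo = int(run_starts[0])
        hi = lo
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
    f_max_above = float(freqs[np.flatnonzero(above)[-1]])
    domain_hi = domain_step * max(1.0, np.ceil(f_max_above / domain_step))
    return BandSummary(
        peak_freq=peak_freq,
        main_band=(float(freqs[lo]), float(freqs[hi])),
        main_domain=(float(freqs[0]), float(domain_hi)),
        threshold=threshold_pct,
    )


def hilbert_spectrum(
    imf: np.ndarray,
    ana: AnalyticSeries,
    e_total: float,
    bin_width: float = 1.0,
    time_decimation: int = 1,
) -> TimeFrequencyEnergy:
    """Un-summed (time, frequency) energy grid of one IMF.

    Summing the grid over time and normalising reproduces :func:`marginal`
    exactly. ``time_decimation`` pools consecutive samples into coarser
    time columns (energy is summed, so mass is conserved).
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    x = np.asarray(imf, dtype=float)
    bins = _bin_grid(ana.fs, bin_width)
    n_t = int(np.ceil(x.size / time_decimation))
    grid = np.zeros((bins.size, n_t))
    if np.any(x):
        f_idx = _bin_indices(ana, bins.size, bin_width)
        t_idx = np.arange(x.size) // time_decimation
        np.add.at(grid, (f_idx, t_idx), x * x)
    return TimeFrequencyEnergy(grid=grid, bins=bins, bin_width=bin_width, normalizer=e_total)
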