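"""Per-window detector features: ERD, ESD, ESED and CESED.

All four features reduce one window's decomposition to a scalar:

ERD   energy ratio (%) of the chosen IMF — E_IMFi = sum(IMF_i^2)/E_total * 100
ESD   highest marginal-spectrum bin (%) of the chosen IMF inside the main
      frequency domain
ESED  Shannon entropy (nats) of the total-energy-normalised marginal energy
      distribution, H_i = -sum_j P_ij * ln(P_ij) with P_ij = E_ij / E_total.
      P is deliberately NOT renormalised to sum to 1: dividing by the whole
      window's energy rather than the in-range energy is what distinguishes
      ESED from an ordinary spectral entropy (and motivates CESED).
CESED entropy (nats) of the min-max scaled, then renormalised, marginal
      energies restricted to the main domain: S_j = (E_j - min E)/(max E - min E),
      P_j = S_j / sum(S), H = -sum P ln P.

Conventions: natural logarithm throughout; 0·ln 0 = 0; a flat (or empty)
spectrum in the CESED domain carries no information and maps to 0, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .emd import IMFDecomposition
from .hht import MarginalSpectrum, analytic, marginal

__all__ = [
    "EnergySummary",
    "FeatureSeries",
    "energy_summary",
    "select_cimf",
    "average_imf_ratios",
    "segment_marginals",
    "spectral_entropy",
    "concentrated_entropy",
    "erd",
    "esd",
    "esed",
    "esed_aggregate",
    "cesed",
    "ALGORITHMS",
]


@dataclass(frozen=True)
class EnergySummary:
    """Total window energy and the percentage share of each component.

    ``imf_ratios[i-1]`` is E_IMFi (%); the residual's share is reported
    separately so the ratios sum to 100%. ``flagged`` marks an all-zero
    window whose ratios are defined as 0.
    """

    e_total: float
    imf_ratios: np.ndarray
    residual_ratio: float
    flagged: bool = False


@dataclass
class FeatureSeries:
    """One detector's scalar feature per window.

    ``flags[k]`` marks window k where the feature was defined by a
    degenerate-case rule (missing IMF, zero energy, flat spectrum).
    """

    algorithm: str
    imf_index: int
    values: np.ndarray
    units: str
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.values.size, dtype=bool)


def energy_summary(dec: IMFDecomposition) -> EnergySummary:
    """Energy bookkeeping of one decomposition (total and % per component)."""
    energies = np.array([float(np.sum(c * c)) for c in dec.imfs])
    res_energy = float(np.sum(dec.residual**2))
    e_total = float(energies.sum() + res_energy)
    if e_total <= 0:
        return EnergySummary(
            e_total=0.0,
            imf_ratios=np.zeros(len(dec.imfs)),
            residual_ratio=0.0,
            flagged=True,
        )
    return EnergySummary(
        e_total=e_total,
        imf_ratios=energies / e_total * 100.0,
        residual_ratio=res_energy / e_total * 100.0,
    )


def average_imf_ratios(decs: Sequence[IMFDecomposition]) -> np.ndarray:
    """Mean energy ratio (%) per IMF position across windows.

    Windows lacking an i-th IMF contribute 0% for that position, so the
    mean is over all windows at every position.
    """
    if not decs:
        raise ValueError("no decompositions given")
    n_pos = max((d.n_imfs for d in decs), default=0)
    if n_pos == 0:
        return np.zeros(0)
    table = np.zeros((len(decs), n_pos))
    for k, d in enumerate(decs):
        s = energy_summary(d)
        table[k, : s.imf_ratios.size] = s.imf_ratios
    return table.mean(axis=0)


def select_cimf(avg_ratios: np.ndarray, k: int = 2) -> tuple[int, ...]:
    """1-based indices of the k IMF positions with the highest average
    energy ratio, descending; ties break toward the lower index."""
    ratios = np.asarray(avg_ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio vector")
    if k > ratios.size:
        raise ValueError(f"k={k} exceeds the {ratios.size} IMF positions present")
    order = np.argsort(-ratios, kind="stable")
    return tuple(int(i) + 1 for i in order[:k])


def segment_marginals(
    decs: Sequence[IMFDecomposition],
    i: int,
    bin_width: float = 1.0,
) -> list[MarginalSpectrum | None]:
    """Marginal spectrum of IMF_i for every window.

    ``None`` marks windows with no i-th IMF or zero total energy; features
    built on these marginals flag such windows and assign 0.
    """
    out: list[MarginalSpectrum | None] = []
    for dec in decs:
        comp = dec.component(i)
        summ = energy_summary(dec)
        if comp is None or summ.flagged:
            out.append(None)
            continue
        fs = dec.source.fs if dec.source is not None else 2.0 * comp.size
        ana = analytic(comp, fs)
        out.append(marginal(comp, ana, summ.e_total, bin_width=bin_width, imf_index=i))
    return out


def spectral_entropy(p: np.ndarray) -> float:
    """-sum p*ln(p) in nats with 0·ln 0 = 0; p need not sum to 1."""
    p = np.asarray(p, dtype=float)
    pos = p[p > 0]
    return float(-np.sum(pos * np.log(pos)))


def concentrated_entropy(energies: np.ndarray) -> tuple[float, bool]:
    """Min-max scale ``energies``, renormalise to a probability vector and
    return its entropy in nats.

    Returns ``(value, flagged)``; a flat or empty vector is degenerate
    (no information) and yields ``(0.0, True)``.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        return 0.0, True
    lo, hi = float(e.min()), float(e.max())
    if hi <= lo:
        return 0.0, True
    s = (e - lo) / (hi - lo)
    p = s / s.sum()
    return spectral_entropy(p), False


def _domain_slice(bins: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    mask = (bins >= f_lo) & (bins <= f_hi) & (bins > 0)
    if not mask.any():
        raise ValueError(f"frequency range ({f_lo}, {f_hi}) selects no bins")
    return mask


def erd(
    decs: Sequence[IMFDecomposition],
    i: int,
    marginals: Sequence[MarginalSpectrum | None] | None = None,
) -> FeatureSeries:
    """Energy ratio distribution: E_IMFi (%) per window."""
    if i < 1:
        raise ValueError("IMF index is 1-based")
    values = np.zeros(len(decs))
    flags = np.zeros(len(decs), dtype=bool)
    for k, dec in enumerate(decs):
        summ = energy_summary(dec)
        if dec.component(i) is None or summ.flagged:
            flags[k] = True
        else:
            values[k] = summ.imf_ratios[i - 1]
    return FeatureSeries(algorithm="erd", imf_index=i, values=values, units="%", flags=flags)


def esd(
    decs: Sequence[IMFDecomposition],
    i: int,
    main_domain: tuple[float, float],
    marginals: Sequence[MarginalSpectrum | None] | None = None,
) -> FeatureSeries:
    """Energy spectrum distribution: the highest marginal-spectrum bin (%)
    of IMF_i inside the main frequency domain, per window."""
    f_lo, f_hi = main_domain
    if f_lo >= f_hi:
        raise ValueError("empty main domain")
    if marginals is None:
        marginals = segment_marginals(decs, i)
    values = np.zeros(len(marginals))
    flags = np.zeros(len(marginals), dtype=bool)
    for k, spec in enumerate(marginals):
        if spec is None:
            flags[k] = True
            continue
        mask = _domain_slice(spec.bins, f_lo, f_hi)
        values[k] = float(spec.energy_ratio[mask].max())
    return FeatureSeries(algorithm="esd", imf_index=i, values=values, units="%", flags=flags)


def esed(
    decs: Sequence[IMFDecomposition],
    i: int,
    freq_range: tuple[float, float] | None = None,
    marginals: Sequence[MarginalSpectrum | None] | None = None,
) -> FeatureSeries:
    """Energy spectrum entropy distribution (nats) of IMF_i per window.

    ``freq_range`` defaults to the full sampling band [1, fs/2]; passing
    the main domain restricts the sum to that range.
    """
    if marginals is None:
        marginals = segment_marginals(decs, i)
    values = np.zeros(len(marginals))
    flags = np.zeros(len(marginals), dtype=bool)
    for k, spec in enumerate(marginals):
        if spec is None:
            flags[k] = True
            continue
        f_lo, f_hi = freq_range if freq_range is not None else (spec.bins[1], spec.bins[-1])
        mask = _domain_slice(spec.bins, f_lo, f_hi)
        values[k] = spectral_entropy(spec.energy_ratio[mask] / 100.0)
    return FeatureSeries(algorithm="esed", imf_index=i, values=values, units="nats", flags=flags)


def esed_aggregate(
    decs: Sequence[IMFDecomposition],
    freq_range: tuple[float, float] | None = None,
) -> FeatureSeries:
    """Whole-signal entropy per window: the sum of the per-IMF entropies
    over every IMF present in that window's decomposition."""
    n = len(decs)
    total = np.zeros(n)
    flags = np.ones(n, dtype=bool)
    n_pos = max((d.n_imfs for d in decs), default=0)
    for i in range(1, n_pos + 1):
        part = esed(decs, i, freq_range=freq_range)
        total += part.values
        flags &= part.flags
    return FeatureSeries(algorithm="esed_total", imf_index=0, values=total, units="nats", flags=flags)


def cesed(
    decs: Sequence[IMFDecomposition],
    i: int,
    main_domain: tuple[float, float],
    marginals: Sequence[MarginalSpectrum | None] | None = None,
) -> FeatureSeries:
    """Concentrated energy spectrum entropy distribution (nats) of IMF_i.

    Min-max normalisation inside the main domain removes offset and gain,
    so the value depends only on the shape of the in-domain spectrum.
    """
    f_lo, f_hi = main_domain
    if f_lo >= f_hi:
        raise ValueError("empty main domain")
    if marginals is None:
        marginals = segment_marginals(decs, i)
    values = np.zeros(len(marginals))
    flags = np.zeros(len(marginals), dtype=bool)
    for k, spec in enumerate(marginals):
        if spec is None:
            flags[k] = True
            continue
        mask = _domain_slice(spec.bins, f_lo, f_hi)
        values[k], flags[k] = concentrated_entropy(spec.energy_ratio[mask])
    return FeatureSeries(algorithm="cesed", imf_index=i, values=values, units="nats", flags=flags)


ALGORITHMS = ("erd", "esd", "esed", "cesed")
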