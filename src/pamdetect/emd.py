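"""Empirical mode decomposition by cubic-spline sifting.

A window ``X(t)`` is decomposed into intrinsic mode functions (IMFs) plus a
residual,

    X(t) = sum_i IMF_i(t) + rf(t),

by iteratively subtracting the mean of the upper and lower extrema
envelopes ("sifting") until the running component satisfies a Cauchy-type
stopping criterion, then repeating on the remainder until it is monotonic.
IMFs are ordered from highest to lowest characteristic frequency; the
decomposition is exactly additive by construction and fully deterministic.

Envelopes are natural cubic splines through the local extrema, with the
boundary handled by mirroring the outermost extrema across each end of the
window (end samples that protrude beyond the outermost extrema are treated
as extrema themselves so the envelopes always enclose the signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .audio import SampledSignal

__all__ = ["EMDConfig", "IMFDecomposition", "decompose", "reconstruct"]


@dataclass(frozen=True)
class EMDConfig:
    """Sifting parameters.

    sd_threshold
        Normalised squared difference between successive sift iterates
        below which a mode is accepted (Cauchy criterion), default 0.2.
    max_sift_iters
        Hard cap on sift iterations per mode.
    max_imfs
        Cap on the number of extracted modes; ``None`` means run until the
        residual is monotonic.
    boundary
        Envelope extension policy; only ``"mirror"`` is implemented.
    """

    max_imfs: int | None = None
    sd_threshold: float = 0.2
    max_sift_iters: int = 100
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.boundary != "mirror":
            raise ValueError(f"unknown boundary policy {self.boundary!r}")


@dataclass
class IMFDecomposition:
    """Ordered IMFs (highest frequency first) plus the residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source: SampledSignal | None = None

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def component(self, i: int) -> np.ndarray | None:
        """1-based access to IMF_i; ``None`` when the mode does not exist."""
        return self.imfs[i - 1] if 1 <= i <= len(self.imfs) else None


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateaus count once (at the end
    of the flat stretch, inheriting the preceding slope)."""
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.empty(0, int), np.empty(0, int)
    s[: nz[0]] = s[nz[0]]
    # forward-fill zero slopes
    idx = np.where(s != 0, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    s = s[idx]
    flips = np.flatnonzero(s[:-1] != s[1:]) + 1
    maxima = flips[s[flips] < 0]
    minima = flips[s[flips] > 0]
    return maxima, minima


def _mirrored_spline(x: np.ndarray, idx: np.ndarray, n: int, n_mirror: int = 2) -> np.ndarray:
    """Envelope through extrema ``idx`` with mirror extension across both
    window ends."""
    left = idx[idx > 0][:n_mirror]
    right = idx[idx < n - 1][-n_mirror:]
    knots = np.concatenate([-left[::-1], idx, 2 * (n - 1) - right[::-1]])
    vals = np.concatenate([x[left[::-1]], x[idx], x[right[::-1]]])
    t = np.arange(n)
    if knots.size < 4:
        return np.interp(t, knots, vals)
    return CubicSpline(knots, vals, bc_type="natural")(t)


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of upper and lower envelopes, or ``None`` when the signal has
    too few extrema to support both."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = x.size
    # end samples protruding beyond the outer extrema act as extrema
    if x[0] >= x[maxima[0]]:
        maxima = np.concatenate([[0], maxima])
    if x[0] <= x[minima[0]]:
        minima = np.concatenate([[0], minima])
    if x[-1] >= x[maxima[-1]]:
        maxima = np.concatenate([maxima, [n - 1]])
    if x[-1] <= x[minima[-1]]:
        minima = np.concatenate([minima, [n - 1]])
    upper = _mirrored_spline(x, maxima, n)
    lower = _mirrored_spline(x, minima, n)
    return 0.5 * (upper + lower)


def _is_done(residual: np.ndarray) -> bool:
    maxima, minima = _local_extrema(residual)
    return maxima.size + minima.size < 3


def decompose(signal: SampledSignal, config: EMDConfig | None = None) -> IMFDecomposition:
    """Sift ``signal`` into IMFs plus a residual.

    A constant or all-zero window yields zero IMFs with the residual equal
    to the input. Non-finite samples raise ``ValueError``.
    """
    config = config or EMDConfig()
    x = np.asarray(signal.samples, dtype=float)
    if x.size < 8:
        raise ValueError(f"segment too short for sifting ({x.size} < 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    while not _is_done(residual):
        if config.max_imfs is not None and len(imfs) >= config.max_imfs:
            break
        h = residual.copy()
        mode = None
        for _ in range(config.max_sift_iters):
            mean = _mean_envelope(h)
            if mean is None:
                break
            h_next = h - mean
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_next) ** 2)) / denom if denom > 0 else 0.0
            h = h_next
            mode = h
            if sd < config.sd_threshold:
                break
        if mode is None:
            break
        imfs.append(mode)
        residual = residual - mode
    return IMFDecomposition(imfs=imfs, residual=residual, source=signal)


def reconstruct(dec: IMFDecomposition) -> np.ndarray:
    """Element-wise sum of all IMFs and the residual (exact by construction)."""
    n = dec.residual.size
    for c in dec.imfs:
        if c.size != n:
            raise ValueError("component length mismatch in decomposition")
    out = dec.residual.copy()
    for c in dec.imfs:
        out += c
    return out
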