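"""WAV input/output and fixed-window segmentation.

A recording is cut into contiguous, non-overlapping windows of fixed
duration (200 ms by default elsewhere in the package); each window is the
unit on which decomposition, feature extraction and detection operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

log = logging.getLogger(__name__)

__all__ = ["Recording", "SampledSignal", "read_wav", "write_wav", "segment"]


@dataclass(frozen=True)
class Recording:
    """A mono amplitude series with its sampling frequency."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.fs


@dataclass(frozen=True)
class SampledSignal:
    """One fixed-duration window of a recording.

    ``index`` is the 0-based window number, ``start_time`` its offset in
    seconds from the start of the recording.
    """

    index: int
    start_time: float
    samples: np.ndarray
    fs: float


# full-scale divisors for integer PCM -> [-1, 1] float
_PCM_SCALE = {
    np.dtype("int16"): 2.0**15,
    np.dtype("int32"): 2.0**31,
}


def read_wav(path: str | Path) -> Recording:
    """Read a WAV file as a mono :class:`Recording`.

    Integer PCM is rescaled to [-1, 1]; IEEE float data is passed through.
    Multi-channel files are reduced to their first channel (a warning is
    logged).
    """
    fs, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if data.ndim > 1:
        log.warning("%s: %d channels, using channel 0 only", path, data.shape[1])
        data = data[:, 0]
    dtype = data.dtype
    if dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[dtype]
    elif dtype == np.dtype("uint8"):  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return Recording(samples=samples, fs=float(fs))


def write_wav(path: str | Path, recording: Recording) -> None:
    """Write a recording as 32-bit IEEE float WAV."""
    wavfile.write(str(path), int(round(recording.fs)), recording.samples.astype(np.float32))


def segment(
    recording: Recording,
    window_ms: float,
    start_s: float = 0.0,
    duration_s: float | None = None,
) -> list[SampledSignal]:
    """Cut ``recording`` into contiguous non-overlapping windows.

    Windows are ``window_ms`` long; any trailing remainder shorter than one
    window is dropped, so a 100 s recording at 200 ms yields exactly 500
    windows.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if duration_s is None:
        duration_s = recording.duration - start_s
    if start_s < 0 or start_s + duration_s > recording.duration + 1e-9:
        raise ValueError("requested span exceeds the recording")
    if duration_s * 1000.0 < window_ms:
        raise ValueError("window longer than the requested duration")

    win_len = int(round(recording.fs * window_ms / 1000.0))
    n_windows = int(np.floor(duration_s * 1000.0 / window_ms))
    offset = int(round(start_s * recording.fs))
    out = []
    for k in range(n_windows):
        lo = offset + k * win_len
        out.append(
            SampledSignal(
                index=k,
                start_time=start_s + k * window_ms / 1000.0,
                samples=recording.samples[lo : lo + win_len],
                fs=recording.fs,
            )
        )
    return out
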