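"""Shared fixtures: tone windows and a small labelled synthetic recording.

Everything is generated programmatically; the heavier decomposition work is
session-scoped so the feature/detection tests reuse one analysis.
"""

from __future__ import annotations

import numpy as np
import pytest

from pamdetect.audio import SampledSignal
from pamdetect.emd import decompose
from pamdetect.synth import SynthConfig, Zone, generate

FS = 4800.0
SEGMENT_SAMPLES = 960  # 200 ms at 4800 Hz


def make_tone(freq: float, fs: float = FS, n: int = SEGMENT_SAMPLES,
              amplitude: float = 1.0, phase: float = 0.0) -> SampledSignal:
    t = np.arange(n) / fs
    return SampledSignal(index=0, start_time=0.0,
                         samples=amplitude * np.sin(2 * np.pi * freq * t + phase), fs=fs)


@pytest.fixture
def tone_39hz() -> SampledSignal:
    return make_tone(39.0)


@pytest.fixture
def two_tone() -> SampledSignal:
    """13 Hz + 150 Hz mixture over one 200 ms window."""
    t = np.arange(SEGMENT_SAMPLES) / FS
    x = np.sin(2 * np.pi * 13 * t) + np.sin(2 * np.pi * 150 * t)
    return SampledSignal(index=0, start_time=0.0, samples=x, fs=FS)


def small_synth_config(seed: int = 0, **overrides) -> SynthConfig:
    """A 10 s two-zone layout (50 windows) for fast end-to-end tests."""
    defaults = dict(
        total_duration=10.0,
        zones=(
            Zone(name="A", start_s=0.0, end_s=5.0, center_freq=39.0, on_fraction=0.36),
            Zone(name="B", start_s=5.0, end_s=10.0, center_freq=13.0, on_fraction=0.34),
        ),
        min_burst_segments=2,
        max_burst_segments=6,
        seed=seed,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_recording():
    return generate(small_synth_config(seed=3))


@pytest.fixture(scope="session")
def small_decompositions(small_recording):
    from pamdetect.audio import segment

    segs = segment(small_recording.recording, 200.0)
    return [decompose(s) for s in segs]
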