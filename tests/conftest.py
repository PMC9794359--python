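"""Shared fixtures and small constructors for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from snoremetrics import (
    AmplitudeEvent,
    AnalysisConfig,
    DominantFreqTrack,
    EnvelopeTrack,
    SnoreCluster,
)


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


def make_envelope(values, hop: float, t0: float = 0.0,
                  end_time: float | None = None) -> EnvelopeTrack:
    """EnvelopeTrack on a regular grid starting at t0 (window-center times)."""
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) * hop
    if end_time is None:
        end_time = float(times[-1] + hop) if values.size else t0
    return EnvelopeTrack(times=times, values=values, hop=hop, end_time=end_time)


def make_dfreq(freqs, step: float = 0.01, t0: float = 0.0,
               bin_width: float = 44100.0 / 512) -> DominantFreqTrack:
    freqs = np.asarray(freqs, dtype=float)
    times = t0 + np.arange(freqs.size) * step
    return DominantFreqTrack(times=times, freqs=freqs, step=step,
                             bin_width=bin_width)


def events_at(onsets, duration: float = 0.5, peak: float = 1.0):
    """Equal-shaped amplitude events at the given onset times."""
    return [
        AmplitudeEvent(start=float(t), end=float(t) + duration,
                       peak_amplitude=peak, peak_time=float(t))
        for t in onsets
    ]


def span_cluster(start: float, end: float, label: str = "snore") -> SnoreCluster:
    """A one-event cluster covering [start, end), used by merging tests."""
    event = AmplitudeEvent(start=start, end=end, peak_amplitude=1.0,
                           peak_time=start)
    return SnoreCluster(events=(event,), label=label)
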