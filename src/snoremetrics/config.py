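"""Analysis configuration.

All numeric constants of the detection pipeline live here so that a whole
run is reproducible from one frozen object.  Defaults follow the published
workflow this package automates: 600-s analysis segments, a Hilbert
amplitude envelope smoothed by a 1000-sample moving average with 25%
window overlap, amplitude events at 70% of the segment maximum with a
1-ms minimum duration, a 0.01-s dominant-frequency grid, and silent
pauses of at most 100 s absorbed into snore episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ConfigError


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the snore-detection pipeline.

    Parameters
    ----------
    segment_length : float
        Length of one analysis segment in seconds (default 600).
    freq_step : float
        Spacing of the dominant-frequency grid in seconds (default 0.01).
    envelope_window : int
        Moving-average window for envelope smoothing, in samples (default 1000).
    envelope_overlap : float
        Fractional overlap of successive smoothing windows (default 0.25,
        i.e. a hop of 750 samples at the default window).
    amplitude_threshold : float
        Event threshold as a percentage of the segment's maximum envelope
        value (default 70).
    min_event_duration : float
        Minimum duration of an amplitude event in seconds (default 0.001).
    min_event_gap : float
        Events separated by less than this many seconds are coalesced into
        one; snores cannot repeat faster than a breath, so sub-second
        threshold re-crossings belong to the same spike (default 0.5).
    max_episode_gap : float
        Silent pause, in seconds, still absorbed into a snore episode
        (default 100, inclusive).
    max_intra_cluster_gap : float
        Maximum inter-onset gap, in seconds, between events of one cluster
        (default 10 — an upper bound on one breathing cycle).
    min_cluster_events : int
        Minimum number of spikes for a cluster to be a snore candidate
        (default 3).
    max_interval_cv : float
        Maximum coefficient of variation of inter-onset intervals for a
        cluster to count as "near-isometric" (default 0.5).
    band_persistence_min : float
        Minimum fraction of in-event dominant-frequency points a fixed
        frequency band must hold (default 0.30).
    freq_window : int
        FFT frame length for dominant-frequency analysis, in samples
        (default 512; one bin is sample_rate/512 ≈ 86.1 Hz at 44.1 kHz).
    freq_floor : float
        Frames whose peak amplitude is below this fraction of the segment
        maximum report no dominant frequency (default 0.05).
    """

    segment_length: float = 600.0
    freq_step: float = 0.01
    envelope_window: int = 1000
    envelope_overlap: float = 0.25
    amplitude_threshold: float = 70.0
    min_event_duration: float = 0.001
    min_event_gap: float = 0.5
    max_episode_gap: float = 100.0
    max_intra_cluster_gap: float = 10.0
    min_cluster_events: int = 3
    max_interval_cv: float = 0.5
    band_persistence_min: float = 0.30
    freq_window: int = 512
    freq_floor: float = 0.05

    def __post_init__(self) -> None:
        positive = (
            "segment_length",
            "freq_step",
            "envelope_window",
            "min_event_duration",
            "min_event_gap",
            "max_episode_gap",
            "max_intra_cluster_gap",
            "min_cluster_events",
            "max_interval_cv",
            "freq_window",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("envelope_overlap", "band_persistence_min", "freq_floor"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.amplitude_threshold < 100.0:
            raise ConfigError("amplitude_threshold must lie in (0, 100)")
        if self.max_intra_cluster_gap >= self.max_episode_gap:
            raise ConfigError(
                "max_intra_cluster_gap must be smaller than max_episode_gap"
            )

    @property
    def envelope_hop(self) -> int:
        """Hop between smoothing windows, in samples."""
        return int(round((1.0 - self.envelope_overlap) * self.envelope_window))

    def replace(self, **overrides) -> "AnalysisConfig":
        """Return a copy with the given fields overridden (re-validated)."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return AnalysisConfig(**values)
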