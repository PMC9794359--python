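"""Episode assembly: absorb pauses of at most 100 s and report snoring rate.

The whole-night snoring duration is the total time covered by snore
episodes, where an episode is a maximal chain of snore clusters whose
successive silent gaps do not exceed ``max_episode_gap`` (100 s,
inclusive).  Gaps are measured end-of-cluster to start-of-next.  Assembly
operates on recording-global times, so clusters straddling a 600-s
segment cut merge normally.  Time before sleep onset is not excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnalysisConfig
from .detect import NOISE, SNORE, SnoreCluster
from .errors import ConfigError, ConsistencyError

__all__ = ["SnoreEpisode", "RecordingSummary", "merge_episodes",
           "summarize_recording", "merge_spans"]

_EPS = 1e-9


@dataclass(frozen=True)
class SnoreEpisode:
    """A maximal chain of snore clusters with internal gaps <= 100 s."""

    start: float
    end: float
    clusters: tuple[SnoreCluster, ...]
    internal_gap_total: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class RecordingSummary:
    """Whole-recording totals: duration, snoring duration, snoring rate."""

    total_duration: float
    snoring_duration: float
    snoring_rate: float
    n_episodes: int
    n_noise_clusters: int

    def to_dict(self) -> dict:
        return {
            "total_s": self.total_duration,
            "snore_s": self.snoring_duration,
            "rate_pct": self.snoring_rate,
            "n_episodes": self.n_episodes,
            "n_noise_clusters": self.n_noise_clusters,
        }


def merge_spans(
    spans: list[tuple[float, float]], max_gap: float
) -> list[tuple[float, float]]:
    """Merge ordered half-open spans whose gaps are at most ``max_gap``.

    The primitive behind both episode assembly and ground-truth duration:
    consecutive spans with ``next_start - prev_end <= max_gap`` coalesce
    into one span from the first start to the last end.
    """
    merged: list[list[float]] = []
    for start, end in spans:
        if merged and start - merged[-1][1] <= max_gap + _EPS:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def merge_episodes(
    clusters: list[SnoreCluster], cfg: AnalysisConfig | None = None
) -> list[SnoreEpisode]:
    """Merge snore-labeled clusters across gaps of at most 100 s.

    Noise clusters never open nor bridge an episode.  Input clusters must
    be time-ordered.
    """
    cfg = cfg or AnalysisConfig()
    starts = [c.start for c in clusters]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ConsistencyError("clusters must be time-ordered")
    snoring = [c for c in clusters if c.label == SNORE]

    episodes = []
    group: list[SnoreCluster] = []
    for cluster in snoring:
        if group and cluster.start - group[-1].end > cfg.max_episode_gap + _EPS:
            episodes.append(_build_episode(group))
            group = []
        group.append(cluster)
    if group:
        episodes.append(_build_episode(group))
    return episodes


def _build_episode(group: list[SnoreCluster]) -> SnoreEpisode:
    start, end = group[0].start, group[-1].end
    covered = sum(c.duration for c in group)
    return SnoreEpisode(
        start=start,
        end=end,
        clusters=tuple(group),
        internal_gap_total=(end - start) - covered,
    )


def summarize_recording(
    episodes: list[SnoreEpisode],
    total_duration: float,
    clusters: list[SnoreCluster] | None = None,
) -> RecordingSummary:
    """Whole-recording snoring duration and rate from assembled episodes."""
    if total_duration <= 0:
        raise ConfigError("total_duration must be positive")
    for ep in episodes:
        if ep.start < -_EPS or ep.end > total_duration + _EPS:
            raise ConsistencyError(
                f"episode [{ep.start}, {ep.end}) extends beyond the "
                f"{total_duration}-s recording"
            )
    snoring = sum(ep.duration for ep in episodes)
    n_noise = sum(1 for c in (clusters or []) if c.label == NOISE)
    return RecordingSummary(
        total_duration=total_duration,
        snoring_duration=snoring,
        snoring_rate=100.0 * snoring / total_duration,
        n_episodes=len(episodes),
        n_noise_clusters=n_noise,
    )
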