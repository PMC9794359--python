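"""Amplitude events, spike clusters, fixed frequency bands, snore/noise labels.

A snore, on a whole-night spectrogram, is a repeated cluster of
near-isometric amplitude spikes paired with one or more persistent
("fixed") frequency bands; everything else above threshold — footsteps,
doors, water flow, talking — lacks either the repeated amplitudes or the
bands and is labeled noise.  This module operationalizes that visual rule:

* :func:`detect_events` thresholds the smoothed envelope at a percentage of
  the segment maximum and keeps runs longer than a minimum duration;
* :func:`form_clusters` groups events whose onsets follow within one
  breathing cycle and scores how isometric (CV of inter-onset intervals)
  and how ascending–descending (rank correlation with a tent profile) the
  group is;
* :func:`extract_bands` looks for dominant-frequency mass concentrated in a
  narrow bin neighborhood during the cluster's events;
* :func:`classify_cluster` applies the snore criteria (enough spikes,
  near-isometric intervals, at least one band).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .errors import ConsistencyError
from .features import DominantFreqTrack, EnvelopeTrack

__all__ = [
    "AmplitudeEvent",
    "FrequencyBand",
    "SnoreCluster",
    "detect_events",
    "form_clusters",
    "extract_bands",
    "classify_cluster",
]

SNORE = "snore"
NOISE = "noise"


@dataclass(frozen=True)
class AmplitudeEvent:
    """One supra-threshold envelope run (a "spike")."""

    start: float
    end: float
    peak_amplitude: float
    peak_time: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ConsistencyError("event end must exceed start")
        if not self.start <= self.peak_time < self.end:
            raise ConsistencyError("peak_time must lie in [start, end)")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class FrequencyBand:
    """A fixed frequency band: `center` in Hz, `persistence` the fraction
    of in-event dominant-frequency points assigned to it."""

    center: float
    persistence: float


@dataclass(frozen=True)
class SnoreCluster:
    """A group of amplitude events plus the statistics the label rests on.

    `interval_cv` (sample sd / mean of inter-onset intervals) is defined
    only for clusters of >= 3 events.  `trend_score` is the Spearman
    correlation of event peak amplitudes with a symmetric tent profile —
    descriptive of the ascending–descending pattern, never a filter.
    """

    events: tuple[AmplitudeEvent, ...]
    interval_cv: float | None = None
    trend_score: float | None = None
    bands: tuple[FrequencyBand, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.events:
            raise ConsistencyError("a cluster must contain at least one event")
        starts = [e.start for e in self.events]
        ends = [e.end for e in self.events]
        if any(s2 < e1 for e1, s2 in zip(ends, starts[1:])):
            raise ConsistencyError("cluster events must be ordered and disjoint")

    @property
    def start(self) -> float:
        return self.events[0].start

    @property
    def end(self) -> float:
        return self.events[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.start for e in self.events])


def detect_events(
    env: EnvelopeTrack, cfg: AnalysisConfig | None = None
) -> list[AmplitudeEvent]:
    """Threshold the envelope into amplitude events.

    Maximal runs of envelope points at or above
    ``amplitude_threshold/100 × max(env.values)`` become half-open time
    intervals ``[first point, last point + hop)``, clipped to the segment
    end.  Runs shorter than ``min_event_duration`` are dropped; surviving
    events closer than ``min_event_gap`` are coalesced (sub-second
    threshold re-crossings belong to the same snore).  An all-zero
    envelope yields no events.
    """
    cfg = cfg or AnalysisConfig()
    values = env.values
    if values.size == 0 or values.max() <= 0.0:
        return []
    threshold = (cfg.amplitude_threshold / 100.0) * values.max()
    mask = values >= threshold
    if not mask.any():
        return []

    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_starts, run_stops = edges[::2], edges[1::2]  # stop exclusive

    # coalesce runs separated by < min_event_gap before duration filtering
    intervals: list[list[int]] = []
    for i0, i1 in zip(run_starts, run_stops):
        if intervals and env.times[i0] - (env.times[intervals[-1][1] - 1] + env.hop) < cfg.min_event_gap:
            intervals[-1][1] = i1
        else:
            intervals.append([i0, i1])

    events = []
    for i0, i1 in intervals:
        start = env.times[i0]
        end = min(env.times[i1 - 1] + env.hop, env.end_time)
        if end - start < cfg.min_event_duration or end <= start:
            continue
        k = i0 + int(np.argmax(values[i0:i1]))
        events.append(
            AmplitudeEvent(
                start=float(start),
                end=float(end),
                peak_amplitude=float(values[k]),
                peak_time=float(env.times[k]),
            )
        )
    return events


def _tent_profile(n: int) -> np.ndarray:
    """Symmetric ascending–descending template of length n."""
    idx = np.arange(n, dtype=float)
    return np.minimum(idx, (n - 1) - idx)


def _trend_score(peaks: np.ndarray) -> float:
    """Spearman correlation of peak amplitudes with the tent template."""
    if peaks.size < 3:
        return 0.0
    tent = _tent_profile(peaks.size)
    if np.ptp(peaks) == 0 or np.ptp(tent) == 0:
        return 0.0
    rho = stats.spearmanr(peaks, tent).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def form_clusters(
    events: list[AmplitudeEvent], cfg: AnalysisConfig | None = None
) -> list[SnoreCluster]:
    """Group time-ordered events into spike clusters.

    Consecutive events whose inter-onset gap is at most
    ``max_intra_cluster_gap`` share a cluster.  Clusters with fewer than
    ``min_cluster_events`` events are emitted pre-labeled noise; the rest
    carry ``interval_cv`` and ``trend_score`` and are left unlabeled for
    :func:`classify_cluster`.
    """
    cfg = cfg or AnalysisConfig()
    if not events:
        return []
    starts = [e.start for e in events]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ConsistencyError("events must be time-ordered")

    groups: list[list[AmplitudeEvent]] = [[events[0]]]
    for prev, cur in zip(events, events[1:]):
        if cur.start - prev.start <= cfg.max_intra_cluster_gap:
            groups[-1].append(cur)
        else:
            groups.append([cur])

    clusters = []
    for group in groups:
        if len(group) < cfg.min_cluster_events:
            clusters.append(SnoreCluster(events=tuple(group), label=NOISE))
            continue
        onsets = np.array([e.start for e in group])
        intervals = np.diff(onsets)
        cv = float(np.std(intervals, ddof=1) / np.mean(intervals))
        peaks = np.array([e.peak_amplitude for e in group])
        clusters.append(
            SnoreCluster(
                events=tuple(group),
                interval_cv=cv,
                trend_score=_trend_score(peaks),
            )
        )
    return clusters


def extract_bands(
    cluster: SnoreCluster,
    freqs: DominantFreqTrack,
    cfg: AnalysisConfig | None = None,
) -> list[FrequencyBand]:
    """Find fixed frequency bands in a cluster's dominant-frequency points.

    Defined dominant-frequency points falling inside any event of the
    cluster are quantized to FFT-bin-width bins; any bin, merged with its
    immediate neighbors, that holds at least ``band_persistence_min`` of
    the points becomes a band centered on the mean of its member
    frequencies.  Bands are returned sorted by persistence, descending.
    """
    cfg = cfg or AnalysisConfig()
    inside = np.zeros(freqs.times.size, dtype=bool)
    for event in cluster.events:
        lo = np.searchsorted(freqs.times, event.start, side="left")
        hi = np.searchsorted(freqs.times, event.end, side="left")
        inside[lo:hi] = True
    member = freqs.freqs[inside & freqs.defined]
    total = member.size
    if total == 0:
        return []

    bins = np.round(member / freqs.bin_width).astype(np.int64)
    counts = np.bincount(bins)
    order = np.argsort(counts, kind="stable")[::-1]
    used = np.zeros(total, dtype=bool)
    bands = []
    for b in order:
        if counts[b] == 0:
            break
        in_hood = (np.abs(bins - b) <= 1) & ~used
        persistence = in_hood.sum() / total
        if persistence >= cfg.band_persistence_min:
            bands.append(
                FrequencyBand(
                    center=float(member[in_hood].mean()),
                    persistence=float(persistence),
                )
            )
            used |= in_hood
    bands.sort(key=lambda band: band.persistence, reverse=True)
    return bands


def classify_cluster(
    cluster: SnoreCluster, cfg: AnalysisConfig | None = None
) -> SnoreCluster:
    """Label a cluster snore or noise.

    Snore iff the cluster has at least ``min_cluster_events`` events, its
    inter-onset intervals are near-isometric (``interval_cv`` at most
    ``max_interval_cv``), and it shows at least one fixed frequency band.
    Pure function of those three fields; idempotent.
    """
    cfg = cfg or AnalysisConfig()
    is_snore = (
        cluster.n_events >= cfg.min_cluster_events
        and cluster.interval_cv is not None
        and cluster.interval_cv <= cfg.max_interval_cv
        and len(cluster.bands) >= 1
    )
    return dataclasses.replace(cluster, label=SNORE if is_snore else NOISE)
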