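"""End-to-end orchestration: recording -> features -> clusters -> summary.

Feature extraction is per 600-s segment (the amplitude threshold is
relative to each segment's own envelope maximum, so a loud event early in
the night does not mask quiet snoring hours later), while clustering and
episode assembly operate on recording-global times so that snore activity
straddling a segment cut merges normally.

`extract_features` is split from `detect_from_features` so that one
feature pass can serve several detector parameterizations — e.g. two
amplitude thresholds standing in for two human examiners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSegment, segment_audio
from .config import AnalysisConfig
from .detect import (
    AmplitudeEvent,
    SnoreCluster,
    classify_cluster,
    detect_events,
    extract_bands,
    form_clusters,
)
from .episodes import RecordingSummary, SnoreEpisode, merge_episodes, summarize_recording
from .features import DominantFreqTrack, EnvelopeTrack, dominant_frequency, hilbert_envelope

__all__ = ["SegmentFeatures", "AnalysisResult", "extract_features",
           "detect_from_features", "analyze_recording"]

logger = logging.getLogger("snoremetrics")


@dataclass(frozen=True)
class SegmentFeatures:
    """Feature tracks of one analysis segment (global timestamps)."""

    start_time: float
    duration: float
    envelope: EnvelopeTrack
    dfreq: DominantFreqTrack


@dataclass(frozen=True)
class AnalysisResult:
    """Everything one recording analysis produced."""

    summary: RecordingSummary
    episodes: list[SnoreEpisode]
    clusters: list[SnoreCluster]
    events: list[AmplitudeEvent]
    features: list[SegmentFeatures]


def extract_features(
    audio: AudioSegment, cfg: AnalysisConfig | None = None
) -> list[SegmentFeatures]:
    """Cut the recording into segments and compute both feature tracks.

    Trailing segments too short for even one analysis window are skipped
    (they can contribute no events).
    """
    cfg = cfg or AnalysisConfig()
    feats = []
    for i, seg in enumerate(segment_audio(audio, cfg)):
        if seg.n_samples < max(cfg.envelope_window, cfg.freq_window):
            logger.info(
                "segment %d (%.2f s) shorter than one analysis window; skipped",
                i, seg.duration,
            )
            continue
        logger.info("segment %d: features over [%.0f, %.0f) s",
                    i, seg.start_time, seg.end_time)
        feats.append(
            SegmentFeatures(
                start_time=seg.start_time,
                duration=seg.duration,
                envelope=hilbert_envelope(seg, cfg),
                dfreq=dominant_frequency(seg, cfg),
            )
        )
    return feats


def _pooled_dfreq(feats: list[SegmentFeatures], cfg: AnalysisConfig) -> DominantFreqTrack:
    """Concatenate per-segment dominant-frequency tracks into global time."""
    times = np.concatenate([f.dfreq.times for f in feats])
    freqs = np.concatenate([f.dfreq.freqs for f in feats])
    return DominantFreqTrack(
        times=times, freqs=freqs, step=cfg.freq_step,
        bin_width=feats[0].dfreq.bin_width,
    )


def detect_from_features(
    feats: list[SegmentFeatures], cfg: AnalysisConfig | None = None
) -> tuple[list[AmplitudeEvent], list[SnoreCluster]]:
    """Run detection and classification on precomputed feature tracks."""
    cfg = cfg or AnalysisConfig()
    events: list[AmplitudeEvent] = []
    for f in feats:
        events.extend(detect_events(f.envelope, cfg))
    if not events:
        return [], []
    dfreq = _pooled_dfreq(feats, cfg)
    clusters = []
    for cluster in form_clusters(events, cfg):
        if cluster.label is None:
            bands = tuple(extract_bands(cluster, dfreq, cfg))
            cluster = SnoreCluster(
                events=cluster.events,
                interval_cv=cluster.interval_cv,
                trend_score=cluster.trend_score,
                bands=bands,
            )
        clusters.append(classify_cluster(cluster, cfg))
    return events, clusters


def analyze_recording(
    audio: AudioSegment, cfg: AnalysisConfig | None = None
) -> AnalysisResult:
    """Full pipeline: features, events, clusters, episodes, summary."""
    cfg = cfg or AnalysisConfig()
    feats = extract_features(audio, cfg)
    events, clusters = detect_from_features(feats, cfg)
    episodes = merge_episodes(clusters, cfg)
    summary = summarize_recording(episodes, audio.duration, clusters)
    logger.info(
        "recording %.0f s: %d events, %d clusters, %d episodes, rate %.2f%%",
        audio.duration, len(events), len(clusters), len(episodes),
        summary.snoring_rate,
    )
    return AnalysisResult(
        summary=summary,
        episodes=episodes,
        clusters=clusters,
        events=events,
        features=feats,
    )
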