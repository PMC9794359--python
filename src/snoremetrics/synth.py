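"""Seeded synthetic whole-night-like recordings with ground-truth labels.

The generator emulates the morphology the detector is built to recognize:
snore bouts are breathing-periodic trains of harmonic bursts (fundamental
drawn per bout from 110–190 Hz, the typical snoring fundamental range;
raised-cosine burst envelope) whose per-burst peak amplitudes follow a
shallow tent — the ascending–descending, near-isometric pattern of real
snore clusters — and whose spectra therefore show fixed frequency bands at
the harmonics.  Between bouts lie silent gaps drawn from choices that
straddle the 100-s pause rule, so episode merging is exercised on both
sides of the boundary.  Interleaved noise events are aperiodic broadband
transients (footsteps, doors, water flow) with neither periodic onsets nor
stable dominant frequencies.  Everything is driven by one seed: identical
seed and config give bit-identical audio and labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSegment
from .config import AnalysisConfig
from .episodes import merge_spans
from .features import analytic_magnitude
from .errors import ConfigError, FeasibilityError

__all__ = ["SynthConfig", "GroundTruthLabel", "generate_recording",
           "true_snoring_duration"]

SNORE_BOUT = "snore_bout"
NOISE_EVENT = "noise_event"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording generator.

    Durations in seconds, frequencies in Hz.  `snore_fraction` is the
    target fraction of the recording spent inside snore bouts (before the
    100-s-gap merging that defines the snoring duration proper).
    `tent_floor` is the relative amplitude of the quietest burst of a bout
    (0.8 keeps spikes near-isometric while preserving the
    ascending–descending trend).  `background_level` is the RMS of the
    white background noise relative to the loudest burst peak.
    """

    duration: float
    seed: int = 0
    sample_rate: float = 44100.0
    breathing_period: float = 4.0
    breathing_jitter: float = 0.05
    f0_range: tuple[float, float] = (110.0, 190.0)
    n_harmonics: int = 6
    extra_bands: tuple[float, ...] = ()
    burst_duration: float = 1.0
    bout_length_range: tuple[int, int] = (5, 30)
    bout_gap_choices: tuple[float, ...] = (30.0, 90.0, 150.0)
    snore_fraction: float = 0.35
    tent_floor: float = 0.8
    noise_event_rate: float = 2.0
    background_level: float = 0.01

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        nyquist = self.sample_rate / 2.0
        if not 0 < self.f0_range[0] <= self.f0_range[1] < nyquist:
            raise ConfigError("f0_range must lie within (0, sample_rate/2)")
        if any(f <= 0 or f >= nyquist for f in self.extra_bands):
            raise ConfigError("extra_bands must lie within (0, sample_rate/2)")
        if not 0.0 <= self.snore_fraction <= 1.0:
            raise ConfigError("snore_fraction must lie in [0, 1]")
        if not 0.0 < self.tent_floor <= 1.0:
            raise ConfigError("tent_floor must lie in (0, 1]")
        if min(self.noise_event_rate, self.background_level) < 0:
            raise ConfigError("rates and levels must be non-negative")
        if self.breathing_period <= 0 or self.burst_duration <= 0:
            raise ConfigError("breathing_period and burst_duration must be positive")
        if self.burst_duration > self.breathing_period:
            raise ConfigError("burst_duration must not exceed breathing_period")


@dataclass(frozen=True)
class GroundTruthLabel:
    """A labeled interval of the synthetic recording."""

    start: float
    end: float
    kind: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ConfigError("label end must exceed start")


def _check_feasible(cfg: SynthConfig) -> None:
    mean_bout = np.mean(cfg.bout_length_range) * cfg.breathing_period
    achievable = mean_bout / (mean_bout + min(cfg.bout_gap_choices))
    if cfg.snore_fraction > achievable:
        raise FeasibilityError(
            f"snore_fraction {cfg.snore_fraction:.2f} exceeds the "
            f"~{achievable:.2f} achievable with the configured bout lengths "
            f"and gaps"
        )


def _burst(rng: np.random.Generator, cfg: SynthConfig, f0: float,
           phases: np.ndarray, extra_phases: np.ndarray) -> np.ndarray:
    """One harmonic burst under a raised-cosine envelope.

    The burst is normalized by the mean magnitude of its analytic signal
    (its perceived level) rather than its waveform peak: random harmonic
    phases change the crest factor from bout to bout, and amplitude-
    envelope levels — what both human scorers and the detector threshold —
    should be comparable across bouts of one recording.
    """
    m = int(round(cfg.burst_duration * cfg.sample_rate))
    tt = np.arange(m) / cfg.sample_rate
    wave = np.zeros(m)
    for h in range(1, cfg.n_harmonics + 1):
        wave += (1.0 / h) * np.sin(2 * np.pi * h * f0 * tt + phases[h - 1])
    for f_extra, phi in zip(cfg.extra_bands, extra_phases):
        wave += 0.25 * np.sin(2 * np.pi * f_extra * tt + phi)
    level = float(np.mean(analytic_magnitude(wave)))
    if level > 0:
        wave /= level
    return wave * np.hanning(m)


def _tent_amplitudes(n: int, floor: float) -> np.ndarray:
    """Per-burst peak amplitudes rising from `floor` to 1 and back."""
    if n == 1:
        return np.ones(1)
    x = np.arange(n) / (n - 1)
    return floor + (1.0 - floor) * (1.0 - np.abs(2.0 * x - 1.0))


def generate_recording(
    cfg: SynthConfig,
) -> tuple[AudioSegment, list[GroundTruthLabel]]:
    """Synthesize a recording and its ground-truth interval labels.

    Bouts are placed sequentially, separated by gaps drawn from
    ``bout_gap_choices``, until the target ``snore_fraction`` of the
    recording is covered (or the recording ends); broadband noise
    transients arrive at ``noise_event_rate`` per minute at uniform random
    times.  The waveform is peak-normalized to 0.9.
    """
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sample_rate
    n = int(round(cfg.duration * sr))
    x = rng.normal(0.0, cfg.background_level, n) if cfg.background_level > 0 else np.zeros(n)

    labels: list[GroundTruthLabel] = []
    snore_time = 0.0
    t = 0.0
    lo, hi = cfg.bout_length_range
    while t < cfg.duration and snore_time < cfg.snore_fraction * cfg.duration:
        n_breaths = int(rng.integers(lo, hi + 1))
        f0 = rng.uniform(*cfg.f0_range)
        phases = rng.uniform(0, 2 * np.pi, cfg.n_harmonics)
        extra_phases = rng.uniform(0, 2 * np.pi, len(cfg.extra_bands))
        periods = cfg.breathing_period * (
            1.0 + cfg.breathing_jitter * rng.standard_normal(n_breaths)
        )
        periods = np.maximum(periods, cfg.burst_duration)
        onsets = t + np.concatenate(([0.0], np.cumsum(periods[:-1])))
        onsets = onsets[onsets + cfg.burst_duration <= cfg.duration]
        if onsets.size == 0:
            break
        amps = _tent_amplitudes(onsets.size, cfg.tent_floor)
        burst = _burst(rng, cfg, f0, phases, extra_phases)
        for onset, amp in zip(onsets, amps):
            i0 = int(round(onset * sr))
            x[i0 : i0 + burst.size] += amp * burst[: n - i0]
        bout_end = float(onsets[-1]) + cfg.burst_duration
        labels.append(GroundTruthLabel(start=t, end=bout_end, kind=SNORE_BOUT))
        snore_time += bout_end - t
        t = bout_end + float(rng.choice(cfg.bout_gap_choices))

    n_noise = rng.poisson(cfg.noise_event_rate * cfg.duration / 60.0)
    noise_spans = []
    for _ in range(n_noise):
        dur = float(rng.uniform(0.2, 1.5))
        if dur >= cfg.duration:
            dur = cfg.duration / 2.0
        start = float(rng.uniform(0.0, cfg.duration - dur))
        amp = float(rng.uniform(0.5, 0.9))
        m = int(round(dur * sr))
        if m < 2:
            continue
        transient = rng.standard_normal(m)
        transient *= amp / float(np.mean(analytic_magnitude(transient)))
        transient *= np.hanning(m)
        i0 = int(round(start * sr))
        x[i0 : i0 + m] += transient[: n - i0]
        noise_spans.append((start, start + dur))

    # same-kind labels must not overlap; random transients may collide
    noise_spans.sort()
    for start, end in merge_spans(noise_spans, max_gap=0.0):
        labels.append(GroundTruthLabel(start=start, end=end, kind=NOISE_EVENT))
    labels.sort(key=lambda lab: (lab.start, lab.kind))

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioSegment(samples=x, sample_rate=sr, start_time=0.0), labels


def true_snoring_duration(
    labels: list[GroundTruthLabel], cfg: AnalysisConfig | None = None
) -> float:
    """Ground-truth snoring duration under the 100-s pause rule.

    Applies the same gap merging to snore-bout labels that episode
    assembly applies to detected clusters, so recovery tests compare like
    with like.
    """
    cfg = cfg or AnalysisConfig()
    spans = sorted(
        (lab.start, lab.end) for lab in labels if lab.kind == SNORE_BOUT
    )
    merged = merge_spans(spans, cfg.max_episode_gap)
    return float(sum(end - start for start, end in merged))
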