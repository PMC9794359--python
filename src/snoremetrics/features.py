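"""Per-segment feature tracks: smoothed Hilbert envelope and dominant frequency.

The two tracks are the amplitude domain and frequency domain the detection
stage pairs up: the magnitude of the analytic signal, block-averaged over
1000-sample windows at 25% overlap, and the peak spectral bin of a Hann-
windowed 512-sample frame every 0.01 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .audio_io import AudioSegment
from .config import AnalysisConfig
from .errors import ConfigError, DegenerateInputError

__all__ = [
    "EnvelopeTrack",
    "DominantFreqTrack",
    "analytic_magnitude",
    "hilbert_envelope",
    "dominant_frequency",
]

_DFREQ_CHUNK = 8192  # frames per FFT batch; bounds memory at ~64 MB


@dataclass(frozen=True)
class EnvelopeTrack:
    """Smoothed amplitude envelope sampled on a regular grid.

    `times` are absolute seconds (window centers), `values` the windowed
    mean of the analytic-signal magnitude, `hop` the grid spacing in
    seconds, and `end_time` the end of the segment the track was computed
    from (events are clipped to it).
    """

    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    hop: float
    end_time: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ConfigError("times and values must be equal-length 1-D arrays")
        if np.any(values < 0):
            raise ConfigError("envelope values must be non-negative")


@dataclass(frozen=True)
class DominantFreqTrack:
    """Dominant frequency on a regular time grid.

    `freqs` holds the frequency (Hz) of the maximal non-DC spectral bin per
    frame, or NaN where the frame's peak amplitude fell below the silence
    floor ("undefined").  `bin_width` is one FFT bin in Hz.
    """

    times: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    step: float
    bin_width: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "freqs", freqs)
        if times.shape != freqs.shape or times.ndim != 1:
            raise ConfigError("times and freqs must be equal-length 1-D arrays")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of points with a defined dominant frequency."""
        return np.isfinite(self.freqs)


def analytic_magnitude(samples: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude).

    Computed from the one-sided spectrum: rfft, double the strictly
    positive (non-Nyquist) bins, inverse complex FFT.  Identical to the
    textbook construction that zeroes the negative-frequency half of the
    full spectrum.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    if n == 0:
        raise DegenerateInputError("cannot take the analytic signal of an empty array")
    spectrum = scipy.fft.rfft(x)
    full = np.zeros(n, dtype=np.complex128)
    full[: spectrum.size] = spectrum
    full[1 : (n + 1) // 2] *= 2.0  # positive bins; DC and Nyquist unscaled
    return np.abs(scipy.fft.ifft(full))


def hilbert_envelope(
    segment: AudioSegment, cfg: AnalysisConfig | None = None
) -> EnvelopeTrack:
    """Smoothed Hilbert amplitude envelope of one segment.

    The analytic-signal magnitude is block-averaged over windows of
    ``cfg.envelope_window`` samples whose successive windows overlap by
    ``cfg.envelope_overlap`` of the window (hop = 750 samples at defaults);
    each point is timestamped at its window center.

    Raises
    ------
    DegenerateInputError
        If the segment is shorter than one smoothing window.
    """
    cfg = cfg or AnalysisConfig()
    n = segment.n_samples
    window = cfg.envelope_window
    if n < window:
        raise DegenerateInputError(
            f"segment has {n} samples; envelope smoothing needs at least "
            f"{window} (one window)"
        )
    hop = cfg.envelope_hop
    mag = analytic_magnitude(segment.samples)
    n_points = (n - window) // hop + 1
    starts = np.arange(n_points) * hop
    csum = np.concatenate(([0.0], np.cumsum(mag)))
    values = (csum[starts + window] - csum[starts]) / window
    times = segment.start_time + (starts + window / 2.0) / segment.sample_rate
    return EnvelopeTrack(
        times=times,
        values=values,
        hop=hop / segment.sample_rate,
        end_time=segment.end_time,
    )


def dominant_frequency(
    segment: AudioSegment, cfg: AnalysisConfig | None = None
) -> DominantFreqTrack:
    """Dominant frequency every ``cfg.freq_step`` seconds.

    Each grid tick takes a ``cfg.freq_window``-sample Hann-windowed frame
    centered at the tick; frames that would extend past the segment edge
    are skipped.  The reported frequency is the maximal non-DC bin of the
    magnitude spectrum; frames whose peak sample amplitude is below
    ``cfg.freq_floor`` times the segment maximum are NaN ("undefined").
    """
    cfg = cfg or AnalysisConfig()
    n = segment.n_samples
    window = cfg.freq_window
    if n < window:
        raise DegenerateInputError(
            f"segment has {n} samples; dominant-frequency analysis needs at "
            f"least {window} (one frame)"
        )
    sr = segment.sample_rate
    half = window // 2

    # local tick times k*freq_step whose centered frame fits entirely
    n_ticks = int(np.floor(segment.duration / cfg.freq_step)) + 1
    local = np.arange(n_ticks) * cfg.freq_step
    centers = np.round(local * sr).astype(np.int64)
    starts = centers - half
    keep = (starts >= 0) & (starts + window <= n)
    local, starts = local[keep], starts[keep]

    seg_max = float(np.max(np.abs(segment.samples))) if n else 0.0
    floor_amp = cfg.freq_floor * seg_max
    taper = np.hanning(window + 1)[:window]  # periodic Hann
    freq_axis = np.fft.rfftfreq(window, d=1.0 / sr)

    freqs = np.full(local.size, np.nan)
    offsets = np.arange(window)
    for lo in range(0, starts.size, _DFREQ_CHUNK):
        idx = starts[lo : lo + _DFREQ_CHUNK]
        frames = segment.samples[idx[:, None] + offsets]
        peaks = np.max(np.abs(frames), axis=1)
        live = peaks >= floor_amp if seg_max > 0 else np.zeros(idx.size, bool)
        if not np.any(live):
            continue
        spectra = np.abs(scipy.fft.rfft(frames[live] * taper, axis=1))
        best = np.argmax(spectra[:, 1:], axis=1) + 1  # DC excluded
        block = np.full(idx.size, np.nan)
        block[live] = freq_axis[best]
        freqs[lo : lo + _DFREQ_CHUNK] = block

    return DominantFreqTrack(
        times=segment.start_time + local,
        freqs=freqs,
        step=cfg.freq_step,
        bin_width=sr / window,
    )
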