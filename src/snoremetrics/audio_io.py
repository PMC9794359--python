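"""Reading WAV recordings and cutting them into analysis segments.

Input files are uncompressed RIFF/PCM WAV (the recorders of interest write
44.1 kHz, 16-bit linear PCM).  Multi-channel recordings are mixed to mono by
the arithmetic mean of the channels; integer samples are normalized to
[-1, 1] by the type's maximum magnitude, so every downstream threshold is
relative and the absolute recording level is irrelevant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .config import AnalysisConfig
from .errors import ConfigError, FormatError

__all__ = ["AudioSegment", "read_wav", "write_wav", "segment_audio"]

# scale factors for integer PCM -> [-1, 1]
_INT_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass(frozen=True)
class AudioSegment:
    """A contiguous block of mono audio samples.

    Attributes
    ----------
    samples : np.ndarray
        Normalized amplitudes in [-1, 1], float64.
    sample_rate : float
        Sampling rate in Hz.
    start_time : float
        Offset of the first sample from the start of the recording, seconds.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigError("samples must be a non-empty 1-D array")
        if self.start_time < 0:
            raise ConfigError("start_time must be non-negative")
        if not np.all(np.isfinite(samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


def read_wav(path: os.PathLike | str) -> AudioSegment:
    """Read a PCM WAV file as a normalized mono :class:`AudioSegment`.

    Multi-channel files are averaged across channels sample-wise.  Integer
    PCM (8/16/24/32-bit) is scaled to [-1, 1]; float files are clipped to
    that range.

    Raises
    ------
    FileNotFoundError
        If `path` does not exist.
    FormatError
        For compressed (non-PCM) or malformed WAV files.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"cannot read {path!r} as PCM WAV: {exc}") from exc

    data = np.atleast_1d(data)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        mixed = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_SCALE:
        mixed = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        mixed = np.clip(data.astype(np.float64), -1.0, 1.0)
    else:
        raise FormatError(
            f"unsupported WAV sample format {data.dtype} in {path!r}"
        )
    if mixed.ndim == 2:
        mixed = mixed.mean(axis=1)
    return AudioSegment(samples=mixed, sample_rate=float(rate), start_time=0.0)


def write_wav(path: os.PathLike | str, audio: AudioSegment) -> None:
    """Write an :class:`AudioSegment` as 16-bit PCM WAV."""
    clipped = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), int(round(audio.sample_rate)), pcm)


def segment_audio(
    audio: AudioSegment, cfg: AnalysisConfig | None = None
) -> list[AudioSegment]:
    """Cut a recording into consecutive fixed-length analysis segments.

    The segments form a half-open, non-overlapping, exhaustive cover of the
    recording; the final segment may be shorter.  Concatenating the segments
    reproduces the input exactly.
    """
    cfg = cfg or AnalysisConfig()
    chunk = int(round(cfg.segment_length * audio.sample_rate))
    if chunk < 1:
        raise ConfigError("segment_length too small for this sample rate")
    out = []
    for offset in range(0, audio.n_samples, chunk):
        block = audio.samples[offset : offset + chunk]
        out.append(
            AudioSegment(
                samples=block,
                sample_rate=audio.sample_rate,
                start_time=audio.start_time + offset / audio.sample_rate,
            )
        )
    return out
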