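"""Two-panel segment plots: dominant frequency above, envelope below.

Mirrors the visual layout snore scoring is done with: for each analysis
segment the frequency domain (dominant frequency, Hz) is stacked over the
amplitude domain (smoothed Hilbert envelope) on a shared time axis, with
detected amplitude events shaded.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .detect import AmplitudeEvent
from .errors import ConsistencyError
from .features import DominantFreqTrack, EnvelopeTrack

__all__ = ["plot_segment"]


def _overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def plot_segment(
    env: EnvelopeTrack,
    dfreq: DominantFreqTrack,
    events: list[AmplitudeEvent],
    path: os.PathLike | str,
) -> None:
    """Render one segment to a PNG at `path`.

    Raises :class:`ConsistencyError` if the two tracks (or the events) do
    not come from the same stretch of recording.
    """
    if env.times.size == 0 or dfreq.times.size == 0:
        raise ConsistencyError("cannot plot empty feature tracks")
    e_lo, e_hi = float(env.times[0]), float(env.times[-1])
    f_lo, f_hi = float(dfreq.times[0]), float(dfreq.times[-1])
    if not _overlap(e_lo, e_hi, f_lo, f_hi):
        raise ConsistencyError(
            "envelope and dominant-frequency tracks cover disjoint times"
        )
    for ev in events:
        if not _overlap(ev.start, ev.end, e_lo - env.hop, env.end_time):
            raise ConsistencyError(
                f"event [{ev.start}, {ev.end}) lies outside the plotted segment"
            )

    fig, (ax_f, ax_a) = plt.subplots(
        2, 1, sharex=True, figsize=(12, 5), constrained_layout=True
    )
    defined = dfreq.defined
    ax_f.plot(dfreq.times[defined], dfreq.freqs[defined], ".", ms=1.5,
              color="tab:blue")
    ax_f.set_ylabel("dominant frequency (Hz)")
    ax_f.set_ylim(bottom=0)

    ax_a.plot(env.times, env.values, lw=0.6, color="tab:gray")
    for ev in events:
        ax_a.axvspan(ev.start, ev.end, color="tab:orange", alpha=0.35, lw=0)
    ax_a.set_ylabel("envelope amplitude")
    ax_a.set_xlabel("time (s)")
    fig.savefig(os.fspath(path), dpi=110)
    plt.close(fig)
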