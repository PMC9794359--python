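# Methods

## The measurement model

Snoring, acoustically, is breathing-synchronous vibration of upper-airway
soft tissue: a periodic train of short harmonic sound bursts, one per
breath (every ~2–6 s), with a fundamental typically in the 110–190 Hz
range and reported spectral content up to ~5 kHz. On a two-panel
time–frequency/time–amplitude plot a snore bout shows as (i) a cluster of
near-isometric amplitude spikes, usually rising and then falling in height
across the bout, and (ii) one or more narrow, temporally stable ("fixed")
frequency bands. Transient household noises — footsteps, doors, water
flow, talking — produce amplitude excursions too, but with irregular
timing and broadband, unstable spectra. The pipeline encodes exactly this
discrimination and nothing more; it is a transcription of a visual scoring
rule into testable operations, not a learned classifier.

The target quantity is the **snoring rate**: snoring duration over total
recording duration, in percent, where the snoring duration counts snore
episodes *including* silent pauses of at most 100 s between snore clusters
(a snorer who pauses briefly between bouts is still "snoring" for the
purposes of the whole-night total). Time before sleep onset is not
excluded; rates are therefore conservative for recordings that include
extended wakefulness.

## Pipeline stages and their assumptions

1. **Audio input.** PCM WAV, any common bit depth; stereo is mixed to mono
   by channel mean (two-microphone recorders give no principled channel
   preference). Integer samples are normalized by the type's maximum
   magnitude; every later threshold is relative, so absolute gain is
   irrelevant. No resampling, no noise suppression.
2. **Segmentation.** Fixed 600-s segments; the final partial segment is
   processed, not discarded. Feature extraction and event thresholding
   are per-segment; clustering and episode assembly run on
   recording-global times, so activity straddling a cut merges normally.
3. **Envelope.** Magnitude of the analytic signal, computed via
   rfft → one-sided doubling → complex inverse FFT (numerically identical
   to the textbook Hilbert construction; roughly 2.5× faster on 600-s
   segments), then block means over 1000-sample windows with 25% overlap
   (hop 750 samples ≈ 17 ms at 44.1 kHz), timestamped at window centers.
4. **Dominant frequency.** Every 0.01 s, a Hann-windowed 512-sample frame
   centered on the tick (edge-clipped frames skipped, < 6 ms per segment
   edge); the reported frequency is the maximal non-DC bin. The DC bin is
   excluded because a defined dominant frequency must be positive and a
   DC peak carries no pitch. Frames whose peak sample amplitude is below
   5% of the segment maximum are "undefined" — this reproduces the blank
   frequency track during silence. No parabolic interpolation: band
   extraction operates at bin resolution (≈ 86.1 Hz) by design.
5. **Events.** Maximal envelope runs at ≥ 70% of the segment's envelope
   maximum, minimum duration 1 ms. Runs separated by less than
   `min_event_gap` = 0.5 s are coalesced first: residual envelope ripple
   at the snore fundamental (the 22.7-ms smoothing window spans only ~3
   fundamental periods) can split one spike into several crossings
   milliseconds apart, and a snore cannot repeat faster than a breath.
   Without coalescing, those fragments would wreck the inter-onset
   regularity statistic below.
6. **Clusters.** Events whose onsets follow within 10 s — an upper bound
   on one breathing cycle, well below the 100-s episode rule — form a
   cluster. Near-isometry is operationalized as the coefficient of
   variation of inter-onset intervals (sample standard deviation over
   mean, ddof = 1 as in R's `sd`), defined for ≥ 3 events. The
   ascending–descending tendency is reported as a Spearman correlation
   between event peak amplitudes and a symmetric tent profile
   (`trend_score`), but never used as a filter: the pattern is typical,
   not universal, and gating on it would discard real snoring.
7. **Bands.** In-event dominant-frequency points are quantized to FFT
   bins; any bin, merged with its immediate neighbors, holding ≥ 30% of
   the points is a band (greedy, by count, without double-counting
   points). The 30% persistence floor and one-bin neighbor merging are
   this package's reading of "visibly fixed"; both are configurable.
8. **Label.** Snore iff ≥ 3 events, interval CV ≤ 0.5, and ≥ 1 band.
9. **Episodes.** Snore clusters merge across gaps (end-to-start) of at
   most 100 s, inclusive; noise clusters never open or bridge an episode.
   Snoring duration is summed episode time; rate is its percentage of the
   recording.

### Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| segment_length | 600 | s | analysis/plotting unit of the workflow |
| envelope_window / overlap | 1000 / 0.25 | samples / – | envelope smoothing scale |
| amplitude_threshold | 70 | % of segment env. max | spike threshold |
| min_event_duration | 0.001 | s | discard sub-millisecond blips |
| min_event_gap | 0.5 | s | coalesce ripple re-crossings (sub-breath) |
| freq_step / freq_window | 0.01 / 512 | s / samples | dominant-frequency grid and frame |
| freq_floor | 0.05 | fraction of segment max | undefined-frequency floor |
| max_intra_cluster_gap | 10 | s | one breathing cycle, generously |
| min_cluster_events | 3 | count | a cluster is plural spikes |
| max_interval_cv | 0.5 | – | "near-isometric" operationalized |
| band_persistence_min | 0.30 | fraction | "visibly fixed" operationalized |
| max_episode_gap | 100 | s | the pause rule, inclusive |

## The synthetic generator

`snoremetrics.synth` emulates the features the detector keys on, with
every draw controlled by one seed:

* **Bouts**: 5–30 breaths at a 4.0-s breathing period (5% Gaussian
  jitter), each breath a 1-s harmonic burst (fundamental drawn per bout
  from 110–190 Hz, six harmonics at 1/h amplitude, raised-cosine
  envelope). Per-burst peak amplitudes follow a tent from 0.8 up to 1.0
  and back — ascending–descending but near-isometric, matching the
  described morphology; a deeper tent would contradict "near-isometric"
  and starve the relative threshold. Bursts are normalized by their mean
  analytic magnitude (perceived level), not waveform peak, because random
  harmonic phases change the crest factor from bout to bout while
  perceived snore loudness within one night is comparable.
* **Gaps** between bouts are drawn from {30, 90, 150} s — deliberately
  straddling the 100-s rule so merging is exercised on both sides.
* **Noise events**: Poisson-arriving (2/min) broadband transients,
  0.2–1.5 s, at 0.5–0.9 of snore level — aperiodic onsets, scattered
  dominant frequencies.
* **Background**: white noise at 1% RMS of snore level.

Ground-truth snoring duration applies the same 100-s merging to bout
labels that the pipeline applies to detections, so recovery comparisons
are like-for-like.

What the generator does **not** model: realistic snore timbre and its
night-long drift, multiple sleepers, room reverberation, continuous
appliance hum (available as `extra_bands`/config options but off by
default), apnea acoustics, and level drift from posture changes. Passing
recovery tests therefore demonstrates the pipeline's internal
consistency under the stated morphology assumptions — not clinical
performance on real patients.

## Numerical choices

* Analytic signal at exact segment length (no padding), double precision;
  the envelope's windowed means use a cumulative sum (relative error
  ~1e-9 over 26.4 M samples, orders below any threshold decision).
* Event intervals are half-open `[first point, last point + hop)`,
  clipped to the segment end; all times are seconds from recording start.
* A gap of exactly 100 s merges ("no more than 100 s" is inclusive;
  comparisons carry a 1 ns tolerance).
* An all-zero envelope yields no events (a 0% threshold of silence would
  otherwise select everything).
* `interval_cv` for a constant spike train is exactly 0; `trend_score`
  is 0 for constant peaks (rank correlation undefined).
* Frames clipped at segment edges are skipped, not zero-padded.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate with: 20 seeded 1-s
signals against the brute-force envelope oracle; tones at 150/1000/3000 Hz
and a hypothesis sweep over 100 Hz–5 kHz; 1000 random span/gap
configurations against an interval-union oracle; 600-s silence and a
600-s continuous-snore positive control; 20 ten-minute recordings with
bout fractions spread 0–40% (ground-truth rates ~0–70% after merging) for
rate recovery and for the 60-vs-80 threshold ("two examiners") agreement;
and 10 ten-minute noise-only recordings. Ten-minute recordings keep the
full-night morphology (bouts, straddling gaps, transients) while one
recording analyzes in seconds.

## Known limitations

* **Relative thresholds are brittle to a single loud outlier.** The spike
  threshold is a percentage of the *segment's* envelope maximum. If a
  loud transient lands on top of a snore burst, their envelopes add and
  can inflate that maximum by 25% or more, pushing every ordinary burst
  in the same segment below threshold — the higher the threshold, the
  worse (at 80% a single collision can blank a whole 600-s segment; at
  60–70% the damage is partial). In genuine whole-night use the recording
  spans dozens of 600-s segments and a collision poisons only its own
  segment; ten-minute validation recordings are a single segment, which
  makes this failure mode visible in the 60-vs-80 examiner-proxy
  comparison. This is a property of the max-relative threshold rule
  itself, faithfully implemented, and the reason the original visual
  workflow kept a human re-listening step for ambiguous stretches.
* The interval-CV gate assumes reasonably regular breathing; severely
  irregular (e.g. apneic) snoring may be rejected as noise.
* Dominant frequency is bin-resolution (≈ 86 Hz); closely spaced bands
  merge.
* One microphone, one sleeper: snoring from a second person in the room
  is indistinguishable from the subject's.
* Time before sleep onset is counted in the denominator, biasing rates
  downward for recordings with long wake periods.
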