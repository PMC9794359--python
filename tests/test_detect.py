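"""Event thresholding, clustering, band extraction, and classification."""

import dataclasses
import statistics

import numpy as np
import pytest

from snoremetrics import (
    ConsistencyError,
    FrequencyBand,
    SnoreCluster,
    classify_cluster,
    detect_events,
    extract_bands,
    form_clusters,
)

from conftest import events_at, make_dfreq, make_envelope


class TestDetectEvents:
    def test_single_plateau(self, cfg):
        """A plateau at >= 70% of the maximum becomes one event."""
        hop = 0.01
        values = np.full(300, 0.1)
        values[100:200] = 1.0  # t in [1.0, 2.0)
        events = detect_events(make_envelope(values, hop), cfg)
        assert len(events) == 1
        ev = events[0]
        assert ev.start == pytest.approx(1.0, abs=hop)
        assert ev.end == pytest.approx(2.0, abs=2 * hop)
        assert ev.peak_amplitude == 1.0
        assert ev.start <= ev.peak_time < ev.end

    def test_five_equal_bumps(self, cfg):
        hop = 0.01
        values = np.full(500, 0.05)
        starts = [50, 140, 230, 320, 410]
        for s in starts:
            values[s : s + 30] = 1.0
        events = detect_events(make_envelope(values, hop), cfg)
        assert len(events) == 5
        for ev, s in zip(events, starts):
            assert ev.start == pytest.approx(s * hop, abs=hop)

    def test_sub_dmin_run_discarded(self, cfg):
        """An isolated supra-threshold point narrower than dmin vanishes."""
        hop = 0.0001  # run duration 0.1 ms < min_event_duration 1 ms
        values = np.full(20000, 0.1)
        values[10000] = 1.0
        assert detect_events(make_envelope(values, hop), cfg) == []

    def test_all_zero_envelope(self, cfg):
        assert detect_events(make_envelope(np.zeros(100), 0.01), cfg) == []

    def test_close_crossings_coalesce(self, cfg):
        """Threshold re-crossings separated by < min_event_gap merge."""
        hop = 0.01
        values = np.full(400, 0.1)
        values[100:120] = 1.0
        values[125:145] = 1.0  # 0.05-s dip, same snore
        values[300:320] = 1.0  # 1.55 s later, separate event
        events = detect_events(make_envelope(values, hop), cfg)
        assert len(events) == 2
        assert events[0].end - events[0].start == pytest.approx(0.45, abs=2 * hop)

    def test_events_disjoint_and_ordered(self, cfg):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(size=3000))
        events = detect_events(make_envelope(values, 0.01), cfg)
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start

    @pytest.mark.parametrize("seed", range(4))
    def test_raising_threshold_never_increases_event_time(self, seed, cfg):
        rng = np.random.default_rng(seed)
        # smooth positive envelope with multiple excursions
        raw = np.abs(np.convolve(rng.normal(size=4000), np.ones(80) / 80,
                                 mode="same"))
        track = make_envelope(raw, 0.01)
        totals = []
        for thr in (30.0, 50.0, 70.0, 90.0):
            events = detect_events(track, cfg.replace(amplitude_threshold=thr))
            totals.append(sum(e.duration for e in events))
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestFormClusters:
    def test_perfectly_isometric_onsets(self, cfg):
        clusters = form_clusters(events_at([0, 4, 8, 12, 16]), cfg)
        assert len(clusters) == 1
        assert clusters[0].interval_cv == 0.0
        assert clusters[0].label is None

    def test_distant_singletons_prelabeled_noise(self, cfg):
        clusters = form_clusters(events_at([0, 30]), cfg)
        assert [c.label for c in clusters] == ["noise", "noise"]
        assert all(c.interval_cv is None for c in clusters)

    def test_interval_cv_matches_direct_formula(self, cfg):
        """Onsets 0, 2, 9 form one cluster; its CV equals sd/mean of {2, 7}."""
        clusters = form_clusters(events_at([0, 2, 9]), cfg)
        assert len(clusters) == 1
        expected = statistics.stdev([2.0, 7.0]) / statistics.mean([2.0, 7.0])
        assert clusters[0].interval_cv == pytest.approx(expected)

    def test_gap_rule_splits_groups(self, cfg):
        clusters = form_clusters(events_at([0, 4, 8, 30, 34, 38]), cfg)
        assert len(clusters) == 2
        assert all(c.n_events == 3 for c in clusters)

    def test_tent_shaped_peaks_score_high(self, cfg):
        events = [
            dataclasses.replace(e, peak_amplitude=p)
            for e, p in zip(events_at([0, 4, 8, 12, 16]),
                            [0.5, 0.8, 1.0, 0.8, 0.5])
        ]
        clusters = form_clusters(events, cfg)
        assert clusters[0].trend_score > 0.8

    def test_unordered_events_rejected(self, cfg):
        with pytest.raises(ConsistencyError):
            form_clusters(events_at([4, 0]), cfg)

    def test_clusters_partition_events(self, cfg):
        rng = np.random.default_rng(9)
        onsets = np.cumsum(rng.uniform(0.6, 20.0, 50))
        events = events_at(onsets)
        clusters = form_clusters(events, cfg)
        flattened = [e for c in clusters for e in c.events]
        assert flattened == events


class TestExtractBands:
    def _cluster(self, span=10.0):
        return SnoreCluster(events=tuple(events_at([0.0], duration=span)))

    def test_constant_frequency_single_band(self, cfg):
        track = make_dfreq(np.full(1000, 140.0))
        bands = extract_bands(self._cluster(), track, cfg)
        assert len(bands) == 1
        assert bands[0].center == pytest.approx(140.0)
        assert bands[0].persistence == 1.0

    def test_two_bands_sorted_by_persistence(self, cfg):
        freqs = np.array([150.0] * 600 + [450.0] * 400)
        bands = extract_bands(self._cluster(), make_dfreq(freqs), cfg)
        assert len(bands) == 2
        assert bands[0].center == pytest.approx(150.0)
        assert bands[0].persistence == pytest.approx(0.6)
        assert bands[1].center == pytest.approx(450.0)
        assert bands[1].persistence == pytest.approx(0.4)

    def test_uniform_scatter_yields_no_bands(self, cfg):
        rng = np.random.default_rng(13)
        freqs = rng.uniform(50.0, 5000.0, 1000)
        track = make_dfreq(freqs)
        # counting oracle: no 3-bin neighborhood reaches 30%
        bins = np.round(freqs / track.bin_width).astype(int)
        counts = np.bincount(bins)
        padded = np.concatenate(([0], counts, [0]))
        triple = padded[:-2] + padded[1:-1] + padded[2:]
        assert triple.max() / 1000 < cfg.band_persistence_min
        assert extract_bands(self._cluster(), track, cfg) == []

    def test_only_in_event_points_count(self, cfg):
        """Frequency mass outside the cluster's events is ignored."""
        freqs = np.full(1000, 140.0)
        freqs[500:] = np.nan  # after the event, undefined anyway
        cluster = SnoreCluster(events=tuple(events_at([0.0], duration=2.0)))
        bands = extract_bands(cluster, make_dfreq(freqs), cfg)
        assert len(bands) == 1
        assert bands[0].persistence == 1.0  # of the 200 in-event points

    def test_no_defined_points_no_bands(self, cfg):
        track = make_dfreq(np.full(100, np.nan))
        assert extract_bands(self._cluster(), track, cfg) == []


class TestClassifyCluster:
    def _candidate(self, n_events=5, cv=0.0, bands=(FrequencyBand(140.0, 0.9),)):
        return SnoreCluster(
            events=tuple(events_at(np.arange(n_events) * 4.0)),
            interval_cv=cv,
            trend_score=0.5,
            bands=tuple(bands),
        )

    def test_all_criteria_met_is_snore(self, cfg):
        assert classify_cluster(self._candidate(), cfg).label == "snore"

    def test_irregular_intervals_are_noise(self, cfg):
        assert classify_cluster(self._candidate(cv=0.9), cfg).label == "noise"

    def test_missing_bands_are_noise(self, cfg):
        assert classify_cluster(self._candidate(bands=()), cfg).label == "noise"

    def test_too_few_events_are_noise(self, cfg):
        cluster = SnoreCluster(events=tuple(events_at([0.0, 4.0])),
                               interval_cv=0.0,
                               bands=(FrequencyBand(140.0, 0.9),))
        assert classify_cluster(cluster, cfg).label == "noise"

    def test_idempotent(self, cfg):
        once = classify_cluster(self._candidate(), cfg)
        assert classify_cluster(once, cfg) == once

    def test_label_ignores_unrelated_fields(self, cfg):
        """Pure function of (event count, interval_cv, bands): perturbing
        the trend score never flips the label."""
        base = self._candidate()
        for trend in (-1.0, 0.0, 1.0):
            perturbed = dataclasses.replace(base, trend_score=trend)
            assert classify_cluster(perturbed, cfg).label == "snore"
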