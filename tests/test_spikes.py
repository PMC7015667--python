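"""Burst classification, detection, and spike-train metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prehear.spikes import (
    BURST_MAX_S,
    MINI_BURST_MAX_S,
    SpikeTrain,
    bin_firing_rate,
    burst_metrics,
    classify_isis,
    detect_bursts,
    detect_spikes,
    isi_log_histogram,
)
from prehear.synth import SpikeGenSpec, gen_spike_train, render_spike_trace

# ISI values representative of each class, used to build trains from labels
ISI_FOR_LABEL = {"non_burst": 1.5, "burst": 0.1, "mini_burst": 0.01}


def train_from_labels(labels):
    isis = np.array([ISI_FOR_LABEL[l] for l in labels])
    times = np.concatenate([[1.0], 1.0 + np.cumsum(isis)])
    return SpikeTrain(times, times[-1] + 1.0)


def brute_force_bursts(labels, min_burst=10):
    """Independent oracle: exhaustive scan of label runs.

    Splits the label sequence at non-burst intervals and keeps every
    segment containing >= min_burst burst labels; returns
    (first_spike_idx, last_spike_idx, n_spikes) per qualifying run.
    """
    segments, cur = [], []
    for idx, lab in enumerate(labels):
        if lab == "non_burst":
            if cur:
                segments.append(cur)
            cur = []
        else:
            cur.append(idx)
    if cur:
        segments.append(cur)
    out = []
    for seg in segments:
        n_burst = sum(1 for i in seg if labels[i] == "burst")
        if n_burst >= min_burst:
            out.append((seg[0], seg[-1] + 1, seg[-1] + 1 - seg[0] + 1))
    return out


class TestClassifyISIs:
    @pytest.mark.parametrize(
        "isi,label",
        [
            (0.5, "burst"),
            (2.0, "non_burst"),
            (0.010, "mini_burst"),
            (MINI_BURST_MAX_S, "burst"),  # closed lower edge of the burst class
            (BURST_MAX_S, "burst"),  # closed upper edge
            (BURST_MAX_S + 1e-6, "non_burst"),
        ],
    )
    def test_interval_classes(self, isi, label):
        train = SpikeTrain(np.array([1.0, 1.0 + isi]), 5.0)
        cls = classify_isis(train)
        assert list(cls.labels) == [label]

    def test_partition_is_total(self, rng):
        isis = rng.uniform(1e-4, 3.0, 500)
        times = np.concatenate([[0.1], 0.1 + np.cumsum(isis)])
        cls = classify_isis(SpikeTrain(times, times[-1] + 1))
        assert len(cls.labels) == len(times) - 1
        assert set(cls.labels) <= {"burst", "non_burst", "mini_burst"}

    def test_single_spike_yields_empty_classification(self):
        cls = classify_isis(SpikeTrain(np.array([1.0]), 5.0))
        assert len(cls.labels) == 0


class TestDetectBursts:
    def test_eleven_spikes_regular(self):
        times = 1.0 + 0.1 * np.arange(11)
        bursts = detect_bursts(classify_isis(SpikeTrain(times, 10.0)))
        assert len(bursts) == 1
        b = bursts[0]
        assert b.n_spikes == 11
        assert b.duration == pytest.approx(1.0)

    def test_ten_spikes_below_rule(self):
        times = 1.0 + 0.1 * np.arange(10)  # only 9 burst intervals
        assert detect_bursts(classify_isis(SpikeTrain(times, 10.0))) == []

    def test_mini_burst_neither_breaks_nor_counts(self):
        # burst x5, mini, burst x5 -> 10 qualifying intervals over 12 spikes
        labels = ["burst"] * 5 + ["mini_burst"] + ["burst"] * 5
        train = train_from_labels(labels)
        bursts = detect_bursts(classify_isis(train))
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 12
        # but with one fewer burst interval the mini-burst must not rescue it
        labels = ["burst"] * 5 + ["mini_burst"] + ["burst"] * 4
        assert detect_bursts(classify_isis(train_from_labels(labels))) == []

    def test_non_burst_terminates_run(self):
        labels = ["burst"] * 9 + ["non_burst"] + ["burst"] * 9
        assert detect_bursts(classify_isis(train_from_labels(labels))) == []

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sampled_from(["burst", "non_burst", "mini_burst"]),
            min_size=1,
            max_size=60,
        )
    )
    def test_agrees_with_brute_force_oracle(self, labels):
        train = train_from_labels(labels)
        got = detect_bursts(classify_isis(train))
        expected = brute_force_bursts(labels)
        assert len(got) == len(expected)
        for b, (i0, i1, n) in zip(got, expected):
            assert b.start == pytest.approx(train.times[i0])
            assert b.end == pytest.approx(train.times[i1])
            assert b.n_spikes == n

    def test_time_shift_invariance(self, rng):
        labels = rng.choice(["burst", "non_burst", "mini_burst"], 80).tolist()
        train = train_from_labels(labels)
        b0 = detect_bursts(classify_isis(train))
        b1 = detect_bursts(classify_isis(train.shifted(7.5)))
        assert len(b0) == len(b1)
        for a, b in zip(b0, b1):
            assert b.start == pytest.approx(a.start + 7.5)
            assert b.end == pytest.approx(a.end + 7.5)
            assert b.n_spikes == a.n_spikes

    def test_merge_of_silence_separated_trains(self):
        t1 = 1.0 + 0.1 * np.arange(12)
        t2 = 10.0 + 0.1 * np.arange(15)
        merged = SpikeTrain(np.concatenate([t1, t2]), 20.0)
        bursts = detect_bursts(classify_isis(merged))
        parts = detect_bursts(classify_isis(SpikeTrain(t1, 5.0))) + detect_bursts(
            classify_isis(SpikeTrain(t2, 15.0))
        )
        assert [(b.start, b.end, b.n_spikes) for b in bursts] == [
            (b.start, b.end, b.n_spikes) for b in parts
        ]


class TestBurstMetrics:
    def test_burst_frequency_per_minute(self):
        times = 1.0 + 0.1 * np.arange(11)
        train = SpikeTrain(times, 300.0)
        bursts = detect_bursts(classify_isis(train))
        m = burst_metrics(bursts * 5, train, 300.0)
        assert m.burst_freq == pytest.approx(1.0)

    def test_periodic_train_cv_zero(self):
        train = SpikeTrain(0.5 + 0.25 * np.arange(100), 30.0)
        m = burst_metrics([], train, 30.0)
        assert m.isi_cv == 0.0
        assert m.mean_duration is None and m.mean_spikes_per_burst is None

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(7)
        isis = rng.exponential(0.1, 10_000)
        times = np.cumsum(isis)
        train = SpikeTrain(times, times[-1] + 1)
        m = burst_metrics([], train, train.duration)
        assert m.isi_cv == pytest.approx(1.0, abs=0.05)

    def test_mean_ap_freq_counts_all_spikes(self):
        train = SpikeTrain(np.linspace(0.1, 99.9, 200), 100.0)
        m = burst_metrics([], train, 100.0)
        assert m.mean_ap_freq == pytest.approx(2.0)


class TestHistogramAndRate:
    def test_single_isi_lands_in_one_bin(self):
        train = SpikeTrain(np.array([1.0, 1.1]), 5.0)
        counts, edges = isi_log_histogram(train)
        assert counts.sum() == 1
        k = counts.argmax()
        assert edges[k] <= 0.1 <= edges[k + 1]

    def test_counts_match_direct_tally(self, rng):
        isis = rng.uniform(0.0005, 20.0, 400)
        times = np.concatenate([[0.1], 0.1 + np.cumsum(isis)])
        train = SpikeTrain(times, times[-1] + 1)
        counts, _ = isi_log_histogram(train, isi_range=(0.001, 10.0))
        direct = np.sum((train.isis >= 0.001) & (train.isis <= 10.0))
        assert counts.sum() == direct

    def test_geometric_edges(self):
        train = SpikeTrain(np.array([1.0, 1.1]), 5.0)
        _, edges = isi_log_histogram(train, bins_per_decade=5, isi_range=(0.01, 1.0))
        ratios = edges[1:] / edges[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_rate_vector_sums_to_spike_count(self, rng):
        times = np.sort(rng.uniform(0, 9.99, 37))
        times = np.unique(times)
        train = SpikeTrain(times, 10.0)
        rate = bin_firing_rate(train, 1.0)
        assert rate.size == 10
        assert rate.sum() * 1.0 == len(train)

    def test_empty_train_zero_rates(self):
        rate = bin_firing_rate(SpikeTrain(np.empty(0), 5.0), 1.0)
        assert rate.shape == (5,) and not rate.any()


class TestDetectSpikes:
    def test_recovers_injected_spike_times(self, rng):
        times = np.sort(rng.uniform(0.5, 9.5, 20))
        train = SpikeTrain(times, 10.0)
        x = render_spike_trace(train, rate_hz=5000, noise_sd=0.02, seed=3)
        det = detect_spikes(x, 5000)
        assert len(det) == 20
        assert np.max(np.abs(det.times - times)) <= 2 / 5000

    def test_flat_trace_no_spikes(self):
        det = detect_spikes(np.zeros(5000), 5000.0)
        assert len(det) == 0

    def test_threshold_insensitive_on_clean_train(self, rng):
        times = np.sort(rng.uniform(0.5, 9.5, 15))
        x = render_spike_trace(SpikeTrain(times, 10.0), rate_hz=5000, noise_sd=0.01, seed=4)
        n4 = len(detect_spikes(x, 5000, threshold_k=4))
        n6 = len(detect_spikes(x, 5000, threshold_k=6))
        assert n4 == n6 == 15

    def test_empty_trace_is_an_error(self):
        with pytest.raises(ValueError):
            detect_spikes(np.empty(0), 5000.0)


class TestGenerator:
    def test_forced_schedule_yields_expected_bursts(self):
        spec = SpikeGenSpec(
            duration=600, burst_rate=1.0, spikes_per_burst=15, tonic_rate=0.0, seed=11
        )
        train, log = gen_spike_train(spec)
        assert 5 <= len(log) <= 16  # ~10 expected
        isis = train.isis
        # intra-burst ISIs only (no tonic spikes): all in the burst class
        within = isis[isis <= 1.0]
        assert within.size and within.min() >= 0.03

    def test_all_rates_zero_empty_train(self):
        train, log = gen_spike_train(
            SpikeGenSpec(duration=100, burst_rate=0, tonic_rate=0, seed=1)
        )
        assert len(train) == 0 and len(log) == 0

    def test_seed_determinism(self):
        spec = SpikeGenSpec(duration=300, burst_rate=2, seed=7, mini_burst_prob=0.1)
        t1, l1 = gen_spike_train(spec)
        t2, l2 = gen_spike_train(spec)
        assert np.array_equal(t1.times, t2.times)
        assert l1.events == l2.events

    def test_ground_truth_matches_detector(self):
        spec = SpikeGenSpec(duration=600, burst_rate=2, tonic_rate=0.0, seed=5)
        train, log = gen_spike_train(spec)
        bursts = detect_bursts(classify_isis(train))
        assert len(bursts) == len(log)
        for b, ev in zip(bursts, log.events):
            assert b.start == pytest.approx(ev["start"])
            assert b.n_spikes == ev["n_spikes"]
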