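import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meamicro as mm
from oracles import bursts_reference, spike_contrast_reference


class TestISIHistogram:
    def test_constant_isi(self):
        h = mm.isi_histogram(np.array([0.0, 0.010, 0.020, 0.030]))
        assert h.n_isi == 3
        assert h.counts[10] == 3  # all three 10 ms intervals in one bin

    def test_single_spike_empty(self):
        assert mm.isi_histogram(np.array([0.5])).n_isi == 0

    def test_overflow_pooled(self):
        h = mm.isi_histogram(np.array([0.0, 2.5]), max_isi_ms=1000)
        assert h.n_isi == 1 and h.counts[-1] == 1

    def test_poisson_isi_mean(self, rng):
        t = np.cumsum(rng.exponential(0.1, 10_000))
        h = mm.isi_histogram(t, max_isi_ms=2000)
        centers = np.append(h.bin_edges_ms[:-1] + 0.5, 2000.0)
        mean_ms = np.sum(centers * h.counts) / h.n_isi
        assert mean_ms == pytest.approx(100.0, abs=5.0)


class TestKLDivergence:
    def test_identity_zero(self):
        p = mm.ISIHistogram([0, 1, 2], [3, 5, 0])
        assert mm.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        p = mm.ISIHistogram([0, 1, 2], [2, 2, 0])
        q = mm.ISIHistogram([0, 1, 2], [1, 3, 0])
        expect = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)  # 0.1438 nats
        assert mm.kl_divergence(p, q, epsilon=0) == pytest.approx(expect)

    def test_asymmetry(self):
        p = mm.ISIHistogram([0, 1, 2], [2, 2, 0])
        q = mm.ISIHistogram([0, 1, 2], [1, 3, 0])
        rev = mm.kl_divergence(q, p, epsilon=0)
        assert rev == pytest.approx(0.25 * np.log(0.5) + 0.75 * np.log(1.5))
        assert rev != mm.kl_divergence(p, q, epsilon=0)

    def test_incompatible_binning(self):
        p = mm.ISIHistogram([0, 1, 2], [1, 1, 0])
        q = mm.ISIHistogram([0, 2, 4], [1, 1, 0])
        with pytest.raises(ValueError, match="incompatible"):
            mm.kl_divergence(p, q)

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4),
           st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_nonnegative(self, cp, cq):
        if sum(cp) == 0 or sum(cq) == 0:
            return
        p = mm.ISIHistogram([0, 1, 2, 3], cp)
        q = mm.ISIHistogram([0, 1, 2, 3], cq)
        assert mm.kl_divergence(p, q) >= -1e-12


class TestConditionDivergence:
    @staticmethod
    def _poisson_set(rate, duration, seed):
        cfg = mm.SimConfig(n_neurons=1, duration=duration, mean_rate=rate,
                           burst_rate=0.0, refractory_ms=0.0, seed=seed)
        sts, _ = mm.simulate_spike_trains(cfg)
        return mm.SpikeTrainSet({"e0": sts.train("n0")}, duration)

    @staticmethod
    def _bursty_set(duration, seed):
        # burst_rate x spikes_per_burst = 1 x 5 = 5 Hz mean, same as Poisson
        cfg = mm.SimConfig(n_neurons=1, duration=duration, mean_rate=0.0,
                           burst_rate=1.0, spikes_per_burst=5, seed=seed)
        sts, _ = mm.simulate_spike_trains(cfg)
        return mm.SpikeTrainSet({"e0": sts.train("n0")}, duration)

    def test_sparse_electrode_excluded(self, rng):
        few = np.sort(rng.uniform(0, 100, 301))      # 300 ISIs: excluded
        many = np.sort(rng.uniform(0, 100, 1000))
        base = mm.SpikeTrainSet({"a": few, "b": many}, 100.0)
        treat = mm.SpikeTrainSet({"a": many + 1e-4, "b": few + 1e-4}, 101.0)
        df = mm.condition_divergence(mm.ConditionPair(base, treat))
        assert not df.set_index("electrode").loc["a", "included"]
        assert np.isnan(df.set_index("electrode").loc["a", "kl_nats"])

    def test_regime_change_exceeds_within_condition(self):
        duration = 200.0
        for seed in range(3):
            base = self._poisson_set(5.0, duration, seed)
            within = self._poisson_set(5.0, duration, seed + 100)
            between = self._bursty_set(duration, seed + 200)
            kl_within = mm.condition_divergence(
                mm.ConditionPair(base, within))["kl_nats"].iloc[0]
            kl_between = mm.condition_divergence(
                mm.ConditionPair(base, between))["kl_nats"].iloc[0]
            assert kl_between > kl_within


class TestSpikeContrast:
    def test_identical_regular_trains_perfectly_synchronous(self):
        # 0.5 s period, spikes interior to the observation window so no
        # cluster is clipped at the span edges
        t = 1.0 + 0.5 * np.arange(199)
        assert mm.spike_contrast([t] * 4, t_start=0.0, t_stop=101.0) == \
            pytest.approx(1.0)

    def test_independent_trains_low(self, rng):
        trains = [np.sort(rng.uniform(0, 300, 1500)) for _ in range(4)]
        assert mm.spike_contrast(trains) < 0.3

    def test_constant_lag_near_independent_level(self, rng):
        t = np.sort(rng.uniform(0, 300, 1500))
        indep = [np.sort(rng.uniform(0, 300, 1500)) for _ in range(2)]
        lagged_s = mm.spike_contrast([t, t + 2.0])
        indep_s = mm.spike_contrast(indep)
        assert lagged_s < 2 * indep_s  # same order of magnitude, far from 1

    def test_needs_two_trains(self):
        with pytest.raises(ValueError):
            mm.spike_contrast([np.array([1.0, 2.0])])

    def test_matches_reference_implementation(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 5))
            trains = [np.sort(rng.uniform(0, 2.0, int(rng.integers(5, 30))))
                      for _ in range(n)]
            mine = mm.spike_contrast(trains, t_start=0.0, t_stop=2.0,
                                     min_bin_s=0.02)
            ref = spike_contrast_reference(trains, 0.0, 2.0, min_bin_s=0.02)
            assert mine == pytest.approx(ref, abs=1e-6)


class TestParticipationRatio:
    def test_identical_trains_rank_one(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        assert mm.participation_ratio([t] * 4, duration=100.0) == \
            pytest.approx(0.25, abs=1e-9)

    def test_independent_trains_near_one(self, rng):
        trains = [np.sort(rng.uniform(0, 600, 3000)) for _ in range(4)]
        assert mm.participation_ratio(trains, duration=600.0) == \
            pytest.approx(1.0, abs=0.05)

    def test_single_train_is_one(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        assert mm.participation_ratio([t], duration=10.0) == 1.0

    def test_zero_variance_channel_dropped_with_warning(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        with pytest.warns(UserWarning, match="zero-variance"):
            pr = mm.participation_ratio([t, t, np.empty(0)], duration=100.0)
        assert pr == pytest.approx(0.5, abs=1e-9)  # two identical trains


class TestBursts:
    def test_three_spike_burst(self):
        b = mm.detect_bursts(np.array([0.0, 0.005, 0.009]))
        assert len(b) == 1
        assert b[0].n_spikes == 3
        assert b[0].duration == pytest.approx(0.009)

    def test_slow_firing_no_bursts(self):
        assert mm.detect_bursts(np.arange(0, 2, 0.1)) == []

    def test_merge_below_min_ibi(self):
        t = np.array([0.0, 0.005, 0.009, 0.159, 0.164, 0.169])
        merged = mm.detect_bursts(t)
        assert len(merged) == 1 and merged[0].n_spikes == 6
        t2 = np.array([0.0, 0.005, 0.009, 0.309, 0.314, 0.319])
        assert len(mm.detect_bursts(t2)) == 2

    def test_equals_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 25))
            scale = rng.choice([0.004, 0.02, 0.15])
            t = np.unique(np.cumsum(rng.exponential(scale, n)))
            mine = [(b.start, b.end, b.n_spikes)
                    for b in mm.detect_bursts(t)]
            ref = [(pytest.approx(s), pytest.approx(e), n_)
                   for s, e, n_ in bursts_reference(t)]
            assert mine == ref


class TestNetworkBursts:
    def test_onsets_within_window(self):
        bs = {c: [mm.Burst(o, o + 0.01, 3, c)]
              for c, o in [("a", 0.0), ("b", 0.002), ("c", 0.004)]}
        nb = mm.detect_network_bursts(bs)
        assert len(nb) == 1 and nb[0].time == 0.0

    def test_span_exceeding_window(self):
        bs = {c: [mm.Burst(o, o + 0.01, 3, c)]
              for c, o in [("a", 0.0), ("b", 0.002), ("c", 0.008)]}
        assert mm.detect_network_bursts(bs) == []

    def test_burst_free_electrode_blocks_all(self):
        bs = {"a": [mm.Burst(0.0, 0.01, 3)], "b": [mm.Burst(0.001, 0.01, 3)],
              "c": []}
        assert mm.detect_network_bursts(bs, electrodes=["a", "b", "c"]) == []


class TestRatesAndDirectionality:
    def test_firing_rate(self, rng):
        assert mm.firing_rate(np.zeros(600), 100.0) == 6.0
        assert mm.firing_rate(np.empty(0), 10.0) == 0.0
        t = np.cumsum(rng.exponential(0.2, 1000))
        t = t[t < 200.0]
        assert mm.firing_rate(t, 200.0) == pytest.approx(5.0, abs=0.5)

    def test_shifted_train_peak_lag(self, rng):
        a = np.sort(rng.uniform(0, 100, 500))
        lag, asym = mm.directionality(a, a + 0.002, duration=101.0)
        assert lag == pytest.approx(2.0, abs=1.0)
        assert asym > 0

    def test_autocorrelation_symmetric(self, rng):
        a = np.sort(rng.uniform(0, 100, 500))
        lag, asym = mm.directionality(a, a, duration=100.0)
        assert lag == 0.0
        assert abs(asym) < 0.1

    def test_independent_pairs_null(self):
        ok = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = np.sort(r.uniform(0, 100, 500))
            b = np.sort(r.uniform(0, 100, 500))
            _, asym = mm.directionality(a, b, duration=100.0)
            ok += abs(asym) < 0.1
        assert ok >= 9


def test_synchrony_summary_fields(sim_circuit):
    _, _, _, sts, _ = sim_circuit
    s = mm.synchrony_summary(sts)
    assert 0 < s.spike_contrast <= 1
    assert 0 < s.participation_ratio <= 1
    assert s.mean_firing_rate_hz > 0
    assert s.n_electrodes == 2
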