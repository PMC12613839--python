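import numpy as np
import pandas as pd
import pytest

import meamicro as mm
from conftest import render_events

FS = 25_000.0


def _spiky_recording(peaks, duration=5.0, noise_sd=4.0, t0=0.0, seed=0):
    """Single-channel recording with injected narrow troughs.

    ``peaks`` is a list of (time_s, amplitude_uv) with amplitude < 0.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    x = rng.normal(0, noise_sd, n)
    for t, amp in peaks:
        i = int(round((t - t0) * FS))
        x[i - 3:i + 4] += amp * np.hanning(7)
    return mm.Recording(x[None, :], FS, ["e0"], t0=t0)


class TestResponseGates:
    def test_clear_peak_accepted_with_latency(self):
        rec = _spiky_recording([(1.020, -80.0)])
        stims = [mm.StimEvent(1.0, "light", 50.0, "a")]
        (r,) = mm.extract_evoked_responses(rec, stims)
        assert r.n_aps == 1
        assert r.first_latency_ms == pytest.approx(20.0, abs=0.2)
        assert r.amplitudes_uv[0] > 50.0

    def test_small_amplitude_rejected(self):
        # -30 μV clears the 5xMAD detection threshold (~20 μV) but not
        # the 50 μV artifact gate
        rec = _spiky_recording([(1.020, -30.0)])
        stims = [mm.StimEvent(1.0, "light", 50.0, "a")]
        (r,) = mm.extract_evoked_responses(rec, stims)
        assert r.n_aps == 0

    def test_peak_outside_window_rejected(self):
        rec = _spiky_recording([(1.200, -80.0)])  # 200 ms > 150 ms window
        stims = [mm.StimEvent(1.0, "light", 50.0, "a")]
        (r,) = mm.extract_evoked_responses(rec, stims)
        assert r.n_aps == 0

    def test_gates_hold_over_random_protocols(self, rng):
        for _ in range(5):
            onsets = np.sort(rng.uniform(0.5, 8.0, 6))
            onsets = onsets[np.diff(np.append(onsets, 1e9)) > 0.3]
            peaks = [(o + rng.uniform(0.005, 0.3), -float(rng.uniform(30, 90)))
                     for o in onsets]
            rec = _spiky_recording(peaks, duration=10.0,
                                   seed=int(rng.integers(1e6)))
            stims = [mm.StimEvent(o, "light", 50.0, "p") for o in onsets]
            for r in mm.extract_evoked_responses(rec, stims):
                stim_onset = stims[r.stim_index].onset
                for t, a in zip(r.peak_times, r.amplitudes_uv):
                    assert stim_onset < t <= stim_onset + 0.150
                    assert a > 50.0

    def test_window_truncated_at_next_pulse(self):
        rec = _spiky_recording([], duration=3.0)
        stims = [mm.StimEvent(1.0, "light", 50.0, "10Hz"),
                 mm.StimEvent(1.1, "light", 50.0, "10Hz")]
        r0, r1 = mm.extract_evoked_responses(rec, stims)
        assert r0.truncated and not r1.truncated


class TestLatencyStats:
    def test_constant_latency_no_deltas(self):
        peaks = [(o + 0.012, -80.0) for o in np.arange(0.5, 5.0, 0.45)]
        rec = _spiky_recording(peaks)
        stims = [mm.StimEvent(o, "light", 50.0, "g")
                 for o in np.arange(0.5, 5.0, 0.45)]
        _, per_group = mm.latency_stats(
            mm.extract_evoked_responses(rec, stims))
        row = per_group.iloc[0]
        assert row["mean_latency_ms"] == pytest.approx(12.0, abs=0.2)
        assert np.isnan(row["mean_delta_latency_ms"])

    def test_delta_latency_between_consecutive_peaks(self):
        rec = _spiky_recording([(1.010, -80.0), (1.025, -80.0)])
        stims = [mm.StimEvent(1.0, "light", 50.0, "g")]
        (r,) = mm.extract_evoked_responses(rec, stims)
        assert r.delta_latencies_ms == pytest.approx([15.0], abs=0.2)

    def test_time_shift_invariance(self):
        peaks = [(1.020, -80.0), (2.035, -80.0)]
        rec0 = _spiky_recording(peaks, t0=0.0)
        shift = 3.0
        rec1 = _spiky_recording([(t + shift, a) for t, a in peaks],
                                duration=5.0 + shift, t0=shift)
        stims0 = [mm.StimEvent(1.0, "light"), mm.StimEvent(2.0, "light")]
        stims1 = [mm.StimEvent(1.0 + shift, "light"),
                  mm.StimEvent(2.0 + shift, "light")]
        lat0 = [r.first_latency_ms
                for r in mm.extract_evoked_responses(rec0, stims0)]
        lat1 = [r.first_latency_ms
                for r in mm.extract_evoked_responses(rec1, stims1)]
        assert lat0 == pytest.approx(lat1, abs=0.05)

    def test_latency_drift_recovered(self, layout5):
        """High-frequency trains with +2 ms latency per pulse after the
        first are recovered from the rendered recording within 0.5 ms."""
        events, evoked = mm.simulate_stim_protocol(
            "optogenetic", n_pulses=8, frequency_hz=2.0, pulse_ms=50,
            latency_ms=10.0, latency_jitter_ms=0.05, latency_drift_ms=2.0,
            seed=1)
        cfg = mm.SimConfig(duration=6.0, mean_rate=0, burst_rate=0, seed=1)
        rec = render_events(evoked, layout5, cfg)
        resp = mm.extract_evoked_responses(mm.preprocess(rec), events,
                                           electrodes=["e0"])
        lats = np.array([r.first_latency_ms for r in resp])
        expect = 10.0 + 2.0 * np.arange(8)
        assert lats == pytest.approx(expect, abs=0.5)


class TestArtifactBlanking:
    def test_blanked_span_interpolated(self):
        rec = _spiky_recording([(1.0, -500.0)])  # artifact at the onset
        stims = [mm.StimEvent(1.0, "electrical", 0.2, "15uA")]
        out = mm.blank_artifacts(rec, stims, blank_ms=2.0)
        i = int(1.0 * FS)
        assert np.abs(out.data[0, i]) < 50.0

    def test_true_aps_outside_blank_survive(self):
        rec = _spiky_recording([(1.0, -400.0), (1.030, -80.0)])
        stims = [mm.StimEvent(1.0, "electrical", 0.2, "15uA")]
        (r,) = mm.extract_evoked_responses(rec, stims)
        assert r.n_aps == 1
        assert r.first_latency_ms == pytest.approx(30.0, abs=0.2)


class TestEfficacyByCount:
    def test_equal_rates_fold_change_one(self):
        df = pd.DataFrame([
            {"circuit": "c1", "n_neurons": 1, "epoch": "baseline",
             "rate_hz": 2.0},
            {"circuit": "c1", "n_neurons": 1, "epoch": "stim",
             "rate_hz": 2.0},
        ])
        out = mm.stim_efficacy_by_count(df)
        assert len(out) == 1
        assert out.loc[0, "median_fold_change"] == 1.0

    def test_superlinear_law_recovered(self):
        """Evoked rate r0·2^(n-1): fold changes recovered within 10%."""
        rows = []
        duration, r0 = 100.0, 1.0
        for n in range(1, 5):
            for seed in range(10):
                r = np.random.default_rng(1000 * n + seed)
                base = np.sort(r.uniform(0, duration,
                                         r.poisson(r0 * duration)))
                stim = np.sort(r.uniform(0, duration,
                                         r.poisson(r0 * 2 ** (n - 1)
                                                   * duration)))
                cid = f"c{n}-{seed}"
                rows += [
                    {"circuit": cid, "n_neurons": n, "epoch": "baseline",
                     "rate_hz": mm.firing_rate(base, duration)},
                    {"circuit": cid, "n_neurons": n, "epoch": "stim",
                     "rate_hz": mm.firing_rate(stim, duration)},
                ]
        out = mm.stim_efficacy_by_count(pd.DataFrame(rows))
        for _, row in out.iterrows():
            expect = 2.0 ** (row["n_neurons"] - 1)
            assert row["median_fold_change"] == pytest.approx(expect,
                                                              rel=0.1)

    def test_missing_baseline_errors(self):
        df = pd.DataFrame([{"circuit": "c1", "n_neurons": 1,
                            "epoch": "stim", "rate_hz": 2.0}])
        with pytest.raises(ValueError, match="baseline"):
            mm.stim_efficacy_by_count(df)
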