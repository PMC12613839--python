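# meamicro

Analysis of extracellular recordings from **few-neuron microcircuits on
multielectrode arrays** — circuits of 1–4 neurons whose axons run
through microfluidic channels across a row of electrodes (200 μm pitch).
At this scale spike sorting fails (the same neuron appears on several
electrodes and burst waveforms superpose), so the pipeline works
electrode-wise:

* **Preprocessing** — 2nd-order 100 Hz Butterworth high-pass
  (zero-phase) and global common median referencing.
* **Spike detection** — negative threshold at 5 × MAD with a 0.2 ms
  local-extremum exclusion sweep.
* **Conduction velocity** — per AP and electrode pair, from
  baseline-SD threshold crossings: the crossing is the first departure
  beyond 5 SD of the 10 ms pre-seed baseline, APs with a spike inside
  that baseline window are rejected, and velocity is electrode distance
  over crossing-time difference, v = d/Δt, grouped by layout segment
  (individual vs bundled axon spans).
* **Firing-regime comparison** — per-electrode ISI histograms (1 ms
  bins) compared across pharmacological conditions by
  KL(P,Q) = Σ P ln(P/Q), with a > 400-interval inclusion rule.
* **Synchrony** — spike contrast (multi-timescale, (0, 1]);
  participation ratio PR = (Σλ)²/(N Σλ²) of the eigenvalues of the
  5 ms-binned correlation matrix (→ 1 decoupled, 1/N fully coupled);
  MaxInterval bursts (≤ 10 ms intra-burst ISI, ≥ 3 spikes, ≥ 1 ms,
  200 ms merge) and network bursts (onsets on all electrodes within
  5 ms); cross-correlogram directionality.
* **Stimulation responses** — evoked AP extraction in a 150 ms
  post-onset window with a 50 μV artifact gate, first-AP latencies and
  delta latencies per protocol, electrical-artifact blanking.
* **Simulator** — synthetic recordings with per-AP ground truth: sparse
  (< 6 Hz) burst-dominated firing with a tunable synchrony jitter,
  conduction velocity decreasing with the number of co-active axons
  (v = v0/(1 + c·(n − 1))), biphasic μV-scale templates on Gaussian
  noise, and electrical/light stimulus trains.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
import numpy as np
import meamicro as mm

layout = mm.build_circuit_layout(5, 200.0)          # 5 electrodes, 200 μm
cfg = mm.SimConfig(n_neurons=3, duration=60.0, seed=42)
rec, true_trains, truth = mm.simulate_circuit(cfg, layout)

clean = mm.preprocess(rec)                          # 100 Hz HP + CMR
spikes = mm.detect_spikes(clean)                    # 5xMAD threshold
ests = mm.estimate_velocities(clean, layout)
v = [e.velocity_m_s for e in ests if e.status == "accepted"]
summary = mm.synchrony_summary(true_trains)

print(f"median velocity:     {np.median(v):.3f} m/s")
print(f"spike contrast:      {summary.spike_contrast:.3f}")
print(f"participation ratio: {summary.participation_ratio:.3f}")
```

prints

```
median velocity:     0.995 m/s
spike contrast:      0.618
participation ratio: 0.643
```

The circuit was simulated with v0 = 1 m/s and coupling 0.25, so APs
travel at 1.0, 0.8 or 0.667 m/s depending on how many of the three
axons are co-active.  Most accepted APs are isolated (velocity
estimation rejects APs with a spike in their baseline window, which
removes most within-burst events), so the median recovered velocity
sits at the single-axon value, 0.3 % off the ground truth.  Spike
contrast 0.62 and PR 0.64 reflect the default partially jittered
shared-burst firing: clearly synchronized (contrast far above the
independent-train level ≈ 0.25) but not perfectly coupled (PR well
above 1/N ≈ 0.33).

The same chain is available from the shell:

```sh
meamicro simulate --seed 42 --n-neurons 3 --duration 60 --out sim/
meamicro preprocess sim/recording.h5 --out clean.h5
meamicro detect clean.h5 --out spikes.csv
meamicro velocity clean.h5 sim/layout.json --out vel/
meamicro dynamics spikes.csv --out dyn/
```

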