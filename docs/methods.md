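# Methods

`meamicro` analyzes extracellular recordings of very small neuronal
circuits — one to four neurons whose axons run through microfluidic
channels across a row of substrate electrodes (nominal pitch 200 μm, as
on a standard 60-electrode array).  This note documents the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the simulation-based tests do and do not show.

## Units and conventions

Seconds, microvolts, micrometres and metres-per-second everywhere inside
the library; conversions happen only at I/O boundaries.  Timestamps are
real-valued seconds; sample↔time conversion is floor-based
(`time_to_sample(t) = floor(t·fs)`), and sample `i` maps to time
`t0 + i/fs`.

## Preprocessing

Second-order Butterworth high-pass at 100 Hz followed by global common
median referencing (per-sample subtraction of the across-channel
median; even channel counts use the mean of the two central values).
The filter is applied zero-phase (forward–backward), so the effective
magnitude response is |H(f)|² and no group delay is introduced.  Phase
handling does not affect relative inter-electrode delays — the velocity
signal — but causal filtering would shift absolute latencies by a
fraction of the spike width; zero-phase avoids that.

Note that CMR is an order statistic, not a linear operation: it commutes
with filtering only when the median channel is pinned (e.g. a majority
of channels carrying exactly the shared component), which is what the
corresponding test constructs.  On generic data the two orders differ at
the μV level.  A second practical consequence: subtracting a median in
which a channel participates slightly compresses that channel's central
quantiles, so the MAD underestimates the post-CMR standard deviation by
≈ 1/√n_channels-scale factors.  With ≈ 30 or more channels in the
reference the effect on threshold detection is negligible; the simulator
therefore includes silent "background" grid electrodes
(`n_noise_channels`, default 25) so the median behaves as on a real
array.

## Spike detection

No spike sorting: with 1–4 neurons seen redundantly on several
electrodes and strongly superposed burst waveforms, sorters cannot
recover unit identities, so all analysis is electrode-wise.  A sample is
a spike if it falls below −5 × the channel's MAD noise level (MAD scaled
by 1.4826 for Gaussian consistency; a raw-MAD switch exists) and is the
minimum within a ±0.2 ms exclusion sweep.  Ties break to the earliest
sample.  Noise is estimated on the full trace, spikes included — at
sparse rates (< 6 Hz) the robust estimator is unaffected.

## Conduction velocity

Peak times are unreliable across electrodes during bursts, so each AP's
reference point per electrode is the first departure of the voltage
from baseline by more than 5 standard deviations, where mean and SD are
estimated on the 10 ms immediately preceding a seed time placed 1 ms
before the AP.  APs with another detected spike inside their baseline
window are rejected (`rejected_contaminated`); traces that never cross
within the 5 ms search horizon give `rejected_no_crossing`.  Velocity is
pair distance over crossing-time difference for consecutive electrodes
along the path (end-to-end optionally), grouped by layout segment;
segment summaries require ≥ 10 accepted APs before medians are emitted.

Numerical choices:

* **Crossing polarity** — "departure beyond k·SD" is evaluated on the
  magnitude of the deviation from the baseline mean, since extracellular
  spikes go negative first; a trace that *rises* crosses identically.
* **Sub-sample interpolation** — the crossing time is linearly
  interpolated between the last sub-threshold and the first
  supra-threshold sample.  At 25 kHz a 200 μm pair at 1 m/s has a 0.2 ms
  (5-sample) delay; whole-sample quantization alone would contribute up
  to 20 % per-pair error, while interpolation brings the median error
  well under 5 %.  For a signal that reaches threshold exactly on a
  sample, interpolation returns that sample time exactly.
* **Seed propagation** — the same AP is tracked across the path by
  placing each downstream search window just after the upstream
  crossing, advanced by the fastest plausible travel time (velocity
  prior 0.1–10 m/s), so burst neighbours are not mismatched.
* **Δt ≤ 0** — below time resolution or out of order: rejected, never a
  velocity.

## ISI statistics and condition comparison

ISI histograms use 1 ms bins with intervals above 1 s pooled in an
overflow bin (still counted).  Interval values are rounded at the
nanosecond scale before binning so exact-edge intervals do not scatter
across adjacent bins through float error.  The Kullback–Leibler
divergence KL(P,Q) = Σ P ln(P/Q) (natural log, nats) compares baseline
vs treated histograms per electrode.  Zero bins are handled by additive
smoothing over the union support: each histogram receives ε = 1/(its
total interval count) per bin before normalization, so smoothing
vanishes as data grow; an explicit ε (including 0) can be passed.
Electrodes with ≤ 400 intervals in either condition are excluded (sparse
histograms make KL unstable) and reported as skipped.

## Synchrony measures

**Spike contrast.**  For a geometric grid of bin sizes from half the
observation span shrinking by 0.9 down to max(min ISI/2, 10 ms), the
pooled activity is binned into half-overlapping windows;
C(b) = Σ|Δθ|/(2·n_spikes) measures how peaked the pooled activity is,
A(b) = (Σ n_k θ_k / Σθ_k − 1)/(N − 1) how many trains share the peaks,
and the synchrony index is max_b C·A ∈ (0, 1].  Identical trains whose
spikes are isolated at some grid bin size give exactly 1; clusters
clipped at the span edges lose one contrast edge each, so the
fixed-point is attained for spikes interior to the window.  The test
suite checks the implementation against an independent loop-based
reference implementation of the same published algorithm; no external
implementation of it is distributed with the package's dependencies.

**Participation ratio.**  Trains are binned at 5 ms, the Pearson
correlation matrix of the binned counts is formed, and its eigenvalues
give PR = (Σλ)²/(N·Σλ²).  Decoupled channels (correlation ≈ identity)
give PR → 1, a single shared mode gives 1/N.  Zero-variance channels
are dropped from N with a warning rather than imputed.

**Bursts.**  MaxInterval with a single ISI threshold (10 ms) serving as
both start and continuation criterion; runs with ≥ 3 spikes are
candidates, candidates closer than 200 ms merge (spikes inside the
merged span are counted), and merged bursts shorter than 1 ms are
dropped.  Isolated spikes never seed a merge, so slow regular firing
yields no bursts.

**Network bursts.**  A network burst occurs where every electrode of the
active set (electrodes with ≥ 1 burst; a strict full-circuit set can be
passed) has a burst onset within a common 5 ms window; the event time is
the earliest onset and participating onsets are consumed so one volley
counts once.

**Directionality.**  Cross-correlogram of 1 ms-binned trains within
±50 ms; reported are the peak lag (positive = second train follows the
first) and the asymmetry (positive-lag mass − negative)/(total), zero
lag excluded.

## Stimulation analysis

Evoked responses are the detected peaks in (onset, onset + 150 ms],
amplitude-gated at > 50 μV (peak-to-baseline magnitude on the
preprocessed trace) to exclude artifacts; failed stimuli are retained.
Response windows are truncated at the next onset when pulses are closer
than the window (e.g. 5 Hz trains) and flagged.  First-AP latency is
light-on to peak; delta latencies are peak-to-peak within one response.
Electrical pulses leave large shared artifacts, so samples within ±2 ms
of each electrical onset are blanked by linear interpolation before
detection.  Rate-vs-circuit-size tables report median rates and
per-circuit fold changes only; hypothesis testing is deliberately left
to external tools.

## The simulator

The generator emulates the study conditions the analysis is built for
and provides per-AP ground truth:

* **Circuits** — 1–4 neurons per microchannel, a linear path of 5
  electrodes at 200 μm pitch by default, with optional labelled segments
  (e.g. individual 0–200 μm vs bundled 200–800 μm spans).
* **Firing** — per-neuron background Poisson (default 2 Hz, kept below
  the 6 Hz sparse regime) plus network-wide Poisson burst events
  (default 0.5 /s, 5 spikes per burst at 5 ms intra-burst ISI), each
  neuron's burst onset jittered by `sync_jitter` (default 2 ms) — the
  synchrony dial.  A 2 ms refractory keeps trains strictly increasing.
* **Velocity** — each AP's co-active axon count n (distinct neurons
  firing within ±1 ms) sets its speed v = v0/(1 + c·(n − 1)), default
  v0 = 1 m/s, c = 0.25.  This is a minimal monotone stand-in for
  activity-dependent slowing in a shared channel, not a biophysical
  model; per-segment velocity overrides compose with it.
* **Rendering** — a biphasic cubic-spline template (−60 μV trough, 1 ms
  width, 35 % rebound) is added on every path electrode at the arrival
  time implied by cumulative distance and the AP's velocity; templates
  are evaluated at continuous offsets so sub-sample delays survive
  sampling, while detected timestamps remain on the grid.  White
  Gaussian noise (default 5 μV SD) is added everywhere, including the
  silent background electrodes.  Default sampling rate 25 kHz; all
  timing parameters are specified in milliseconds, so results are
  robust to the exact rate.
* **Stimulation** — electrical trains (default 30 biphasic ±15 μA,
  100 μs per phase, 1800 ms between pulses — onset period is the
  biphasic width plus the gap) and light trains (50 or 100 ms pulses at
  0.5–5 Hz), with configurable evoked latency, jitter, per-pulse AP
  count, delta latency, and per-pulse latency drift.

What the simulator does **not** model: biophysical (cable-equation)
ephaptic fields, waveform attenuation and shape change along the axon,
electrode impedance variation, LFP, drift, or non-Gaussian noise.
Passing the recovery tests therefore shows the analysis is correct and
well-conditioned under the stated regime, not that it is robust to every
property of real recordings.

## Problem sizes in the test and acceptance runs

Simulated recovery tests use 10–30 s renders at 25 kHz with 30 channels,
10 seeds for the stochastic criteria, 100+ train sets for the
participation-ratio sweep, and 1000 random trains for the burst-rule
oracle; these sizes put every stochastic check far from its threshold
(e.g. velocity medians recover within ~0.3 % against a 5 % criterion)
while keeping the whole suite at around a minute of compute.

## Known limitations

* Velocity estimation assumes the layout path order matches propagation
  direction; antidromic APs appear as rejected (Δt < 0) pairs rather
  than negative velocities.
* The amplitude gate for evoked responses reads the trace at the
  detected peak sample; strong superposition inside a response window
  can bias amplitudes.
* KL values depend (weakly, through smoothing) on the histogram range;
  the 1 s overflow cap is configurable.
* Spike-contrast values are comparable only between runs using the same
  bin-grid parameters.
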