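"""Synthetic MEA microcircuit recordings with known ground truth.

Emulates few-neuron (1-4 axons per microchannel) circuits on a 200 μm
pitch electrode grid: sparse background firing (default below 6 Hz),
shared burst events with tunable per-neuron jitter (the synchrony dial),
action potentials propagating along the in-channel electrode path at a
velocity that decreases with the number of co-active axons, Gaussian
background noise, and electrical / light stimulus trains with configurable
evoked responses.  Every stage returns the ground truth needed to score
the corresponding analysis module.

The velocity-vs-count law ``v = v0 / (1 + c * (n_active - 1))`` is a
minimal monotone model of activity-dependent slowing in a shared channel;
it is a stand-in for the physics, chosen only to give the analysis a known
monotone target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import CircuitLayout, Recording, Segment, SpikeTrainSet
from .stimulation import StimEvent

__all__ = [
    "APTemplate",
    "SimConfig",
    "GroundTruth",
    "build_circuit_layout",
    "simulate_spike_trains",
    "velocity_model",
    "render_extracellular",
    "simulate_circuit",
    "channel_occupancy_fraction",
    "simulate_stim_protocol",
]


@dataclass(frozen=True)
class APTemplate:
    """Extracellular AP waveform: biphasic, cubic-spline shaped.

    The trough (reference point) sits at offset zero; support spans
    ``[-width/4, +3*width/4]``.  ``rebound`` is the positive lobe as a
    fraction of the trough magnitude.
    """

    amplitude_uv: float = -60.0
    width_ms: float = 1.0
    biphasic: bool = True
    rebound: float = 0.35

    def __call__(self, dt_s: np.ndarray) -> np.ndarray:
        """Evaluate the waveform at offsets ``dt_s`` (s) from the trough."""
        w = self.width_ms * 1e-3
        a = self.amplitude_uv
        pos = -self.rebound * a if self.biphasic else 0.0
        x = np.array([-0.25, 0.0, 0.25, 0.5, 0.75]) * w
        y = np.array([0.0, a, 0.0, pos, 0.0])
        spline = CubicSpline(x, y, bc_type="clamped")
        dt = np.asarray(dt_s, dtype=float)
        out = spline(dt)
        out[(dt < x[0]) | (dt > x[-1])] = 0.0
        return out

    @property
    def support_s(self) -> tuple[float, float]:
        w = self.width_ms * 1e-3
        return (-0.25 * w, 0.75 * w)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated microchannel circuit.

    Defaults are the regime the analysis is built for: up to four axons
    per channel, sparse firing (< 6 Hz per neuron), burst-dominated
    activity, 200 μm electrode pitch, μV-scale biphasic spikes on
    Gaussian noise.
    """

    n_neurons: int = 1
    duration: float = 60.0
    fs: float = 25_000.0
    mean_rate: float = 2.0            # background Poisson rate per neuron (Hz)
    burst_rate: float = 0.5           # shared burst events per second
    spikes_per_burst: int = 5
    intra_burst_isi_ms: float = 5.0
    sync_jitter: float = 0.002        # s, per-neuron jitter of burst onsets
    v0: float = 1.0                   # baseline conduction velocity (m/s)
    coupling: float = 0.25            # ephaptic slowing coefficient (>= 0)
    segment_velocities: Mapping[str, float] | None = None
    coincidence_ms: float = 1.0       # window defining "co-active" axons
    refractory_ms: float = 2.0
    noise_sd: float = 5.0             # μV
    n_noise_channels: int = 25        # silent grid electrodes (for CMR)
    template: APTemplate = field(default_factory=APTemplate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mean_rate < 0 or self.burst_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 1 <= self.n_neurons:
            raise ValueError("need at least one neuron")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-AP truth for one simulated circuit.

    Arrays are aligned: spike ``i`` belongs to neuron ``neuron[i]``, fired
    at ``times[i]`` (s, continuous), with ``n_active[i]`` axons co-active
    and propagated at ``velocity[i]`` m/s (the whole-path scale; segment
    overrides multiply on top).
    """

    times: np.ndarray
    neuron: np.ndarray
    n_active: np.ndarray
    velocity: np.ndarray
    stim_times: np.ndarray | None = None
    config: SimConfig | None = None

    def train_of(self, neuron_idx: int) -> np.ndarray:
        return self.times[self.neuron == neuron_idx]


def velocity_model(n_active: int, v0: float, coupling: float) -> float:
    """Conduction velocity of an AP with ``n_active`` co-active axons.

    ``v0 / (1 + coupling * (n_active - 1))`` — equals ``v0`` for a lone
    axon or zero coupling, and strictly decreases with each additional
    co-active axon when ``coupling > 0``.
    """
    if n_active < 1:
        raise ValueError("n_active must be >= 1")
    return v0 / (1.0 + coupling * (n_active - 1))


def build_circuit_layout(n_channels_per_path: int,
                         pitch_um: float = 200.0,
                         segment_spec: Mapping[str, tuple[float, float]] | None = None,
                         name: str = "sim-circuit") -> CircuitLayout:
    """Linear in-channel electrode path on a regular grid.

    ``segment_spec`` maps labels to ``(start_um, stop_um)`` spans of the
    cumulative path distance; spans must not overlap and must cover the
    whole path.
    """
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    if n_channels_per_path < 1:
        raise ValueError("empty path")
    ids = [f"e{i}" for i in range(n_channels_per_path)]
    positions = {cid: (i * pitch_um, 0.0) for i, cid in enumerate(ids)}
    segments: list[Segment] = []
    if segment_spec:
        segments = [Segment(lbl, float(a), float(b))
                    for lbl, (a, b) in segment_spec.items()]
        total = (n_channels_per_path - 1) * pitch_um
        covered = sorted((s.start_um, s.stop_um) for s in segments)
        pos = covered[0][0]
        for a, b in covered:
            if a > pos:
                raise ValueError(f"segment spec leaves gap at {pos} μm")
            pos = max(pos, b)
        if covered[0][0] > 0 or pos < total:
            raise ValueError("segment spec does not cover the path")
    return CircuitLayout(positions, [ids], segments, pitch_um, name)


def _one_neuron_train(rng: np.random.Generator, cfg: SimConfig,
                      burst_events: np.ndarray) -> np.ndarray:
    spikes = []
    if cfg.mean_rate > 0:
        n_bg = rng.poisson(cfg.mean_rate * cfg.duration)
        spikes.append(rng.uniform(0.0, cfg.duration, n_bg))
    if burst_events.size and cfg.spikes_per_burst > 0:
        onset = burst_events + rng.normal(0.0, cfg.sync_jitter,
                                          burst_events.size)
        isi = cfg.intra_burst_isi_ms * 1e-3
        offs = np.arange(cfg.spikes_per_burst) * isi
        spikes.append((onset[:, None] + offs[None, :]).ravel())
    if not spikes:
        return np.empty(0)
    t = np.sort(np.concatenate(spikes))
    t = t[(t >= 0) & (t < cfg.duration)]
    # enforce refractoriness so trains are strictly increasing
    if t.size:
        keep = np.ones(t.size, bool)
        last = t[0]
        for i in range(1, t.size):
            if t[i] - last < cfg.refractory_ms * 1e-3:
                keep[i] = False
            else:
                last = t[i]
        t = t[keep]
    return t


def simulate_spike_trains(config: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate per-neuron spike trains: background Poisson firing plus
    network-wide burst events jittered per neuron by ``sync_jitter``.

    Returns the trains (channel ids ``n0..n{k-1}``) and a
    :class:`GroundTruth` with per-AP co-active counts and velocities.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_events = rng.poisson(config.burst_rate * config.duration)
    burst_events = np.sort(rng.uniform(0.0, config.duration, n_events))
    trains = {f"n{i}": _one_neuron_train(rng, config, burst_events)
              for i in range(config.n_neurons)}
    sts = SpikeTrainSet(trains, config.duration,
                        {"seed": config.seed, "kind": "simulated"})

    times = np.concatenate([trains[f"n{i}"] for i in range(config.n_neurons)]
                           or [np.empty(0)])
    neuron = np.concatenate(
        [np.full(trains[f"n{i}"].size, i) for i in range(config.n_neurons)]
        or [np.empty(0, int)]).astype(int)
    order = np.argsort(times, kind="stable")
    times, neuron = times[order], neuron[order]
    n_active = _count_coactive(times, neuron, config.n_neurons,
                               config.coincidence_ms * 1e-3)
    vel = np.array([velocity_model(int(n), config.v0, config.coupling)
                    for n in n_active])
    gt = GroundTruth(times, neuron, n_active, vel, None, config)
    return sts, gt


def _count_coactive(times: np.ndarray, neuron: np.ndarray, n_neurons: int,
                    window_s: float) -> np.ndarray:
    """Distinct neurons with a spike within ±window of each spike."""
    out = np.ones(times.size, dtype=int)
    if n_neurons == 1:
        return out
    for i, t in enumerate(times):
        lo = np.searchsorted(times, t - window_s, "left")
        hi = np.searchsorted(times, t + window_s, "right")
        out[i] = np.unique(neuron[lo:hi]).size
    return out


def _path_delays(layout: CircuitLayout, path: Sequence[str],
                 config: SimConfig) -> np.ndarray:
    """Per-electrode arrival delay (s) for a unit velocity scale.

    Integrates travel time over the path, honouring per-segment velocity
    overrides (``segment_velocities``); unlabelled spans run at ``v0``.
    The per-AP co-activity slowdown multiplies these delays uniformly.
    """
    cum = layout.cumulative_distances(path)
    delays = [0.0]
    for i, d in enumerate(layout.path_distances(path)):
        label = layout.pair_segment(path, i)
        v = config.v0
        if config.segment_velocities and label in config.segment_velocities:
            v = config.segment_velocities[label]
        delays.append(delays[-1] + d / (v * 1e6))  # m/s -> μm/s
    assert len(delays) == len(cum)
    return np.asarray(delays)


def render_extracellular(gt: GroundTruth, layout: CircuitLayout,
                         config: SimConfig,
                         rng: np.random.Generator | None = None) -> Recording:
    """Render spike trains into an extracellular voltage matrix.

    Every AP appears on each path electrode as the template delayed by the
    cumulative travel time at its assigned velocity; waveform superposition
    during bursts is additive.  White Gaussian noise of ``noise_sd`` μV is
    added per sample.  Templates are evaluated at continuous offsets, so
    sub-sample propagation delays survive sampling.
    """
    rng = (np.random.default_rng(config.seed + 1_000_003)
           if rng is None else rng)
    path = layout.paths[0]
    n_samples = int(round(config.duration * config.fs))
    # spike-free grid electrodes outside the channel make the global
    # common median behave as on a full array
    bg_ids = [f"bg{i}" for i in range(config.n_noise_channels)]
    data = np.zeros((len(path) + len(bg_ids), n_samples))
    base_delays = _path_delays(layout, path, config)
    lo, hi = config.template.support_s
    slowdown = config.v0 / gt.velocity  # >= 1; scales all travel times
    for j in range(len(path)):
        arrivals = gt.times + base_delays[j] * slowdown
        for t_a in arrivals:
            i0 = max(0, int(np.floor((t_a + lo) * config.fs)))
            i1 = min(n_samples, int(np.ceil((t_a + hi) * config.fs)) + 1)
            if i1 <= i0:
                continue
            tt = np.arange(i0, i1) / config.fs
            data[j, i0:i1] += config.template(tt - t_a)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, data.shape)
    return Recording(data, config.fs, list(path) + bg_ids, 0.0, layout.name,
                     {"kind": "simulated", "seed": config.seed})


def simulate_circuit(config: SimConfig,
                     layout: CircuitLayout | None = None
                     ) -> tuple[Recording, SpikeTrainSet, GroundTruth]:
    """Convenience: trains + rendering with a default 5-electrode path."""
    if layout is None:
        layout = build_circuit_layout(5, 200.0)
    rng = np.random.default_rng(config.seed)
    sts, gt = simulate_spike_trains(config, rng)
    rec = render_extracellular(gt, layout, config, rng)
    return rec, sts, gt


def channel_occupancy_fraction(n_axons: int, axon_diameter_um: float = 1.0,
                               channel_height_um: float = 5.0,
                               channel_width_um: float = 30.0) -> float:
    """Fraction of the microchannel cross-section occupied by axons.

    ``n * π (d/2)^2 / (h * w)``; with four 1 μm axons in a 5 × 30 μm
    channel this is π/150 ≈ 2% — the rest of the channel is medium.
    """
    if n_axons < 0:
        raise ValueError("n_axons must be >= 0")
    if min(axon_diameter_um, channel_height_um, channel_width_um) <= 0:
        raise ValueError("dimensions must be positive")
    frac = (n_axons * np.pi * (axon_diameter_um / 2.0) ** 2
            / (channel_height_um * channel_width_um))
    if frac > 1:
        raise ValueError(f"non-physical occupancy {frac:.3f} > 1")
    return float(frac)


def simulate_stim_protocol(kind: str,
                           n_pulses: int = 30,
                           t_start: float = 0.5,
                           # electrical protocol
                           phase_us: float = 100.0,
                           amplitude_ua: float = 15.0,
                           interpulse_ms: float = 1800.0,
                           # optogenetic protocol
                           frequency_hz: float = 1.0,
                           pulse_ms: float = 50.0,
                           # evoked-response ground truth
                           latency_ms: float = 10.0,
                           latency_jitter_ms: float = 0.2,
                           latency_drift_ms: float = 0.0,
                           aps_per_pulse: int = 1,
                           delta_latency_ms: float = 15.0,
                           seed: int = 0,
                           ) -> tuple[list[StimEvent], np.ndarray]:
    """Stimulus train plus ground-truth evoked AP times.

    ``electrical``: biphasic pulses (−amp then +amp, ``phase_us`` each)
    separated by ``interpulse_ms`` of silence, so the onset period is the
    biphasic width plus the interpulse interval.  ``optogenetic``: light
    pulses of ``pulse_ms`` at ``frequency_hz``.

    Each pulse evokes ``aps_per_pulse`` APs: the first at ``latency_ms``
    (+ Gaussian jitter), subsequent ones ``delta_latency_ms`` apart.
    ``latency_drift_ms`` adds a per-pulse latency increment across the
    train (pulse 0 is unaffected), emulating slowed responses late in
    high-frequency trains.
    """
    rng = np.random.default_rng(seed)
    if n_pulses < 0:
        raise ValueError("n_pulses must be >= 0")
    if kind == "electrical":
        width_s = 2 * phase_us * 1e-6
        period = width_s + interpulse_ms * 1e-3
        label = f"{amplitude_ua:g}uA"
        pulse_width_ms = width_s * 1e3
    elif kind == "optogenetic":
        if frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        period = 1.0 / frequency_hz
        pulse_width_ms = pulse_ms
        if pulse_ms * 1e-3 > period:
            raise ValueError(
                f"{pulse_ms} ms pulses overlap at {frequency_hz} Hz")
        label = f"{frequency_hz:g}Hz/{pulse_ms:g}ms"
    else:
        raise ValueError(f"unknown stimulation kind {kind!r}")

    events = [StimEvent(onset=t_start + k * period,
                        kind="electrical" if kind == "electrical" else "light",
                        pulse_width_ms=pulse_width_ms, label=label)
              for k in range(n_pulses)]
    evoked = []
    for p, ev in enumerate(events):
        lat = (latency_ms + latency_drift_ms * p
               + rng.normal(0.0, latency_jitter_ms))
        for k in range(aps_per_pulse):
            evoked.append(ev.onset + (lat + k * delta_latency_ms) * 1e-3)
    return events, np.asarray(evoked)
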