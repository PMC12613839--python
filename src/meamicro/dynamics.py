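"""Spike-train statistics for microcircuit recordings.

Because a few neurons are seen on several electrodes, electrode-level
firing statistics (not sorted units) carry the signal here:

* ISI histograms (1 ms bins) and their Kullback-Leibler divergence
  quantify regularity changes between pharmacological conditions
  without sorting.
* Spike contrast gives a multi-timescale synchrony index in (0, 1].
* The participation ratio (PR) of the binned-activity correlation
  spectrum measures dimensionality: near 1 for decoupled activity,
  1/N when everything is driven by one common mode.
* MaxInterval burst detection, network bursts (bursts coincident across
  all electrodes within 5 ms), firing rates and cross-correlogram
  directionality complete the per-circuit summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import ConditionPair, SpikeTrainSet

__all__ = [
    "ISIHistogram",
    "Burst",
    "NetworkBurst",
    "SynchronySummary",
    "isi_histogram",
    "kl_divergence",
    "condition_divergence",
    "spike_contrast",
    "participation_ratio",
    "detect_bursts",
    "detect_network_bursts",
    "firing_rate",
    "directionality",
    "synchrony_summary",
]


# --------------------------------------------------------------------------
# ISI histograms and Kullback-Leibler divergence
# --------------------------------------------------------------------------

@dataclass
class ISIHistogram:
    """Histogram of inter-spike intervals.

    ``counts`` has one entry per regular bin plus a final overflow bin
    for intervals beyond ``bin_edges_ms[-1]``; ``n_isi`` counts every
    interval including overflow.
    """

    bin_edges_ms: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_ms = np.asarray(self.bin_edges_ms, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        if self.counts.size != self.bin_edges_ms.size:
            raise ValueError("counts must have one regular bin per edge "
                             "interval plus one overflow bin")

    @property
    def n_isi(self) -> int:
        return int(self.counts.sum())

    def compatible(self, other: "ISIHistogram") -> bool:
        return (self.counts.size == other.counts.size
                and np.allclose(self.bin_edges_ms, other.bin_edges_ms))


def isi_histogram(train: np.ndarray, bin_ms: float = 1.0,
                  max_isi_ms: float = 1000.0) -> ISIHistogram:
    """Histogram of consecutive inter-spike intervals at 1 ms resolution.

    Intervals above ``max_isi_ms`` are pooled into an overflow bin that
    still counts toward ``n_isi``.  Fewer than two spikes yield an empty
    histogram.
    """
    train = np.asarray(train, dtype=float)
    edges = np.arange(0.0, max_isi_ms + bin_ms, bin_ms)
    # ns-scale rounding keeps exact-edge intervals (e.g. 10.0 ms) from
    # scattering across two bins through float error
    isis_ms = np.round(np.diff(train) * 1e3, 6)
    counts, _ = np.histogram(isis_ms, bins=edges)
    overflow = int(np.sum(isis_ms >= edges[-1]))
    return ISIHistogram(edges, np.append(counts, overflow))


def kl_divergence(P: ISIHistogram, Q: ISIHistogram,
                  epsilon: float | None = None) -> float:
    """Kullback-Leibler divergence KL(P, Q) = Σ P(x) ln(P(x)/Q(x)), nats.

    Counts are normalized to probabilities after additive smoothing:
    ``epsilon`` is added to each bin of the union support before
    normalization (default: each histogram gets 1/its own total, so
    smoothing vanishes as data grows).  Asymmetric by construction;
    always ≥ 0 and 0 iff the smoothed distributions coincide.
    """
    if P.n_isi == 0 or Q.n_isi == 0:
        raise ValueError("KL divergence of an empty histogram")
    if not P.compatible(Q):
        raise ValueError("histograms have incompatible binnings")
    support = (P.counts + Q.counts) > 0
    eps_p = 1.0 / P.n_isi if epsilon is None else epsilon
    eps_q = 1.0 / Q.n_isi if epsilon is None else epsilon
    p = P.counts[support] + eps_p
    q = Q.counts[support] + eps_q
    p = p / p.sum()
    q = q / q.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return float(np.sum(terms))


def condition_divergence(pair: ConditionPair, min_isi: int = 400,
                         bin_ms: float = 1.0,
                         max_isi_ms: float = 1000.0) -> pd.DataFrame:
    """Per-electrode KL(baseline, treated) of ISI histograms.

    Electrodes where either condition has ≤ ``min_isi`` intervals are
    excluded from the divergence (sparse histograms make KL unstable)
    but still listed with ``included=False``.
    """
    rows = []
    for cid in sorted(pair.baseline.channel_ids):
        hp = isi_histogram(pair.baseline.train(cid), bin_ms, max_isi_ms)
        hq = isi_histogram(pair.treated.train(cid), bin_ms, max_isi_ms)
        ok = hp.n_isi > min_isi and hq.n_isi > min_isi
        rows.append({
            "electrode": cid,
            "kl_nats": kl_divergence(hp, hq) if ok else float("nan"),
            "n_isi_baseline": hp.n_isi,
            "n_isi_treated": hq.n_isi,
            "included": ok,
            "condition": pair.label,
        })
    df = pd.DataFrame(rows)
    if not df["included"].any():
        warnings.warn(f"condition {pair.label!r}: all electrodes excluded "
                      f"by the >{min_isi}-ISI rule")
    return df


# --------------------------------------------------------------------------
# Spike contrast
# --------------------------------------------------------------------------

def _theta_and_active(trains: Sequence[np.ndarray], t_start: float,
                      t_stop: float, bin_size: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts and active-train counts per half-overlapping bin."""
    step = bin_size / 2.0
    edges = np.arange(t_start, t_stop + step, step)
    per_train = np.vstack([np.histogram(st, bins=edges)[0] for st in trains])
    overlapped = per_train[:, :-1] + per_train[:, 1:]
    theta = overlapped.sum(axis=0)
    n_active = np.count_nonzero(overlapped, axis=0)
    return theta, n_active


def spike_contrast(trains: SpikeTrainSet | Sequence[np.ndarray],
                   t_start: float | None = None,
                   t_stop: float | None = None,
                   min_bin_s: float = 0.01,
                   shrink: float = 0.9,
                   return_trace: bool = False):
    """Multi-timescale spike-train synchrony in (0, 1].

    For a geometric grid of bin sizes from half the observation span down
    to half the minimum ISI (floored at ``min_bin_s``), bins the pooled
    activity into half-overlapping windows and computes

    * contrast  C(b) = Σ|Δθ_k| / (2 · total spikes) — how peaked the
      pooled activity is at that timescale, and
    * active fraction A(b) = (Σ n_k θ_k / Σ θ_k − 1) / (N − 1) — how many
      trains share those peaks,

    where θ_k are pooled per-bin counts and n_k the number of trains
    active in bin k.  The synchrony index is max_b C(b)·A(b): 1 for
    identical trains, near 0 for independent ones.
    """
    if isinstance(trains, SpikeTrainSet):
        arrs = [trains.train(c) for c in trains.channel_ids]
    else:
        arrs = [np.asarray(t, dtype=float) for t in trains]
    arrs = [a for a in arrs if a.size]
    n = len(arrs)
    if n < 2:
        raise ValueError("spike contrast needs >= 2 non-empty trains")
    all_spikes = np.concatenate(arrs)
    total = all_spikes.size
    t_start = float(all_spikes.min()) if t_start is None else t_start
    t_stop = float(all_spikes.max()) if t_stop is None else t_stop
    if t_stop <= t_start:
        raise ValueError("degenerate observation span")
    isis = [np.diff(a) for a in arrs if a.size > 1]
    isi_min = min((i.min() for i in isis if i.size), default=np.inf)
    bin_max = (t_stop - t_start) / 2.0
    bin_min = max(isi_min / 2.0, min_bin_s)
    bin_min = min(bin_min, bin_max)  # always evaluate at least one size

    bins, curve = [], []
    b = bin_max
    while b >= bin_min * (1 - 1e-12):
        theta, n_active = _theta_and_active(arrs, t_start, t_stop, b)
        theta_sum = theta.sum()
        if theta_sum == 0:
            contrast = active = 0.0
        else:
            contrast = np.abs(np.diff(theta)).sum() / (2.0 * total)
            active = ((n_active * theta).sum() / theta_sum - 1.0) / (n - 1.0)
        bins.append(b)
        curve.append(contrast * active)
        b *= shrink
    s = float(np.max(curve))
    if return_trace:
        return s, np.asarray(bins), np.asarray(curve)
    return s


# --------------------------------------------------------------------------
# Participation ratio
# --------------------------------------------------------------------------

def participation_ratio(trains: SpikeTrainSet | Sequence[np.ndarray],
                        bin_ms: float = 5.0,
                        duration: float | None = None) -> float:
    """Eigenvalue participation ratio of binned-activity correlations.

    Trains are binned to counts (5 ms default), the pairwise Pearson
    correlation matrix is formed, and its eigenvalues λ_i give
    PR = (Σλ)² / (N·Σλ²) ∈ (0, 1].  All-equal eigenvalues (decoupled
    channels) give 1; a single dominant mode (rank one) gives 1/N.
    Zero-variance channels are dropped from N with a warning.
    """
    if isinstance(trains, SpikeTrainSet):
        arrs = [trains.train(c) for c in trains.channel_ids]
        duration = trains.duration if duration is None else duration
    else:
        arrs = [np.asarray(t, dtype=float) for t in trains]
        if duration is None:
            duration = max((a.max() for a in arrs if a.size), default=0.0)
    if duration <= 0 or not any(a.size for a in arrs):
        raise ValueError("participation ratio of empty activity")
    edges = np.arange(0.0, duration + bin_ms * 1e-3, bin_ms * 1e-3)
    binned = np.vstack([np.histogram(a, bins=edges)[0] for a in arrs])
    var = binned.var(axis=1)
    if np.any(var == 0):
        warnings.warn(f"dropping {int((var == 0).sum())} zero-variance "
                      "channel(s) from the participation ratio")
        binned = binned[var > 0]
    n = binned.shape[0]
    if n == 0:
        raise ValueError("no channels with variance left")
    if n == 1:
        return 1.0
    corr = np.corrcoef(binned)
    lam = np.linalg.eigvalsh(corr)
    return float(lam.sum() ** 2 / (n * np.sum(lam ** 2)))


# --------------------------------------------------------------------------
# Bursts and network bursts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Burst:
    """One burst on one electrode (times in s)."""

    start: float
    end: float
    n_spikes: int
    electrode: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NetworkBurst:
    """Burst onsets coincident across all active electrodes."""

    time: float           # earliest onset in the coincidence window
    span_ms: float        # spread of the participating onsets
    onsets: Mapping[str, float] = field(default_factory=dict)


def detect_bursts(train: np.ndarray, max_isi_ms: float = 10.0,
                  min_spikes: int = 3, min_duration_ms: float = 1.0,
                  min_ibi_ms: float = 200.0,
                  electrode: str | None = None) -> list[Burst]:
    """MaxInterval burst detection.

    Maximal runs of consecutive ISIs ≤ ``max_isi_ms`` with at least
    ``min_spikes`` spikes are burst candidates; candidates separated by
    less than ``min_ibi_ms`` are merged (spikes falling inside the merged
    span are counted in); merged bursts shorter than ``min_duration_ms``
    are discarded.
    """
    t = np.asarray(train, dtype=float)
    if t.size == 0:
        return []
    max_isi = max_isi_ms * 1e-3
    # maximal runs of ISIs <= max_isi
    breaks = np.flatnonzero(np.diff(t) > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    cand = [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_spikes]
    # merge candidates closer than the minimum inter-burst interval
    merged: list[list[int]] = []
    for s, e in cand:
        if merged and t[s] - t[merged[-1][1]] < min_ibi_ms * 1e-3:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        start, end = t[s], t[e]
        if (end - start) * 1e3 < min_duration_ms:
            continue
        n = int(np.sum((t >= start) & (t <= end)))
        out.append(Burst(float(start), float(end), n, electrode))
    return out


def detect_network_bursts(bursts: Mapping[str, Sequence[Burst]],
                          window_ms: float = 5.0,
                          electrodes: Sequence[str] | None = None
                          ) -> list[NetworkBurst]:
    """Bursts present on every electrode within a common window.

    ``electrodes`` defaults to the active set (electrodes with at least
    one burst); pass the full circuit set to require literally every
    electrode.  A network burst is recorded where each required
    electrode has a burst onset inside one ``window_ms`` span; its time
    is the earliest onset, and participating onsets are consumed so one
    volley yields one event.
    """
    if electrodes is None:
        electrodes = [c for c, bl in bursts.items() if len(bl)]
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("empty electrode set")
    if any(c not in bursts or not len(bursts[c]) for c in electrodes):
        return []
    onsets = sorted((b.start, c) for c in electrodes for b in bursts[c])
    w = window_ms * 1e-3
    out: list[NetworkBurst] = []
    i = 0
    while i < len(onsets):
        t0 = onsets[i][0]
        in_win: dict[str, float] = {}
        j = i
        while j < len(onsets) and onsets[j][0] <= t0 + w:
            in_win.setdefault(onsets[j][1], onsets[j][0])
            j += 1
        if len(in_win) == len(electrodes):
            span = (max(in_win.values()) - min(in_win.values())) * 1e3
            out.append(NetworkBurst(t0, span, dict(in_win)))
            i = j  # consume the volley
        else:
            i += 1
    return out


def firing_rate(train: np.ndarray, duration: float) -> float:
    """Mean firing rate (Hz) = spike count / duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(np.asarray(train)) / duration


# --------------------------------------------------------------------------
# Cross-correlation directionality
# --------------------------------------------------------------------------

def directionality(train_a: np.ndarray, train_b: np.ndarray,
                   max_lag_ms: float = 50.0, bin_ms: float = 1.0,
                   duration: float | None = None
                   ) -> tuple[float, float]:
    """Peak lag (ms) and asymmetry of the a→b cross-correlogram.

    Positive peak lag means b fires after a (propagation a→b).  The
    asymmetry index is (mass at positive lags − mass at negative lags) /
    total mass within ±``max_lag_ms``, zero lag excluded; it is positive
    for consistent a-leads-b timing and ≈ 0 for independent trains.
    """
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both trains must be non-empty")
    if duration is None:
        duration = max(a.max(), b.max())
    edges = np.arange(0.0, duration + bin_ms * 1e-3, bin_ms * 1e-3)
    xa = np.histogram(a, bins=edges)[0].astype(float)
    xb = np.histogram(b, bins=edges)[0].astype(float)
    corr = _signal.correlate(xb, xa, mode="full")
    lags = _signal.correlation_lags(xb.size, xa.size, mode="full")
    max_lag = int(round(max_lag_ms / bin_ms))
    sel = np.abs(lags) <= max_lag
    corr, lags = corr[sel], lags[sel]
    if corr.sum() == 0:
        raise ValueError("degenerate cross-correlogram (no coincidences "
                         f"within ±{max_lag_ms} ms)")
    peak_lag_ms = float(lags[np.argmax(corr)] * bin_ms)
    pos = corr[lags > 0].sum()
    neg = corr[lags < 0].sum()
    asym = float((pos - neg) / (pos + neg)) if pos + neg else 0.0
    return peak_lag_ms, asym


# --------------------------------------------------------------------------
# Per-circuit summary
# --------------------------------------------------------------------------

@dataclass
class SynchronySummary:
    """One circuit's synchrony and burst metrics."""

    spike_contrast: float
    participation_ratio: float
    burst_rate_per_min: float          # mean bursts/min per electrode
    network_burst_rate_per_min: float
    mean_firing_rate_hz: float
    n_electrodes: int
    firing_rates_hz: Mapping[str, float] = field(default_factory=dict)


def synchrony_summary(trains: SpikeTrainSet, pr_bin_ms: float = 5.0,
                      nb_window_ms: float = 5.0,
                      burst_kwargs: dict | None = None) -> SynchronySummary:
    """Compute the full per-circuit synchrony/burst summary."""
    burst_kwargs = burst_kwargs or {}
    rates = {c: firing_rate(trains.train(c), trains.duration)
             for c in trains.channel_ids}
    bursts = {c: detect_bursts(trains.train(c), electrode=c, **burst_kwargs)
              for c in trains.channel_ids}
    n_bursts = np.mean([len(b) for b in bursts.values()])
    try:
        nb = detect_network_bursts(bursts, window_ms=nb_window_ms)
    except ValueError:
        nb = []
    sc = spike_contrast(trains, t_start=0.0, t_stop=trains.duration)
    pr = participation_ratio(trains, bin_ms=pr_bin_ms)
    minutes = trains.duration / 60.0
    return SynchronySummary(
        spike_contrast=sc,
        participation_ratio=pr,
        burst_rate_per_min=float(n_bursts / minutes),
        network_burst_rate_per_min=len(nb) / minutes,
        mean_firing_rate_hz=float(np.mean(list(rates.values()))),
        n_electrodes=len(trains.channel_ids),
        firing_rates_hz=rates,
    )
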