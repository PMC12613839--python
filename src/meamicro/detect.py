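"""Electrode-wise threshold spike detection.

Spike sorting is deliberately absent: in few-neuron microchannel circuits
the same neuron is seen on several electrodes and burst waveforms
superpose, which defeats template-matching sorters.  Detection is a
robust threshold on each electrode instead: a sample is a spike if it
falls below −k × MAD (negative deflections, by default k = 5) and is the
extremum within an exclusion sweep (±0.2 ms) around it.  Detected peak
timestamps are the spike trains for all downstream analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import Recording, SpikeTrainSet, sample_to_time

__all__ = ["noise_level_mad", "detect_spikes"]

MAD_SCALE = 1.4826  # normal-consistent scaling of the raw MAD


def noise_level_mad(trace: np.ndarray, scaled: bool = True) -> float:
    """Noise level of a trace as the (scaled) median absolute deviation.

    ``median(|x - median(x)|)``, multiplied by 1.4826 so the estimate is
    consistent for the SD of Gaussian noise.  Robust to the spikes riding
    on the noise at sparse firing rates.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 2:
        raise ValueError("need at least 2 samples to estimate noise")
    mad = float(np.median(np.abs(trace - np.median(trace))))
    return mad * MAD_SCALE if scaled else mad


def _peaks_one_channel(x: np.ndarray, thr: float, sweep: int) -> np.ndarray:
    """Indices of local minima below ``-thr``, one per ±sweep window."""
    size = 2 * sweep + 1
    local_min = ndimage.minimum_filter1d(x, size=size, mode="nearest")
    cand = np.flatnonzero((x < -thr) & (x == local_min))
    if cand.size == 0:
        return cand
    # ties / plateaus within the sweep: keep the earliest sample
    keep = [cand[0]]
    for i in cand[1:]:
        if i - keep[-1] > sweep:
            keep.append(i)
        elif x[i] < x[keep[-1]]:
            keep[-1] = i
    return np.asarray(keep)


def detect_spikes(rec: Recording, k_mad: float = 5.0,
                  exclude_sweep_ms: float = 0.2,
                  sign: str = "neg",
                  mad_scaled: bool = True) -> SpikeTrainSet:
    """Threshold detection on every channel of a preprocessed recording.

    Parameters
    ----------
    k_mad : float
        Threshold in multiples of the per-channel MAD noise level.
    exclude_sweep_ms : float
        Half-width of the local-extremum exclusion window; of two peaks
        closer than this the deeper one wins (earliest on exact ties).
    sign : {"neg", "pos", "both"}
        Deflection polarity to detect.  Extracellular somatic/axonal
        spikes are negative-first, the default.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    if sign not in ("neg", "pos", "both"):
        raise ValueError(f"unknown sign {sign!r}")
    sweep = max(1, int(round(exclude_sweep_ms * 1e-3 * rec.fs)))
    trains: dict[str, np.ndarray] = {}
    noise: dict[str, float] = {}
    for cid, x in zip(rec.channel_ids, rec.data):
        level = noise_level_mad(x, scaled=mad_scaled)
        noise[cid] = level
        thr = k_mad * level
        idx_list = []
        if sign in ("neg", "both"):
            idx_list.append(_peaks_one_channel(x, thr, sweep))
        if sign in ("pos", "both"):
            idx_list.append(_peaks_one_channel(-x, thr, sweep))
        idx = np.unique(np.concatenate(idx_list))
        trains[cid] = sample_to_time(idx, rec.fs, rec.t0)
    return SpikeTrainSet(
        trains, rec.t0 + rec.duration,
        {"detector": "mad-threshold", "k_mad": k_mad,
         "exclude_sweep_ms": exclude_sweep_ms, "sign": sign,
         "mad_scaled": mad_scaled, "noise_uv": noise})
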