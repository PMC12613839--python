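"""Evoked-response analysis for light and electrical stimulation.

Responses to each stimulus are the detected AP peaks inside a 150 ms
post-onset window, amplitude-gated at 50 μV to exclude artifacts.  The
first-AP latency (light-on to peak) and the delta latencies between
consecutive AP peaks within one response are the summary statistics;
they are grouped by protocol (frequency / pulse width / intensity label).

Electrical pulses leave large artifacts on all electrodes, so samples
within a short span around each electrical onset are blanked by linear
interpolation before detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import Recording, SpikeTrainSet
from .detect import detect_spikes

__all__ = [
    "StimEvent",
    "EvokedResponse",
    "blank_artifacts",
    "extract_evoked_responses",
    "latency_stats",
    "stim_efficacy_by_count",
]


@dataclass(frozen=True)
class StimEvent:
    """One stimulus pulse."""

    onset: float                 # s
    kind: str = "light"          # "light" or "electrical"
    pulse_width_ms: float = 50.0
    label: str = ""              # protocol label, e.g. "2Hz/50ms" or "15uA"


@dataclass
class EvokedResponse:
    """Detected APs on one electrode after one stimulus."""

    stim_index: int
    electrode: str
    peak_times: np.ndarray       # s, absolute
    amplitudes_uv: np.ndarray
    onset: float
    label: str = ""
    truncated: bool = False      # window shortened by the next pulse

    @property
    def n_aps(self) -> int:
        return int(len(self.peak_times))

    @property
    def first_latency_ms(self) -> float:
        if self.n_aps == 0:
            return float("nan")
        return float((self.peak_times[0] - self.onset) * 1e3)

    @property
    def delta_latencies_ms(self) -> np.ndarray:
        return np.diff(self.peak_times) * 1e3


def _check_increasing(stims: Sequence[StimEvent]) -> None:
    onsets = [s.onset for s in stims]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("stimulus onsets must be strictly increasing")


def blank_artifacts(rec: Recording, stims: Sequence[StimEvent],
                    blank_ms: float = 2.0) -> Recording:
    """Linearly interpolate across ±``blank_ms`` around electrical onsets."""
    data = rec.data.copy()
    half = int(round(blank_ms * 1e-3 * rec.fs))
    for s in stims:
        if s.kind != "electrical":
            continue
        c = int(round((s.onset - rec.t0) * rec.fs))
        i0, i1 = max(0, c - half), min(rec.n_samples - 1, c + half)
        if i1 <= i0:
            continue
        for row in data:
            row[i0:i1 + 1] = np.linspace(row[i0], row[i1], i1 - i0 + 1)
    return rec.copy_with(data, artifact_blank_ms=blank_ms)


def extract_evoked_responses(rec: Recording, stims: Sequence[StimEvent],
                             window_ms: float = 150.0,
                             min_amp_uv: float = 50.0,
                             k_mad: float = 5.0,
                             blank_ms: float = 2.0,
                             spikes: SpikeTrainSet | None = None,
                             electrodes: Sequence[str] | None = None,
                             ) -> list[EvokedResponse]:
    """Per-stimulus, per-electrode evoked AP peaks.

    Peaks come from threshold detection on the preprocessed (and, for
    electrical stimulation, artifact-blanked) recording; a peak belongs
    to a response if it lies in ``(onset, onset + window_ms]`` and its
    magnitude exceeds ``min_amp_uv``.  When the next pulse starts before
    the window ends, the window is truncated there and flagged.  Failed
    stimuli (no accepted peak) are retained with empty arrays.
    """
    _check_increasing(stims)
    if any(s.onset < rec.t0 or s.onset > rec.t0 + rec.duration
           for s in stims):
        raise ValueError("stimulus onset outside the recording")
    if any(s.kind == "electrical" for s in stims):
        rec = blank_artifacts(rec, stims, blank_ms)
    if spikes is None:
        spikes = detect_spikes(rec, k_mad=k_mad)
    electrodes = (list(rec.channel_ids) if electrodes is None
                  else [str(c) for c in electrodes])
    win = window_ms * 1e-3
    out: list[EvokedResponse] = []
    for i, s in enumerate(stims):
        t_end = s.onset + win
        truncated = False
        if i + 1 < len(stims) and stims[i + 1].onset < t_end:
            t_end = stims[i + 1].onset
            truncated = True
        for cid in electrodes:
            t = spikes.train(cid)
            sel = (t > s.onset) & (t <= t_end)
            peaks = t[sel]
            trace = rec.channel(cid)
            idx = np.clip(np.round((peaks - rec.t0) * rec.fs).astype(int),
                          0, rec.n_samples - 1)
            amps = np.abs(trace[idx])
            keep = amps > min_amp_uv
            out.append(EvokedResponse(i, cid, peaks[keep], amps[keep],
                                      s.onset, s.label, truncated))
    return out


def latency_stats(responses: Sequence[EvokedResponse],
                  ci: float = 0.95) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latency summaries per protocol group.

    Returns ``(per_response, per_group)``: one row per stimulus ×
    electrode with first-AP latency and AP count, and one row per
    protocol label with mean latency ± t-based confidence interval,
    mean delta latency, response fraction and the APs-per-pulse mean.
    Groups with no successful response keep NaN summaries.
    """
    rows = [{
        "label": r.label, "stim_index": r.stim_index,
        "electrode": r.electrode, "n_aps": r.n_aps,
        "first_latency_ms": r.first_latency_ms,
        "mean_delta_latency_ms": (float(np.mean(r.delta_latencies_ms))
                                  if r.n_aps > 1 else float("nan")),
        "truncated": r.truncated,
    } for r in responses]
    per_response = pd.DataFrame(rows)
    groups = []
    for label, g in per_response.groupby("label", sort=True):
        lat = g["first_latency_ms"].dropna().to_numpy()
        deltas = np.concatenate(
            [r.delta_latencies_ms for r in responses
             if r.label == label and r.n_aps > 1] or [np.empty(0)])
        if lat.size:
            mean = float(lat.mean())
            if lat.size > 1 and lat.std(ddof=1) > 0:
                half = float(_stats.t.ppf(0.5 + ci / 2, lat.size - 1)
                             * lat.std(ddof=1) / np.sqrt(lat.size))
            else:
                half = 0.0
        else:
            mean = half = float("nan")
        groups.append({
            "label": label,
            "n_stimuli": int(g["stim_index"].nunique()),
            "n_responses": int((g["n_aps"] > 0).sum()),
            "mean_latency_ms": mean,
            "latency_ci_half_ms": half,
            "mean_delta_latency_ms": (float(deltas.mean())
                                      if deltas.size else float("nan")),
            "mean_aps_per_pulse": float(g["n_aps"].mean()),
        })
    return per_response, pd.DataFrame(groups)


def stim_efficacy_by_count(rates: pd.DataFrame) -> pd.DataFrame:
    """Evoked-rate change vs circuit size.

    ``rates`` needs columns ``circuit``, ``n_neurons``, ``epoch``
    ("baseline" or "stim") and ``rate_hz``.  Returns per-``n_neurons``
    median baseline and stimulation rates and the median per-circuit
    fold change (stim / baseline).  No hypothesis testing is done here;
    the table is meant for external statistics.
    """
    required = {"circuit", "n_neurons", "epoch", "rate_hz"}
    if not required.issubset(rates.columns):
        raise ValueError(f"rates table needs columns {sorted(required)}")
    wide = rates.pivot_table(index=["circuit", "n_neurons"], columns="epoch",
                             values="rate_hz", aggfunc="mean").reset_index()
    if "baseline" not in wide or wide["baseline"].isna().any():
        raise ValueError("missing baseline epoch for some circuit")
    wide["fold_change"] = wide["stim"] / wide["baseline"]
    out = (wide.groupby("n_neurons")
           .agg(n_circuits=("circuit", "nunique"),
                median_baseline_hz=("baseline", "median"),
                median_stim_hz=("stim", "median"),
                median_fold_change=("fold_change", "median"))
           .reset_index())
    return out
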