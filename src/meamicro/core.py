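"""Core data model for microchannel MEA circuit analysis.

Internal unit conventions, fixed at every interface:

* time        — seconds (timestamps are real-valued, not sample indices)
* voltage     — microvolts (μV)
* distance    — micrometres (μm)
* velocity    — metres per second (m/s)

Conversions from other units happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "Segment",
    "CircuitLayout",
    "SpikeTrainSet",
    "ConditionPair",
    "sample_to_time",
    "time_to_sample",
]


def sample_to_time(index: np.ndarray | int, fs: float, t0: float = 0.0):
    """Convert sample indices to timestamps (seconds). Index 0 maps to ``t0``."""
    return t0 + np.asarray(index, dtype=float) / fs


def time_to_sample(t: np.ndarray | float, fs: float, t0: float = 0.0):
    """Convert timestamps to sample indices (floor-based)."""
    return np.floor((np.asarray(t, dtype=float) - t0) * fs).astype(np.int64)


@dataclass
class Recording:
    """Multi-channel extracellular voltage recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples in μV.
    fs : float
        Sampling rate in Hz.
    channel_ids : sequence of str
        Ordered channel identifiers, one per data row.
    t0 : float
        Time of the first sample (s).
    layout_ref : str, optional
        Identifier of the associated :class:`CircuitLayout`.
    meta : dict
        Provenance: input path, processing parameters, seed.
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    t0: float = 0.0
    layout_ref: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_ids = [str(c) for c in self.channel_ids]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"channel count mismatch: {len(self.channel_ids)} ids for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(str(channel_id))]

    def times(self) -> np.ndarray:
        return sample_to_time(np.arange(self.n_samples), self.fs, self.t0)

    def copy_with(self, data: np.ndarray, **meta) -> "Recording":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Recording(data, self.fs, list(self.channel_ids), self.t0,
                         self.layout_ref, new_meta)


@dataclass(frozen=True)
class Segment:
    """A labelled span of cumulative distance along a microchannel path."""

    label: str
    start_um: float
    stop_um: float

    def __post_init__(self) -> None:
        if self.stop_um <= self.start_um:
            raise ValueError(f"segment {self.label!r}: empty span "
                             f"[{self.start_um}, {self.stop_um}]")

    def contains(self, d_um: float) -> bool:
        return self.start_um <= d_um < self.stop_um


@dataclass
class CircuitLayout:
    """Electrode geometry of one microchannel circuit.

    ``paths`` are ordered electrode sequences along a microchannel, in the
    direction of expected propagation.  ``segments`` label spans of the
    cumulative path distance (e.g. where axons run individually vs bundled).
    Distances are taken from the device design, not inferred from data.
    """

    positions: Mapping[str, tuple[float, float]]
    paths: Sequence[Sequence[str]]
    segments: Sequence[Segment] = field(default_factory=list)
    pitch_um: float = 200.0
    name: str = "layout"

    def __post_init__(self) -> None:
        self.positions = {str(k): (float(v[0]), float(v[1]))
                          for k, v in dict(self.positions).items()}
        self.paths = [[str(c) for c in p] for p in self.paths]
        for p in self.paths:
            if not p:
                raise ValueError("empty electrode path")
            for d in self.path_distances(p):
                if d <= 0:
                    raise ValueError("consecutive path electrodes must have "
                                     "strictly positive separation")
        segs = sorted(self.segments, key=lambda s: s.start_um)
        for a, b in zip(segs, segs[1:]):
            if b.start_um < a.stop_um:
                raise ValueError(f"overlapping segments {a.label!r}/{b.label!r}")
        self.segments = list(self.segments)

    def path_distances(self, path: Sequence[str]) -> list[float]:
        """Euclidean distances (μm) between consecutive electrodes."""
        pts = [np.asarray(self.positions[str(c)]) for c in path]
        return [float(np.linalg.norm(b - a)) for a, b in zip(pts, pts[1:])]

    def cumulative_distances(self, path: Sequence[str]) -> list[float]:
        """Cumulative distance (μm) of each electrode from the path start."""
        out = [0.0]
        for d in self.path_distances(path):
            out.append(out[-1] + d)
        return out

    def segment_of(self, d_um: float) -> str | None:
        """Segment label at cumulative distance ``d_um`` (None if unlabelled)."""
        for seg in self.segments:
            if seg.contains(d_um):
                return seg.label
        return None

    def pair_segment(self, path: Sequence[str], i: int) -> str | None:
        """Segment label of electrode pair (i, i+1), assigned by midpoint."""
        cum = self.cumulative_distances(path)
        mid = 0.5 * (cum[i] + cum[i + 1])
        return self.segment_of(mid)


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps for one recording.

    ``trains`` maps channel id to a strictly increasing float array of
    spike times (s); ``duration`` is the recording length (s).
    """

    trains: Mapping[str, np.ndarray]
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        clean: dict[str, np.ndarray] = {}
        for cid, t in dict(self.trains).items():
            t = np.asarray(t, dtype=float).ravel()
            if t.size:
                if np.any(np.diff(t) <= 0):
                    raise ValueError(f"channel {cid}: timestamps not strictly "
                                     "increasing")
                if t[0] < 0 or t[-1] > self.duration:
                    raise ValueError(f"channel {cid}: timestamps outside "
                                     f"[0, {self.duration}]")
            clean[str(cid)] = t
        self.trains = clean

    @property
    def channel_ids(self) -> list[str]:
        return list(self.trains.keys())

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def train(self, channel_id: str) -> np.ndarray:
        return self.trains[str(channel_id)]

    def subset(self, channel_ids: Iterable[str]) -> "SpikeTrainSet":
        ids = [str(c) for c in channel_ids]
        return SpikeTrainSet({c: self.trains[c] for c in ids}, self.duration,
                             dict(self.meta))


@dataclass
class ConditionPair:
    """Matched spike-train sets for two pharmacological conditions."""

    baseline: SpikeTrainSet
    treated: SpikeTrainSet
    label: str = "treated"

    def __post_init__(self) -> None:
        if set(self.baseline.channel_ids) != set(self.treated.channel_ids):
            raise ValueError("channel ids differ between conditions")
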