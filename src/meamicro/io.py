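"""Reading and writing of recordings, layouts, spike trains and metric tables.

Native recording container is HDF5 (dataset ``/data`` in μV, attributes
``fs``, ``unit``, ``channel_ids``, ``t0``, ``layout_ref``).  A flat binary
matrix with a JSON sidecar is also read, for interchange with minimal
acquisition dumps; the sidecar declares dtype, channel count, sampling
rate and a multiplicative scale to μV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import CircuitLayout, Recording, Segment, SpikeTrainSet

__all__ = [
    "read_recording",
    "write_recording",
    "write_metrics",
    "read_metrics",
    "write_spike_trains",
    "read_spike_trains",
    "write_layout",
    "read_layout",
]

_SIDECAR_REQUIRED = ("dtype", "n_channels", "fs_hz", "unit_scale_to_uv")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to the native HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["unit"] = "uV"
        f.attrs["fs"] = float(rec.fs)
        f.attrs["t0"] = float(rec.t0)
        f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        f.attrs["layout_ref"] = rec.layout_ref or ""
        f.attrs["meta_json"] = json.dumps(rec.meta, default=str)
    return path


def _read_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise KeyError(f"{path}: missing /data dataset")
        for key in ("fs", "channel_ids"):
            if key not in f.attrs:
                raise KeyError(f"{path}: missing required attribute {key!r}")
        data = f["data"][...]
        fs = float(f.attrs["fs"])
        channel_ids = [str(c) for c in f.attrs["channel_ids"]]
        t0 = float(f.attrs.get("t0", 0.0))
        layout_ref = str(f.attrs.get("layout_ref", "")) or None
        meta = json.loads(str(f.attrs.get("meta_json", "{}")))
    meta.setdefault("source", str(path))
    return Recording(data, fs, channel_ids, t0, layout_ref, meta)


def _read_flat(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"no JSON sidecar found for {path}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise KeyError(f"{sidecar}: missing metadata keys {missing}")
    raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    n_ch = int(meta["n_channels"])
    if n_ch <= 0 or raw.size % n_ch:
        raise ValueError(
            f"{path}: {raw.size} samples not divisible into "
            f"{n_ch} declared channels")
    data = raw.reshape(n_ch, -1).astype(float) * float(meta["unit_scale_to_uv"])
    channel_ids = [str(c) for c in
                   meta.get("channel_ids", range(n_ch))]
    if len(channel_ids) != n_ch:
        raise ValueError(f"{sidecar}: channel_ids length != n_channels")
    return Recording(data, float(meta["fs_hz"]), channel_ids,
                     float(meta.get("t0", 0.0)), meta.get("layout_ref"),
                     {"source": str(path)})


def read_recording(path: str | Path, format: str = "auto") -> Recording:
    """Read a recording; ``format`` is ``hdf5``, ``flat`` or ``auto``.

    Flat binary requires a JSON sidecar next to the file declaring
    ``dtype``, ``n_channels``, ``fs_hz`` and ``unit_scale_to_uv`` (values
    are converted to μV on load).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "hdf5" if h5py.is_hdf5(path) else "flat"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "flat":
        return _read_flat(path)
    raise ValueError(f"unknown recording format {format!r}")


def _to_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for r in results:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            rows.append(r)
        else:
            raise TypeError(f"cannot serialize {type(r).__name__} to a row")
    return pd.DataFrame(rows)


def write_metrics(results: Any, path: str | Path,
                  columns: Sequence[str] | None = None) -> Path:
    """Write stage output as a delimited text table (CSV, header always).

    Accepts a DataFrame or an iterable of dataclasses/dicts.  Column order
    is the dataclass field order (or ``columns`` if given) so repeated runs
    produce byte-identical headers.  An empty result yields a header-only
    file when ``columns`` is provided, else an empty file with header row
    of the frame.
    """
    path = Path(path)
    frame = _to_frame(results)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    frame.to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spike_trains(sts: SpikeTrainSet, path: str | Path) -> Path:
    """Write spike trains as CSV (columns ``channel,time_s``).

    The recording duration and provenance ride along in ``#``-prefixed
    header comments so the file round-trips losslessly.
    """
    path = Path(path)
    rows = [(cid, t) for cid in sts.channel_ids for t in sts.trains[cid]]
    with open(path, "w") as f:
        f.write(f"# duration_s={sts.duration!r}\n")
        f.write(f"# meta={json.dumps(sts.meta, default=str)}\n")
        f.write("channel,time_s\n")
        for cid, t in rows:
            f.write(f"{cid},{float(t)!r}\n")
    return path


def read_spike_trains(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    duration = None
    meta: dict = {}
    header_lines = 0
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "duration_s":
                duration = float(val)
            elif key.strip() == "meta":
                meta = json.loads(val)
    if duration is None:
        raise KeyError(f"{path}: missing duration_s header")
    df = pd.read_csv(path, skiprows=header_lines, dtype={"channel": str})
    trains = {str(cid): np.sort(g["time_s"].to_numpy(float))
              for cid, g in df.groupby("channel", sort=True)}
    return SpikeTrainSet(trains, duration, meta)


def write_layout(layout: CircuitLayout, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "name": layout.name,
        "pitch_um": layout.pitch_um,
        "positions": {c: list(p) for c, p in layout.positions.items()},
        "paths": [list(p) for p in layout.paths],
        "segments": [{"label": s.label, "start_um": s.start_um,
                      "stop_um": s.stop_um} for s in layout.segments],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_layout(path: str | Path) -> CircuitLayout:
    d = json.loads(Path(path).read_text())
    return CircuitLayout(
        positions={c: tuple(p) for c, p in d["positions"].items()},
        paths=d["paths"],
        segments=[Segment(s["label"], s["start_um"], s["stop_um"])
                  for s in d.get("segments", [])],
        pitch_um=d.get("pitch_um", 200.0),
        name=d.get("name", "layout"),
    )
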