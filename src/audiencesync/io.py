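"""Reading and writing the pipeline's on-disk formats.

Group recordings travel in a single HDF5 container (one group per subject,
with channel labels, rate and outlier mask); features, ISC series and scan
results are tidy CSV; configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import FeatureSeries, GroupRecording, Recording
from .isc import ISCSeries

__all__ = ["save_group", "load_group", "save_features", "load_features",
           "isc_to_frame", "save_isc", "load_config", "save_config"]


def save_group(group: GroupRecording, path: str | Path) -> None:
    """Write a GroupRecording to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["aligned"] = group.aligned
        f.attrs["sample_rate"] = group.sample_rate
        for i, rec in enumerate(group.recordings):
            g = f.create_group(f"subject_{i:03d}")
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["sample_rate"] = rec.sample_rate
            g.create_dataset("samples", data=rec.samples, compression="gzip")
            g.create_dataset("channel_labels",
                             data=np.array(rec.channel_labels, dtype="S"))
            if rec.mask is not None:
                g.create_dataset("mask", data=rec.mask, compression="gzip")


def load_group(path: str | Path) -> GroupRecording:
    with h5py.File(path, "r") as f:
        recs = []
        for key in sorted(k for k in f.keys() if k.startswith("subject_")):
            g = f[key]
            labels = [s.decode() for s in g["channel_labels"][()]]
            recs.append(Recording(
                subject_id=str(g.attrs["subject_id"]),
                channel_labels=labels,
                sample_rate=float(g.attrs["sample_rate"]),
                samples=g["samples"][()],
                mask=g["mask"][()] if "mask" in g else None,
            ))
        return GroupRecording(recs, aligned=bool(f.attrs.get("aligned", False)))


def save_features(features: dict[str, FeatureSeries], path: str | Path) -> None:
    """Tidy CSV: name, t_s, value, units."""
    rows = []
    for name, fs in features.items():
        for t, v in zip(fs.times, fs.values):
            rows.append({"name": name, "t_s": t, "value": v, "units": fs.units})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_features(path: str | Path) -> dict[str, FeatureSeries]:
    df = pd.read_csv(path)
    out = {}
    for name, sub in df.groupby("name", sort=False):
        t = sub["t_s"].to_numpy()
        rate = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
        units = str(sub["units"].iloc[0]) if "units" in sub else ""
        if units == "nan":
            units = ""
        out[str(name)] = FeatureSeries(name=str(name), rate=float(round(rate, 6)),
                                       values=sub["value"].to_numpy(),
                                       units=units, start=float(t[0]))
    return out


def isc_to_frame(series: list[ISCSeries]) -> pd.DataFrame:
    """Tidy frame: band, component, window_start_s, isc."""
    rows = []
    for s in series:
        for t, v in zip(s.start_times, s.values):
            rows.append({"band": s.band, "component": s.component,
                         "window_start_s": t, "isc": v})
    return pd.DataFrame(rows)


def save_isc(series: list[ISCSeries], path: str | Path) -> None:
    isc_to_frame(series).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
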