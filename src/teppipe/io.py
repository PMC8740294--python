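"""On-disk cohort and result formats.

A cohort directory contains:

* ``cohort.tsv`` -- one row per subject: subject_id, group, seed
* ``<subject_id>.npy`` -- the trials x channels x samples epoch array (uV)
* ``<subject_id>.json`` -- sidecar header: sfreq, first sample time,
  channel names and planar positions

Feature tables are plain CSV; reports are JSON with NaN serialized as null.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Cohort, EpochSet, SubjectRecord
from .montage import ChannelLayout

__all__ = ["save_cohort", "load_cohort", "save_features", "load_features",
           "write_json"]


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "seed": -1 if s.seed is None else s.seed})
        np.save(out / f"{s.subject_id}.npy", s.epochs.data)
        header = {
            "sfreq": s.epochs.sfreq,
            "tmin": float(s.epochs.times[0]),
            "n_samples": int(s.epochs.times.size),
            "channels": list(s.epochs.layout.names),
            "pos2d": s.epochs.layout.pos2d.tolist(),
            "group": s.group,
        }
        (out / f"{s.subject_id}.json").write_text(json.dumps(header))
    pd.DataFrame(rows).to_csv(out / "cohort.tsv", sep="\t", index=False)
    return out


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    meta = pd.read_csv(src / "cohort.tsv", sep="\t")
    subjects = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        header = json.loads((src / f"{sid}.json").read_text())
        layout = ChannelLayout(tuple(header["channels"]),
                               np.asarray(header["pos2d"]))
        data = np.load(src / f"{sid}.npy")
        times = header["tmin"] + np.arange(header["n_samples"]) / header["sfreq"]
        epochs = EpochSet(data=data, times=times, sfreq=header["sfreq"],
                          layout=layout)
        seed = int(row["seed"])
        subjects.append(SubjectRecord(subject_id=sid, group=str(row["group"]),
                                      epochs=epochs,
                                      seed=None if seed < 0 else seed))
    return Cohort(subjects)


def save_features(table: pd.DataFrame, path: str | Path,
                  config_hash: str | None = None) -> Path:
    """Write the feature table as CSV, optionally stamped with a config hash
    in a leading comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        table.to_csv(fh, index=False)
    return path


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def write_json(obj, path: str | Path) -> Path:
    """Write JSON with numpy scalars coerced and NaN mapped to null."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_sanitize(obj), indent=2, sort_keys=True))
    return path
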