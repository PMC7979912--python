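"""CSV/JSON schemas shared by the analyses and the CLI.

* length samples: ``condition,time_h,length_nm`` (one row per ribbon)
* gel lanes: ``label,role,intensity,loaded_volume_uL,reaction_volume_uL,
  duration_h,seed_conc``
* results: plain JSON with dataclasses flattened
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, List, Sequence

import numpy as np
import pandas as pd

from .gelquant import GelLane
from .growth import LengthSample

__all__ = [
    "write_length_samples",
    "read_length_samples",
    "write_gel_lanes",
    "read_gel_lanes",
    "write_json",
    "read_json",
]


def write_length_samples(samples: Sequence[LengthSample], path: str | Path) -> Path:
    rows = [
        {"condition": s.condition, "time_h": s.time_h, "length_nm": ln}
        for s in samples
        for ln in s.lengths
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["condition", "time_h", "length_nm"]).to_csv(
        path, index=False
    )
    return path


def read_length_samples(path: str | Path) -> List[LengthSample]:
    df = pd.read_csv(path)
    required = {"condition", "time_h", "length_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"length-sample CSV missing columns: {sorted(missing)}")
    out = []
    for (cond, t), grp in df.groupby(["condition", "time_h"], sort=True):
        out.append(
            LengthSample(
                time_h=float(t),
                lengths=grp["length_nm"].to_numpy(dtype=float),
                condition=str(cond),
            )
        )
    return out


def write_gel_lanes(lanes: Sequence[GelLane], path: str | Path) -> Path:
    rows = [dataclasses.asdict(l) for l in lanes]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_gel_lanes(path: str | Path) -> List[GelLane]:
    df = pd.read_csv(path)
    required = {
        "intensity",
        "loaded_volume_uL",
        "reaction_volume_uL",
        "duration_h",
        "role",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gel-lane CSV missing columns: {sorted(missing)}")
    lanes = []
    for _, row in df.iterrows():
        seed = row.get("seed_conc")
        lanes.append(
            GelLane(
                intensity=float(row["intensity"]),
                loaded_volume_uL=float(row["loaded_volume_uL"]),
                reaction_volume_uL=float(row["reaction_volume_uL"]),
                duration_h=float(row["duration_h"]),
                role=str(row["role"]),
                seed_conc=None if pd.isna(seed) else float(seed),
                label=str(row.get("label", "")),
            )
        )
    return lanes


class _Encoder(json.JSONEncoder):
    def default(self, o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_Encoder)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> Dict:
    with open(path) as fh:
        return json.load(fh)
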