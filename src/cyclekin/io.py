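"""File formats: track/trace/segmentation CSV, results JSON, run manifest.

All CSV files are comma-separated UTF-8 with a mandatory header row and
"." decimals; times are minutes from imaging start as floats.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fucci import FluorescenceTrace, PhaseSegmentation
from .lineage import LineageTree, build_trees

TRACK_COLUMNS = [
    "tree_id", "well_id", "cell_id", "parent_id", "birth_time_min",
    "end_time_min", "fate", "generation_offset", "size_class", "cd62l_class",
]
TRACE_COLUMNS = ["cell_id", "time_min", "ko2_au", "ag_au"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_tracks(path) -> pd.DataFrame:
    """Read a track CSV into the canonical record table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in TRACK_COLUMNS if c not in ("size_class", "cd62l_class")]
    _require_columns(df, required, path)
    for col in ("birth_time_min", "end_time_min"):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise SchemaError(
                f"{path}: non-numeric {col} at data row {bad + 1}"
            ) from None
    df["generation_offset"] = df["generation_offset"].astype(int)
    for col in ("size_class", "cd62l_class"):
        if col not in df.columns:
            df[col] = ""
    df.loc[df["parent_id"] == "", "parent_id"] = None
    return df[TRACK_COLUMNS]


def tracks_frame(trees: list[LineageTree]) -> pd.DataFrame:
    """Canonical track table (pre-order within tree, trees sorted by id)."""
    rows = []
    for tree in sorted(trees, key=lambda t: t.tree_id):
        for n in tree.nodes():
            rows.append(
                {
                    "tree_id": tree.tree_id,
                    "well_id": tree.well_id,
                    "cell_id": n.cell_id,
                    "parent_id": n.parent_id or "",
                    "birth_time_min": round(n.birth_time, 4),
                    "end_time_min": round(n.end_time, 4),
                    "fate": n.fate.value,
                    "generation_offset": n.generation_offset,
                    "size_class": n.size_class or "",
                    "cd62l_class": n.cd62l_class or "",
                }
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(trees: list[LineageTree], path) -> None:
    tracks_frame(trees).to_csv(path, index=False)


def read_track_trees(path, **kw) -> list[LineageTree]:
    df = read_tracks(path)
    records = df.to_dict("records")
    for r in records:
        if r["parent_id"] == "":
            r["parent_id"] = None
    return build_trees(pd.DataFrame(records), **kw)


def write_traces(traces: dict[str, FluorescenceTrace], path) -> None:
    frames = []
    for cid in sorted(traces):
        tr = traces[cid]
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "time_min": np.round(tr.times, 4),
                    "ko2_au": np.round(tr.ko2, 4),
                    "ag_au": np.round(tr.ag, 4),
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_traces(path) -> dict[str, FluorescenceTrace]:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    out = {}
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        out[str(cid)] = FluorescenceTrace(
            cell_id=str(cid),
            times=grp["time_min"].to_numpy(float),
            ko2=grp["ko2_au"].to_numpy(float),
            ag=grp["ag_au"].to_numpy(float),
        )
    return out


def write_segmentations(segs: list[PhaseSegmentation], path) -> None:
    frames = [s.to_frame() for s in segs]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "start_min", "end_min", "state"])
    )
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = __version__

    def finalize(self) -> None:
        self.finished = _now()
        for f in self.outputs:
            if not Path(f).exists():
                raise FileNotFoundError(f"manifest lists missing output: {f}")

    def write(self, path) -> None:
        self.finalize()
        write_json(self.__dict__, path)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def new_manifest(command: str, config_hash: str, seed: int | None) -> RunManifest:
    return RunManifest(command=command, config_hash=config_hash, seed=seed, started=_now())


def hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
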