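"""Readers and writers for the package's tabular formats.

One tabular dialect throughout: long/tidy CSV with a fixed column order for
diffability.  Trace tables carry (well, t_h, channel, value[, culture_type]);
count tables carry (day, species, count).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import E_CROSS, E_WT, S_CROSS, S_WT
from .media import MediaConfig
from .model import Trajectory

REQUIRED_TRACE_COLUMNS = ["well", "t_h", "channel", "value"]
REQUIRED_COUNT_COLUMNS = ["day", "species", "count"]

_STRAINS_BY_NAME = {"E": E_WT, "E_cross": E_CROSS, "S": S_WT,
                    "S_cross": S_CROSS}


def _read_csv(path: Union[str, Path], required, numeric) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise DataError(
                f"{path}: non-numeric {col!r} at row {int(bad[0]) + 2}")
        df[col] = vals
    return df


def read_timeseries(path: Union[str, Path]) -> pd.DataFrame:
    """Read a tidy trace CSV; typed error naming the offending row/column."""
    df = _read_csv(path, REQUIRED_TRACE_COLUMNS, ["t_h", "value"])
    if df.empty:
        raise DataError(f"{path}: no trace rows")
    return df


def write_timeseries(traces: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = [c for c in REQUIRED_TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise DataError(f"traces missing columns {missing}")
    cols = REQUIRED_TRACE_COLUMNS + [c for c in traces.columns
                                     if c not in REQUIRED_TRACE_COLUMNS]
    traces[cols].to_csv(path, index=False)


def read_counts(path: Union[str, Path]) -> pd.DataFrame:
    return _read_csv(path, REQUIRED_COUNT_COLUMNS, ["day", "count"])


def write_counts(counts: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = [c for c in REQUIRED_COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise DataError(f"counts missing columns {missing}")
    cols = REQUIRED_COUNT_COLUMNS + [c for c in counts.columns
                                     if c not in REQUIRED_COUNT_COLUMNS]
    counts[cols].to_csv(path, index=False)


def write_trajectory(traj: Trajectory, out_dir: Union[str, Path]) -> None:
    """Export a simulation: dense long-format CSV plus the daily samples."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(out / "trajectory.csv", index=False)
    traj.daily_frame().to_csv(out / "daily.csv", index=False)


def load_bundle(bundle_dir: Union[str, Path]):
    """Reload a written pseudo-experiment bundle (see synth.make_fixture_suite)."""
    from .synth import FixtureBundle, FixtureCondition

    d = Path(bundle_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {d}")
    manifest = json.loads(manifest_path.read_text())
    conditions = {}
    for cid, c in manifest["conditions"].items():
        conditions[cid] = FixtureCondition(
            donor=_STRAINS_BY_NAME[c["donor"]],
            recipient=_STRAINS_BY_NAME[c["recipient"]],
            media=MediaConfig(f_L=c["f_L"], f_W=c["f_W"],
                              mannose=c["mannose"]),
            n_donor=c["n_donor"], n_recipient=c["n_recipient"])
    images = {}
    files = manifest.get("files", {})
    if files.get("images"):
        import tifffile

        for key, name in files["images"].items():
            stack = tifffile.imread(d / name).astype(float)
            images[float(key)] = (stack[0], stack[1])
    return FixtureBundle(
        traces=read_timeseries(d / "traces.csv"),
        counts=read_counts(d / "counts.csv"),
        cfu=pd.read_csv(d / "cfu.csv"),
        images=images, conditions=conditions, manifest=manifest)
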