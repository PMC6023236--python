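"""CSV and JSON dialects used across the pipeline.

Force files come in two dialects, distinguished by header:

* raw 8-channel: ``time,fx12,fx34,fy14,fy23,fz1,fz2,fz3,fz4`` (s, N)
* pre-reduced:   ``time,FX,FY,FZ,copX,copY`` (s, N, m)

Marker files: ``time,led1X,led1Y,led1Z,led2X,led2Y,led2Z`` (s, m).
Columns are header-keyed, so order does not matter.  NaN gaps of at
most five samples are linearly interpolated (and logged); longer runs
raise.  Trial results serialize to JSON with stable key order, floats
at 12 significant digits, and a configuration hash, so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .energetics import TrialEnergetics
from .errors import DialectError, GapError, InputError
from .forceplate import CHANNEL_NAMES, ChannelRecord, GRFSeries
from .kinematics import MarkerSeries

__all__ = [
    "read_force_csv",
    "read_marker_csv",
    "write_force_csv",
    "write_marker_csv",
    "write_trial_json",
    "read_trial_json",
]

log = logging.getLogger("heelstrike")

RAW_FORCE_COLUMNS = ("time",) + CHANNEL_NAMES
REDUCED_FORCE_COLUMNS = ("time", "FX", "FY", "FZ", "copX", "copY")
MARKER_COLUMNS = ("time", "led1X", "led1Y", "led1Z", "led2X", "led2Y", "led2Z")

MAX_GAP = 5  # samples


def _fill_gaps(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    """Linearly interpolate NaN runs of <= MAX_GAP samples; error beyond."""
    for col in columns:
        isna = df[col].isna().to_numpy()
        if not isna.any():
            continue
        # length of each NaN run
        idx = np.flatnonzero(isna)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if run.size > MAX_GAP:
                raise GapError(
                    f"{what} column {col}: {run.size}-sample gap at rows "
                    f"[{run[0]}, {run[-1]}] exceeds the {MAX_GAP}-sample maximum"
                )
            log.info("%s column %s: filled %d-sample gap at row %d",
                     what, col, run.size, run[0])
        df[col] = df[col].interpolate(method="linear", limit_area="inside")
        if df[col].isna().any():
            raise GapError(f"{what} column {col}: gap at record edge cannot be filled")
    return df


def read_force_csv(path: str | Path) -> ChannelRecord | GRFSeries:
    """Read a force file, auto-detecting the dialect from the header."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(RAW_FORCE_COLUMNS) <= cols:
        df = _fill_gaps(df, list(RAW_FORCE_COLUMNS), "force")
        return ChannelRecord(
            time=df["time"].to_numpy(),
            **{c: df[c].to_numpy() for c in CHANNEL_NAMES},
        )
    if set(REDUCED_FORCE_COLUMNS) <= cols:
        df = _fill_gaps(df, ["time", "FX", "FY", "FZ"], "force")
        return GRFSeries(
            time=df["time"].to_numpy(),
            F_X=df["FX"].to_numpy(), F_Y=df["FY"].to_numpy(), F_Z=df["FZ"].to_numpy(),
            cop_X=df["copX"].to_numpy(), cop_Y=df["copY"].to_numpy(),
        )
    raise DialectError(
        f"unknown force header {sorted(cols)}; expected "
        f"{list(RAW_FORCE_COLUMNS)} or {list(REDUCED_FORCE_COLUMNS)}"
    )


def read_marker_csv(path: str | Path) -> MarkerSeries:
    """Read a two-LED marker file."""
    df = pd.read_csv(path)
    if not set(MARKER_COLUMNS) <= set(df.columns):
        raise DialectError(
            f"unknown marker header {sorted(df.columns)}; expected {list(MARKER_COLUMNS)}"
        )
    df = _fill_gaps(df, list(MARKER_COLUMNS), "marker")
    return MarkerSeries(
        time=df["time"].to_numpy(),
        led1=df[["led1X", "led1Y", "led1Z"]].to_numpy(),
        led2=df[["led2X", "led2Y", "led2Z"]].to_numpy(),
    )


def write_force_csv(rec: ChannelRecord | GRFSeries, path: str | Path) -> None:
    if isinstance(rec, ChannelRecord):
        df = pd.DataFrame({"time": rec.time,
                           **{c: getattr(rec, c) for c in CHANNEL_NAMES}})
    else:
        df = pd.DataFrame({
            "time": rec.time, "FX": rec.F_X, "FY": rec.F_Y, "FZ": rec.F_Z,
            "copX": rec.cop_X, "copY": rec.cop_Y,
        })
    df.to_csv(path, index=False, float_format="%.9g")


def write_marker_csv(markers: MarkerSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "time": markers.time,
        "led1X": markers.led1[:, 0], "led1Y": markers.led1[:, 1], "led1Z": markers.led1[:, 2],
        "led2X": markers.led2[:, 0], "led2Y": markers.led2[:, 1], "led2Z": markers.led2[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.10g")


def _round12(obj):
    """Round floats to 12 significant digits recursively."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    return obj


def write_trial_json(
    result: TrialEnergetics, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Serialize a trial result (stable key order, 12 significant digits)."""
    payload = _round12(result.to_dict())
    payload["config_hash"] = (config or PipelineConfig()).hash()
    payload["software_version"] = __version__
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_trial_json(path: str | Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if "W" not in payload:
        raise InputError(f"{path} does not look like a trial result")
    return payload
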