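"""Delimited-text formats for trial tables and mouse trajectories.

Both files are plain CSV with a header row, preceded by a one-line schema
comment (``# serialbias-schema: <kind> v<major>.<minor>``). Readers accept
files without the comment (assumed v1) and reject newer major versions.

Trial table columns:
    participant, task, report_type, trial_index,
    target_deg, prev_target_deg, response_deg, is_random
Trajectory table (long format) columns:
    participant, trial_index, report_type, timestamp_ms, x_px, y_px,
    target_angle_deg
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .errors import TRIAL_COLUMNS
from .simulate import TrajectorySamples

__all__ = [
    "SCHEMA_VERSION",
    "write_trials",
    "read_trials",
    "write_trajectories",
    "read_trajectories",
]

SCHEMA_VERSION = (1, 0)

TRAJECTORY_COLUMNS = [
    "participant", "trial_index", "report_type",
    "timestamp_ms", "x_px", "y_px", "target_angle_deg",
]

_SCHEMA_RE = re.compile(r"#\s*serialbias-schema:\s*(\w+)\s+v(\d+)\.(\d+)")


def _schema_line(kind: str) -> str:
    return f"# serialbias-schema: {kind} v{SCHEMA_VERSION[0]}.{SCHEMA_VERSION[1]}\n"


def _check_schema(path, kind: str):
    with open(path) as fh:
        first = fh.readline()
    m = _SCHEMA_RE.match(first)
    if not m:
        return 0  # no schema line: legacy/external file, header on line 1
    found_kind, major = m.group(1), int(m.group(2))
    if found_kind != kind:
        raise ValueError(f"{path}: schema kind {found_kind!r}, expected {kind!r}")
    if major > SCHEMA_VERSION[0]:
        raise ValueError(
            f"{path}: schema major version {major} is newer than supported "
            f"{SCHEMA_VERSION[0]}"
        )
    return 1


def _numeric(df, col, *, allow_missing=False, lines=None):
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() if allow_missing else out.isna()
    if bad.any():
        where = (lines[bad] if lines is not None else df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"column {col!r}: unparseable values at line(s) {where}")
    return out


def write_trials(trials: pd.DataFrame, path):
    with open(path, "w") as fh:
        fh.write(_schema_line("trials"))
        trials.to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; angles are wrap-normalized."""
    skip = _check_schema(path, "trials")
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    lines = pd.Series(df.index + skip + 2, index=df.index)  # 1-based file lines
    for col in ("target_deg", "response_deg"):
        vals = _numeric(df, col, lines=lines)
        out_of_range = (vals < 0) | (vals >= 360)
        if out_of_range.any():
            warnings.warn(
                f"{path}: {int(out_of_range.sum())} value(s) in {col!r} outside "
                "[0, 360); wrapped onto the wheel"
            )
        df[col] = wrap_angle(vals.to_numpy(float))
    prev = _numeric(df, "prev_target_deg", allow_missing=True, lines=lines)
    with np.errstate(invalid="ignore"):
        df["prev_target_deg"] = np.where(
            prev.isna(), np.nan, wrap_angle(prev.fillna(0.0).to_numpy(float))
        )
    df["is_random"] = df["is_random"].astype(bool)
    df["trial_index"] = _numeric(df, "trial_index", lines=lines).astype(int)

    dup = df.duplicated(["participant", "trial_index", "report_type"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, trial_index, report_type) at "
            f"line(s) {lines[dup].tolist()[:5]}"
        )
    return df


def write_trajectories(trajectories: dict, path):
    """Write a ``(participant, report_type, trial_index) -> TrajectorySamples``
    map as one long-format CSV."""
    frames = []
    for (participant, report_type, trial_index), traj in trajectories.items():
        frames.append(pd.DataFrame({
            "participant": participant,
            "trial_index": trial_index,
            "report_type": report_type,
            "timestamp_ms": traj.timestamps,
            "x_px": traj.xs,
            "y_px": traj.ys,
            "target_angle_deg": traj.target_angle,
        }))
    long = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_schema_line("trajectories"))
        long.to_csv(fh, index=False)


def read_trajectories(path, trials: pd.DataFrame | None = None) -> dict:
    """Read a long-format trajectory table into per-response samples.

    Rows are grouped by (participant, report_type, trial_index) and sorted
    by timestamp; duplicate timestamps within a response are rejected. When
    ``trials`` is given, trajectories without a matching trial record raise
    an orphan error.
    """
    skip = _check_schema(path, "trajectories")
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    known = None
    if trials is not None:
        known = set(zip(trials["participant"], trials["report_type"], trials["trial_index"]))
    out = {}
    for key, grp in df.groupby(["participant", "report_type", "trial_index"], sort=True):
        participant, report_type, trial_index = key
        if known is not None and key not in known:
            raise ValueError(f"{path}: orphan trajectory {key} has no trial record")
        grp = grp.sort_values("timestamp_ms")
        t = grp["timestamp_ms"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-increasing timestamps in trajectory {key}")
        out[(participant, report_type, int(trial_index))] = TrajectorySamples(
            timestamps=t,
            xs=grp["x_px"].to_numpy(float),
            ys=grp["y_px"].to_numpy(float),
            target_angle=float(grp["target_angle_deg"].iloc[0]),
        )
    return out
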