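"""Mouse-trajectory preprocessing and serial-bias trajectory statistics.

Each response's cursor path is reduced to a time-normalized horizontal
deviation profile: movement onset (first sample more than 10 px from the
screen center) defines 0% of movement time and the final click 100%; the
path is linearly interpolated onto an even grid, rigidly rotated so that
the target's wheel direction points up, and the rotated x-coordinate ``h``
(positive = clockwise side of the target, matching the response-error sign
convention) is re-anchored to the onset point so that h(0) = 0.

Two summary statistics feed the DoG fits:

* AUC — the trapezoid integral of h over normalized time [0, 1]; the
  endpoint-excluded variant integrates ``h(t) - t*h(1)``, removing the
  straight ramp to the final click (the unique linear detrend that zeroes
  the endpoint while keeping h(0) = 0). The two variants always satisfy
  AUC_with - AUC_without = h(1)/2.
* the deviation profile — h at the 20 nodes 5%, 10%, ..., 100%, which feeds
  the four-level (time-resolved) hierarchical model.

Movement-onset latencies support a within-cell median split (trials at or
below the median go to the early set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import assign_condition, summarize_conditions, synthesize_edge
from .simulate import TrajectorySamples

__all__ = [
    "UnusableTrajectoryError",
    "AlignedTrajectory",
    "AUCResult",
    "detect_onset",
    "normalize_time",
    "rotate_to_target",
    "compute_auc",
    "auc_result",
    "preprocess_trajectory",
    "trajectory_features",
    "auc_condition_summaries",
    "deviation_profiles",
    "median_split_by_onset",
]

ONSET_THRESHOLD_PX = 10.0
N_GRID = 101  # even grid on [0, 1]; embeds the 5%-step nodes exactly
TIME_NODES = np.round(np.arange(1, 21) * 0.05, 2)  # 0.05 .. 1.00


class UnusableTrajectoryError(ValueError):
    """Raised when a path never leaves the onset threshold or has no movement."""


@dataclass
class AlignedTrajectory:
    """Time-normalized, target-rotated horizontal deviation profile."""

    t_norm: np.ndarray  # grid on [0, 1]; 0 = movement onset, 1 = click
    h: np.ndarray       # horizontal offset, px; h[0] == 0 by construction
    onset_latency_ms: float


@dataclass
class AUCResult:
    auc_with_endpoint: float   # px * (unit normalized time)
    auc_without_endpoint: float
    endpoint_offset: float     # h(1), px


def detect_onset(traj: TrajectorySamples, threshold_px: float = ONSET_THRESHOLD_PX):
    """First sample strictly more than ``threshold_px`` from the start.

    Returns ``(onset_index, latency_ms)``; latency is that sample's
    timestamp. Raises :class:`UnusableTrajectoryError` when no sample
    exceeds the threshold.
    """
    dx = traj.xs - traj.xs[0]
    dy = traj.ys - traj.ys[0]
    dist = np.hypot(dx, dy)
    beyond = np.flatnonzero(dist > threshold_px)
    if beyond.size == 0:
        raise UnusableTrajectoryError(
            f"cursor never moved more than {threshold_px} px from the start"
        )
    i = int(beyond[0])
    return i, float(traj.timestamps[i])


def normalize_time(traj: TrajectorySamples, onset_index: int, n_grid: int = N_GRID):
    """Linear interpolation of the path onto an even grid over [onset, click].

    Returns ``(t_norm, x, y)``; grid endpoints reproduce the onset and click
    positions exactly.
    """
    t0 = traj.timestamps[onset_index]
    t1 = traj.timestamps[-1]
    if not (t1 > t0):
        raise UnusableTrajectoryError("movement onset coincides with the click")
    t_norm = np.linspace(0.0, 1.0, n_grid)
    t = t0 + t_norm * (t1 - t0)
    x = np.interp(t, traj.timestamps[onset_index:], traj.xs[onset_index:])
    y = np.interp(t, traj.timestamps[onset_index:], traj.ys[onset_index:])
    return t_norm, x, y


def rotate_to_target(xs, ys, target_angle: float):
    """Rigid rotation mapping the target's wheel direction onto vertical.

    Wheel angles are measured clockwise from the positive vertical axis, so
    a point at wheel angle ``target + phi`` and radius r maps to
    ``(r sin phi, r cos phi)``: its first coordinate ``h`` is positive on
    the clockwise side of the target. Returns ``(h, v)``.
    """
    rad = np.deg2rad(float(target_angle))
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    h = xs * np.cos(rad) - ys * np.sin(rad)
    v = xs * np.sin(rad) + ys * np.cos(rad)
    return h, v


def preprocess_trajectory(traj: TrajectorySamples,
                          threshold_px: float = ONSET_THRESHOLD_PX,
                          n_grid: int = N_GRID) -> AlignedTrajectory:
    """Onset detection + time normalization + rotation, h anchored at onset."""
    onset_index, latency = detect_onset(traj, threshold_px)
    t_norm, x, y = normalize_time(traj, onset_index, n_grid)
    h, _ = rotate_to_target(x, y, traj.target_angle)
    return AlignedTrajectory(t_norm=t_norm, h=h - h[0], onset_latency_ms=latency)


def compute_auc(aligned: AlignedTrajectory, include_endpoint: bool = True) -> float:
    """Trapezoid integral of the horizontal deviation over normalized time.

    With ``include_endpoint=False`` the straight ramp to the final cursor
    position, ``t * h(1)``, is subtracted before integrating.
    """
    h = aligned.h
    if not include_endpoint:
        h = h - aligned.t_norm * h[-1]
    return float(np.trapezoid(h, aligned.t_norm))


def auc_result(aligned: AlignedTrajectory) -> AUCResult:
    return AUCResult(
        auc_with_endpoint=compute_auc(aligned, include_endpoint=True),
        auc_without_endpoint=compute_auc(aligned, include_endpoint=False),
        endpoint_offset=float(aligned.h[-1]),
    )


def trajectory_features(trajectories: dict,
                        threshold_px: float = ONSET_THRESHOLD_PX,
                        auc_scale: float = 1.0) -> pd.DataFrame:
    """Per-response trajectory statistics for a whole dataset.

    ``trajectories`` maps ``(participant, report_type, trial_index)`` to
    :class:`TrajectorySamples` (the simulator's and the reader's layout).
    Unusable paths are kept with ``usable=False`` and NaN statistics; the
    node columns ``h_5 .. h_100`` hold the deviation at the 20 time nodes.
    ``auc_scale`` rescales both AUC variants (e.g. 100 for percent-time
    units).
    """
    rows = []
    for (participant, report_type, trial_index), traj in trajectories.items():
        rec = {
            "participant": participant,
            "report_type": report_type,
            "trial_index": trial_index,
        }
        try:
            aligned = preprocess_trajectory(traj, threshold_px)
        except UnusableTrajectoryError:
            rec.update({
                "usable": False, "onset_latency_ms": np.nan,
                "auc_with": np.nan, "auc_without": np.nan, "endpoint": np.nan,
            })
            rec.update({f"h_{int(round(t * 100))}": np.nan for t in TIME_NODES})
            rows.append(rec)
            continue
        res = auc_result(aligned)
        rec.update({
            "usable": True,
            "onset_latency_ms": aligned.onset_latency_ms,
            "auc_with": res.auc_with_endpoint * auc_scale,
            "auc_without": res.auc_without_endpoint * auc_scale,
            "endpoint": res.endpoint_offset,
        })
        idx = np.rint(TIME_NODES * (aligned.t_norm.size - 1)).astype(int)
        for t, i in zip(TIME_NODES, idx):
            rec[f"h_{int(round(t * 100))}"] = aligned.h[i]
        rows.append(rec)
    return pd.DataFrame(rows)


def _merge_with_conditions(features: pd.DataFrame, trials: pd.DataFrame,
                           flip_sign: bool = False) -> pd.DataFrame:
    assigned = assign_condition(trials, flip_sign=flip_sign)
    keys = ["participant", "report_type", "trial_index"]
    merged = features.merge(
        assigned[keys + ["condition_bin", "included"]], on=keys, how="left",
        validate="one_to_one",
    )
    merged["included"] = merged["included"].fillna(False) & merged["usable"]
    return merged


def auc_condition_summaries(features: pd.DataFrame, trials: pd.DataFrame,
                            *, flip_sign: bool = False,
                            edge_variant: str = "mean") -> pd.DataFrame:
    """Mean AUC per participant x report type x relative-color bin.

    Plain (linear) means — AUC is not an angle. Returns the ten-bin table
    with both variants as columns ``auc_with`` and ``auc_without``.
    """
    merged = _merge_with_conditions(features, trials, flip_sign)
    with_ep = synthesize_edge(
        summarize_conditions(merged, value_col="auc_with", circular=False),
        value_col="auc_with", variant=edge_variant,
    )
    without_ep = synthesize_edge(
        summarize_conditions(merged, value_col="auc_without", circular=False),
        value_col="auc_without", variant=edge_variant,
    )
    return with_ep.merge(
        without_ep.drop(columns=["n_trials"]),
        on=["participant", "report_type", "bin_center"],
        validate="one_to_one",
    )


def deviation_profiles(features: pd.DataFrame, trials: pd.DataFrame,
                       *, flip_sign: bool = False,
                       edge_variant: str = "mean") -> pd.DataFrame:
    """Mean horizontal deviation at the 20 time nodes per cell and bin.

    Tidy output (participant, report_type, time_point, bin_center,
    mean_dev, n_trials); feeds the four-level hierarchical fit.
    """
    merged = _merge_with_conditions(features, trials, flip_sign)
    node_cols = {f"h_{int(round(t * 100))}": t for t in TIME_NODES}
    long = merged.melt(
        id_vars=["participant", "report_type", "trial_index", "condition_bin", "included"],
        value_vars=list(node_cols),
        var_name="node", value_name="mean_dev",
    )
    long["time_point"] = long["node"].map(node_cols)
    nine = summarize_conditions(
        long, value_col="mean_dev", circular=False, extra_keys=("time_point",)
    )
    return synthesize_edge(nine, value_col="mean_dev", variant=edge_variant)


def median_split_by_onset(features: pd.DataFrame) -> pd.DataFrame:
    """Label each usable trajectory early/late by within-cell median latency.

    Trials at or below the participant-by-report median onset latency are
    ``early``; strictly above, ``late``. Cells with fewer than 2 usable
    trials (or an empty late half, e.g. all latencies tied) are flagged in
    the ``onset_split_ok`` column.
    """
    df = features.copy()
    usable = df["usable"].fillna(False)
    med = (
        df[usable]
        .groupby(["participant", "report_type"])["onset_latency_ms"]
        .transform("median")
    )
    half = pd.Series(pd.NA, index=df.index, dtype="object")
    half[usable] = np.where(df.loc[usable, "onset_latency_ms"] <= med, "early", "late")
    df["onset_half"] = half

    ok = (
        df[usable]
        .groupby(["participant", "report_type"])["onset_half"]
        .agg(lambda s: (s == "early").any() and (s == "late").any() and s.size >= 2)
        .rename("onset_split_ok")
        .reset_index()
    )
    df = df.merge(ok, on=["participant", "report_type"], how="left")
    df["onset_split_ok"] = df["onset_split_ok"].fillna(False)
    return df
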