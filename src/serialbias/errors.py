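"""From trial records to condition-binned circular mean errors.

The serial-bias predictor ``x`` is the previous trial's target color
relative to the current target, ``x = wrap(prev_target - target)``:
negative = previous target counterclockwise of the current one, positive =
clockwise. Response errors share the sign convention (positive = clockwise
of the target), so positive mean error at positive ``x`` is attraction.

Trials are binned on the nine step conditions -144:36:+144. Random-condition
trials, trials immediately following a random trial (their ``x`` is off the
36-degree grid), and the first trial of each block are excluded. After
binning, a tenth bin at +/-180 is synthesized by averaging the two edge
bins, giving the ten conditions the DoG curve is fitted to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circular_mean, signed_difference, wrap_signed
from .simulate import REPORT_TYPES, STEP_OFFSETS

__all__ = [
    "compute_error",
    "assign_condition",
    "summarize_conditions",
    "synthesize_edge",
    "prepare_condition_summaries",
    "correlate_alphas",
]

#: tolerance (degrees) for snapping a non-random trial's x onto the step grid
GRID_TOL = 1.0

TRIAL_COLUMNS = [
    "participant", "task", "report_type", "trial_index",
    "target_deg", "prev_target_deg", "response_deg", "is_random",
]


def compute_error(trials: pd.DataFrame) -> pd.Series:
    """Signed response error, response minus target, in (-180, +180]."""
    for col in ("response_deg", "target_deg"):
        if col not in trials:
            raise ValueError(f"missing column {col!r}")
        if trials[col].isna().any():
            raise ValueError(f"column {col!r} contains missing values")
    return pd.Series(
        signed_difference(trials["response_deg"].to_numpy(float),
                          trials["target_deg"].to_numpy(float)),
        index=trials.index,
        name="error_deg",
    )


def assign_condition(trials: pd.DataFrame, *, flip_sign: bool = False) -> pd.DataFrame:
    """Attach relative-color offsets, condition bins, and inclusion flags.

    Adds columns: ``error_deg``, ``x_deg`` (previous target relative to the
    current one; flipped if ``flip_sign``), ``condition_bin`` (one of the
    nine step offsets, NaN when excluded), ``included`` and
    ``exclusion_reason`` in {first_trial, random_condition, post_random}.

    A non-random, non-post-random trial whose ``x`` is more than 1 degree
    off the 36-degree grid indicates corrupted data and raises.
    """
    df = trials.copy()
    df["error_deg"] = compute_error(df)
    prev = df["prev_target_deg"].to_numpy(float)
    tgt = df["target_deg"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        x = np.where(np.isnan(prev), np.nan, wrap_signed(np.nan_to_num(prev) - tgt))
    if flip_sign:
        flipped = wrap_signed(-np.nan_to_num(x))  # negation; -180 maps to +180
        x = np.where(np.isnan(x), np.nan, flipped)
    df["x_deg"] = x

    is_random = df["is_random"].to_numpy(bool)
    post_random = (
        df.sort_values("trial_index")
        .groupby(["participant", "task", "report_type"], sort=False)["is_random"]
        .shift(1, fill_value=False)
        .reindex(df.index)
        .to_numpy(bool)
    )
    first = np.isnan(x)

    reason = np.full(df.shape[0], None, dtype=object)
    reason[post_random] = "post_random"
    reason[is_random] = "random_condition"
    reason[first] = "first_trial"
    included = first | is_random | post_random
    included = ~included
    df["included"] = included
    df["exclusion_reason"] = reason

    steps = np.asarray(STEP_OFFSETS, float)
    bins = np.full(df.shape[0], np.nan)
    if included.any():
        xi = x[included]
        nearest = steps[np.argmin(np.abs(xi[:, None] - steps[None, :]), axis=1)]
        off = np.abs(xi - nearest)
        if np.any(off > GRID_TOL):
            bad = np.flatnonzero(included)[off > GRID_TOL][:5]
            raise ValueError(
                "data integrity: included trials with relative color off the "
                f"36-degree grid by more than {GRID_TOL} degree at rows {bad.tolist()}"
            )
        bins[included] = nearest
    df["condition_bin"] = bins
    return df


def summarize_conditions(assigned: pd.DataFrame, value_col: str = "error_deg",
                         *, circular: bool = True,
                         extra_keys: tuple = ()) -> pd.DataFrame:
    """Per-cell mean of ``value_col`` over the nine raw condition bins.

    Cells are participant x report type (x ``extra_keys``) x bin. Circular
    means are used for angular values; plain means otherwise (e.g. AUCs).
    A cell with no included trials raises, listing the missing cells.
    """
    df = assigned[assigned["included"]]
    keys = ["participant", "report_type", *extra_keys, "condition_bin"]
    grouped = df.groupby(keys, sort=True)[value_col]
    mean = grouped.apply(lambda v: circular_mean(v.to_numpy()) if circular else float(np.mean(v)))
    count = grouped.size()
    out = pd.DataFrame({value_col: mean, "n_trials": count}).reset_index()

    cells = out.groupby(["participant", "report_type", *extra_keys], sort=True)["condition_bin"].agg(set)
    expected = set(float(s) for s in STEP_OFFSETS)
    missing = {idx: sorted(expected - got) for idx, got in cells.items() if expected - got}
    if missing:
        raise ValueError(f"cells with empty condition bins: {missing}")
    out = out.rename(columns={"condition_bin": "bin_center"})
    return out


def synthesize_edge(summaries: pd.DataFrame, value_col: str = "error_deg",
                    *, variant: str = "mean") -> pd.DataFrame:
    """Append the synthesized +/-180 bin, keeping the nine raw bins (10 total).

    ``variant='mean'`` (default) places the plain average of the -144 and
    +144 bin means at +180 — the DoG predicts a near-zero value there under
    odd symmetry. ``variant='odd'`` uses the sign-respecting half-difference
    (e(+144) - e(-144))/2 instead.
    """
    if variant not in ("mean", "odd"):
        raise ValueError(f"unknown edge-synthesis variant {variant!r}")
    keys = [c for c in summaries.columns
            if c not in ("bin_center", value_col, "n_trials")]
    rows = []
    for idx, grp in summaries.groupby(keys, sort=True):
        by_bin = grp.set_index("bin_center")[value_col]
        if -144.0 not in by_bin.index or 144.0 not in by_bin.index:
            raise ValueError(f"cell {idx}: missing edge bin(s), cannot synthesize +/-180")
        lo, hi = by_bin.loc[-144.0], by_bin.loc[144.0]
        val = (lo + hi) / 2.0 if variant == "mean" else (hi - lo) / 2.0
        n = int(grp.set_index("bin_center")["n_trials"].loc[[-144.0, 144.0]].sum())
        rec = dict(zip(keys, idx if isinstance(idx, tuple) else (idx,)))
        rec.update({"bin_center": 180.0, value_col: val, "n_trials": n})
        rows.append(rec)
    out = pd.concat([summaries, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values([*keys, "bin_center"], ignore_index=True)


def prepare_condition_summaries(trials: pd.DataFrame, *, flip_sign: bool = False,
                                edge_variant: str = "mean") -> pd.DataFrame:
    """Trials -> ten-bin circular mean error table (the DoG fit's y values)."""
    assigned = assign_condition(trials, flip_sign=flip_sign)
    nine = summarize_conditions(assigned)
    return synthesize_edge(nine, variant=edge_variant)


def correlate_alphas(alphas: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-participant bias amplitudes.

    ``alphas`` is a participant-indexed frame with one column per report
    type (posterior-mean amplitudes). Returns one row per report-type pair
    with r, df = n - 2, and the two-sided p value. Constant columns and
    missing values raise.
    """
    cols = [c for c in REPORT_TYPES if c in alphas.columns]
    if len(cols) < 2:
        raise ValueError("need at least two report-type columns")
    if alphas[cols].isna().any().any():
        raise ValueError("missing amplitude values")
    n = alphas.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            va, vb = alphas[a].to_numpy(float), alphas[b].to_numpy(float)
            if np.std(va) == 0 or np.std(vb) == 0:
                raise ValueError(f"zero variance in {a!r} or {b!r}: correlation undefined")
            r, p = stats.pearsonr(va, vb)
            rows.append({"pair": f"{a}~{b}", "r": float(r), "df": n - 2, "p": float(p)})
    return pd.DataFrame(rows)
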