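"""Cleaning rules and derived behavioural/EMG summary measures.

All summary measures operate subject-wise (paired analyses): stopping delay
is the excess of successful-stop unimanual RT over bimanual go RT within a
condition; proactive slowing is the bimanual-RT difference between the
proactive and reactive conditions; relative RT and relative EMG onset
subtract each trial's SSD before averaging, the natural clock for a response
triggered by the stop signal.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .task_design import CORRECT_UNIMANUAL, DR, DS, LS, PROACTIVE, REACTIVE, RS


def _is_stop(df: pd.DataFrame) -> pd.Series:
    return df["stimulus"].isin((LS, RS))


def _is_successful_stop(df: pd.DataFrame) -> pd.Series:
    correct = df["stimulus"].map(CORRECT_UNIMANUAL)
    return _is_stop(df) & (df["response"] == correct)


def exclude_participants(
    dataset: pd.DataFrame, min_stop_success: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participants whose overall stop-success rate is below
    ``min_stop_success`` (strict inequality); returns the reduced dataset and
    an exclusion report listing every participant's rate."""
    stop = dataset[_is_stop(dataset)]
    rates = (
        _is_successful_stop(stop)
        .groupby(stop["participant"])
        .mean()
        .rename("stop_success_rate")
        .reset_index()
    )
    rates["excluded"] = rates["stop_success_rate"] < min_stop_success
    keep = set(rates.loc[~rates["excluded"], "participant"])
    return dataset[dataset["participant"].isin(keep)].copy(), rates


def clean_bimanual(
    dataset: pd.DataFrame, max_async_ms: float = 50.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop bimanual (DR) responses whose left-right press asynchrony exceeds
    ``max_async_ms`` (strict) and set the surviving DR trials' RT to the mean
    of the two presses.  Idempotent.  Returns the cleaned dataset and a
    per-participant removal report."""
    df = dataset.copy()
    is_dr = df["response"] == DR
    if is_dr.any():
        missing = is_dr & (df["rt_left_ms"].isna() | df["rt_right_ms"].isna())
        if missing.any():
            bad = df.loc[missing, ["participant", "condition", "trial"]].iloc[0]
            raise ValueError(
                "DR-labelled trial without both press times "
                f"(first: participant {bad['participant']}, "
                f"{bad['condition']} trial {bad['trial']})"
            )
    async_ = (df["rt_left_ms"] - df["rt_right_ms"]).abs()
    drop = is_dr & (async_ > max_async_ms)
    df.loc[is_dr & ~drop, "rt_ms"] = (
        df.loc[is_dr & ~drop, ["rt_left_ms", "rt_right_ms"]].mean(axis=1)
    )
    report = (
        pd.DataFrame({
            "participant": df.loc[is_dr, "participant"],
            "removed": drop[is_dr],
        })
        .groupby("participant")["removed"]
        .agg(n_bimanual="count", n_removed="sum")
        .reset_index()
    )
    report["removed_fraction"] = report["n_removed"] / report["n_bimanual"]
    return df[~drop].copy(), report


def flag_fast_guesses(
    dataset: pd.DataFrame, threshold_ms: float = 100.0
) -> pd.DataFrame:
    """Annotate (never remove) unimanual responses on stop trials faster than
    ``threshold_ms`` after the stop signal (strict) — likely anticipations or
    lucky guesses rather than genuine triggered responses."""
    df = dataset.copy()
    uni = _is_stop(df) & df["response"].isin(("LR", "RR")) & df["rt_ms"].notna()
    rel = df["rt_ms"] - df["ssd_ms"]
    df["fast_guess"] = uni & (rel < threshold_ms)
    return df


def fast_guess_counts(flagged: pd.DataFrame) -> pd.DataFrame:
    """Per-condition counts and proportions of flagged fast guesses among
    successful stop trials."""
    succ = flagged[_is_successful_stop(flagged)]
    out = (
        succ.groupby("condition")["fast_guess"]
        .agg(n_flagged="sum", n_successful_stops="count")
        .reset_index()
    )
    out["proportion"] = out["n_flagged"] / out["n_successful_stops"]
    return out


def summarize_subject(
    dataset: pd.DataFrame, emg_features: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per participant x condition summary table.

    Fields: mean successful bi-go RT, mean successful stop RT, stopping delay
    (stop - bi-go), relative RT (stop RT - SSD), partial-burst proportion,
    mean CancelTime and relative EMG onset (both require ``emg_features``:
    one row per trial with cancel_time_ms / rt_emg_onset_rel_ms columns), and
    the cross-condition proactive slowing.  Fields without supporting trials
    are NaN (absent), never zero.
    """
    rows = []
    for (pid, cond), grp in dataset.groupby(["participant", "condition"]):
        go_rt = grp.loc[(grp["stimulus"] == DS) & (grp["response"] == DR), "rt_ms"]
        succ = grp[_is_successful_stop(grp)]
        entry = {
            "participant": pid,
            "condition": cond,
            "mean_go_rt_ms": go_rt.mean() if len(go_rt) else np.nan,
            "mean_stop_rt_ms": succ["rt_ms"].mean() if len(succ) else np.nan,
            "relative_rt_ms": (succ["rt_ms"] - succ["ssd_ms"]).mean()
            if len(succ) else np.nan,
            "n_successful_stops": len(succ),
        }
        entry["stopping_delay_ms"] = (
            entry["mean_stop_rt_ms"] - entry["mean_go_rt_ms"]
            if len(succ) and len(go_rt) else np.nan
        )
        if emg_features is not None:
            feats = emg_features[
                (emg_features["participant"] == pid)
                & (emg_features["condition"] == cond)
            ]
            stop_feats = feats.merge(
                succ[["participant", "condition", "trial"]],
                on=["participant", "condition", "trial"],
            )
            if len(stop_feats):
                has_partial = stop_feats["cancel_time_ms"].notna()
                entry["partial_burst_proportion"] = has_partial.mean()
                entry["mean_cancel_time_ms"] = (
                    stop_feats.loc[has_partial, "cancel_time_ms"].mean()
                    if has_partial.any() else np.nan
                )
                if "rt_emg_onset_rel_ms" in stop_feats:
                    entry["relative_emg_onset_ms"] = stop_feats[
                        "rt_emg_onset_rel_ms"
                    ].mean()
            else:
                entry["partial_burst_proportion"] = np.nan
                entry["mean_cancel_time_ms"] = np.nan
        rows.append(entry)
    out = pd.DataFrame(rows)
    slowing = (
        out.pivot(index="participant", columns="condition", values="mean_go_rt_ms")
        .assign(
            proactive_slowing_ms=lambda t: t.get(PROACTIVE, np.nan)
            - t.get(REACTIVE, np.nan)
        )["proactive_slowing_ms"]
        .reset_index()
    )
    return out.merge(slowing, on="participant", how="left")
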