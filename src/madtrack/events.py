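"""Outlier, persistent-outlier, spike, and configuration calling.

An *outlier* is a single observation whose robust score strictly exceeds the
upper cutoff or falls strictly below the lower cutoff.  A *persistent
outlier* is an (individual, protein) pair with at least three longitudinal
outlier observations.  A *spike* is an absolute robust-score change between
adjacent draws of one individual strictly exceeding the delta cutoff.  A
protein's *outlier configuration* is the pair (number of outlier
observations, number of distinct contributing individuals) across the whole
cohort — e.g. outliers in 7 observations split across 3 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaling import ScaledCohort, ThresholdSet, adjacent_deltas

CALL_COLUMNS = ["individual_id", "sample_id", "protein_id", "draw_day", "robust_score", "direction"]


@dataclass(frozen=True)
class OutlierConfiguration:
    """Cross-individual outlier tally for one protein."""

    protein_id: str
    n_outlier_obs: int
    n_individuals: int


def call_outliers(scaled: ScaledCohort, thresholds: ThresholdSet) -> pd.DataFrame:
    """Flag every observation beyond the outlier cutoffs (strict inequality).

    Returns one row per call with columns ``individual_id, sample_id,
    protein_id, draw_day, robust_score, direction`` where direction is
    ``high`` (score > upper) or ``low`` (score < lower), sorted by key so the
    output is independent of input row order.
    """
    s = scaled.scores.dropna(subset=["robust_score"])
    high = s["robust_score"] > thresholds.upper
    low = s["robust_score"] < thresholds.lower
    calls = s[high | low].copy()
    calls["direction"] = np.where(calls["robust_score"] > thresholds.upper, "high", "low")
    return (
        calls[CALL_COLUMNS]
        .sort_values(["individual_id", "protein_id", "draw_day", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def find_persistent(
    calls: pd.DataFrame,
    min_obs: int = 3,
    *,
    consecutive: bool = False,
    scaled: ScaledCohort | None = None,
) -> pd.DataFrame:
    """Collapse outlier calls into persistent-outlier records.

    An (individual, protein) pair is persistent when at least ``min_obs`` of
    its longitudinal observations are outliers, in either direction; records
    mixing high and low calls are flagged via ``mixed_direction``.  With
    ``consecutive=True`` the ``min_obs`` outliers must occupy consecutive
    draws of the individual's full schedule (requires ``scaled`` for the
    schedule); by default any ``min_obs`` longitudinal outliers qualify.

    Returns columns ``individual_id, protein_id, n_outlier_obs, sample_ids,
    directions, mixed_direction`` with sample_ids/directions as draw-ordered
    tuples.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=[
                "individual_id",
                "protein_id",
                "n_outlier_obs",
                "sample_ids",
                "directions",
                "mixed_direction",
            ]
        )
    ordered = calls.sort_values(
        ["individual_id", "protein_id", "draw_day", "sample_id"], kind="mergesort"
    )

    if consecutive:
        if scaled is None:
            raise ValueError("consecutive=True requires the scaled cohort for draw positions")
        sched = (
            scaled.scores[["individual_id", "sample_id", "draw_day"]]
            .drop_duplicates()
            .sort_values(["individual_id", "draw_day", "sample_id"], kind="mergesort")
        )
        sched["position"] = sched.groupby("individual_id").cumcount()
        ordered = ordered.merge(
            sched[["individual_id", "sample_id", "position"]],
            on=["individual_id", "sample_id"],
        ).sort_values(["individual_id", "protein_id", "position"], kind="mergesort")

    records = []
    for (ind, prot), grp in ordered.groupby(["individual_id", "protein_id"], sort=True):
        if consecutive:
            pos = grp["position"].to_numpy()
            runs = np.split(np.arange(len(pos)), np.nonzero(np.diff(pos) != 1)[0] + 1)
            best = max(runs, key=len)
            if len(best) < min_obs:
                continue
            grp = grp.iloc[best]
        elif len(grp) < min_obs:
            continue
        directions = tuple(grp["direction"])
        records.append(
            {
                "individual_id": ind,
                "protein_id": prot,
                "n_outlier_obs": len(grp),
                "sample_ids": tuple(grp["sample_id"]),
                "directions": directions,
                "mixed_direction": len(set(directions)) > 1,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "individual_id",
            "protein_id",
            "n_outlier_obs",
            "sample_ids",
            "directions",
            "mixed_direction",
        ],
    )


def find_spikes(
    scaled: ScaledCohort,
    thresholds: ThresholdSet,
    strict_adjacency: bool = False,
) -> pd.DataFrame:
    """Flag adjacent-draw score jumps whose magnitude exceeds the delta cutoff.

    Adjacency skips missing observations by default, pairing the nearest
    available draws; ``strict_adjacency`` restricts pairs to consecutive
    schedule positions.  Returns one row per spike with columns
    ``individual_id, protein_id, from_sample_id, to_sample_id, from_day,
    to_day, signed_delta, delta`` (delta = |signed_delta|, strictly greater
    than the cutoff).
    """
    pairs = adjacent_deltas(scaled, strict_adjacency=strict_adjacency)
    pairs["delta"] = pairs["signed_delta"].abs()
    spikes = pairs[pairs["delta"] > thresholds.delta]
    return (
        spikes[
            [
                "individual_id",
                "protein_id",
                "from_sample_id",
                "to_sample_id",
                "from_day",
                "to_day",
                "signed_delta",
                "delta",
            ]
        ]
        .sort_values(["individual_id", "protein_id", "to_day", "to_sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def summarize_configuration(calls: pd.DataFrame, protein_id: str) -> OutlierConfiguration:
    """Tally one protein's outlier observations and contributing individuals."""
    if calls.empty or protein_id not in set(calls["protein_id"]):
        return OutlierConfiguration(protein_id, 0, 0)
    sub = calls[calls["protein_id"] == protein_id]
    return OutlierConfiguration(
        protein_id=protein_id,
        n_outlier_obs=int(len(sub)),
        n_individuals=int(sub["individual_id"].nunique()),
    )


def summarize_configurations(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-protein configurations for every protein with at least one call.

    Returns columns ``protein_id, n_outlier_obs, n_individuals`` sorted by
    descending n_outlier_obs then protein_id.
    """
    if calls.empty:
        return pd.DataFrame(columns=["protein_id", "n_outlier_obs", "n_individuals"])
    cfg = (
        calls.groupby("protein_id")
        .agg(n_outlier_obs=("sample_id", "size"), n_individuals=("individual_id", "nunique"))
        .reset_index()
    )
    return cfg.sort_values(
        ["n_outlier_obs", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
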