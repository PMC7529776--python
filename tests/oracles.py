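"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — sort-based medians, explicit loops —
and shares no code with the package.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd


def median_oracle(values) -> float:
    ordered = sorted(float(v) for v in values)
    n = len(ordered)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    if n % 2 == 1:
        return ordered[mid]
    return (ordered[mid - 1] + ordered[mid]) / 2.0


def mad_oracle(values) -> tuple[float, float]:
    center = median_oracle(values)
    scale = median_oracle([abs(v - center) for v in values])
    return center, scale


def percentile_oracle(values, pct: float) -> float:
    """Linear interpolation between closest order statistics."""
    ordered = sorted(float(v) for v in values)
    n = len(ordered)
    if n == 1:
        return ordered[0]
    h = (n - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return ordered[lo] * (1 - frac) + ordered[hi] * frac


def outlier_scan_oracle(scores: pd.DataFrame, lower: float, upper: float) -> set[tuple]:
    """Set of (individual, sample, protein, direction) outlier keys."""
    out = set()
    for _, row in scores.iterrows():
        score = row["robust_score"]
        if pd.isna(score):
            continue
        if score > upper:
            out.add((row["individual_id"], row["sample_id"], row["protein_id"], "high"))
        elif score < lower:
            out.add((row["individual_id"], row["sample_id"], row["protein_id"], "low"))
    return out


def spike_scan_oracle(scores: pd.DataFrame, delta_cutoff: float) -> set[tuple]:
    """Set of (individual, protein, from_sample, to_sample, signed_delta) spikes.

    Adjacency pairs consecutive non-missing observations in (draw_day,
    sample_id) order within each (individual, protein).
    """
    spikes = set()
    scored = scores[~scores["robust_score"].isna()]
    for (ind, prot), grp in scored.groupby(["individual_id", "protein_id"]):
        rows = sorted(grp.itertuples(), key=lambda r: (r.draw_day, r.sample_id))
        for prev, cur in zip(rows, rows[1:]):
            signed = cur.robust_score - prev.robust_score
            if abs(signed) > delta_cutoff:
                spikes.add((ind, prot, prev.sample_id, cur.sample_id, round(signed, 9)))
    return spikes


def exceedance_oracle(
    scores: pd.DataFrame,
    lower: float,
    upper: float,
    observation_sets: list[list[tuple[str, str]]],
    protein_ids: list[str],
    min_outlier_obs: int,
) -> int:
    """Count (repetition, protein) pairs with >= min_outlier_obs outliers."""
    flag = {}
    for _, row in scores.iterrows():
        score = row["robust_score"]
        is_out = (not pd.isna(score)) and (score > upper or score < lower)
        flag[(row["individual_id"], row["sample_id"], row["protein_id"])] = is_out
    exceed = 0
    for rep in observation_sets:
        for prot in protein_ids:
            count = sum(flag.get((ind, smp, prot), False) for ind, smp in rep)
            if count >= min_outlier_obs:
                exceed += 1
    return exceed


def empirical_p_oracle(k: int, n: int) -> Fraction:
    return Fraction(k, n) if k > 0 else Fraction(1, n)
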