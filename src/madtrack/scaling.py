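"""Per-protein robust scaling and percentile-derived cutoffs.

Each protein is standardized by its own median and median absolute deviation
(MAD), pooled over every individual and draw in the cohort:

    robust_score = (abundance - median) / MAD,   MAD = median(|x - median(x)|)

No consistency constant (1.4826) is applied: scores are in raw MAD units, the
convention in which trajectory values like "9.7 MAD" are reported.  Proteins
with zero MAD or too few observations are flagged degenerate and excluded
from scoring.

Outlier cutoffs are percentiles of the pooled robust-score distribution over
all (observation, protein) pairs — by default the 1st and 99th — and the
spike ("delta") cutoff is a percentile of |Δscore| between adjacent draws of
the same individual for the same protein.  Percentiles interpolate linearly
between order statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import CohortTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 20


@dataclass(frozen=True)
class ThresholdSet:
    """Outlier and spike cutoffs with their percentile provenance.

    ``lower``/``upper`` bound single-observation robust scores; ``delta``
    bounds the absolute score change between adjacent draws.  Inequalities
    downstream are strict (score must exceed the cutoff).
    """

    lower: float
    upper: float
    delta: float
    lower_pct: float = 1.0
    upper_pct: float = 99.0
    delta_pct: float = 99.0

    def __post_init__(self) -> None:
        if not (self.lower < 0 < self.upper):
            raise ValueError("expected lower < 0 < upper")
        if self.delta <= 0:
            raise ValueError("delta cutoff must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ScaledCohort:
    """A cohort with per-measurement robust scores and per-protein references.

    ``scores`` is the measurement table plus ``robust_score`` (NaN for
    missing observations and for degenerate proteins).  ``references`` has
    one row per protein: ``protein_id, center, scale, n_obs, degenerate``.
    ``subjects`` carries the metadata through for status-aware analyses.
    """

    scores: pd.DataFrame
    references: pd.DataFrame
    subjects: pd.DataFrame

    @property
    def analyzed_proteins(self) -> list[str]:
        ref = self.references
        return sorted(ref.loc[~ref["degenerate"], "protein_id"])


def compute_mad(values) -> tuple[float, float]:
    """Median and MAD of a sequence.

    Returns ``(center, scale)`` with ``center = median(values)`` and
    ``scale = median(|v - center|)``; no consistency constant.  Raises on
    empty or non-finite input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("compute_mad requires a non-empty sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("compute_mad requires finite values")
    center = float(np.median(arr))
    scale = float(np.median(np.abs(arr - center)))
    return center, scale


def scale_cohort(cohort: CohortTable, min_obs: int = DEFAULT_MIN_OBS) -> ScaledCohort:
    """Robust-scale every protein against its pooled cohort reference.

    The reference (median, MAD) of each protein is computed from all
    non-missing observations across all individuals, cases and controls
    pooled.  A protein is degenerate — flagged, counted in the log, and left
    unscored — when its MAD is 0 or it has fewer than ``min_obs``
    observations.
    """
    m = cohort.measurements
    observed = m.dropna(subset=["abundance"])
    grouped = observed.groupby("protein_id")["abundance"]
    center = grouped.median()
    scale = (observed["abundance"] - observed["protein_id"].map(center)).abs().groupby(
        observed["protein_id"]
    ).median()
    n_obs = grouped.size()

    references = pd.DataFrame(
        {
            "protein_id": center.index,
            "center": center.to_numpy(),
            "scale": scale.reindex(center.index).to_numpy(),
            "n_obs": n_obs.reindex(center.index).to_numpy(),
        }
    )
    # proteins never observed at all
    unseen = sorted(set(m["protein_id"]) - set(references["protein_id"]))
    if unseen:
        references = pd.concat(
            [
                references,
                pd.DataFrame(
                    {"protein_id": unseen, "center": np.nan, "scale": np.nan, "n_obs": 0}
                ),
            ],
            ignore_index=True,
        )
    references["degenerate"] = (references["scale"].fillna(0) == 0) | (
        references["n_obs"] < min_obs
    )
    references = references.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
    n_deg = int(references["degenerate"].sum())
    if n_deg:
        logger.info("excluded %d degenerate proteins from scoring", n_deg)

    scores = m.merge(
        references[["protein_id", "center", "scale", "degenerate"]], on="protein_id", how="left"
    )
    ok = ~scores["degenerate"]
    scores["robust_score"] = np.where(
        ok, (scores["abundance"] - scores["center"]) / scores["scale"], np.nan
    )
    scores = scores.drop(columns=["center", "scale", "degenerate"])
    return ScaledCohort(scores=scores, references=references, subjects=cohort.subjects)


def adjacent_deltas(scaled: ScaledCohort, strict_adjacency: bool = False) -> pd.DataFrame:
    """Score changes between adjacent draws, per (individual, protein).

    Draws are ordered by (draw_day, sample_id).  By default a missing
    observation is skipped and the nearest available draws are paired;
    with ``strict_adjacency`` only consecutive positions of the full draw
    schedule form a pair.  Returns one row per pair with columns
    ``individual_id, protein_id, from_sample_id, to_sample_id, from_day,
    to_day, from_score, to_score, signed_delta``.
    """
    s = scaled.scores.dropna(subset=["robust_score"])
    s = s.sort_values(
        ["individual_id", "protein_id", "draw_day", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)

    grp = s.groupby(["individual_id", "protein_id"], sort=False)
    same = grp.ngroup().diff() == 0

    if strict_adjacency:
        # schedule positions come from all draws, including unscored ones
        sched = (
            scaled.scores[["individual_id", "sample_id", "draw_day"]]
            .drop_duplicates()
            .sort_values(["individual_id", "draw_day", "sample_id"], kind="mergesort")
        )
        sched["position"] = sched.groupby("individual_id").cumcount()
        s = s.merge(sched[["individual_id", "sample_id", "position"]], on=["individual_id", "sample_id"])
        s = s.sort_values(
            ["individual_id", "protein_id", "draw_day", "sample_id"], kind="mergesort"
        ).reset_index(drop=True)
        adjacent = same & (s["position"].diff() == 1)
    else:
        adjacent = same

    pairs = pd.DataFrame(
        {
            "individual_id": s["individual_id"],
            "protein_id": s["protein_id"],
            "from_sample_id": s["sample_id"].shift(1),
            "to_sample_id": s["sample_id"],
            "from_day": s["draw_day"].shift(1),
            "to_day": s["draw_day"],
            "from_score": s["robust_score"].shift(1),
            "to_score": s["robust_score"],
        }
    )[adjacent.to_numpy()].reset_index(drop=True)
    pairs["signed_delta"] = pairs["to_score"] - pairs["from_score"]
    pairs["from_day"] = pairs["from_day"].astype(int)
    return pairs


def fit_thresholds(
    scaled: ScaledCohort,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    delta_pct: float = 99.0,
    controls_only: bool = False,
) -> ThresholdSet:
    """Fit outlier and delta cutoffs from pooled percentiles.

    ``lower``/``upper`` are the stated percentiles of the pooled robust-score
    distribution over every scored observation of every non-degenerate
    protein; ``delta`` is the stated percentile of |Δscore| over all
    adjacent same-individual, same-protein draw pairs.  ``controls_only``
    restricts the pools to control individuals (sensitivity analysis).
    Raises if fewer than two adjacent pairs exist anywhere.
    """
    scores = scaled.scores
    if controls_only:
        controls = set(scaled.subjects.loc[scaled.subjects["status"] == "control", "individual_id"])
        scaled = ScaledCohort(
            scores=scores[scores["individual_id"].isin(controls)].reset_index(drop=True),
            references=scaled.references,
            subjects=scaled.subjects,
        )
        scores = scaled.scores

    pooled = scores["robust_score"].dropna().to_numpy()
    if pooled.size < 2 or scaled.references.loc[~scaled.references["degenerate"]].shape[0] < 2:
        raise ValueError("need at least 2 non-degenerate proteins with scores")
    lower = float(np.percentile(pooled, lower_pct))
    upper = float(np.percentile(pooled, upper_pct))

    deltas = adjacent_deltas(scaled)["signed_delta"].abs().to_numpy()
    if deltas.size < 2:
        raise ValueError("fewer than 2 adjacent observation pairs; cannot fit delta cutoff")
    delta = float(np.percentile(deltas, delta_pct))

    return ThresholdSet(
        lower=lower,
        upper=upper,
        delta=delta,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        delta_pct=delta_pct,
    )
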