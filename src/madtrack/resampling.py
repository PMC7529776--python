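"""Triplet-resampling empirical null for cross-individual outlier configurations.

To judge whether a protein being an outlier in, say, 7 observations across 3
distinct individuals could arise by chance, the cohort is resampled: each
repetition draws ``n_individuals_sampled`` individuals without replacement,
then ``n_obs_per_individual`` of each individual's draws without replacement,
and counts per-protein outliers among the pooled observations (9 by default).
Every non-degenerate protein is evaluated on the same sampled draw set per
repetition.  The empirical p-value of a configuration with at least
``min_outlier_obs`` outliers is the exceedance count over all
(repetition × protein) observations; a zero count is reported as the
conservative bound 1/total rather than p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaling import ScaledCohort, ThresholdSet


@dataclass(frozen=True)
class ResamplingSpec:
    """Resampling design: 3 individuals × 3 observations, 5000 repetitions."""

    n_individuals_sampled: int = 3
    n_obs_per_individual: int = 3
    n_repetitions: int = 5000
    min_outlier_obs: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals_sampled, self.n_obs_per_individual, self.n_repetitions) < 1:
            raise ValueError("resampling dimensions must be positive")
        if self.min_outlier_obs < 1:
            raise ValueError("min_outlier_obs must be positive")


@dataclass(frozen=True)
class ResamplingResult:
    """Outcome of a resampling run.

    ``empirical_p = exceedance_count / total_observations`` when the count is
    positive; a zero count sets ``zero_count`` and reports the upper bound
    ``1 / total_observations`` instead.
    """

    exceedance_count: int
    n_repetitions: int
    n_proteins_analyzed: int
    total_observations: int
    empirical_p: float
    zero_count: bool

    def display_p(self) -> str:
        """Two-significant-figure display, '< bound' when no exceedances."""
        if self.zero_count:
            return f"< {self.empirical_p:.1e}"
        return f"{self.empirical_p:.1e}"


def empirical_p(exceedance_count: int, total_observations: int) -> float:
    """Plain exceedance ratio; rounding is a display concern.

    A zero exceedance count returns the conservative bound
    ``1 / total_observations``.
    """
    if exceedance_count < 0 or total_observations <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    if exceedance_count == 0:
        return 1.0 / total_observations
    return exceedance_count / total_observations


def sample_observation_sets(
    scaled: ScaledCohort, spec: ResamplingSpec
) -> list[list[tuple[str, str]]]:
    """The per-repetition (individual_id, sample_id) draws, deterministic by seed.

    Individuals are eligible when they have at least ``n_obs_per_individual``
    draws; raises if fewer than ``n_individuals_sampled`` individuals are
    eligible.  Exposed separately so the exceedance counting can be verified
    against an independent implementation on identical draw sets.
    """
    sched = (
        scaled.scores[["individual_id", "sample_id"]]
        .drop_duplicates()
        .sort_values(["individual_id", "sample_id"], kind="mergesort")
    )
    samples_by_ind: dict[str, list[str]] = {
        ind: list(grp["sample_id"]) for ind, grp in sched.groupby("individual_id")
    }
    eligible = sorted(
        ind for ind, smp in samples_by_ind.items() if len(smp) >= spec.n_obs_per_individual
    )
    if len(eligible) < spec.n_individuals_sampled:
        raise ValueError(
            f"only {len(eligible)} individuals have >= {spec.n_obs_per_individual} draws; "
            f"need {spec.n_individuals_sampled}"
        )

    rng = np.random.default_rng(spec.seed)
    reps: list[list[tuple[str, str]]] = []
    for _ in range(spec.n_repetitions):
        chosen = rng.choice(len(eligible), size=spec.n_individuals_sampled, replace=False)
        obs: list[tuple[str, str]] = []
        for idx in chosen:
            ind = eligible[idx]
            smp = samples_by_ind[ind]
            picked = rng.choice(len(smp), size=spec.n_obs_per_individual, replace=False)
            obs.extend((ind, smp[j]) for j in picked)
        reps.append(obs)
    return reps


def count_outliers_per_protein(
    scaled: ScaledCohort,
    thresholds: ThresholdSet,
    observation_sets: list[list[tuple[str, str]]],
) -> np.ndarray:
    """Per-(repetition, protein) outlier counts over the sampled observations.

    Returns an integer array of shape (n_repetitions, n_proteins_analyzed)
    with proteins in sorted non-degenerate order; missing observations count
    as non-outliers.
    """
    proteins = scaled.analyzed_proteins
    s = scaled.scores[scaled.scores["protein_id"].isin(proteins)]
    outlier = (s["robust_score"] > thresholds.upper) | (s["robust_score"] < thresholds.lower)
    flags = (
        s.assign(outlier=outlier.fillna(False))
        .pivot_table(
            index=["individual_id", "sample_id"],
            columns="protein_id",
            values="outlier",
            aggfunc="first",
            fill_value=False,
        )
        .reindex(columns=proteins, fill_value=False)
        .astype(bool)
    )
    row_index = {key: i for i, key in enumerate(flags.index)}
    matrix = flags.to_numpy()

    idx = np.array(
        [[row_index[obs] for obs in rep] for rep in observation_sets], dtype=np.intp
    )
    # (reps, obs_per_rep, proteins) -> sum over sampled observations
    counts = matrix[idx].sum(axis=1)
    return counts.astype(np.int64)


def resample_null(
    scaled: ScaledCohort, thresholds: ThresholdSet, spec: ResamplingSpec
) -> ResamplingResult:
    """Run the triplet-resampling null and return its exceedance summary.

    Deterministic given (cohort, thresholds, spec): exceedance_count is the
    number of (repetition, protein) pairs whose sampled observations contain
    at least ``spec.min_outlier_obs`` outlier calls.
    """
    observation_sets = sample_observation_sets(scaled, spec)
    counts = count_outliers_per_protein(scaled, thresholds, observation_sets)
    exceed = int((counts >= spec.min_outlier_obs).sum())
    n_proteins = counts.shape[1]
    total = spec.n_repetitions * n_proteins
    return ResamplingResult(
        exceedance_count=exceed,
        n_repetitions=spec.n_repetitions,
        n_proteins_analyzed=n_proteins,
        total_observations=total,
        empirical_p=empirical_p(exceed, total),
        zero_count=exceed == 0,
    )
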