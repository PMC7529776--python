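"""Shared fixtures: toy cohorts built in memory, plus generator-backed ones."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from madtrack import CohortTable, ScaledCohort, SimulationConfig, generate_cohort


def make_measurements(rows: list[tuple]) -> pd.DataFrame:
    """Rows of (individual_id, sample_id, draw_day, protein_id, abundance)."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "sample_id", "draw_day", "protein_id", "abundance"],
    )


def make_subjects(individuals: dict[str, str]) -> pd.DataFrame:
    """Map individual_id -> status; cases get a placeholder cancer type."""
    return pd.DataFrame(
        {
            "individual_id": list(individuals),
            "status": list(individuals.values()),
            "cancer_type": [
                "testopathy" if s == "case" else np.nan for s in individuals.values()
            ],
            "sex": "unknown",
            "age_at_baseline": pd.array([None] * len(individuals), dtype="Int64"),
        }
    )


def make_scaled(scores: pd.DataFrame, subjects: pd.DataFrame | None = None) -> ScaledCohort:
    """Wrap a hand-built score table (with a robust_score column) as a ScaledCohort."""
    proteins = sorted(scores["protein_id"].unique())
    references = pd.DataFrame(
        {
            "protein_id": proteins,
            "center": 0.0,
            "scale": 1.0,
            "n_obs": scores.groupby("protein_id").size().reindex(proteins).to_numpy(),
            "degenerate": False,
        }
    )
    if subjects is None:
        subjects = make_subjects({ind: "control" for ind in scores["individual_id"].unique()})
    return ScaledCohort(scores=scores, references=references, subjects=subjects)


def random_cohort(rng: np.random.Generator, n_ind=4, n_prot=5, n_draws=4) -> CohortTable:
    """A small random cohort assembled directly, independent of the generator."""
    rows = []
    for i in range(n_ind):
        ind = f"I{i}"
        days = np.sort(rng.choice(np.arange(-900, 0), size=n_draws, replace=False))
        for j, day in enumerate(days):
            for p in range(n_prot):
                rows.append((ind, f"I{i}_s{j}", int(day), f"P{p}", float(rng.normal(p, 1 + p))))
    measurements = make_measurements(rows)
    subjects = make_subjects({f"I{i}": "control" for i in range(n_ind)})
    return CohortTable(measurements=measurements, subjects=subjects)


@pytest.fixture
def toy_cohort() -> CohortTable:
    """2 individuals x 2 proteins x 3 draws = 12 measurements."""
    rows = []
    for ind, status_days in {"A": [-300, -200, -100], "B": [0, 150, 310]}.items():
        for j, day in enumerate(status_days):
            for prot, base in [("P1", 5.0), ("P2", 8.0)]:
                rows.append((ind, f"{ind}_s{j}", day, prot, base + 0.1 * j))
    return CohortTable(
        measurements=make_measurements(rows),
        subjects=make_subjects({"A": "case", "B": "control"}),
    )


@pytest.fixture(scope="session")
def small_generated():
    """A modest generated cohort reused across read-only tests."""
    config = SimulationConfig(n_cases=3, n_controls=12, n_proteins=30, seed=2024)
    return generate_cohort(config)
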