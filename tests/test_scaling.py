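"""Robust scaling and percentile cutoffs, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from madtrack import (
    CohortTable,
    ThresholdSet,
    adjacent_deltas,
    compute_mad,
    fit_thresholds,
    scale_cohort,
)
from conftest import make_measurements, make_subjects, random_cohort
from oracles import mad_oracle, percentile_oracle


def test_compute_mad_examples():
    assert compute_mad([1, 2, 3, 4, 5]) == (3.0, 1.0)
    assert compute_mad([5, 5, 5]) == (5.0, 0.0)


def test_compute_mad_rejects_bad_input():
    with pytest.raises(ValueError):
        compute_mad([])
    with pytest.raises(ValueError):
        compute_mad([1.0, np.nan])


def test_compute_mad_matches_sort_oracle():
    rng = np.random.default_rng(100)
    for _ in range(100):
        values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=rng.integers(1, 1000))
        assert compute_mad(values) == mad_oracle(values)


def test_scale_cohort_basic_transform():
    """Protein with cohort values [1..5]: the value 5 scores (5-3)/1 = 2."""
    rows = [("A", f"A_s{i}", -500 + 100 * i, "P1", float(v)) for i, v in enumerate([1, 2, 3, 4, 5])]
    rows += [("A", f"A_s{i}", -500 + 100 * i, "P2", 7.0) for i in range(5)]
    cohort = CohortTable(
        measurements=make_measurements(rows), subjects=make_subjects({"A": "control"})
    )
    scaled = scale_cohort(cohort, min_obs=1)
    s = scaled.scores
    assert s.loc[(s["protein_id"] == "P1") & (s["abundance"] == 5.0), "robust_score"].iloc[0] == 2.0
    # constant protein is degenerate: flagged, unscored
    ref = scaled.references.set_index("protein_id")
    assert bool(ref.loc["P2", "degenerate"])
    assert s.loc[s["protein_id"] == "P2", "robust_score"].isna().all()
    assert scaled.analyzed_proteins == ["P1"]


def test_min_obs_marks_sparse_proteins_degenerate(small_generated):
    cohort, _ = small_generated
    scaled = scale_cohort(cohort, min_obs=10**6)
    assert scaled.references["degenerate"].all()


def test_per_protein_score_median_zero_mad_one(small_generated):
    """Normalization identities: median 0 and median |score| 1 per protein."""
    cohort, _ = small_generated
    scaled = scale_cohort(cohort, min_obs=5)
    scored = scaled.scores.dropna(subset=["robust_score"])
    med = scored.groupby("protein_id")["robust_score"].median()
    assert np.allclose(med, 0.0, atol=1e-9)
    mad = scored.groupby("protein_id")["robust_score"].apply(lambda v: np.median(np.abs(v)))
    assert np.allclose(mad, 1.0, atol=1e-9)


def test_shift_scale_equivariance(small_generated):
    """x -> a*x + b leaves a protein's robust scores unchanged."""
    cohort, _ = small_generated
    target = cohort.protein_ids[0]
    scaled = scale_cohort(cohort, min_obs=5)
    transformed = cohort.measurements.copy()
    mask = transformed["protein_id"] == target
    transformed.loc[mask, "abundance"] = 3.7 * transformed.loc[mask, "abundance"] - 11.0
    scaled_t = scale_cohort(
        CohortTable(measurements=transformed, subjects=cohort.subjects), min_obs=5
    )
    orig = scaled.scores.loc[scaled.scores["protein_id"] == target, "robust_score"]
    new = scaled_t.scores.loc[scaled_t.scores["protein_id"] == target, "robust_score"]
    assert np.allclose(orig.to_numpy(), new.to_numpy(), atol=1e-9)


def test_fit_thresholds_extreme_percentiles():
    """Pooled scores exactly {-5..5} with 0/100 percentiles -> cutoffs -5, 5."""
    rows = []
    # two proteins whose scored values tile -5..5 after scaling by (median 0, MAD 1)
    values = list(range(-5, 6))
    for i, v in enumerate(values):
        rows.append(("A", f"A_s{i:02d}", -600 + 50 * i, "P1", float(v)))
        rows.append(("A", f"A_s{i:02d}", -600 + 50 * i, "P2", float(v)))
    cohort = CohortTable(
        measurements=make_measurements(rows), subjects=make_subjects({"A": "control"})
    )
    scaled = scale_cohort(cohort, min_obs=1)
    th = fit_thresholds(scaled, lower_pct=0, upper_pct=100, delta_pct=99)
    # MAD of -5..5 is 3, so the pooled extremes are -5/3 and 5/3
    assert th.lower == pytest.approx(-5 / 3)
    assert th.upper == pytest.approx(5 / 3)


def test_fit_thresholds_matches_percentile_oracle():
    """Pooled and delta percentiles equal a full-sort interpolation oracle."""
    rng = np.random.default_rng(200)
    for _ in range(100):
        cohort = random_cohort(
            rng,
            n_ind=int(rng.integers(2, 5)),
            n_prot=int(rng.integers(2, 5)),
            n_draws=int(rng.integers(3, 6)),
        )
        scaled = scale_cohort(cohort, min_obs=1)
        lo_p, up_p, d_p = rng.uniform(0, 10), rng.uniform(90, 100), rng.uniform(50, 100)
        th = fit_thresholds(scaled, lower_pct=lo_p, upper_pct=up_p, delta_pct=d_p)
        pooled = scaled.scores["robust_score"].dropna().tolist()
        assert th.lower == pytest.approx(percentile_oracle(pooled, lo_p), abs=1e-12)
        assert th.upper == pytest.approx(percentile_oracle(pooled, up_p), abs=1e-12)
        deltas = adjacent_deltas(scaled)["signed_delta"].abs().tolist()
        assert th.delta == pytest.approx(percentile_oracle(deltas, d_p), abs=1e-12)


def test_fit_thresholds_row_order_invariant():
    rng = np.random.default_rng(7)
    cohort = random_cohort(rng)
    shuffled = CohortTable(
        measurements=cohort.measurements.sample(frac=1, random_state=1).reset_index(drop=True),
        subjects=cohort.subjects,
    )
    th_a = fit_thresholds(scale_cohort(cohort, min_obs=1))
    th_b = fit_thresholds(scale_cohort(shuffled, min_obs=1))
    assert th_a == th_b


def test_delta_requires_adjacent_pairs():
    rows = [("A", "A_s0", -10, "P1", 1.0), ("A", "A_s0", -10, "P2", 2.0),
            ("B", "B_s0", 0, "P1", 3.0), ("B", "B_s0", 0, "P2", 4.0),
            ("A", "A_s1", -5, "P1", 1.5)]
    cohort = CohortTable(
        measurements=make_measurements(rows),
        subjects=make_subjects({"A": "control", "B": "control"}),
    )
    scaled = scale_cohort(cohort, min_obs=1)
    with pytest.raises(ValueError, match="delta|degenerate|non-degenerate"):
        fit_thresholds(scaled)


def test_adjacency_skips_missing_by_default():
    """A missing middle draw pairs its neighbours; strict mode drops the pair."""
    rows = [
        ("A", "A_s0", -300, "P1", 0.0),
        ("A", "A_s1", -200, "P1", np.nan),
        ("A", "A_s2", -100, "P1", 10.0),
        ("A", "A_s0", -300, "P2", 1.0),
        ("A", "A_s1", -200, "P2", 2.0),
        ("A", "A_s2", -100, "P2", 3.0),
    ]
    cohort = CohortTable(
        measurements=make_measurements(rows), subjects=make_subjects({"A": "control"})
    )
    scaled = scale_cohort(cohort, min_obs=1)
    default = adjacent_deltas(scaled)
    p1 = default[default["protein_id"] == "P1"]
    assert len(p1) == 1
    assert (p1["from_sample_id"].iloc[0], p1["to_sample_id"].iloc[0]) == ("A_s0", "A_s2")
    strict = adjacent_deltas(scaled, strict_adjacency=True)
    assert strict[strict["protein_id"] == "P1"].empty
    assert len(strict[strict["protein_id"] == "P2"]) == 2


def test_controls_only_restricts_pool(small_generated):
    cohort, _ = small_generated
    scaled = scale_cohort(cohort, min_obs=5)
    th_all = fit_thresholds(scaled)
    th_ctrl = fit_thresholds(scaled, controls_only=True)
    assert th_all != th_ctrl  # different pools on a finite cohort
    assert th_ctrl.lower < 0 < th_ctrl.upper


def test_threshold_set_serialization_round_trip(tmp_path):
    th = ThresholdSet(lower=-3.755, upper=4.431, delta=5.224)
    th.to_json(tmp_path / "th.json")
    assert ThresholdSet.from_json(tmp_path / "th.json") == th


def test_threshold_set_invariants():
    with pytest.raises(ValueError):
        ThresholdSet(lower=1.0, upper=2.0, delta=1.0)
    with pytest.raises(ValueError):
        ThresholdSet(lower=-1.0, upper=2.0, delta=0.0)
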