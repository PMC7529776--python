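"""Outlier, persistent-outlier, spike and configuration calling."""

import numpy as np
import pandas as pd
import pytest

from madtrack import (
    ThresholdSet,
    call_outliers,
    find_persistent,
    find_spikes,
    scale_cohort,
    summarize_configuration,
    summarize_configurations,
)
from conftest import make_scaled, random_cohort
from oracles import outlier_scan_oracle, spike_scan_oracle

STUDY_THRESHOLDS = ThresholdSet(lower=-3.755, upper=4.431, delta=5.224)


def scores_from(rows):
    """Rows of (individual, sample, day, protein, robust_score)."""
    df = pd.DataFrame(
        rows, columns=["individual_id", "sample_id", "draw_day", "protein_id", "robust_score"]
    )
    df.insert(4, "abundance", df["robust_score"])
    return df


def trajectory(ind, prot, scores, start_day=-600, step=130):
    return [
        (ind, f"{ind}_s{i:02d}", start_day + step * i, prot, float(v))
        for i, v in enumerate(scores)
    ]


def test_boundary_scores_are_not_outliers():
    """'Above'/'below' are strict: a score equal to the cutoff is not called."""
    scaled = make_scaled(scores_from(trajectory("A", "P1", [4.431, -3.755, 0.0])))
    assert call_outliers(scaled, STUDY_THRESHOLDS).empty


def test_persistent_high_trajectory_called_each_draw():
    """Four consecutive draws at 9.7-10.7 MAD yield four high calls."""
    scaled = make_scaled(scores_from(trajectory("A", "P1", [9.7, 10.2, 10.5, 10.7])))
    calls = call_outliers(scaled, STUDY_THRESHOLDS)
    assert len(calls) == 4
    assert (calls["direction"] == "high").all()
    persistent = find_persistent(calls)
    assert len(persistent) == 1
    rec = persistent.iloc[0]
    assert rec["n_outlier_obs"] == 4
    assert rec["sample_ids"] == tuple(f"A_s{i:02d}" for i in range(4))
    assert not rec["mixed_direction"]


def test_persistent_threshold_of_three():
    """3 of 4 outlier draws qualify; 2 do not."""
    three = make_scaled(scores_from(trajectory("A", "P1", [5.0, 0.0, 6.0, 7.0])))
    calls = call_outliers(three, STUDY_THRESHOLDS)
    rec = find_persistent(calls)
    assert len(rec) == 1 and rec.iloc[0]["n_outlier_obs"] == 3
    two = make_scaled(scores_from(trajectory("B", "P1", [5.0, 0.0, 6.0, 0.0])))
    assert find_persistent(call_outliers(two, STUDY_THRESHOLDS)).empty


def test_mixed_direction_flagged_and_counted():
    scaled = make_scaled(scores_from(trajectory("A", "P1", [5.0, -4.0, 6.0])))
    persistent = find_persistent(call_outliers(scaled, STUDY_THRESHOLDS))
    assert len(persistent) == 1
    assert persistent.iloc[0]["mixed_direction"]
    assert persistent.iloc[0]["directions"] == ("high", "low", "high")


def test_consecutive_mode_requires_a_run():
    """Outliers at draws 0, 2, 3 of 4: a 3-run only exists without gaps."""
    rows = trajectory("A", "P1", [6.0, 0.0, 6.0, 6.0])
    scaled = make_scaled(scores_from(rows))
    calls = call_outliers(scaled, STUDY_THRESHOLDS)
    assert len(find_persistent(calls)) == 1  # default: any three longitudinal outliers
    strict = find_persistent(calls, consecutive=True, scaled=scaled)
    assert strict.empty  # longest consecutive run is 2
    rows2 = trajectory("B", "P1", [0.0, 6.0, 6.0, 6.0])
    scaled2 = make_scaled(scores_from(rows2))
    calls2 = call_outliers(scaled2, STUDY_THRESHOLDS)
    assert len(find_persistent(calls2, consecutive=True, scaled=scaled2)) == 1


def test_leukemia_scenario_thirteen_persistent_proteins():
    """13 proteins, each an outlier at all 3 draws of one individual, give 13 records."""
    rows = []
    for p in range(13):
        rows += trajectory("cll", f"P{p:02d}", [6.0, 7.0, 6.5], start_day=-346, step=129)
    for p in range(13, 20):  # quiet proteins
        rows += trajectory("cll", f"P{p:02d}", [0.1, -0.2, 0.3], start_day=-346, step=129)
    scaled = make_scaled(scores_from(rows))
    persistent = find_persistent(call_outliers(scaled, STUDY_THRESHOLDS))
    assert len(persistent) == 13
    assert (persistent["individual_id"] == "cll").all()
    assert (persistent["n_outlier_obs"] == 3).all()


def test_spike_from_low_to_high_levels():
    """A -2.9 -> 6.5 MAD jump is a spike of delta 9.4 at the 5.224 cutoff."""
    scaled = make_scaled(scores_from(trajectory("A", "P1", [-2.9, 6.5])))
    spikes = find_spikes(scaled, STUDY_THRESHOLDS)
    assert len(spikes) == 1
    assert spikes.iloc[0]["delta"] == pytest.approx(9.4)
    assert spikes.iloc[0]["signed_delta"] == pytest.approx(9.4)


def test_spike_boundary_is_strict():
    scaled = make_scaled(scores_from(trajectory("A", "P1", [0.0, 5.224])))
    assert find_spikes(scaled, STUDY_THRESHOLDS).empty


def test_spike_sign_preserved_for_drops():
    scaled = make_scaled(scores_from(trajectory("A", "P1", [6.5, -2.9])))
    spikes = find_spikes(scaled, STUDY_THRESHOLDS)
    assert spikes.iloc[0]["signed_delta"] == pytest.approx(-9.4)
    assert spikes.iloc[0]["delta"] == pytest.approx(9.4)


def test_configuration_counts_observations_and_individuals():
    rows = trajectory("A", "CEACAM5", [9.7, 10.2, 10.5, 10.7])
    rows += trajectory("B", "CEACAM5", [5.0, 6.0, 7.0])
    scaled = make_scaled(scores_from(rows))
    calls = call_outliers(scaled, STUDY_THRESHOLDS)
    cfg = summarize_configuration(calls, "CEACAM5")
    assert (cfg.n_outlier_obs, cfg.n_individuals) == (7, 2)
    assert summarize_configuration(calls, "UNKNOWN") == summarize_configuration(calls[:0], "UNKNOWN")
    assert summarize_configuration(calls, "UNKNOWN").n_outlier_obs == 0


def test_configuration_split_across_three_individuals():
    """7 outlier observations split across 3 unique individuals -> (7, 3)."""
    rows = trajectory("pancreatic", "CEACAM5", [9.7, 10.2, 10.5, 10.7])
    rows += trajectory("lung", "CEACAM5", [4.9, 7.0])
    rows += trajectory("breast", "CEACAM5", [12.5])
    rows += trajectory("ctrl", "CEACAM5", [0.5, -0.2, 1.0])
    scaled = make_scaled(scores_from(rows))
    calls = call_outliers(scaled, STUDY_THRESHOLDS)
    cfg = summarize_configuration(calls, "CEACAM5")
    assert (cfg.n_outlier_obs, cfg.n_individuals) == (7, 3)
    table = summarize_configurations(calls)
    assert table.iloc[0]["protein_id"] == "CEACAM5"
    assert table.iloc[0]["n_individuals"] == 3


def test_calls_and_spikes_match_scan_oracles():
    """Vectorized calling equals a row-by-row brute-force scan."""
    rng = np.random.default_rng(300)
    for _ in range(100):
        cohort = random_cohort(
            rng,
            n_ind=int(rng.integers(2, 5)),
            n_prot=int(rng.integers(2, 5)),
            n_draws=int(rng.integers(3, 6)),
        )
        scaled = scale_cohort(cohort, min_obs=1)
        lower, upper = -float(rng.uniform(0.5, 2.5)), float(rng.uniform(0.5, 2.5))
        delta = float(rng.uniform(0.5, 3.0))
        th = ThresholdSet(lower=lower, upper=upper, delta=delta)
        calls = call_outliers(scaled, th)
        got = set(
            zip(calls["individual_id"], calls["sample_id"], calls["protein_id"], calls["direction"])
        )
        assert got == outlier_scan_oracle(scaled.scores, lower, upper)
        spikes = find_spikes(scaled, th)
        got_spikes = set(
            zip(
                spikes["individual_id"],
                spikes["protein_id"],
                spikes["from_sample_id"],
                spikes["to_sample_id"],
                spikes["signed_delta"].round(9),
            )
        )
        assert got_spikes == spike_scan_oracle(scaled.scores, delta)


def test_call_monotonicity_in_thresholds():
    """Raising the upper cutoff never increases high calls; lowering min_obs never loses records."""
    rng = np.random.default_rng(301)
    cohort = random_cohort(rng, n_ind=6, n_prot=8, n_draws=5)
    scaled = scale_cohort(cohort, min_obs=1)
    uppers = [0.5, 1.0, 1.5, 2.0, 3.0]
    highs = [
        (call_outliers(scaled, ThresholdSet(-10.0, u, 1.0))["direction"] == "high").sum()
        for u in uppers
    ]
    assert all(a >= b for a, b in zip(highs, highs[1:]))
    calls = call_outliers(scaled, ThresholdSet(-1.0, 1.0, 1.0))
    n_by_min = [len(find_persistent(calls, min_obs=m)) for m in (5, 4, 3, 2, 1)]
    assert all(a <= b for a, b in zip(n_by_min, n_by_min[1:]))
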