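"""Draw-schedule summaries and the end-to-end analysis report.

The schedule summary mirrors a cohort-description table: per individual, the
number of draws, the earliest and latest draw days, and the mean time between
draws, which for draws spanning the schedule equals
(max draw_day − min draw_day) / (n_draws − 1).  Group-level mean intervals
are computed both by pooling all consecutive same-individual intervals and as
the mean of per-individual means, since the two conventions differ on
unbalanced cohorts.

The analysis report bundles the thresholds, schedules, event sets,
configurations and resampling result into one deterministic, machine-readable
object, with a human-readable rendering alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import CohortTable
from .scaling import ScaledCohort, ThresholdSet
from .resampling import ResamplingResult


@dataclass(frozen=True)
class ScheduleSummary:
    """One individual's draw schedule descriptors.

    ``mean_interval_days`` is (max draw_day − min draw_day)/(n_draws − 1),
    None when the individual has fewer than two draws.
    """

    individual_id: str
    n_draws: int
    earliest_day: int
    latest_day: int
    mean_interval_days: float | None


def summarize_schedule(cohort: CohortTable, individual_id: str) -> ScheduleSummary:
    """Schedule descriptors for one individual, interval to one decimal."""
    sched = cohort.schedule()
    days = sched.loc[sched["individual_id"] == individual_id, "draw_day"].to_numpy()
    if days.size == 0:
        raise KeyError(f"unknown individual {individual_id!r}")
    n = int(days.size)
    earliest, latest = int(days.min()), int(days.max())
    mean_interval = round((latest - earliest) / (n - 1), 1) if n >= 2 else None
    return ScheduleSummary(
        individual_id=individual_id,
        n_draws=n,
        earliest_day=earliest,
        latest_day=latest,
        mean_interval_days=mean_interval,
    )


def summarize_all_schedules(cohort: CohortTable) -> pd.DataFrame:
    """Schedule summaries for every individual, as a DataFrame."""
    rows = [asdict(summarize_schedule(cohort, ind)) for ind in cohort.individual_ids]
    return pd.DataFrame(rows)


def _intervals(cohort: CohortTable, individual_ids) -> dict[str, np.ndarray]:
    sched = cohort.schedule()
    out = {}
    for ind in individual_ids:
        days = sched.loc[sched["individual_id"] == ind, "draw_day"].to_numpy()
        if days.size >= 2:
            out[ind] = np.diff(np.sort(days))
    return out


def group_mean_interval(
    cohort: CohortTable, status: str, per_individual: bool = False
) -> float:
    """Mean days between consecutive draws for one status group.

    Default pools every consecutive same-individual interval across the
    group; ``per_individual=True`` instead averages the per-individual mean
    intervals.  Raises when no individual in the group has two draws.
    """
    members = cohort.subjects.loc[cohort.subjects["status"] == status, "individual_id"]
    if members.empty:
        raise ValueError(f"no individuals with status {status!r}")
    intervals = _intervals(cohort, members)
    if not intervals:
        raise ValueError(f"no individual with >= 2 draws in status {status!r}")
    if per_individual:
        return float(np.mean([np.mean(v) for v in intervals.values()]))
    return float(np.mean(np.concatenate(list(intervals.values()))))


def export_trajectories(scaled: ScaledCohort) -> pd.DataFrame:
    """Long table of robust-score trajectories for plotting.

    Columns ``individual_id, protein_id, draw_day, robust_score``, scored
    observations only, sorted deterministically.
    """
    traj = scaled.scores.dropna(subset=["robust_score"])
    return (
        traj[["individual_id", "protein_id", "draw_day", "robust_score"]]
        .sort_values(["individual_id", "protein_id", "draw_day"], kind="mergesort")
        .reset_index(drop=True)
    )


def _check_traceable(events: pd.DataFrame, known: set[tuple[str, str]], label: str) -> None:
    for _, row in events.iterrows():
        key = (row["individual_id"], row["protein_id"])
        if key not in known:
            raise ValueError(f"{label} record {key} does not trace to a scored measurement")


def build_report(
    cohort: CohortTable,
    scaled: ScaledCohort,
    thresholds: ThresholdSet,
    persistent: pd.DataFrame,
    spikes: pd.DataFrame,
    configurations: pd.DataFrame,
    resampling: ResamplingResult | None = None,
) -> dict:
    """Assemble the deterministic end-to-end analysis report.

    Every persistent/spike record must trace back to a scored (individual,
    protein) pair of this cohort, otherwise the stage outputs do not belong
    together and a hard error is raised.  The returned dict is JSON-ready;
    identical inputs yield a byte-identical ``json.dumps`` rendering.
    """
    scored = scaled.scores.dropna(subset=["robust_score"])
    known = set(zip(scored["individual_id"], scored["protein_id"]))
    _check_traceable(persistent, known, "persistent outlier")
    _check_traceable(spikes, known, "spike")

    n_deg = int(scaled.references["degenerate"].sum())
    report = {
        "thresholds": asdict(thresholds),
        "cohort": {
            "n_individuals": int(cohort.subjects.shape[0]),
            "n_cases": int((cohort.subjects["status"] == "case").sum()),
            "n_controls": int((cohort.subjects["status"] == "control").sum()),
            "n_proteins_measured": len(cohort.protein_ids),
            "n_proteins_analyzed": len(scaled.analyzed_proteins),
        },
        "schedules": summarize_all_schedules(cohort).to_dict(orient="records"),
        "group_mean_interval_days": {
            status: {
                "pooled": round(group_mean_interval(cohort, status), 1),
                "per_individual_mean": round(
                    group_mean_interval(cohort, status, per_individual=True), 1
                ),
            }
            for status in sorted(cohort.subjects["status"].unique())
        },
        "persistent_outliers": _records(persistent),
        "spikes": _records(spikes),
        "configurations": _records(configurations),
        "exclusions": {"degenerate_proteins": n_deg},
    }
    if resampling is not None:
        res = asdict(resampling)
        res["display_p"] = resampling.display_p()
        report["resampling"] = res
    return report


def _records(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            {k: (list(v) if isinstance(v, tuple) else _plain(v)) for k, v in rec.items()}
        )
    return out


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def report_to_json(report: dict) -> str:
    """Canonical JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2)


def render_markdown(report: dict) -> str:
    """Short human-readable summary of an analysis report."""
    c = report["cohort"]
    t = report["thresholds"]
    lines = [
        "# Longitudinal outlier analysis",
        "",
        f"Cohort: {c['n_individuals']} individuals "
        f"({c['n_cases']} cases, {c['n_controls']} controls), "
        f"{c['n_proteins_measured']} proteins measured, "
        f"{c['n_proteins_analyzed']} analyzed.",
        "",
        f"Cutoffs: lower {t['lower']:.3f}, upper {t['upper']:.3f} "
        f"(percentiles {t['lower_pct']:g}/{t['upper_pct']:g}), "
        f"delta {t['delta']:.3f} (percentile {t['delta_pct']:g}).",
        "",
        f"Persistent outliers: {len(report['persistent_outliers'])}",
        f"Spikes: {len(report['spikes'])}",
        f"Proteins with outlier calls: {len(report['configurations'])}",
    ]
    mixed = [r for r in report["persistent_outliers"] if r.get("mixed_direction")]
    if mixed:
        lines.append(f"Mixed-direction persistent records: {len(mixed)}")
    if "resampling" in report:
        r = report["resampling"]
        lines += [
            "",
            f"Resampling null: {r['exceedance_count']} of {r['total_observations']} "
            f"(repetition x protein) observations exceeded; empirical p {r['display_p']}.",
        ]
    return "\n".join(lines) + "\n"
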