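"""Seeded synthetic-cohort generator with injectable outlier signatures.

Emulates the structure of a longitudinal wellness cohort profiled on a
multiplexed plasma-protein panel: ~79 individuals (10 cancer cases, 69
controls), ~1196 proteins, 3–6 blood draws each spaced 120–240 days apart.
Abundances live on a log-like relative scale and are modeled as

    abundance = protein baseline + individual offset + observation noise

with all three Gaussian.  Ground-truth signal is injected on chosen
(individual, protein) pairs as one of three archetypes seen in pre-diagnostic
trajectories: a persistent elevation, a monotone rise, or a rapid one-step
spike.  Injection magnitudes are expressed in robust-score units: the added
abundance shift is ``magnitude`` times the protein's null MAD-equivalent
scale, so a magnitude-8 persistent injection sits ~8 MADs above the median
once the cohort is robust-scaled.

Case draw schedules use the diagnosis as day 0: ``n_draws`` inter-draw
intervals are sampled (the last one being the gap between the final draw and
diagnosis), placing draw *j* at day −(sum of intervals *j*..end), so the
first draw sits at −(sum of all sampled intervals) and every draw day is
negative.  Controls are anchored to enrollment at day 0 with positive
subsequent days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import CohortTable

# MAD of a standard normal; converts an SD to the MAD-equivalent scale.
NORMAL_MAD = float(norm.ppf(0.75))

ARCHETYPES = ("persistent", "monotone_rise", "spike")


@dataclass(frozen=True)
class Injection:
    """One ground-truth signal on an (individual, protein) pair.

    ``magnitude`` is in robust-score units (MADs of the protein's null
    distribution); the signal spans ``duration_draws`` draws starting at the
    0-based ``onset_draw`` of the individual's time-ordered schedule.
    """

    individual_id: str
    protein_id: str
    archetype: str
    magnitude: float
    onset_draw: int
    duration_draws: int

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if self.onset_draw < 0 or self.duration_draws < 1:
            raise ValueError("onset_draw must be >= 0 and duration_draws >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for cohort generation.

    Defaults mirror the emulated study: 10 cases + 69 controls, 1196
    proteins, 3–6 draws per individual at 120–240-day intervals.  The
    variance components (within_subject_sd=1, between_subject_sd=0.5,
    protein_location_spread=2, on the log-like abundance scale) are
    documented generator choices, not estimates.
    """

    n_cases: int = 10
    n_controls: int = 69
    n_proteins: int = 1196
    draws_per_individual: tuple[int, int] = (3, 6)
    interval_days: tuple[int, int] = (120, 240)
    protein_location_spread: float = 2.0
    within_subject_sd: float = 1.0
    between_subject_sd: float = 0.5
    missing_rate: float = 0.0
    injections: tuple[Injection, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.draws_per_individual
        if lo < 3:
            raise ValueError("draws_per_individual lower bound must be >= 3")
        if lo > hi:
            raise ValueError("draws_per_individual range is empty")
        ilo, ihi = self.interval_days
        if ilo < 1 or ilo > ihi:
            raise ValueError("interval_days range invalid")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_cases < 0 or self.n_controls < 0 or self.n_proteins < 1:
            raise ValueError("cohort dimensions must be positive")

    @property
    def null_scale(self) -> float:
        """MAD-equivalent scale of the null observation distribution.

        Pooled across individuals an observation is Gaussian with variance
        within² + between²; its MAD is that SD times the normal MAD constant.
        """
        sd = float(np.hypot(self.within_subject_sd, self.between_subject_sd))
        return NORMAL_MAD * sd


@dataclass
class TruthLabels:
    """Ground-truth record of injected events, one row per injection.

    ``events`` columns: individual_id, protein_id, archetype, magnitude,
    onset_draw, duration_draws, sample_ids (tuple of affected samples in
    draw order).
    """

    events: pd.DataFrame

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out["sample_ids"] = out["sample_ids"].map(";".join)
        out.to_csv(path, index=False)


def archetype_profile(archetype: str, magnitude: float, duration_draws: int) -> np.ndarray:
    """Per-draw offsets (robust-score units) for one signal archetype.

    persistent     constant ``magnitude`` over the whole duration
    monotone_rise  linear ramp from 0 to ``magnitude`` inclusive
    spike          flat 0 with a single jump to ``magnitude`` on the last draw
    """
    if duration_draws < 1:
        raise ValueError("duration_draws must be >= 1")
    if archetype == "persistent":
        return np.full(duration_draws, float(magnitude))
    if archetype == "monotone_rise":
        if duration_draws == 1:
            return np.array([float(magnitude)])
        return np.linspace(0.0, float(magnitude), duration_draws)
    if archetype == "spike":
        prof = np.zeros(duration_draws)
        prof[-1] = float(magnitude)
        return prof
    raise ValueError(f"unknown archetype {archetype!r}")


def _subject_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    ids = [f"case_{i + 1:02d}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_controls)
    ]
    status = ["case"] * config.n_cases + ["control"] * config.n_controls
    cancer_types = ["synthetic neoplasm"] * config.n_cases + [np.nan] * config.n_controls
    sex = rng.choice(["F", "M"], size=n)
    age = rng.integers(40, 80, size=n)
    return pd.DataFrame(
        {
            "individual_id": ids,
            "status": status,
            "cancer_type": cancer_types,
            "sex": sex,
            "age_at_baseline": pd.array(age, dtype="Int64"),
        }
    )


def _draw_days(config: SimulationConfig, rng: np.random.Generator, is_case: bool) -> np.ndarray:
    lo, hi = config.draws_per_individual
    ilo, ihi = config.interval_days
    n_draws = int(rng.integers(lo, hi + 1))
    intervals = rng.integers(ilo, ihi + 1, size=n_draws)
    if is_case:
        # day of draw j = -(gap to diagnosis + intervals back to draw j)
        days = -np.cumsum(intervals[::-1])[::-1]
    else:
        days = np.concatenate([[0], np.cumsum(intervals[:-1])])
    return days.astype(int)


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, TruthLabels]:
    """Generate a seeded cohort plus ground-truth labels for its injections.

    Deterministic given ``config.seed``.  Per-protein baselines and
    per-(individual, protein) offsets are drawn once; observation noise is
    i.i.d.  Missingness is applied last and never removes an injected
    observation.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _subject_frame(config, rng)
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    protein_index = {p: i for i, p in enumerate(proteins)}

    baselines = rng.normal(0.0, config.protein_location_spread, size=config.n_proteins)

    frames = []
    sample_ids_by_individual: dict[str, list[str]] = {}
    for _, subj in subjects.iterrows():
        ind = subj["individual_id"]
        days = _draw_days(config, rng, subj["status"] == "case")
        samples = [f"{ind}_s{j + 1:02d}" for j in range(len(days))]
        sample_ids_by_individual[ind] = samples
        offsets = rng.normal(0.0, config.between_subject_sd, size=config.n_proteins)
        noise = rng.normal(
            0.0, config.within_subject_sd, size=(len(days), config.n_proteins)
        )
        abundance = baselines[None, :] + offsets[None, :] + noise
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "sample_id": np.repeat(samples, config.n_proteins),
                    "draw_day": np.repeat(days, config.n_proteins),
                    "protein_id": np.tile(proteins, len(days)),
                    "abundance": abundance.ravel(),
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)
    measurements = measurements.set_index(["individual_id", "sample_id", "protein_id"])

    truth_rows = []
    protected: set[tuple[str, str, str]] = set()
    for inj in config.injections:
        if inj.individual_id not in sample_ids_by_individual:
            raise ValueError(f"injection references unknown individual {inj.individual_id!r}")
        if inj.protein_id not in protein_index:
            raise ValueError(f"injection references unknown protein {inj.protein_id!r}")
        samples = sample_ids_by_individual[inj.individual_id]
        if inj.onset_draw + inj.duration_draws > len(samples):
            raise ValueError(
                f"injection on {inj.individual_id} exceeds its {len(samples)} draws"
            )
        affected = samples[inj.onset_draw : inj.onset_draw + inj.duration_draws]
        profile = archetype_profile(inj.archetype, inj.magnitude, inj.duration_draws)
        for sample, offset in zip(affected, profile):
            key = (inj.individual_id, sample, inj.protein_id)
            measurements.loc[key, "abundance"] += offset * config.null_scale
            protected.add(key)
        truth_rows.append(
            {
                "individual_id": inj.individual_id,
                "protein_id": inj.protein_id,
                "archetype": inj.archetype,
                "magnitude": inj.magnitude,
                "onset_draw": inj.onset_draw,
                "duration_draws": inj.duration_draws,
                "sample_ids": tuple(affected),
            }
        )

    measurements = measurements.reset_index()
    if config.missing_rate > 0:
        missing = rng.random(len(measurements)) < config.missing_rate
        if protected:
            keys = pd.MultiIndex.from_frame(
                measurements[["individual_id", "sample_id", "protein_id"]]
            )
            missing &= ~keys.isin(protected)
        measurements.loc[missing, "abundance"] = np.nan

    truth = TruthLabels(
        events=pd.DataFrame(
            truth_rows,
            columns=[
                "individual_id",
                "protein_id",
                "archetype",
                "magnitude",
                "onset_draw",
                "duration_draws",
                "sample_ids",
            ],
        )
    )
    return CohortTable(measurements=measurements, subjects=subjects), truth
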