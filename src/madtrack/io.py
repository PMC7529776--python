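"""Cohort data model and delimited-file I/O.

The cohort is a tidy long-format table of protein measurements — one row per
(individual, sample, protein) — plus a per-individual metadata table carrying
case/control status and demographics.  Abundances are on a log-like relative
scale (Olink NPX-style); ``draw_day`` is an integer day relative to the
individual's reference event: negative days precede a case's diagnosis, while
control draws are anchored to enrollment at day 0.

File dialect: comma-separated UTF-8 with a header row.  Measurement columns
are ``individual_id, sample_id, draw_day, protein_id, abundance``; metadata
columns are ``individual_id, status, cancer_type, sex, age_at_baseline``.
An empty abundance cell is a missing observation (kept, scored as NaN
downstream); a non-empty cell that does not parse as a number is dropped and
counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["individual_id", "sample_id", "draw_day", "protein_id", "abundance"]
METADATA_COLUMNS = ["individual_id", "status", "cancer_type", "sex", "age_at_baseline"]

VALID_STATUS = frozenset({"case", "control"})
VALID_SEX = frozenset({"F", "M", "unknown"})


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


@dataclass
class CohortTable:
    """Longitudinal measurements joined with subject metadata.

    Parameters
    ----------
    measurements
        One row per (individual_id, sample_id, protein_id); columns
        ``individual_id, sample_id, draw_day, protein_id, abundance``.
        NaN abundance marks a missing observation.
    subjects
        One row per individual; columns ``individual_id, status,
        cancer_type, sex, age_at_baseline``.
    """

    measurements: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.measurements = self.measurements.reset_index(drop=True)
        self.subjects = self.subjects.reset_index(drop=True)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        m, s = self.measurements, self.subjects
        for col in MEASUREMENT_COLUMNS:
            if col not in m.columns:
                raise CohortValidationError(f"measurements missing required column {col!r}")
        for col in METADATA_COLUMNS:
            if col not in s.columns:
                raise CohortValidationError(f"metadata missing required column {col!r}")

        dup = m.duplicated(["individual_id", "sample_id", "protein_id"])
        if dup.any():
            first = m.loc[dup.idxmax(), ["individual_id", "sample_id", "protein_id"]]
            raise CohortValidationError(
                "duplicate measurement key; first offender: "
                f"({first['individual_id']}, {first['sample_id']}, {first['protein_id']})"
            )

        if s["individual_id"].duplicated().any():
            raise CohortValidationError("duplicate individual_id in metadata")

        unknown = set(m["individual_id"]) - set(s["individual_id"])
        if unknown:
            raise CohortValidationError(
                f"measurement individuals absent from metadata: {sorted(unknown)[:5]}"
            )

        bad_status = set(s["status"]) - VALID_STATUS
        if bad_status:
            raise CohortValidationError(f"invalid status values: {sorted(bad_status)}")
        cases = s[s["status"] == "case"]
        missing_type = cases["cancer_type"].isna() | (cases["cancer_type"].astype(str) == "")
        if missing_type.any():
            bad = cases.loc[missing_type, "individual_id"].iloc[0]
            raise CohortValidationError(f"case {bad!r} has no cancer_type")
        bad_sex = set(s["sex"].fillna("unknown")) - VALID_SEX
        if bad_sex:
            raise CohortValidationError(f"invalid sex values: {sorted(bad_sex)}")

        # one draw_day per (individual, sample)
        days = m.groupby(["individual_id", "sample_id"])["draw_day"].nunique()
        if (days > 1).any():
            ind, smp = days[days > 1].index[0]
            raise CohortValidationError(
                f"sample ({ind}, {smp}) carries more than one draw_day"
            )

    # -- derived views ------------------------------------------------------

    def schedule(self) -> pd.DataFrame:
        """Per-individual draw schedule, time-ordered.

        Returns one row per (individual, sample) with columns ``individual_id,
        sample_id, draw_day, position``.  Samples are ordered by draw_day with
        lexicographic sample_id as the deterministic tie-break; ``position``
        is the 0-based rank within the individual.
        """
        sched = (
            self.measurements[["individual_id", "sample_id", "draw_day"]]
            .drop_duplicates()
            .sort_values(["individual_id", "draw_day", "sample_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        sched["position"] = sched.groupby("individual_id").cumcount()
        return sched

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.subjects["individual_id"])

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.measurements["protein_id"].unique())

    def equals(self, other: "CohortTable") -> bool:
        """Field-by-field equality, insensitive to row order."""

        def canon(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys, kind="mergesort").reset_index(drop=True)

        m_a = canon(self.measurements[MEASUREMENT_COLUMNS], MEASUREMENT_COLUMNS[:4])
        m_b = canon(other.measurements[MEASUREMENT_COLUMNS], MEASUREMENT_COLUMNS[:4])
        s_a = canon(self.subjects[METADATA_COLUMNS], ["individual_id"])
        s_b = canon(other.subjects[METADATA_COLUMNS], ["individual_id"])
        return m_a.equals(m_b) and s_a.equals(s_b)


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required column {missing[0]!r}")
    return df


def read_cohort(measurements_path, metadata_path) -> CohortTable:
    """Read and validate a cohort from two CSV files.

    Rows whose abundance cell is non-empty but not numeric are dropped and
    counted in the log; empty cells become missing observations (NaN).
    Structural violations (missing columns, duplicate keys, measurement
    individuals absent from metadata) raise :class:`CohortValidationError`.
    """
    m = _read_csv(measurements_path, MEASUREMENT_COLUMNS)
    s = _read_csv(metadata_path, METADATA_COLUMNS)

    def parse_float(text: str) -> float:
        # python float() is correctly rounded, so written values read back exactly
        try:
            return float(text)
        except ValueError:
            return np.nan

    raw = m["abundance"].str.strip()
    parsed = raw.map(parse_float)
    unparsable = parsed.isna() & (raw != "")
    n_dropped = int(unparsable.sum())
    if n_dropped:
        logger.warning("dropped %d rows with unparsable abundance", n_dropped)
        m = m[~unparsable].reset_index(drop=True)
        parsed = parsed[~unparsable].reset_index(drop=True)
    m["abundance"] = parsed.astype(float)

    try:
        m["draw_day"] = m["draw_day"].astype(int)
    except ValueError as exc:
        raise CohortValidationError(f"non-integer draw_day: {exc}") from exc

    s = s.copy()
    s["cancer_type"] = s["cancer_type"].map(lambda v: np.nan if v == "" else v)
    s["sex"] = s["sex"].replace("", "unknown")
    age = pd.to_numeric(s["age_at_baseline"].replace("", np.nan), errors="coerce")
    s["age_at_baseline"] = age.astype("Int64")

    return CohortTable(measurements=m, subjects=s)


def write_cohort(cohort: CohortTable, measurements_path, metadata_path) -> None:
    """Write a cohort in the dialect :func:`read_cohort` accepts.

    Reading the files back reproduces the cohort exactly up to row order;
    missing abundances serialize as empty cells.
    """
    m = cohort.measurements[MEASUREMENT_COLUMNS].copy()
    m.to_csv(measurements_path, index=False)
    s = cohort.subjects[METADATA_COLUMNS].copy()
    s.to_csv(metadata_path, index=False)
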