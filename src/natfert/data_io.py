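"""Maternity-history ingestion, filtering and descriptive estimators.

Canonical delimited-text schema (CSV, UTF-8, header row; ages in months,
real-valued for marriage, one row per woman):

======================  =====================================================
column                  meaning
======================  =====================================================
woman_id                unique identifier (string)
cohort                  woman's birth year (integer)
marriage_age_months     age at marriage, months (real)
wife_death_age_months   wife's age at death, months; empty if none observed
spouse_death_age_months wife's age when the spouse died, months; empty if none
observed_to_50          1 if the woman is observed to age 50, else 0
child_birth_ages_months semicolon-separated birth ages in months (may be empty)
======================  =====================================================

Source registers each have bespoke layouts; users map them onto this
schema. No correction for unregistered births is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from natfert.simulate import ASFRSchedule, DEFAULT_AGE_GRID, ReproductiveHistory

MONTHS_AT_50 = 600.0

COLUMNS = (
    "woman_id",
    "cohort",
    "marriage_age_months",
    "wife_death_age_months",
    "spouse_death_age_months",
    "observed_to_50",
    "child_birth_ages_months",
)

__all__ = [
    "COLUMNS",
    "MaternityRecord",
    "SampleDefinition",
    "ReadResult",
    "read_histories",
    "filter_intact",
    "observed_asfr",
    "amenorrhea_lower_bound",
    "descriptives",
    "write_fixture",
]


@dataclass
class MaternityRecord:
    """One woman's maternity history in the canonical schema."""

    woman_id: str
    cohort: int
    marriage_age: float  # months
    child_birth_ages: list[float] = field(default_factory=list)  # months
    wife_death_age: Optional[float] = None  # months
    spouse_death_age: Optional[float] = None  # wife's age in months
    observed_to_50: bool = True

    def validate(self) -> None:
        if not 0 <= self.marriage_age <= 1200:
            raise ValueError("marriage age outside [0, 1200] months")
        births = list(self.child_birth_ages)
        if births != sorted(births):
            raise ValueError("child birth ages must be sorted")
        for b in births:
            if not 0 <= b <= 1200:
                raise ValueError("birth age outside [0, 1200] months")
            if b < self.marriage_age:
                raise ValueError("birth before marriage")


@dataclass(frozen=True)
class SampleDefinition:
    """Cohort range and intactness rule for sample construction."""

    cohort_min: int
    cohort_max: int

    def __post_init__(self) -> None:
        if self.cohort_min > self.cohort_max:
            raise ValueError("empty cohort range")


class ReadResult(NamedTuple):
    records: list[MaternityRecord]
    errors: list[tuple[int, str]]  # (1-based data row number, message)


def _opt_float(s: str) -> Optional[float]:
    s = s.strip()
    return float(s) if s else None


def read_histories(path) -> ReadResult:
    """Read maternity records from a canonical-schema CSV.

    Malformed rows are collected in the error report with their row
    number, never silently dropped; missing required columns are a hard
    error.
    """
    records: list[MaternityRecord] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = csv.DictReader(_skip_comments(fh))
        if rows.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = set(COLUMNS) - set(rows.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for lineno, row in enumerate(rows, start=1):
            try:
                births_field = (row["child_birth_ages_months"] or "").strip()
                births = (
                    [float(v) for v in births_field.split(";")]
                    if births_field
                    else []
                )
                rec = MaternityRecord(
                    woman_id=row["woman_id"].strip(),
                    cohort=int(row["cohort"]),
                    marriage_age=float(row["marriage_age_months"]),
                    child_birth_ages=births,
                    wife_death_age=_opt_float(row["wife_death_age_months"]),
                    spouse_death_age=_opt_float(row["spouse_death_age_months"]),
                    observed_to_50=row["observed_to_50"].strip() in ("1", "true", "True"),
                )
                rec.validate()
                records.append(rec)
            except (ValueError, KeyError) as exc:
                errors.append((lineno, str(exc)))
    return ReadResult(records, errors)


def _skip_comments(fh):
    for line in fh:
        if not line.startswith("#"):
            yield line


def filter_intact(
    records: Sequence[MaternityRecord], sample_def: SampleDefinition
) -> list[MaternityRecord]:
    """Intact marriages within the cohort range.

    Keeps records where the wife is observed to age 50 and neither
    spouse died before the wife reached 50; a spouse death at or after
    the wife's age 50 does not exclude.
    """
    out = []
    for r in records:
        if not r.observed_to_50:
            continue
        if r.wife_death_age is not None and r.wife_death_age < MONTHS_AT_50:
            continue
        if r.spouse_death_age is not None and r.spouse_death_age < MONTHS_AT_50:
            continue
        if not sample_def.cohort_min <= r.cohort <= sample_def.cohort_max:
            continue
        out.append(r)
    return out


def observed_asfr(
    records: Sequence[MaternityRecord],
    age_grid: Sequence[int] = DEFAULT_AGE_GRID,
) -> ASFRSchedule:
    """Observed ASFRs with the simulator's convention.

    Births at completed age ``floor(age_months / 12)`` divided by the
    number of women in the (filtered) sample at every age.
    """
    if len(records) == 0:
        raise ValueError("empty sample")
    ages = np.asarray(age_grid, dtype=int)
    births = np.array(
        [int(b) // 12 for r in records for b in r.child_birth_ages],
        dtype=np.int64,
    )
    counts = np.bincount(births, minlength=int(ages[-1]) + 1) if births.size else np.zeros(int(ages[-1]) + 1, dtype=np.int64)
    return ASFRSchedule(ages=ages, rates=counts[ages] / float(len(records)))


def amenorrhea_lower_bound(records: Sequence[MaternityRecord]) -> float:
    """Lower bound on mean post-partum amenorrhea, in months.

    Mean interval between first and second births minus mean interval
    between marriage and first birth. Records with at least one birth
    contribute to the first mean; records with at least two births to
    the second.
    """
    first = [
        r.child_birth_ages[0] - r.marriage_age
        for r in records
        if len(r.child_birth_ages) >= 1
    ]
    second = [
        r.child_birth_ages[1] - r.child_birth_ages[0]
        for r in records
        if len(r.child_birth_ages) >= 2
    ]
    if not first or not second:
        raise ValueError("no records with enough births for the interval means")
    return float(np.mean(second) - np.mean(first))


def descriptives(records: Sequence[MaternityRecord]) -> dict:
    """Sample counts, completed fertility and marriage-age moments (years)."""
    if len(records) == 0:
        raise ValueError("empty sample")
    counts = [len(r.child_birth_ages) for r in records]
    marr_years = np.array([r.marriage_age for r in records]) / 12.0
    return {
        "n_marriages": len(records),
        "n_births": int(np.sum(counts)),
        "completed_fertility": float(np.mean(counts)),
        "marriage_age_mean": float(marr_years.mean()),
        "marriage_age_sd": float(marr_years.std(ddof=1)) if len(records) > 1 else None,
    }


def write_fixture(
    histories: Sequence[ReproductiveHistory],
    path,
    cohort: int = 1900,
    header_comment: Optional[str] = None,
) -> None:
    """Export simulated histories in the canonical maternity-history schema.

    All exported records are intact by construction (no deaths, observed
    to 50), so the whole observed-data path is exercisable on synthetic
    data.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        w = csv.writer(fh)
        w.writerow(COLUMNS)
        for i, h in enumerate(histories):
            w.writerow(
                [
                    f"w{i:06d}",
                    cohort,
                    repr(float(h.marriage_age)),
                    "",
                    "",
                    1,
                    ";".join(str(int(b)) for b in h.birth_ages),
                ]
            )


def to_records(
    histories: Sequence[ReproductiveHistory], cohort: int = 1900
) -> list[MaternityRecord]:
    """In-memory counterpart of :func:`write_fixture`."""
    return [
        MaternityRecord(
            woman_id=f"w{i:06d}",
            cohort=cohort,
            marriage_age=float(h.marriage_age),
            child_birth_ages=[float(b) for b in h.birth_ages],
        )
        for i, h in enumerate(histories)
    ]
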