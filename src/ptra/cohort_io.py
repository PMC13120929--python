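"""Longitudinal cohort data model and delimited-table I/O.

A cohort is stored as five comma-delimited tables (patients, visits,
relapses, MRI findings, treatment episodes) keyed by an opaque
``patient_id``.  In memory each patient is a :class:`PatientRecord`
holding date-sorted per-stream sequences.  Dates are ISO-8601 calendar
dates; ages are real years under the 365.25-day convention, which
matches the one-decimal granularity used in clinical MS cohort reports.

Missing score values (EDSS, per-system FSS, MS course) are empty cells
in the tables and ``None`` in memory; a missing score at a visit simply
means that visit cannot anchor or confirm a score-change event.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "MsCourse",
    "FunctionalSystem",
    "Visit",
    "MriFinding",
    "TreatmentEpisode",
    "PatientRecord",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "age_at",
]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class CohortValidationError(ValueError):
    """Input rows violate a cohort invariant (e.g. duplicate visit dates)."""


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


class MsCourse(str, enum.Enum):
    """Clinical MS courses; dynamic, recorded at each visit."""

    CIS = "CIS"
    RRMS = "RRMS"
    SPMS = "SPMS"
    PPMS = "PPMS"


class FunctionalSystem(str, enum.Enum):
    """The seven functional systems plus the ambulation score."""

    BOWEL_BLADDER = "bowel_bladder"
    PYRAMIDAL = "pyramidal"
    CEREBELLAR = "cerebellar"
    BRAINSTEM = "brainstem"
    MENTAL = "mental"
    SENSORY = "sensory"
    VISUAL = "visual"
    AMBULATION = "ambulation"


_VALID_EDSS = {i / 2 for i in range(21)}


@dataclass(frozen=True)
class Visit:
    """One clinical visit: date plus (possibly missing) scores.

    ``edss`` is on the 0–10 half-step scale; ``fss`` maps functional
    systems to integer scores; ``ms_course`` is the course recorded at
    the visit.  Any of the three may be missing.
    """

    date: dt.date
    edss: float | None = None
    fss: Mapping[FunctionalSystem, int] = field(default_factory=dict)
    ms_course: MsCourse | None = None

    def __post_init__(self) -> None:
        if self.edss is not None and self.edss not in _VALID_EDSS:
            raise CohortValidationError(
                f"EDSS {self.edss!r} is not a half-step value in [0, 10]"
            )


@dataclass(frozen=True)
class MriFinding:
    date: dt.date
    region: str  # "BR" (brain) or "SC" (spinal cord)
    lesion_increase: bool

    def __post_init__(self) -> None:
        if self.region not in ("BR", "SC"):
            raise CohortValidationError(f"unknown MRI region {self.region!r}")


@dataclass(frozen=True)
class TreatmentEpisode:
    start_date: dt.date
    drug_name: str


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics plus dated event streams.

    Visits are strictly ascending in date (no two visits on the same
    day); other streams are non-decreasing.  All dates lie at or after
    ``birth_date``.
    """

    patient_id: str
    sex: Sex
    birth_date: dt.date
    visits: tuple[Visit, ...] = ()
    relapses: tuple[dt.date, ...] = ()
    mri_findings: tuple[MriFinding, ...] = ()
    treatments: tuple[TreatmentEpisode, ...] = ()

    def __post_init__(self) -> None:
        dates = [v.date for v in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: visits not strictly ascending"
            )
        for d in (
            dates
            + list(self.relapses)
            + [m.date for m in self.mri_findings]
            + [t.start_date for t in self.treatments]
        ):
            if d < self.birth_date:
                raise CohortValidationError(
                    f"patient {self.patient_id}: event date {d} before birth"
                )

    @property
    def baseline_date(self) -> dt.date | None:
        return self.visits[0].date if self.visits else None

    @property
    def last_visit_date(self) -> dt.date | None:
        return self.visits[-1].date if self.visits else None

    def sorted_streams(self) -> "PatientRecord":
        return replace(
            self,
            visits=tuple(sorted(self.visits, key=lambda v: v.date)),
            relapses=tuple(sorted(self.relapses)),
            mri_findings=tuple(sorted(self.mri_findings, key=lambda m: m.date)),
            treatments=tuple(sorted(self.treatments, key=lambda t: t.start_date)),
        )


@dataclass(frozen=True)
class Cohort:
    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate patient_ids in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}


def age_at(record: PatientRecord, date: dt.date) -> float:
    """Exact age in years at ``date`` (day count / 365.25)."""
    if date < record.birth_date:
        raise ValueError(
            f"date {date} precedes birth date {record.birth_date} "
            f"for patient {record.patient_id}"
        )
    return (date - record.birth_date).days / 365.25


# ---------------------------------------------------------------------------
# Table schemas

_FSS_COLUMNS = [f"fss_{fs.value}" for fs in FunctionalSystem]

_SCHEMAS = {
    "patients": ["patient_id", "sex", "birth_date"],
    "visits": ["patient_id", "date", "edss", *_FSS_COLUMNS, "ms_course"],
    "relapses": ["patient_id", "onset_date"],
    "mri": ["patient_id", "date", "region", "lesion_increase"],
    "treatments": ["patient_id", "start_date", "drug_name"],
}


def _read_table(path: Path | str, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} table {path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def _parse_date(cell: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(cell)
    except ValueError as exc:
        raise SchemaError(f"{where}: unparseable date {cell!r}") from exc


def load_cohort(
    patients_table: Path | str,
    visits_table: Path | str,
    relapses_table: Path | str,
    mri_table: Path | str,
    treatments_table: Path | str,
    *,
    drop_single_visit: bool = True,
) -> Cohort:
    """Read the five cohort tables into a :class:`Cohort`.

    Per-patient streams are sorted by date.  With ``drop_single_visit``
    (the default) patients with fewer than two visits are excluded, the
    standard cleaning step for longitudinal trajectory analysis where a
    single recording can anchor no within-patient sequence.
    """
    pat = _read_table(patients_table, "patients")
    vis = _read_table(visits_table, "visits")
    rel = _read_table(relapses_table, "relapses")
    mri = _read_table(mri_table, "mri")
    trt = _read_table(treatments_table, "treatments")

    visits: dict[str, list[Visit]] = {}
    for i, row in vis.iterrows():
        pid = row["patient_id"]
        where = f"visits row {i} (patient {pid})"
        date = _parse_date(row["date"], where)
        edss = float(row["edss"]) if row["edss"] != "" else None
        fss = {
            fs: int(float(row[f"fss_{fs.value}"]))
            for fs in FunctionalSystem
            if row[f"fss_{fs.value}"] != ""
        }
        course = MsCourse(row["ms_course"]) if row["ms_course"] != "" else None
        visits.setdefault(pid, []).append(
            Visit(date=date, edss=edss, fss=fss, ms_course=course)
        )
    for pid, vv in visits.items():
        dates = [v.date for v in vv]
        if len(set(dates)) != len(dates):
            raise CohortValidationError(
                f"patient {pid}: duplicate visit date in visits table"
            )

    relapses: dict[str, list[dt.date]] = {}
    for i, row in rel.iterrows():
        relapses.setdefault(row["patient_id"], []).append(
            _parse_date(row["onset_date"], f"relapses row {i}")
        )
    mris: dict[str, list[MriFinding]] = {}
    for i, row in mri.iterrows():
        mris.setdefault(row["patient_id"], []).append(
            MriFinding(
                date=_parse_date(row["date"], f"mri row {i}"),
                region=row["region"],
                lesion_increase=row["lesion_increase"] in ("1", "true", "True"),
            )
        )
    treatments: dict[str, list[TreatmentEpisode]] = {}
    for i, row in trt.iterrows():
        treatments.setdefault(row["patient_id"], []).append(
            TreatmentEpisode(
                start_date=_parse_date(row["start_date"], f"treatments row {i}"),
                drug_name=row["drug_name"],
            )
        )

    records = []
    for i, row in pat.iterrows():
        pid = row["patient_id"]
        rec = PatientRecord(
            patient_id=pid,
            sex=Sex(row["sex"]),
            birth_date=_parse_date(row["birth_date"], f"patients row {i}"),
            visits=tuple(visits.get(pid, [])),
            relapses=tuple(relapses.get(pid, [])),
            mri_findings=tuple(mris.get(pid, [])),
            treatments=tuple(treatments.get(pid, [])),
        ).sorted_streams()
        if drop_single_visit and len(rec.visits) < 2:
            continue
        records.append(rec)
    return Cohort(patients=tuple(records))


def write_cohort(cohort: Cohort, out_dir: Path | str) -> list[Path]:
    """Write the five cohort tables; inverse of :func:`load_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pat_rows, vis_rows, rel_rows, mri_rows, trt_rows = [], [], [], [], []
    for p in cohort:
        pat_rows.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex.value,
                "birth_date": p.birth_date.isoformat(),
            }
        )
        for v in p.visits:
            row = {
                "patient_id": p.patient_id,
                "date": v.date.isoformat(),
                "edss": "" if v.edss is None else f"{v.edss:g}",
                "ms_course": "" if v.ms_course is None else v.ms_course.value,
            }
            for fs in FunctionalSystem:
                row[f"fss_{fs.value}"] = (
                    str(v.fss[fs]) if fs in v.fss else ""
                )
            vis_rows.append(row)
        for d in p.relapses:
            rel_rows.append({"patient_id": p.patient_id, "onset_date": d.isoformat()})
        for m in p.mri_findings:
            mri_rows.append(
                {
                    "patient_id": p.patient_id,
                    "date": m.date.isoformat(),
                    "region": m.region,
                    "lesion_increase": "1" if m.lesion_increase else "0",
                }
            )
        for t in p.treatments:
            trt_rows.append(
                {
                    "patient_id": p.patient_id,
                    "start_date": t.start_date.isoformat(),
                    "drug_name": t.drug_name,
                }
            )

    paths = []
    for name, rows in (
        ("patients", pat_rows),
        ("visits", vis_rows),
        ("relapses", rel_rows),
        ("mri", mri_rows),
        ("treatments", trt_rows),
    ):
        path = out / f"{name}.csv"
        pd.DataFrame(rows, columns=_SCHEMAS[name]).to_csv(path, index=False)
        paths.append(path)
    return paths
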