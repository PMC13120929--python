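"""Context-specific diagnostic event extraction.

Two event taxonomies are supported, both two-tier (main category /
subcategory, each subcategory belonging to exactly one main category):

* **Cohort exploration** (:func:`extract_events_analysis1`): MS-course
  changes, relapses, regional MRI activity, confirmed ±EDSS and ±FSS
  changes, and DMT (disease-modifying treatment) switches grouped by
  mode of action.
* **Index-treatment follow-up** (:func:`extract_events_analysis2`):
  evidence of disease activity after cladribine initiation (relapse,
  confirmed disability worsening, MRI activity), its absence (NEDA-3),
  the last DMT received before the index treatment, and the count of
  distinct prior DMTs.

A score change (EDSS, or any functional-system score) becomes an event
only when it is *persistent*: the following ``confirmation_visits``
non-missing recordings must differ from the pre-change value in the
same direction.  The event is dated at the first visit showing the
change.  When two or more functional systems change in the same
direction at the same visit, the per-system events are merged into a
single "+FSS"/"-FSS" event.
"""

from __future__ import annotations

import datetime as dt
import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .cohort_io import (
    Cohort,
    FunctionalSystem,
    MsCourse,
    PatientRecord,
)

__all__ = [
    "MainCategory",
    "DiagnosticEvent",
    "EventExtractionConfig",
    "DmtGroup",
    "DmtLookupError",
    "group_dmt",
    "extract_events_analysis1",
    "extract_events_analysis2",
    "index_treatment_start",
    "extract_cohort_events",
    "event_inventory",
    "events_to_frame",
]


class MainCategory(str, enum.Enum):
    MS_COURSE_CHANGE = "MS course change"
    RELAPSE = "Relapse"
    MRI_ACTIVITY = "MRI activity"
    EDSS_CHANGE = "EDSS change"
    FSS_CHANGE = "FSS change"
    DMT_CHANGE = "DMT change"
    EDA3 = "EDA-3"
    NEDA3 = "NEDA-3"
    PRIOR_DMT = "Prior DMT"
    PRIOR_DMT_COUNT = "Prior DMT count"


@dataclass(frozen=True)
class DiagnosticEvent:
    """(patient, date, main category, subcategory) atom.

    ``label(level)`` gives the pair-analysis node label: the subcategory
    at ``sub`` level; at ``main`` level categories collapse to their
    main label, except that EDSS/FSS changes retain their sign
    ("+EDSS", "-FSS", ...).
    """

    patient_id: str
    date: dt.date
    main_category: MainCategory
    subcategory: str

    def label(self, level: str = "sub") -> str:
        if level == "sub":
            return self.subcategory
        if level != "main":
            raise ValueError(f"unknown level {level!r}")
        if self.main_category is MainCategory.EDSS_CHANGE:
            return self.subcategory  # "+EDSS" / "-EDSS"
        if self.main_category is MainCategory.FSS_CHANGE:
            return "+FSS" if self.subcategory.startswith("+") else "-FSS"
        return self.main_category.value


@dataclass(frozen=True)
class EventExtractionConfig:
    """Tunable knobs of both extractions (durations in days)."""

    level: str = "sub"
    confirmation_visits: int = 1
    cdw_sustain_days: int = 183  # "sustained >= 6 months"
    relapse_infection_gap_days: int = 30
    neda_horizon_days: int = 365
    neda_anchor: str = "clad_start"  # or "first_visit"
    clad_baseline_before_days: int = 183
    clad_baseline_after_days: int = 91

    def __post_init__(self) -> None:
        if self.confirmation_visits < 1:
            raise ValueError("confirmation_visits must be >= 1")
        for name in ("cdw_sustain_days", "relapse_infection_gap_days", "neda_horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# DMT grouping


class DmtGroup(str, enum.Enum):
    IFN_GLAT = "IFN/GLAT"
    CD20 = "CD20"
    OTH = "OTH"
    TRF = "TRF"
    DMF = "DMF"
    FNG = "FNG"
    NTZ = "NTZ"
    ALZ = "ALZ"
    CLAD = "CLAD"


# Inventory of DMTs grouped by primary mode of action and strength.
_DMT_INVENTORY: dict[str, DmtGroup] = {
    "interferon-beta-1a": DmtGroup.IFN_GLAT,
    "interferon-beta-1b": DmtGroup.IFN_GLAT,
    "peg-interferon-beta-1a": DmtGroup.IFN_GLAT,
    "glatiramer acetate": DmtGroup.IFN_GLAT,
    "rituximab": DmtGroup.CD20,
    "ocrelizumab": DmtGroup.CD20,
    "ofatumumab": DmtGroup.CD20,
    "mitoxantrone": DmtGroup.OTH,
    "methotrexate": DmtGroup.OTH,
    "azathioprine": DmtGroup.OTH,
    "cyclophosphamide": DmtGroup.OTH,
    "teriflunomide": DmtGroup.TRF,
    "dimethyl fumarate": DmtGroup.DMF,
    "fingolimod": DmtGroup.FNG,
    "natalizumab": DmtGroup.NTZ,
    "alemtuzumab": DmtGroup.ALZ,
    "cladribine": DmtGroup.CLAD,
}
# Group abbreviations resolve to themselves, so tables may carry either.
_DMT_INVENTORY.update({g.value.lower(): g for g in DmtGroup})


class DmtLookupError(KeyError):
    pass


def group_dmt(drug_name: str) -> DmtGroup:
    """Map a drug name (case-insensitive) to its mode-of-action group."""
    key = drug_name.strip().lower()
    if key in _DMT_INVENTORY:
        return _DMT_INVENTORY[key]
    raise DmtLookupError(f"unrecognized DMT name: {drug_name!r}")


# ---------------------------------------------------------------------------
# Confirmed score changes


def _confirmed_changes(
    series: Sequence[tuple[dt.date, float]], confirmation_visits: int
) -> list[tuple[dt.date, int]]:
    """Scan a (date, score) series for persistent changes.

    Returns (event date, direction) tuples; direction is +1/-1.  A
    change from the running baseline at some visit is confirmed when the
    next ``confirmation_visits`` non-missing scores all differ from the
    baseline in the same direction (they need not equal the changed
    value); the baseline then moves to the changed value.
    """
    out: list[tuple[dt.date, int]] = []
    if not series:
        return out
    baseline = series[0][1]
    i = 1
    while i < len(series):
        date, value = series[i]
        if value != baseline:
            direction = 1 if value > baseline else -1
            confirmers = series[i + 1 : i + 1 + confirmation_visits]
            ok = len(confirmers) == confirmation_visits and all(
                (v - baseline) * direction > 0 for _, v in confirmers
            )
            if ok:
                out.append((date, direction))
                baseline = value
        i += 1
    return out


# ---------------------------------------------------------------------------
# Analysis 1: cohort exploration taxonomy


def extract_events_analysis1(
    record: PatientRecord, config: EventExtractionConfig | None = None
) -> list[DiagnosticEvent]:
    """Extract the exploration-taxonomy events for one patient."""
    config = config or EventExtractionConfig()
    if len(record.visits) < 2:
        raise ValueError(
            f"patient {record.patient_id}: need >= 2 visits for event extraction"
        )
    events: list[DiagnosticEvent] = []
    pid = record.patient_id

    def emit(date: dt.date, main: MainCategory, sub: str) -> None:
        events.append(DiagnosticEvent(pid, date, main, sub))

    # MS course changes: "to CIS" only at the first recording; later
    # transitions to RRMS/SPMS at the visit where recorded.
    courses = [(v.date, v.ms_course) for v in record.visits if v.ms_course is not None]
    if courses:
        first_date, first_course = courses[0]
        if first_course is MsCourse.CIS:
            emit(first_date, MainCategory.MS_COURSE_CHANGE, "to CIS")
        prev = first_course
        for date, course in courses[1:]:
            if course != prev:
                if course is MsCourse.RRMS:
                    emit(date, MainCategory.MS_COURSE_CHANGE, "to RRMS")
                elif course is MsCourse.SPMS:
                    emit(date, MainCategory.MS_COURSE_CHANGE, "to SPMS")
                prev = course

    for onset in record.relapses:
        emit(onset, MainCategory.RELAPSE, "Relapse")

    for finding in record.mri_findings:
        if finding.lesion_increase:
            emit(
                finding.date,
                MainCategory.MRI_ACTIVITY,
                "MRI BR" if finding.region == "BR" else "MRI SC",
            )

    edss_series = [(v.date, v.edss) for v in record.visits if v.edss is not None]
    for date, sign in _confirmed_changes(edss_series, config.confirmation_visits):
        emit(date, MainCategory.EDSS_CHANGE, "+EDSS" if sign > 0 else "-EDSS")

    # Per-system FSS changes, then the same-date same-direction merge.
    _FSS_LABEL = {
        FunctionalSystem.BOWEL_BLADDER: "Bowel/Bladder",
        FunctionalSystem.PYRAMIDAL: "Pyramidal",
        FunctionalSystem.CEREBELLAR: "Cerebellar",
        FunctionalSystem.BRAINSTEM: "Brainstem",
        FunctionalSystem.MENTAL: "Mental",
        FunctionalSystem.SENSORY: "Sensory",
        FunctionalSystem.VISUAL: "Visual",
        FunctionalSystem.AMBULATION: "Ambulation",
    }
    fss_hits: dict[tuple[dt.date, int], list[FunctionalSystem]] = {}
    for fs in FunctionalSystem:
        series = [(v.date, float(v.fss[fs])) for v in record.visits if fs in v.fss]
        for date, sign in _confirmed_changes(series, config.confirmation_visits):
            fss_hits.setdefault((date, sign), []).append(fs)
    for (date, sign), systems in sorted(fss_hits.items()):
        prefix = "+" if sign > 0 else "-"
        if len(systems) >= 2:
            emit(date, MainCategory.FSS_CHANGE, f"{prefix}FSS")
        else:
            emit(date, MainCategory.FSS_CHANGE, f"{prefix}{_FSS_LABEL[systems[0]]}")

    for episode in record.treatments:
        emit(episode.start_date, MainCategory.DMT_CHANGE, group_dmt(episode.drug_name).value)

    events.sort(key=lambda e: (e.date, e.main_category.value, e.subcategory))
    return events


# ---------------------------------------------------------------------------
# Analysis 2: index-treatment (cladribine) follow-up taxonomy


def _clad_baseline_edss(
    record: PatientRecord, clad_start: dt.date, config: EventExtractionConfig
) -> float | None:
    """Baseline EDSS: closest recording within 6 months before or 3 after."""
    lo = clad_start - dt.timedelta(days=config.clad_baseline_before_days)
    hi = clad_start + dt.timedelta(days=config.clad_baseline_after_days)
    candidates = [
        (abs((v.date - clad_start).days), v.date <= clad_start, v.edss)
        for v in record.visits
        if v.edss is not None and lo <= v.date <= hi
    ]
    if not candidates:
        return None
    # Closest wins; ties prefer the pre-initiation recording.
    candidates.sort(key=lambda t: (t[0], not t[1]))
    return candidates[0][2]


def _cdw_event_date(
    record: PatientRecord, clad_start: dt.date, config: EventExtractionConfig
) -> dt.date | None:
    """First post-initiation EDSS increase sustained >= cdw_sustain_days.

    Sustained: every later non-missing EDSS up to (and including the
    first beyond) the sustain window stays above baseline; if follow-up
    ends inside the window, the last available recording decides.
    """
    baseline = _clad_baseline_edss(record, clad_start, config)
    if baseline is None:
        return None
    scored = [(v.date, v.edss) for v in record.visits if v.edss is not None]
    post = [(d, e) for d, e in scored if d > clad_start]
    for idx, (date, edss) in enumerate(post):
        if edss <= baseline:
            continue
        horizon = date + dt.timedelta(days=config.cdw_sustain_days)
        followers = []
        for d, e in post[idx + 1 :]:
            followers.append((d, e))
            if d > horizon:
                break
        if followers and all(e > baseline for _, e in followers):
            return date
    return None


def extract_events_analysis2(
    record: PatientRecord,
    clad_start: dt.date,
    config: EventExtractionConfig | None = None,
    infection_dates: Sequence[dt.date] | None = None,
) -> list[DiagnosticEvent]:
    """Extract the index-treatment follow-up events for one patient.

    ``clad_start`` must be the start of a cladribine episode on record.
    When no infection dates are supplied the relapse definition degrades
    to the plain >=24 h symptom criterion (warned once per call).
    """
    config = config or EventExtractionConfig()
    if not any(
        group_dmt(t.drug_name) is DmtGroup.CLAD and t.start_date == clad_start
        for t in record.treatments
    ):
        raise ValueError(
            f"patient {record.patient_id}: no cladribine episode starting {clad_start}"
        )
    if infection_dates is None:
        warnings.warn(
            "no infection dates supplied; relapse events use the plain "
            ">=24 h definition without the infection/fever guard",
            stacklevel=2,
        )
        infection_dates = ()

    events: list[DiagnosticEvent] = []
    pid = record.patient_id
    gap = dt.timedelta(days=config.relapse_infection_gap_days)

    for onset in record.relapses:
        if onset <= clad_start:
            continue
        if any(abs(onset - d) < gap for d in infection_dates):
            continue
        events.append(DiagnosticEvent(pid, onset, MainCategory.EDA3, "Relapse"))

    cdw_date = _cdw_event_date(record, clad_start, config)
    if cdw_date is not None:
        events.append(DiagnosticEvent(pid, cdw_date, MainCategory.EDA3, "CDW"))

    for finding in record.mri_findings:
        if finding.lesion_increase and finding.date > clad_start:
            events.append(DiagnosticEvent(pid, finding.date, MainCategory.EDA3, "MRI"))

    if not events:
        anchor = (
            clad_start
            if config.neda_anchor == "clad_start"
            else (record.baseline_date or clad_start)
        )
        events.append(
            DiagnosticEvent(
                pid,
                anchor + dt.timedelta(days=config.neda_horizon_days),
                MainCategory.NEDA3,
                "NEDA-3",
            )
        )

    prior = [
        t
        for t in record.treatments
        if t.start_date < clad_start and group_dmt(t.drug_name) is not DmtGroup.CLAD
    ]
    if prior:
        last = max(prior, key=lambda t: t.start_date)
        events.append(
            DiagnosticEvent(
                pid, clad_start, MainCategory.PRIOR_DMT, group_dmt(last.drug_name).value
            )
        )
    n_groups = len({group_dmt(t.drug_name) for t in prior})
    events.append(
        DiagnosticEvent(
            pid,
            clad_start,
            MainCategory.PRIOR_DMT_COUNT,
            "<2 DMTs" if n_groups < 2 else ">=2 DMTs",
        )
    )
    events.sort(key=lambda e: (e.date, e.main_category.value, e.subcategory))
    return events


# ---------------------------------------------------------------------------
# Cohort-level helpers


def index_treatment_start(
    record: PatientRecord, group: DmtGroup = DmtGroup.CLAD
) -> dt.date | None:
    """First start date of a treatment in ``group`` (None if absent)."""
    starts = [
        t.start_date for t in record.treatments if group_dmt(t.drug_name) is group
    ]
    return min(starts) if starts else None


def extract_cohort_events(
    cohort: Cohort,
    config: EventExtractionConfig | None = None,
    extractor: Callable[..., list[DiagnosticEvent]] = extract_events_analysis1,
    **extractor_kwargs,
) -> list[DiagnosticEvent]:
    """Flat event list over a cohort under one extractor."""
    config = config or EventExtractionConfig()
    events: list[DiagnosticEvent] = []
    for record in cohort:
        events.extend(extractor(record, config=config, **extractor_kwargs))
    return events


def event_inventory(
    cohort: Cohort,
    extractor: Callable[..., list[DiagnosticEvent]] = extract_events_analysis1,
    config: EventExtractionConfig | None = None,
    events: Iterable[DiagnosticEvent] | None = None,
) -> pd.DataFrame:
    """Per-(main, sub) event and patient counts, sorted by category.

    Pass ``events`` to tabulate an already-extracted list instead of
    re-running the extractor.
    """
    if events is None:
        events = extract_cohort_events(cohort, config=config, extractor=extractor)
    rows = [
        {
            "main_category": e.main_category.value,
            "subcategory": e.subcategory,
            "patient_id": e.patient_id,
        }
        for e in events
    ]
    if not rows:
        return pd.DataFrame(
            columns=["main_category", "subcategory", "n_events", "n_patients"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["main_category", "subcategory"])
        .agg(n_events=("patient_id", "size"), n_patients=("patient_id", "nunique"))
        .reset_index()
        .sort_values(["main_category", "subcategory"])
        .reset_index(drop=True)
    )
    return out


def events_to_frame(
    events: Iterable[DiagnosticEvent], level: str = "sub"
) -> pd.DataFrame:
    """Delimited-table view: patient_id, date, main_category, subcategory, level, label."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date.isoformat(),
                "main_category": e.main_category.value,
                "subcategory": e.subcategory,
                "level": level,
                "label": e.label(level),
            }
            for e in events
        ],
        columns=["patient_id", "date", "main_category", "subcategory", "level", "label"],
    )
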