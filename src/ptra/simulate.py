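"""Synthetic longitudinal MS cohort generator.

The generator emulates the statistical shape of a tertiary-center MS
cohort: ~70% female, baseline age lognormal around a median of 43
years, follow-up lognormal around a median of ~81 months, and a visit
grid whose median count is ~15.  Each event stream (relapses, regional
MRI activity, DMT switches, EDSS/FSS changes) is a thinned Poisson
process with a per-label baseline hazard in events per patient-year.

Dependencies between event types are *planted*: a
:class:`PlantedEffect` multiplies the outcome label's hazard by
``hazard_ratio`` inside a lag window after each trigger event, which
provides closed-form ground truth (:func:`expected_rr`) for recovery
tests of the pair-statistics stage.

EDSS and FSS streams are synthesized backwards from the intended
confirmed-change events: the score steps at the first visit on or after
the simulated change time and is held at later visits, so the
extractor's confirmation rule is exercised rather than bypassed (a
change landing on a patient's last visit stays unconfirmed, as in real
data).  What the generator does **not** model: realistic MS natural
history, treatment effects on hazards, or informative visit timing.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort_io import (
    Cohort,
    FunctionalSystem,
    MriFinding,
    MsCourse,
    PatientRecord,
    Sex,
    TreatmentEpisode,
    Visit,
)
from .events import DmtGroup
from .pairstats import TimeRange

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "DEFAULT_HAZARDS",
    "generate_cohort",
    "null_cohort",
    "expected_rr",
    "hazard_ratio_for_rr",
    "analysis2_config",
]

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
_LABEL_FSS = {v: k for k, v in _FSS_LABEL.items()}

_GROUP_DRUG = {
    DmtGroup.IFN_GLAT: "Glatiramer acetate",
    DmtGroup.CD20: "Ocrelizumab",
    DmtGroup.OTH: "Cyclophosphamide",
    DmtGroup.TRF: "Teriflunomide",
    DmtGroup.DMF: "Dimethyl fumarate",
    DmtGroup.FNG: "Fingolimod",
    DmtGroup.NTZ: "Natalizumab",
    DmtGroup.ALZ: "Alemtuzumab",
    DmtGroup.CLAD: "Cladribine",
}

#: Baseline hazards in events per patient-year, per event label.
#: Chosen so a default-size cohort produces an extracted event total of
#: the order of ten per patient, the density seen in tertiary-center
#: longitudinal MS registries.
DEFAULT_HAZARDS: dict[str, float] = {
    "Relapse": 0.09,
    "MRI BR": 0.07,
    "MRI SC": 0.035,
    "+EDSS": 0.08,
    "-EDSS": 0.05,
    **{f"+{lab}": 0.035 for lab in _FSS_LABEL.values()},
    **{f"-{lab}": 0.025 for lab in _FSS_LABEL.values()},
    "IFN/GLAT": 0.035,
    "OTH": 0.025,
    "CD20": 0.012,
    "TRF": 0.010,
    "DMF": 0.010,
    "FNG": 0.012,
    "NTZ": 0.012,
    "ALZ": 0.012,
}


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative hazard boost of ``outcome`` after each ``trigger``."""

    trigger: str
    outcome: str
    hazard_ratio: float
    lag_lo_days: int = 0
    lag_hi_days: int = 365

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not (0 <= self.lag_lo_days < self.lag_hi_days):
            raise ValueError("need 0 <= lag_lo_days < lag_hi_days")
        if self.trigger == self.outcome:
            raise ValueError("self-exciting planted effects are not supported")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the cohort simulator.

    Ages and follow-up are lognormal (median/sigma parameterization);
    visit intervals are gamma-distributed with shape 2 around
    ``visit_interval_mean_days``.  Course dynamics: patients start as
    CIS (or PPMS), convert to RRMS with ``cis_to_rrms_rate`` per year,
    then to SPMS with ``rrms_to_spms_rate`` per year.
    """

    n_patients: int = 985
    female_fraction: float = 0.6975
    age_median_years: float = 43.1
    age_sigma: float = 0.32
    followup_median_months: float = 80.8
    followup_sigma: float = 0.75
    followup_min_months: float = 3.0
    visit_interval_mean_days: float = 170.0
    visit_interval_min_days: float = 14.0
    baseline_hazards: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    planted_effects: tuple[PlantedEffect, ...] = ()
    cis_fraction: float = 0.85
    ppms_fraction: float = 0.087
    cis_to_rrms_rate: float = 0.7
    rrms_to_spms_rate: float = 0.035
    score_missing_rate: float = 0.04
    calendar_start: dt.date = dt.date(2000, 1, 1)
    calendar_span_days: int = 6574  # baseline dates spread over ~18 years
    with_index_clad: bool = False
    prior_dmt_mean: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.female_fraction < 1):
            raise ValueError("female_fraction must be in (0, 1)")
        if any(h < 0 for h in self.baseline_hazards.values()):
            raise ValueError("hazards must be non-negative")


# ---------------------------------------------------------------------------
# Ground truth


def expected_rr(
    effect: PlantedEffect, baseline_hazard: float, window: TimeRange
) -> float:
    """Closed-form RR of (trigger -> outcome) under the planted model.

    For a single trigger at the anchor, the outcome process has rate
    lam*h on the overlap of the observation window with the lag window
    and lam elsewhere, so with overlap O and window length D (days):

        RR = (1 - exp(-lam*(D-O) - lam*h*O)) / (1 - exp(-lam*D))

    As lam -> 0 this tends to 1 + (h-1)*O/D.  No overlap gives 1.0.
    """
    overlap = max(
        0, min(window.hi, effect.lag_hi_days) - max(window.lo, effect.lag_lo_days)
    )
    if overlap == 0:
        return 1.0
    span = window.hi - window.lo
    lam = baseline_hazard / 365.25  # per day
    h = effect.hazard_ratio
    if lam == 0:
        return 1.0 + (h - 1.0) * overlap / span
    p1 = 1.0 - math.exp(-lam * (span - overlap) - lam * h * overlap)
    p0 = 1.0 - math.exp(-lam * span)
    return p1 / p0


def hazard_ratio_for_rr(
    target_rr: float,
    baseline_hazard: float,
    window: TimeRange,
    lag_lo_days: int = 0,
    lag_hi_days: int = 365,
) -> float:
    """Invert :func:`expected_rr` for the boost giving ``target_rr``."""

    def f(h: float) -> float:
        eff = PlantedEffect("A", "B", h, lag_lo_days, lag_hi_days)
        return expected_rr(eff, baseline_hazard, window) - target_rr

    return float(brentq(f, 1e-9, 1e6))


# ---------------------------------------------------------------------------
# Point-process machinery


def _effect_order(labels: Sequence[str], effects: Sequence[PlantedEffect]) -> list[str]:
    """Topological order: triggers simulated before their outcomes."""
    deps: dict[str, set[str]] = {lab: set() for lab in labels}
    for e in effects:
        if e.outcome in deps and e.trigger in deps:
            deps[e.outcome].add(e.trigger)
    out: list[str] = []
    mark: dict[str, int] = {}

    def visit(lab: str) -> None:
        state = mark.get(lab, 0)
        if state == 1:
            raise ValueError("planted effects form a cycle")
        if state == 2:
            return
        mark[lab] = 1
        for d in deps[lab]:
            visit(d)
        mark[lab] = 2
        out.append(lab)

    for lab in labels:
        visit(lab)
    return out


def _simulate_stream(
    rng: np.random.Generator,
    lam_per_year: float,
    followup_days: float,
    boosts: Sequence[tuple[float, float, float]],
) -> np.ndarray:
    """Event times (days since baseline) of a piecewise-constant-hazard process.

    ``boosts`` are (start_day, end_day, factor) intervals multiplying
    the base rate; overlapping boosts multiply.
    """
    lam = lam_per_year / 365.25
    if lam == 0 or followup_days <= 0:
        return np.empty(0)
    cuts = {0.0, followup_days}
    for s, e, _ in boosts:
        if e > 0 and s < followup_days:
            cuts.add(max(0.0, s))
            cuts.add(min(followup_days, e))
    edges = sorted(cuts)
    times: list[float] = []
    for a, b in zip(edges, edges[1:]):
        factor = 1.0
        mid = (a + b) / 2
        for s, e, f in boosts:
            if s <= mid < e:
                factor *= f
        rate = lam * factor
        n = rng.poisson(rate * (b - a))
        if n:
            times.extend(rng.uniform(a, b, size=n))
    return np.sort(np.array(times))


# ---------------------------------------------------------------------------
# Patient assembly


def _score_series(
    visit_days: np.ndarray,
    start: float,
    up_times: np.ndarray,
    down_times: np.ndarray,
    step: float,
    lo: float,
    hi: float,
) -> list[float]:
    """Piecewise-constant score over the visit grid.

    The score steps at the first visit on or after each change time and
    holds until the next change; changes beyond the last visit are
    silently lost, as they would be in a real registry.
    """
    changes = sorted(
        [(t, +step) for t in up_times] + [(t, -step) for t in down_times]
    )
    values = []
    level = start
    k = 0
    for d in visit_days:
        while k < len(changes) and changes[k][0] <= d:
            level = min(hi, max(lo, level + changes[k][1]))
            k += 1
        values.append(level)
    return values


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Simulate a cohort under ``config``; deterministic given its seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    labels = sorted(set(config.baseline_hazards) | {e.trigger for e in config.planted_effects}
                    | {e.outcome for e in config.planted_effects})
    order = _effect_order(labels, config.planted_effects)
    effects_for = {
        lab: [e for e in config.planted_effects if e.outcome == lab] for lab in labels
    }
    dmt_labels = {g.value for g in DmtGroup}
    fss_labels = set(_LABEL_FSS)

    any_effect_fired = False
    patients: list[PatientRecord] = []
    for k in range(config.n_patients):
        pid = f"P{k:05d}"
        sex = Sex.FEMALE if rng.random() < config.female_fraction else Sex.MALE
        age_years = math.exp(
            rng.normal(math.log(config.age_median_years), config.age_sigma)
        )
        baseline = config.calendar_start + dt.timedelta(
            days=int(rng.integers(0, config.calendar_span_days))
        )
        birth = baseline - dt.timedelta(days=int(round(age_years * 365.25)))
        followup_months = max(
            config.followup_min_months,
            math.exp(
                rng.normal(math.log(config.followup_median_months), config.followup_sigma)
            ),
        )
        followup_days = followup_months * 30.44

        # visit grid: baseline, then gamma-distributed intervals
        days = [0.0]
        while days[-1] < followup_days:
            gap = max(
                config.visit_interval_min_days,
                rng.gamma(2.0, config.visit_interval_mean_days / 2.0),
            )
            days.append(days[-1] + gap)
        days[-1] = followup_days  # last visit closes follow-up
        visit_days = np.unique(np.round(days))
        if len(visit_days) < 2:
            visit_days = np.array([0.0, max(30.0, followup_days)])

        # labeled point events, triggers before outcomes
        stream: dict[str, np.ndarray] = {}
        for lab in order:
            boosts = []
            for e in effects_for[lab]:
                for t in stream.get(e.trigger, ()):
                    boosts.append(
                        (t + e.lag_lo_days, t + e.lag_hi_days, e.hazard_ratio)
                    )
            if boosts:
                any_effect_fired = True
            stream[lab] = _simulate_stream(
                rng,
                config.baseline_hazards.get(lab, 0.0),
                followup_days,
                boosts,
            )

        def to_dates(times: np.ndarray) -> list[dt.date]:
            return [baseline + dt.timedelta(days=int(round(t))) for t in times]

        relapses = to_dates(stream.get("Relapse", np.empty(0)))
        mri = [
            MriFinding(date=d, region="BR", lesion_increase=True)
            for d in to_dates(stream.get("MRI BR", np.empty(0)))
        ] + [
            MriFinding(date=d, region="SC", lesion_increase=True)
            for d in to_dates(stream.get("MRI SC", np.empty(0)))
        ]
        treatments = [
            TreatmentEpisode(start_date=d, drug_name=_GROUP_DRUG[DmtGroup(lab)])
            for lab in sorted(dmt_labels & set(stream))
            for d in to_dates(stream[lab])
        ]

        clad_start = None
        if config.with_index_clad:
            clad_offset = int(rng.integers(0, 91))
            clad_start = baseline + dt.timedelta(days=clad_offset)
            treatments.append(
                TreatmentEpisode(start_date=clad_start, drug_name="Cladribine")
            )
            n_prior = min(4, rng.poisson(config.prior_dmt_mean))
            non_index = [g for g in DmtGroup if g is not DmtGroup.CLAD]
            groups = [
                non_index[i]
                for i in rng.choice(len(non_index), size=n_prior, replace=False)
            ]
            back = clad_offset
            for g in groups:
                back += int(rng.integers(90, 1200))
                start = clad_start - dt.timedelta(days=back - clad_offset + 1)
                if start < birth:
                    continue
                treatments.append(
                    TreatmentEpisode(start_date=start, drug_name=_GROUP_DRUG[g])
                )

        # EDSS / FSS series synthesized from the intended change events
        edss0 = float(rng.choice(np.arange(1.0, 5.5, 0.5)))
        edss_vals = _score_series(
            visit_days,
            edss0,
            stream.get("+EDSS", np.empty(0)),
            stream.get("-EDSS", np.empty(0)),
            step=0.5,
            lo=0.0,
            hi=10.0,
        )
        fss_vals: dict[FunctionalSystem, list[float]] = {}
        for lab, fs in _LABEL_FSS.items():
            fss_vals[fs] = _score_series(
                visit_days,
                float(rng.integers(0, 4)),
                stream.get(f"+{lab}", np.empty(0)),
                stream.get(f"-{lab}", np.empty(0)),
                step=1.0,
                lo=0.0,
                hi=6.0,
            )

        # course dynamics
        u = rng.random()
        if u < config.cis_fraction:
            course0 = MsCourse.CIS
        elif u < config.cis_fraction + config.ppms_fraction:
            course0 = MsCourse.PPMS
        else:
            course0 = MsCourse.RRMS
        if config.with_index_clad:
            course0 = MsCourse.RRMS
        t_rrms = math.inf
        t_spms = math.inf
        if course0 is MsCourse.CIS:
            t_rrms = rng.exponential(365.25 / config.cis_to_rrms_rate)
        if course0 is not MsCourse.PPMS:
            start_rrms = 0.0 if course0 is MsCourse.RRMS else t_rrms
            t_spms = start_rrms + rng.exponential(365.25 / config.rrms_to_spms_rate)

        visits = []
        for i, d in enumerate(visit_days):
            if d >= t_spms:
                course = MsCourse.SPMS
            elif d >= t_rrms:
                course = MsCourse.RRMS
            else:
                course = course0
            edss = None if rng.random() < config.score_missing_rate else edss_vals[i]
            fss = {
                fs: int(vals[i])
                for fs, vals in fss_vals.items()
                if rng.random() >= config.score_missing_rate
            }
            visits.append(
                Visit(
                    date=baseline + dt.timedelta(days=int(d)),
                    edss=edss,
                    fss=fss,
                    ms_course=course,
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                birth_date=birth,
                visits=tuple(visits),
                relapses=tuple(sorted(relapses)),
                mri_findings=tuple(sorted(mri, key=lambda m: m.date)),
                treatments=tuple(sorted(treatments, key=lambda t: t.start_date)),
            )
        )

    if config.planted_effects and not any_effect_fired:
        warnings.warn(
            "no planted effect window overlapped any patient's follow-up; "
            "the planted dependencies left no trace in this cohort"
        )
    return Cohort(patients=tuple(patients))


def null_cohort(
    n_patients: int, hazards: Mapping[str, float] | None = None, seed: int = 0
) -> Cohort:
    """Cohort with mutually independent event streams (no planted effects)."""
    return generate_cohort(
        SyntheticConfig(
            n_patients=n_patients,
            baseline_hazards=dict(hazards) if hazards is not None else dict(DEFAULT_HAZARDS),
            planted_effects=(),
            seed=seed,
        )
    )


def analysis2_config(seed: int = 0, n_patients: int = 83) -> SyntheticConfig:
    """Small-cohort preset mirroring an index-treatment follow-up study:
    every patient starts cladribine shortly after baseline, has 0-4 prior
    DMTs, short follow-up (mean ~22 months) and sparse disease activity.
    """
    return SyntheticConfig(
        n_patients=n_patients,
        female_fraction=0.6386,
        age_median_years=43.0,
        followup_median_months=20.0,
        followup_sigma=0.45,
        followup_min_months=4.0,
        visit_interval_mean_days=120.0,
        baseline_hazards={
            "Relapse": 0.15,
            "MRI BR": 0.05,
            "MRI SC": 0.02,
            "+EDSS": 0.08,
            "-EDSS": 0.04,
        },
        planted_effects=(),
        with_index_clad=True,
        seed=seed,
    )
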