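import datetime as dt

import pandas as pd
import pytest

from ptra.cohort_io import (
    Cohort,
    FunctionalSystem,
    MriFinding,
    MsCourse,
    TreatmentEpisode,
)
from ptra.events import (
    DmtGroup,
    DmtLookupError,
    EventExtractionConfig,
    MainCategory,
    event_inventory,
    extract_cohort_events,
    extract_events_analysis1,
    extract_events_analysis2,
    group_dmt,
    index_treatment_start,
)
from ptra.simulate import SyntheticConfig, analysis2_config, generate_cohort

from conftest import make_patient

D = dt.date


def visits(*specs):
    return tuple(specs)


def labels(events, main=None):
    if main is not None:
        events = [e for e in events if e.main_category is main]
    return [(e.date, e.subcategory) for e in events]


class TestDmtGrouping:
    @pytest.mark.parametrize(
        "drug,group",
        [
            ("Glatiramer acetate", DmtGroup.IFN_GLAT),
            ("peg-interferon-beta-1a", DmtGroup.IFN_GLAT),
            ("Fingolimod", DmtGroup.FNG),
            ("Cyclophosphamide", DmtGroup.OTH),
            ("RITUXIMAB", DmtGroup.CD20),
            ("teriflunomide", DmtGroup.TRF),
            ("Dimethyl Fumarate", DmtGroup.DMF),
            ("Natalizumab", DmtGroup.NTZ),
            ("Alemtuzumab", DmtGroup.ALZ),
            ("Cladribine", DmtGroup.CLAD),
        ],
    )
    def test_inventory(self, drug, group):
        assert group_dmt(drug) is group

    def test_unknown_drug_is_an_error_naming_it(self):
        with pytest.raises(DmtLookupError, match="Imaginarimab"):
            group_dmt("Imaginarimab")


class TestEdssChanges:
    def test_confirmed_increase_dated_at_first_change(self):
        p = make_patient(
            visit_specs=((D(2015, 1, 1), 3.0), (D(2015, 6, 1), 4.0), (D(2016, 1, 1), 4.0))
        )
        ev = labels(extract_events_analysis1(p), MainCategory.EDSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+EDSS")]

    def test_unconfirmed_change_is_dropped(self):
        p = make_patient(
            visit_specs=((D(2015, 1, 1), 3.0), (D(2015, 6, 1), 4.0), (D(2016, 1, 1), 3.0))
        )
        assert labels(extract_events_analysis1(p), MainCategory.EDSS_CHANGE) == []

    def test_confirmation_compares_against_prechange_value(self):
        # 3.0 -> 4.0 confirmed by 3.5 (same direction, not same value)
        p = make_patient(
            visit_specs=((D(2015, 1, 1), 3.0), (D(2015, 6, 1), 4.0), (D(2016, 1, 1), 3.5))
        )
        ev = labels(extract_events_analysis1(p), MainCategory.EDSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+EDSS")]

    def test_reversal_emits_opposite_event(self):
        p = make_patient(
            visit_specs=(
                (D(2015, 1, 1), 3.0),
                (D(2015, 6, 1), 4.0),
                (D(2016, 1, 1), 4.0),
                (D(2016, 6, 1), 3.0),
                (D(2017, 1, 1), 3.0),
            )
        )
        ev = labels(extract_events_analysis1(p), MainCategory.EDSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+EDSS"), (D(2016, 6, 1), "-EDSS")]

    def test_missing_values_skipped_not_confirming(self):
        p = make_patient(
            visit_specs=(
                (D(2015, 1, 1), 3.0),
                (D(2015, 6, 1), 4.0),
                (D(2016, 1, 1), None),
                (D(2016, 6, 1), 4.5),
            )
        )
        ev = labels(extract_events_analysis1(p), MainCategory.EDSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+EDSS")]

    def test_removing_last_visit_never_creates_events(self):
        # confirmation needs a subsequent visit: truncation can only remove
        cohort = generate_cohort(SyntheticConfig(n_patients=25, seed=3))
        for p in cohort:
            if len(p.visits) < 3:
                continue
            full = set(
                (e.date, e.subcategory)
                for e in extract_events_analysis1(p)
                if e.main_category
                in (MainCategory.EDSS_CHANGE, MainCategory.FSS_CHANGE)
            )
            import dataclasses

            trunc = dataclasses.replace(p, visits=p.visits[:-1])
            short = set(
                (e.date, e.subcategory)
                for e in extract_events_analysis1(trunc)
                if e.main_category
                in (MainCategory.EDSS_CHANGE, MainCategory.FSS_CHANGE)
            )
            assert short <= full


class TestFssChanges:
    def test_two_systems_same_direction_merge(self):
        fss = [
            {FunctionalSystem.PYRAMIDAL: 2, FunctionalSystem.SENSORY: 1},
            {FunctionalSystem.PYRAMIDAL: 3, FunctionalSystem.SENSORY: 2},
            {FunctionalSystem.PYRAMIDAL: 3, FunctionalSystem.SENSORY: 2},
        ]
        p = make_patient(
            visit_specs=((D(2015, 1, 1), None), (D(2015, 6, 1), None), (D(2016, 1, 1), None)),
            fss=fss,
        )
        ev = labels(extract_events_analysis1(p), MainCategory.FSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+FSS")]

    def test_single_system_keeps_its_name(self):
        fss = [
            {FunctionalSystem.MENTAL: 2},
            {FunctionalSystem.MENTAL: 3},
            {FunctionalSystem.MENTAL: 3},
        ]
        p = make_patient(
            visit_specs=((D(2015, 1, 1), None), (D(2015, 6, 1), None), (D(2016, 1, 1), None)),
            fss=fss,
        )
        ev = labels(extract_events_analysis1(p), MainCategory.FSS_CHANGE)
        assert ev == [(D(2015, 6, 1), "+Mental")]

    def test_mixed_directions_merge_per_direction(self):
        fss = [
            {FunctionalSystem.PYRAMIDAL: 2, FunctionalSystem.SENSORY: 1,
             FunctionalSystem.MENTAL: 3, FunctionalSystem.VISUAL: 2},
            {FunctionalSystem.PYRAMIDAL: 3, FunctionalSystem.SENSORY: 2,
             FunctionalSystem.MENTAL: 2, FunctionalSystem.VISUAL: 1},
            {FunctionalSystem.PYRAMIDAL: 3, FunctionalSystem.SENSORY: 2,
             FunctionalSystem.MENTAL: 2, FunctionalSystem.VISUAL: 1},
        ]
        p = make_patient(
            visit_specs=((D(2015, 1, 1), None), (D(2015, 6, 1), None), (D(2016, 1, 1), None)),
            fss=fss,
        )
        ev = labels(extract_events_analysis1(p), MainCategory.FSS_CHANGE)
        assert sorted(s for _, s in ev) == ["+FSS", "-FSS"]

    def test_no_duplicate_same_direction_fss_on_one_date(self):
        cohort = generate_cohort(SyntheticConfig(n_patients=30, seed=8))
        for p in cohort:
            fss_ev = [
                e for e in extract_events_analysis1(p)
                if e.main_category is MainCategory.FSS_CHANGE
            ]
            seen = [(e.date, e.subcategory[0]) for e in fss_ev]
            assert len(seen) == len(set(seen))


class TestCourseAndStreams:
    def test_course_sequence(self):
        courses = [MsCourse.CIS, MsCourse.CIS, MsCourse.RRMS, MsCourse.RRMS, MsCourse.SPMS]
        specs = tuple((D(2015, 1, 1) + dt.timedelta(days=180 * i), 3.0) for i in range(5))
        p = make_patient(visit_specs=specs, courses=courses)
        ev = labels(extract_events_analysis1(p), MainCategory.MS_COURSE_CHANGE)
        assert ev == [
            (specs[0][0], "to CIS"),
            (specs[2][0], "to RRMS"),
            (specs[4][0], "to SPMS"),
        ]

    def test_no_to_cis_when_first_course_is_other(self):
        courses = [MsCourse.PPMS, MsCourse.PPMS]
        p = make_patient(courses=courses)
        assert labels(extract_events_analysis1(p), MainCategory.MS_COURSE_CHANGE) == []

    def test_relapse_mri_dmt_streams(self):
        p = make_patient(
            relapses=(D(2015, 2, 1),),
            mri=(
                MriFinding(D(2015, 3, 1), "BR", True),
                MriFinding(D(2015, 4, 1), "SC", False),  # no increase: no event
            ),
            treatments=(TreatmentEpisode(D(2015, 5, 1), "Alemtuzumab"),),
        )
        ev = extract_events_analysis1(p)
        subs = [e.subcategory for e in ev]
        assert "Relapse" in subs and "MRI BR" in subs and "ALZ" in subs
        assert "MRI SC" not in subs

    def test_hierarchy_bijection(self):
        cohort = generate_cohort(SyntheticConfig(n_patients=40, seed=5))
        sub_to_main = {}
        for e in extract_cohort_events(cohort):
            assert sub_to_main.setdefault(e.subcategory, e.main_category) == e.main_category

    def test_main_level_labels_retain_score_sign(self):
        p = make_patient(
            visit_specs=((D(2015, 1, 1), 3.0), (D(2015, 6, 1), 4.0), (D(2016, 1, 1), 4.0))
        )
        ev = [e for e in extract_events_analysis1(p) if e.main_category is MainCategory.EDSS_CHANGE]
        assert ev[0].label("main") == "+EDSS"
        assert ev[0].label("sub") == "+EDSS"


class TestAnalysis2:
    def _clad_patient(self, visit_specs, relapses=(), mri=(), prior=()):
        treatments = tuple(prior) + (TreatmentEpisode(D(2019, 1, 1), "Cladribine"),)
        return make_patient(
            visit_specs=visit_specs,
            relapses=relapses,
            mri=mri,
            treatments=treatments,
        )

    def test_requires_clad_episode(self):
        p = make_patient()
        with pytest.raises(ValueError, match="cladribine"):
            extract_events_analysis2(p, D(2019, 1, 1), infection_dates=())

    def test_neda_when_no_activity(self):
        p = self._clad_patient(
            ((D(2018, 12, 1), 2.0), (D(2019, 6, 1), 2.0), (D(2020, 1, 1), 2.0))
        )
        ev = extract_events_analysis2(
            p, D(2019, 1, 1), EventExtractionConfig(neda_horizon_days=365),
            infection_dates=(),
        )
        neda = [e for e in ev if e.main_category is MainCategory.NEDA3]
        assert len(neda) == 1
        assert neda[0].date == D(2019, 1, 1) + dt.timedelta(days=365)

    def test_neda_exclusive_with_eda(self):
        cohort = generate_cohort(analysis2_config(seed=2))
        for p in cohort:
            ev = extract_events_analysis2(
                p, index_treatment_start(p), infection_dates=()
            )
            has_eda = any(e.main_category is MainCategory.EDA3 for e in ev)
            has_neda = any(e.main_category is MainCategory.NEDA3 for e in ev)
            assert has_eda != has_neda

    def test_prior_dmt_and_count(self):
        prior = (
            TreatmentEpisode(D(2015, 1, 1), "Interferon-beta-1a"),
            TreatmentEpisode(D(2017, 1, 1), "Fingolimod"),
        )
        p = self._clad_patient(
            ((D(2018, 12, 1), 2.0), (D(2019, 6, 1), 2.0)), prior=prior
        )
        ev = extract_events_analysis2(p, D(2019, 1, 1), infection_dates=())
        prior_ev = [e for e in ev if e.main_category is MainCategory.PRIOR_DMT]
        count_ev = [e for e in ev if e.main_category is MainCategory.PRIOR_DMT_COUNT]
        assert prior_ev[0].subcategory == "FNG"
        assert prior_ev[0].date == D(2019, 1, 1)
        assert count_ev[0].subcategory == ">=2 DMTs"
        assert count_ev[0].date == D(2019, 1, 1)

    def test_cdw_sustained_increase_dated_at_first_rise(self):
        p = self._clad_patient(
            (
                (D(2018, 12, 1), 2.0),  # baseline near initiation
                (D(2019, 3, 1), 3.0),   # first rise, day d
                (D(2019, 6, 1), 3.0),
                (D(2019, 9, 20), 3.5),  # > d + 183: sustained
            )
        )
        ev = extract_events_analysis2(p, D(2019, 1, 1), infection_dates=())
        cdw = [e for e in ev if e.subcategory == "CDW"]
        assert [e.date for e in cdw] == [D(2019, 3, 1)]

    def test_transient_increase_is_not_cdw(self):
        p = self._clad_patient(
            (
                (D(2018, 12, 1), 2.0),
                (D(2019, 3, 1), 3.0),
                (D(2019, 5, 1), 2.0),  # back to baseline inside window
                (D(2019, 10, 1), 2.0),
            )
        )
        ev = extract_events_analysis2(p, D(2019, 1, 1), infection_dates=())
        assert [e for e in ev if e.subcategory == "CDW"] == []

    def test_relapse_infection_guard(self):
        p = self._clad_patient(
            ((D(2018, 12, 1), 2.0), (D(2019, 6, 1), 2.0), (D(2020, 1, 1), 2.0)),
            relapses=(D(2019, 4, 1), D(2019, 8, 1)),
        )
        ev = extract_events_analysis2(
            p, D(2019, 1, 1), infection_dates=(D(2019, 4, 10),)
        )
        relapse_dates = [e.date for e in ev if e.subcategory == "Relapse"]
        assert relapse_dates == [D(2019, 8, 1)]  # April relapse within 30 d of fever

    def test_warns_without_infection_table(self):
        p = self._clad_patient(((D(2018, 12, 1), 2.0), (D(2019, 6, 1), 2.0)))
        with pytest.warns(UserWarning, match="infection"):
            extract_events_analysis2(p, D(2019, 1, 1))


class TestInventory:
    def test_empty_cohort(self):
        table = event_inventory(Cohort(patients=()))
        assert len(table) == 0

    def test_single_patient_two_relapses(self):
        p = make_patient(relapses=(D(2015, 2, 1), D(2015, 9, 1)))
        table = event_inventory(Cohort(patients=(p,)))
        row = table[table.subcategory == "Relapse"].iloc[0]
        assert (row.n_events, row.n_patients) == (2, 1)

    def test_matches_independent_groupby(self):
        cohort = generate_cohort(SyntheticConfig(n_patients=30, seed=12))
        events = extract_cohort_events(cohort)
        table = event_inventory(cohort, events=events)
        df = pd.DataFrame(
            {
                "main": [e.main_category.value for e in events],
                "sub": [e.subcategory for e in events],
                "pid": [e.patient_id for e in events],
            }
        )
        expected = (
            df.groupby(["main", "sub"])["pid"].agg(["size", "nunique"]).reset_index()
        )
        merged = table.merge(
            expected, left_on=["main_category", "subcategory"], right_on=["main", "sub"]
        )
        assert len(merged) == len(table) == len(expected)
        assert (merged.n_events == merged["size"]).all()
        assert (merged.n_patients == merged["nunique"]).all()
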