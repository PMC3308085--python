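from datetime import timedelta

import pytest

from raclaims.data_model import Drug, Flag, InfusionEvent, ProcedureEvent, Route
from raclaims.effectiveness_algorithm import (
    check_biologic_switch_or_add,
    check_dose_escalation,
    check_injections,
    check_new_dmard,
    check_oral_glucocorticoid,
    classify_cohort,
    classify_effectiveness,
)

from conftest import INDEX, make_episode, make_fill


def adherent_supply(pid="p1", drug=Drug.ETANERCEPT):
    return [make_fill(pid=pid, drug=drug, day=d) for d in range(0, 360, 28)]


def infusion(day, dose=300.0, drug=Drug.INFLIXIMAB, pid="p1"):
    return InfusionEvent(pid, drug, INDEX + timedelta(days=day), dose)


class TestSwitchOrAdd:
    def test_new_biologic_at_month_5_flags(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        fills = [make_fill(drug=Drug.ADALIMUMAB, day=d) for d in (150, 178)]
        assert check_biologic_switch_or_add(ep, fills, [])

    def test_index_drug_refills_do_not_flag(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        assert not check_biologic_switch_or_add(ep, adherent_supply(), [])

    def test_continuous_second_biologic_is_not_a_switch(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        fills = [make_fill(drug=Drug.ADALIMUMAB, day=d) for d in range(-196, 341, 28)]
        assert not check_biologic_switch_or_add(ep, fills, [])

    def test_restart_after_long_gap_counts_as_initiation(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        fills = [
            make_fill(drug=Drug.ADALIMUMAB, day=-300),
            make_fill(drug=Drug.ADALIMUMAB, day=150),
        ]
        assert check_biologic_switch_or_add(ep, fills, [])


class TestNewDmard:
    def test_mtx_first_filled_at_month_4_flags(self):
        ep = make_episode()
        fills = [make_fill(drug=Drug.METHOTREXATE, day=120, route=Route.ORAL)]
        assert check_new_dmard(ep, fills)

    def test_continued_dmard_does_not_flag(self):
        ep = make_episode()
        fills = [
            make_fill(drug=Drug.HYDROXYCHLOROQUINE, day=d, route=Route.ORAL)
            for d in (-60, 30, 120)
        ]
        assert not check_new_dmard(ep, fills)

    def test_fill_on_index_date_counts_as_already_taking(self):
        ep = make_episode()
        fills = [
            make_fill(drug=Drug.METHOTREXATE, day=d, route=Route.ORAL)
            for d in (0, 60)
        ]
        assert not check_new_dmard(ep, fills)

    def test_fill_one_day_after_index_flags(self):
        ep = make_episode()
        fills = [make_fill(drug=Drug.METHOTREXATE, day=1, route=Route.ORAL)]
        assert check_new_dmard(ep, fills)


class TestDoseEscalation:
    def test_infliximab_300_to_500_flags(self):
        ep = make_episode(drug=Drug.INFLIXIMAB)
        days = [0, 14, 42, 98, 154, 210, 266, 322]
        infusions = [infusion(d, 500.0 if d == 322 else 300.0) for d in days]
        assert check_dose_escalation(ep, [], infusions)

    def test_infliximab_290_to_300_rounds_to_same_bin(self):
        ep = make_episode(drug=Drug.INFLIXIMAB)
        days = [0, 14, 42, 98, 154, 210, 266, 322]
        infusions = [infusion(d, 290.0 if d == 0 else 300.0) for d in days]
        assert not check_dose_escalation(ep, [], infusions)

    def test_infliximab_excess_infusion_count_flags(self):
        ep = make_episode(drug=Drug.INFLIXIMAB)
        days = [0, 14, 42, 98, 154, 180, 210, 238, 266, 322]  # 10 > 1.2 * 8
        assert check_dose_escalation(ep, [], [infusion(d) for d in days])

    def test_abatacept_constant_dose_passes(self):
        ep = make_episode(drug=Drug.ABATACEPT)
        infusions = [infusion(d, 750.0, Drug.ABATACEPT) for d in range(0, 361, 30)]
        assert not check_dose_escalation(ep, [], infusions)

    def test_abatacept_100mg_increase_flags_without_rounding(self):
        ep = make_episode(drug=Drug.ABATACEPT)
        infusions = [infusion(0, 750.0, Drug.ABATACEPT), infusion(330, 850.0, Drug.ABATACEPT)]
        assert check_dose_escalation(ep, [], infusions)
        infusions[-1] = infusion(330, 849.0, Drug.ABATACEPT)
        assert not check_dose_escalation(ep, [], infusions)

    def test_etanercept_double_dose_window_flags(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        fills = [
            make_fill(day=d, quantity=8 if d >= 112 else 4) for d in range(0, 360, 28)
        ]
        assert check_dose_escalation(ep, fills, [])

    def test_etanercept_standard_dose_passes(self):
        ep = make_episode(drug=Drug.ETANERCEPT)
        assert not check_dose_escalation(ep, adherent_supply(), [])

    def test_rituximab_never_flags(self):
        ep = make_episode(drug=Drug.RITUXIMAB)
        infusions = [infusion(0, 1000.0, Drug.RITUXIMAB), infusion(14, 2000.0, Drug.RITUXIMAB)]
        assert not check_dose_escalation(ep, [], infusions)

    def test_nonbiologic_rejected(self):
        ep = make_episode(drug=Drug.HYDROXYCHLOROQUINE)
        with pytest.raises(ValueError):
            check_dose_escalation(ep, [], [])


class TestInjections:
    def proc(self, day, pid="p1"):
        return ProcedureEvent(pid, INDEX + timedelta(days=day))

    def test_two_distinct_days_flags(self):
        ep = make_episode()
        assert check_injections(ep, [self.proc(150), self.proc(240)])

    def test_three_injections_one_day_passes(self):
        ep = make_episode()
        assert not check_injections(ep, [self.proc(150)] * 3)

    def test_injection_before_day_90_ignored(self):
        ep = make_episode()
        assert not check_injections(ep, [self.proc(30), self.proc(89)])

    def test_boundaries_inclusive(self):
        ep = make_episode()
        assert check_injections(ep, [self.proc(90), self.proc(360)])


class TestOralGlucocorticoid:
    def gc(self, day, qty, days_supply=30, anchor=INDEX, pid="p1"):
        return make_fill(
            pid=pid,
            drug=Drug.ORAL_GLUCOCORTICOID,
            day=day,
            days_supply=days_supply,
            strength=5.0,
            quantity=qty,
            route=Route.ORAL,
            anchor=anchor,
        )

    def test_naive_patient_40_days_flags_initiation(self):
        ep = make_episode()
        fills = [self.gc(180, 40, days_supply=40)]
        assert check_oral_glucocorticoid(ep, fills) is Flag.GC_INITIATION

    def test_naive_patient_30_days_passes(self):
        ep = make_episode()
        assert check_oral_glucocorticoid(ep, [self.gc(180, 30)]) is None

    def test_prevalent_at_exactly_120_percent_passes(self):
        ep = make_episode()
        fills = [self.gc(-100, 180), self.gc(-100, 216, anchor=ep.outcome_date)]
        assert check_oral_glucocorticoid(ep, fills) is None

    def test_prevalent_just_above_120_percent_flags(self):
        ep = make_episode()
        fills = [self.gc(-100, 180), self.gc(-100, 216.2, anchor=ep.outcome_date)]
        assert check_oral_glucocorticoid(ep, fills) is Flag.GC_DOSE_INCREASE

    def test_prevalent_with_zero_mg_treated_as_naive(self):
        ep = make_episode()
        fills = [self.gc(-100, 0), self.gc(180, 40, days_supply=40)]
        assert check_oral_glucocorticoid(ep, fills) is Flag.GC_INITIATION

    def test_supply_before_day_90_does_not_count_for_naive(self):
        ep = make_episode()
        assert check_oral_glucocorticoid(ep, [self.gc(30, 40, days_supply=40)]) is None


class TestClassify:
    def test_clean_adherent_course_is_effective(self):
        ep = make_episode()
        res = classify_effectiveness(ep, adherent_supply(), [], [])
        assert res.effective and not res.flags

    def test_multiple_overlapping_flags_recorded(self):
        ep = make_episode()
        fills = adherent_supply()
        fills += [
            make_fill(drug=Drug.ORAL_GLUCOCORTICOID, day=-100, days_supply=30,
                      strength=5.0, quantity=180, route=Route.ORAL),
            make_fill(drug=Drug.ORAL_GLUCOCORTICOID, day=-100, days_supply=30,
                      strength=5.0, quantity=240, route=Route.ORAL,
                      anchor=ep.outcome_date),
            make_fill(drug=Drug.METHOTREXATE, day=120, route=Route.ORAL),
        ]
        res = classify_effectiveness(ep, fills, [], [])
        assert res.flags == {Flag.GC_DOSE_INCREASE, Flag.NEW_DMARD_ADDED}

    def test_rituximab_bare_course_is_effective(self):
        ep = make_episode(drug=Drug.RITUXIMAB)
        infusions = [infusion(0, 1000.0, Drug.RITUXIMAB), infusion(14, 1000.0, Drug.RITUXIMAB)]
        res = classify_effectiveness(ep, [], infusions, [])
        assert res.effective

    def test_determinism(self):
        ep = make_episode()
        fills = adherent_supply()
        r1 = classify_effectiveness(ep, fills, [], [])
        r2 = classify_effectiveness(ep, list(reversed(fills)), [], [])
        assert r1 == r2

    def test_adding_prohibited_event_is_monotone(self, small_cohort):
        """An extra prohibited event can only remove effectiveness."""
        results = classify_cohort(
            small_cohort.episodes,
            small_cohort.fills,
            small_cohort.infusions,
            small_cohort.procedures,
        )
        extra = [
            ProcedureEvent(ep.patient_id, ep.index_date + timedelta(days=120))
            for ep in small_cohort.episodes
        ] + [
            ProcedureEvent(ep.patient_id, ep.index_date + timedelta(days=200))
            for ep in small_cohort.episodes
        ]
        perturbed = classify_cohort(
            small_cohort.episodes,
            small_cohort.fills,
            small_cohort.infusions,
            list(small_cohort.procedures) + extra,
            )
        for before, after in zip(results, perturbed):
            assert before.flags <= after.flags
            if not before.effective:
                assert not after.effective

    def test_events_outside_episode_window_ignored(self):
        ep = make_episode()
        fills = adherent_supply()
        outside = [
            make_fill(drug=Drug.ADALIMUMAB, day=400),
            make_fill(drug=Drug.METHOTREXATE, day=-200, route=Route.ORAL),
        ]
        procs = [ProcedureEvent("p1", INDEX + timedelta(days=380))]
        res = classify_effectiveness(ep, fills + outside, [], procs)
        assert res.effective
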