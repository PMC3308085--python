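"""Synthetic claims cohorts with known ground truth.

Real administrative claims linked to a clinical registry cannot be shipped,
so this module fabricates the four event streams (pharmacy fills, infusion
administrations, injection procedures, registry visits) for cohorts whose
latent state is fully known:

* each patient initiates one index drug and satisfies every eligibility
  rule (active-user oral fill 6-12 months pre-index, baseline visit on the
  index date, outcome visit at 12 months +/- jitter);
* a latent *responder* indicator (the clinical gold standard) drives the
  outcome-visit disease activity: responders reach DAS28 <= 3.2 or improve
  by > 1.2 units and keep full adherence, non-responders do neither;
* independent per-component Bernoulli draws decide which claims-visible
  failure behaviors (non-adherence, biologic switch, new DMARD, dose
  escalation, repeat joint injections, glucocorticoid initiation/increase)
  are written into the streams, with separate probabilities for responders
  and non-responders.

One modelled dependence: a biologic switch in a non-responder truncates the
index-drug supply, so the switch also surfaces as non-adherence, mirroring
how discontinuation and switching pool in practice.  A responder's switch
is generated as an *add-on* that leaves index-drug adherence intact.

Default parameters describe a US veteran RA cohort: 305 episodes, 27%
gold-standard response, baseline DAS28 4.9 +/- 1.6, and a drug mix led by
adalimumab, etanercept and hydroxychloroquine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .data_model import (
    BIOLOGICS,
    Drug,
    EpisodeClass,
    Flag,
    InfusionEvent,
    PharmacyFill,
    ProcedureEvent,
    RegistryVisit,
    Route,
    TreatmentEpisode,
)
from .gold_standard import das28_esr

COMPONENTS = ("nonadherent", "switch", "new_dmard", "escalation", "injections", "gc")

#: Dispensing pattern for drugs whose adherence is MPR-based:
#: (strength mg, quantity per fill, days supply / refill interval, route).
_FILL_PATTERNS: dict[Drug, tuple[float, float, int, Route]] = {
    Drug.ETANERCEPT: (50.0, 4, 28, Route.SUBCUTANEOUS),
    Drug.ADALIMUMAB: (40.0, 2, 28, Route.SUBCUTANEOUS),
    Drug.HYDROXYCHLOROQUINE: (200.0, 60, 30, Route.ORAL),
    Drug.LEFLUNOMIDE: (20.0, 30, 30, Route.ORAL),
    Drug.SULFASALAZINE: (500.0, 120, 30, Route.ORAL),
    Drug.METHOTREXATE: (2.5, 84, 28, Route.ORAL),
}

_INFUSION_DOSE = {Drug.INFLIXIMAB: 300.0, Drug.ABATACEPT: 750.0, Drug.RITUXIMAB: 1000.0}

_DMARD_SET = (Drug.METHOTREXATE, Drug.SULFASALAZINE, Drug.LEFLUNOMIDE, Drug.HYDROXYCHLOROQUINE)


def _default_drug_mix() -> dict[Drug, float]:
    counts = {
        Drug.ABATACEPT: 9,
        Drug.ADALIMUMAB: 74,
        Drug.ETANERCEPT: 60,
        Drug.INFLIXIMAB: 34,
        Drug.RITUXIMAB: 20,
        Drug.HYDROXYCHLOROQUINE: 63,
        Drug.LEFLUNOMIDE: 20,
        Drug.SULFASALAZINE: 25,
    }
    total = sum(counts.values())
    return {d: c / total for d, c in counts.items()}


def _default_responder_probs() -> dict[str, float]:
    # Responders stay adherent by definition; their algorithm failures come
    # from treatment changes made for non-efficacy reasons (dominated by
    # glucocorticoid use for comorbid indications).
    return {
        "nonadherent": 0.0,
        "switch": 0.02,
        "new_dmard": 0.08,
        "escalation": 0.04,
        "injections": 0.03,
        "gc": 0.15,
    }


def _default_nonresponder_probs() -> dict[str, float]:
    # Non-responders mostly discontinue or switch; other components echo the
    # observed reason mix (GC increase > new DMARD > dose increase).
    return {
        "nonadherent": 0.80,
        "switch": 0.10,
        "new_dmard": 0.12,
        "escalation": 0.08,
        "injections": 0.06,
        "gc": 0.15,
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 305
    drug_mix: dict[Drug, float] = field(default_factory=_default_drug_mix)
    true_responder_prevalence: float = 0.27
    baseline_das28_mean: float = 4.9
    baseline_das28_sd: float = 1.6
    responder_failure_probs: dict[str, float] = field(
        default_factory=_default_responder_probs
    )
    nonresponder_failure_probs: dict[str, float] = field(
        default_factory=_default_nonresponder_probs
    )
    outcome_jitter_days: int = 30
    stable_gc_background_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("true_responder_prevalence", "stable_gc_background_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.responder_failure_probs, self.nonresponder_failure_probs):
            for comp, p in probs.items():
                if comp not in COMPONENTS:
                    raise ValueError(f"unknown component {comp!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {comp!r} must be in [0, 1]")
        if self.outcome_jitter_days > 55:
            raise ValueError("outcome jitter must keep visits inside 12 +/- 2 months")


@dataclass
class SyntheticCohort:
    fills: list[PharmacyFill]
    infusions: list[InfusionEvent]
    procedures: list[ProcedureEvent]
    visits: list[RegistryVisit]
    episodes: list[TreatmentEpisode]
    truth: pd.DataFrame


def _applicable_components(drug: Drug, responder: bool) -> set[str]:
    """Components that can actually flip the algorithm for this drug.

    Rituximab has no adherence or escalation criterion; escalation rules
    exist only for biologics; responders are adherent by construction.
    """
    comps = {"switch", "new_dmard", "injections", "gc"}
    if drug in BIOLOGICS and drug != Drug.RITUXIMAB:
        comps.add("escalation")
    if not responder and drug != Drug.RITUXIMAB:
        comps.add("nonadherent")
    return comps


def implied_performance(config: SimulationConfig) -> tuple[float, float]:
    """Analytic sensitivity/specificity of the algorithm implied by the
    per-component failure probabilities and the drug mix.

    Sensitivity: probability that a responder draws no applicable failure.
    Specificity: probability that a non-responder draws at least one.
    """
    total = sum(config.drug_mix.values())
    se = sp = 0.0
    for drug, w in config.drug_mix.items():
        w /= total
        pr = config.responder_failure_probs
        pn = config.nonresponder_failure_probs
        clean_r = math.prod(
            1.0 - pr.get(c, 0.0) for c in _applicable_components(drug, True)
        )
        clean_n = math.prod(
            1.0 - pn.get(c, 0.0) for c in _applicable_components(drug, False)
        )
        se += w * clean_r
        sp += w * (1.0 - clean_n)
    # the mix weights sum to 1 only up to rounding; keep probabilities in range
    return min(se, 1.0), min(sp, 1.0)


# ---------------------------------------------------------------------------
# Registry-visit synthesis
# ---------------------------------------------------------------------------

_LN_ESR_MAX = math.log(140.0)


def visit_for_das28(
    patient_id: str, visit_date: date, target: float, rng: np.random.Generator
) -> RegistryVisit:
    """Construct a registry visit whose DAS28-ESR equals `target` exactly.

    Joint counts and the patient global are drawn at severity-appropriate
    levels; ESR then solves the DAS28 identity.  Feasible for targets in
    roughly [0.5, 8.5] given the component ranges (TJC/SJC 0-28, global
    0-100, ESR 1-140 mm/h).
    """
    if not 0.0 <= target <= 8.5:
        raise ValueError(f"target DAS28 {target} outside the constructible range")
    for _ in range(500):
        tjc = int(np.clip(round(rng.normal(2.4 * target, 3.0)), 0, 28))
        sjc = int(np.clip(round(rng.normal(2.0 * target, 3.0)), 0, 28))
        fixed = 0.56 * math.sqrt(tjc) + 0.28 * math.sqrt(sjc)
        residual = target - fixed
        # residual must be coverable by 0.014*global (<= 1.4) + 0.7*ln ESR
        if not 0.0 <= residual <= 1.4 + 0.7 * _LN_ESR_MAX:
            continue
        pg = float(np.clip(rng.uniform(0.0, 100.0), 0.0, residual / 0.014))
        ln_esr = (residual - 0.014 * pg) / 0.7
        if ln_esr > _LN_ESR_MAX:
            ln_esr = _LN_ESR_MAX
            pg = (residual - 0.7 * ln_esr) / 0.014
            if pg > 100.0:
                continue
        esr = math.exp(ln_esr)
        phys = float(np.clip(rng.normal(pg, 12.0), 0.0, 100.0))
        visit = RegistryVisit(
            patient_id=patient_id,
            date=visit_date,
            tjc28=tjc,
            sjc28=sjc,
            esr_mm_hr=esr,
            patient_global=pg,
            physician_global=phys,
        )
        assert abs(das28_esr(tjc, sjc, esr, pg) - target) < 1e-9
        return visit
    raise RuntimeError(f"could not construct a visit for DAS28 target {target}")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _mpr_fills(
    pid: str, drug: Drug, start: date, stop_day: int, escalate_from: int | None
) -> list[PharmacyFill]:
    """Refills of `drug` every supply interval from `start` while the fill
    day is < stop_day; quantity doubles from `escalate_from` (days)."""
    strength, qty, interval, route = _FILL_PATTERNS[drug]
    fills = []
    day = 0
    while day < stop_day:
        q = qty * 2 if (escalate_from is not None and day >= escalate_from) else qty
        fills.append(
            PharmacyFill(
                patient_id=pid,
                drug=drug,
                fill_date=start + timedelta(days=day),
                days_supply=interval,
                strength_mg=strength,
                quantity=q,
                route=route,
            )
        )
        day += interval
    return fills


def _infusion_schedule_days(drug: Drug, horizon: int) -> list[int]:
    if drug == Drug.INFLIXIMAB:
        days = [d for d in (0, 14, 42, 98) if d <= horizon]
        d = 98 + 56
        while d <= horizon:
            days.append(d)
            d += 56
        return days
    if drug == Drug.ABATACEPT:
        return list(range(0, horizon + 1, 30))
    if drug == Drug.RITUXIMAB:
        return [d for d in (0, 14) if d <= horizon]
    raise ValueError(drug)


def _gc_fill(pid: str, when: date, qty: float, days: int) -> PharmacyFill:
    return PharmacyFill(
        patient_id=pid,
        drug=Drug.ORAL_GLUCOCORTICOID,
        fill_date=when,
        days_supply=days,
        strength_mg=5.0,
        quantity=qty,
        route=Route.ORAL,
    )


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully eligible cohort with a per-patient truth table.

    The truth table records the latent responder status, each intended
    component failure, and the algorithm flags those failures should raise;
    output is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    drugs = list(config.drug_mix)
    mix = np.array([config.drug_mix[d] for d in drugs], dtype=float)
    mix /= mix.sum()

    fills: list[PharmacyFill] = []
    infusions: list[InfusionEvent] = []
    procedures: list[ProcedureEvent] = []
    visits: list[RegistryVisit] = []
    episodes: list[TreatmentEpisode] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        drug = drugs[rng.choice(len(drugs), p=mix)]
        is_dmard_class = drug not in BIOLOGICS
        responder = bool(rng.random() < config.true_responder_prevalence)
        probs = (
            config.responder_failure_probs
            if responder
            else config.nonresponder_failure_probs
        )
        applicable = _applicable_components(drug, responder)
        drawn = {
            c: (c in applicable and rng.random() < probs.get(c, 0.0))
            for c in COMPONENTS
        }

        index_date = date(2004, 1, 1) + timedelta(days=int(rng.integers(0, 1461)))
        horizon = 365 + int(
            rng.integers(-config.outcome_jitter_days, config.outcome_jitter_days + 1)
        )
        outcome_date = index_date + timedelta(days=horizon)

        # --- registry visits -------------------------------------------------
        baseline_das = float(
            np.clip(
                rng.normal(config.baseline_das28_mean, config.baseline_das28_sd),
                2.0,
                8.2,
            )
        )
        if responder:
            if baseline_das > 4.8 and rng.random() < 0.3:
                outcome_das = baseline_das - 1.6  # improved but not LDA
            else:
                outcome_das = float(rng.uniform(1.5, 3.1))
        else:
            floor = max(3.2, baseline_das - 1.2)
            outcome_das = float(min(floor + rng.uniform(0.3, 1.5), 8.2))
        baseline_visit = visit_for_das28(pid, index_date, baseline_das, rng)
        outcome_visit = visit_for_das28(pid, outcome_date, outcome_das, rng)
        visits.extend([baseline_visit, outcome_visit])

        # --- eligibility plumbing -------------------------------------------
        fills.append(
            PharmacyFill(
                patient_id=pid,
                drug=Drug.OTHER_ORAL,
                fill_date=index_date - timedelta(days=240),
                days_supply=30,
                strength_mg=10.0,
                quantity=30,
                route=Route.ORAL,
            )
        )
        if is_dmard_class:
            # anchor methotrexate running before and throughout the episode
            strength, qty, interval, route = _FILL_PATTERNS[Drug.METHOTREXATE]
            day = -364
            while day < horizon:
                fills.append(
                    PharmacyFill(
                        patient_id=pid,
                        drug=Drug.METHOTREXATE,
                        fill_date=index_date + timedelta(days=day),
                        days_supply=interval,
                        strength_mg=strength,
                        quantity=qty,
                        route=route,
                    )
                )
                day += interval

        # --- index-drug supply ----------------------------------------------
        truncated = drawn["nonadherent"] or (drawn["switch"] and not responder)
        stop_day = horizon
        if drawn["nonadherent"]:
            stop_day = min(stop_day, int(0.4 * horizon))
        if drawn["switch"] and not responder:
            stop_day = min(stop_day, 150)
        escalate = drawn["escalation"] and not truncated
        expected_flags: set[Flag] = set()
        if truncated and drug != Drug.RITUXIMAB:
            expected_flags.add(Flag.NONADHERENT_OR_SWITCH)
        if escalate:
            expected_flags.add(Flag.BIOLOGIC_DOSE_ESCALATION)

        if drug in _FILL_PATTERNS:
            fills.extend(
                _mpr_fills(pid, drug, index_date, stop_day, 112 if escalate else None)
            )
        else:
            sched = [d for d in _infusion_schedule_days(drug, horizon) if d <= stop_day]
            base_dose = _INFUSION_DOSE[drug]
            for k, d in enumerate(sched):
                dose = base_dose
                if escalate and k == len(sched) - 1:
                    dose = base_dose + 200.0
                infusions.append(
                    InfusionEvent(
                        patient_id=pid,
                        drug=drug,
                        date=index_date + timedelta(days=d),
                        dose_mg=dose,
                    )
                )

        # --- component events ------------------------------------------------
        if drawn["switch"]:
            expected_flags.add(Flag.BIOLOGIC_SWITCH_OR_ADD)
            new_bio = Drug.ADALIMUMAB if drug != Drug.ADALIMUMAB else Drug.ETANERCEPT
            strength, qty, interval, route = _FILL_PATTERNS[new_bio]
            for d in (150, 150 + interval, 150 + 2 * interval):
                fills.append(
                    PharmacyFill(
                        patient_id=pid,
                        drug=new_bio,
                        fill_date=index_date + timedelta(days=d),
                        days_supply=interval,
                        strength_mg=strength,
                        quantity=qty,
                        route=route,
                    )
                )

        if drawn["new_dmard"]:
            expected_flags.add(Flag.NEW_DMARD_ADDED)
            if is_dmard_class:
                options = [
                    d
                    for d in (Drug.SULFASALAZINE, Drug.LEFLUNOMIDE, Drug.HYDROXYCHLOROQUINE)
                    if d != drug
                ]
                new_dmard = options[int(rng.integers(len(options)))]
            else:
                new_dmard = Drug.METHOTREXATE
            strength, qty, interval, route = _FILL_PATTERNS[new_dmard]
            for d in (120, 120 + interval, 120 + 2 * interval):
                fills.append(
                    PharmacyFill(
                        patient_id=pid,
                        drug=new_dmard,
                        fill_date=index_date + timedelta(days=d),
                        days_supply=interval,
                        strength_mg=strength,
                        quantity=qty,
                        route=route,
                    )
                )

        if drawn["injections"]:
            expected_flags.add(Flag.EXCESS_JOINT_INJECTIONS)
            for d in (150, 240):
                procedures.append(
                    ProcedureEvent(patient_id=pid, date=index_date + timedelta(days=d))
                )

        gc_mode = ""
        if drawn["gc"]:
            if rng.random() < 0.5:
                gc_mode = "initiation"
                expected_flags.add(Flag.GC_INITIATION)
                fills.append(_gc_fill(pid, index_date + timedelta(days=120), 40, 40))
            else:
                gc_mode = "increase"
                expected_flags.add(Flag.GC_DOSE_INCREASE)
                for d in (-150, -90):
                    fills.append(_gc_fill(pid, index_date + timedelta(days=d), 90, 90))
                for d in (-150, -90):
                    fills.append(
                        _gc_fill(pid, outcome_date + timedelta(days=d), 120, 120)
                    )
        elif rng.random() < config.stable_gc_background_prob:
            # Prevalent user on a stable dose: equal cumulative milligrams in
            # the 6 months before index and before outcome (fills anchored to
            # each window so the 1.2x comparison sees a ratio of exactly 1).
            gc_mode = "stable"
            for d in (-150, -70, 60, 120):
                fills.append(_gc_fill(pid, index_date + timedelta(days=d), 30, 30))
            for d in (-150, -70):
                fills.append(_gc_fill(pid, outcome_date + timedelta(days=d), 30, 30))

        episodes.append(
            TreatmentEpisode(
                patient_id=pid,
                index_drug=drug,
                index_date=index_date,
                episode_class=EpisodeClass.DMARD if is_dmard_class else EpisodeClass.BIOLOGIC,
                outcome_visit=outcome_visit,
                baseline_visit=baseline_visit,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "index_drug": drug.value,
                "episode_class": "dmard" if is_dmard_class else "biologic",
                "index_date": index_date.isoformat(),
                "outcome_date": outcome_date.isoformat(),
                "responder": responder,
                "baseline_das28": baseline_das,
                "outcome_das28": outcome_das,
                "gc_mode": gc_mode,
                **{f"fail_{c}": drawn[c] for c in COMPONENTS},
                "expected_flags": "|".join(sorted(f.value for f in expected_flags)),
                "expected_algorithm_effective": not expected_flags,
            }
        )

    fills.sort(key=lambda f: (f.patient_id, f.fill_date, f.drug.value))
    infusions.sort(key=lambda x: (x.patient_id, x.date))
    procedures.sort(key=lambda x: (x.patient_id, x.date))
    visits.sort(key=lambda v: (v.patient_id, v.date))
    return SyntheticCohort(
        fills=fills,
        infusions=infusions,
        procedures=procedures,
        visits=visits,
        episodes=episodes,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Deterministic boundary fixture
# ---------------------------------------------------------------------------


def generate_paper_fixture() -> SyntheticCohort:
    """A deterministic ~30-episode cohort probing every rule at its boundary.

    Each patient exercises one condition of the effectiveness rule at or
    adjacent to its threshold (MPR exactly 0.80, glucocorticoid ratio
    exactly 120%, the infliximab 100-mg round-up edge, one vs two injection
    days, the abatacept one-missed-infusion allowance, ...).  The truth
    table stores the audited expected flags per episode.
    """
    index = date(2006, 1, 5)
    outcome = index + timedelta(days=360)

    fills: list[PharmacyFill] = []
    infusions: list[InfusionEvent] = []
    procedures: list[ProcedureEvent] = []
    visits: list[RegistryVisit] = []
    episodes: list[TreatmentEpisode] = []
    expected: dict[str, frozenset[Flag]] = {}

    def fill(pid, drug, day, days_supply, strength, qty, route=Route.ORAL, anchor=None):
        fills.append(
            PharmacyFill(
                patient_id=pid,
                drug=drug,
                fill_date=(anchor or index) + timedelta(days=day),
                days_supply=days_supply,
                strength_mg=strength,
                quantity=qty,
                route=route,
            )
        )

    def adherent_supply(pid, drug, escalate_from=None):
        if drug in _FILL_PATTERNS:
            strength, qty, interval, route = _FILL_PATTERNS[drug]
            day = 0
            while day < 360:
                q = qty * 2 if (escalate_from is not None and day >= escalate_from) else qty
                fill(pid, drug, day, interval, strength, q, route)
                day += interval
        else:
            for d in _infusion_schedule_days(drug, 360):
                infusions.append(
                    InfusionEvent(
                        patient_id=pid,
                        drug=drug,
                        date=index + timedelta(days=d),
                        dose_mg=_INFUSION_DOSE[drug],
                    )
                )

    def infuse(pid, drug, day, dose):
        infusions.append(
            InfusionEvent(
                patient_id=pid, drug=drug, date=index + timedelta(days=day), dose_mg=dose
            )
        )

    def add_case(pid, drug, flags, episode_class=EpisodeClass.BIOLOGIC):
        fill(pid, Drug.OTHER_ORAL, -240, 30, 10.0, 30)
        baseline = RegistryVisit(pid, index, 8, 6, 30.0, 55.0, 50.0)
        outcome_v = RegistryVisit(pid, outcome, 4, 3, 20.0, 40.0, 35.0)
        visits.extend([baseline, outcome_v])
        episodes.append(
            TreatmentEpisode(
                patient_id=pid,
                index_drug=drug,
                index_date=index,
                episode_class=episode_class,
                outcome_visit=outcome_v,
                baseline_visit=baseline,
            )
        )
        expected[pid] = frozenset(flags)

    # --- medication possession ratio at the 80% boundary -------------------
    pid = "ada_mpr_080"  # 288 supplied days / 360-day window = 0.80 exactly
    for d in (0, 90, 180, 270):
        fill(pid, Drug.ADALIMUMAB, d, 72, 40.0, 5, Route.SUBCUTANEOUS)
    add_case(pid, Drug.ADALIMUMAB, [])

    pid = "ada_mpr_079"  # 284/360 just below threshold
    for d in (0, 90, 180, 270):
        fill(pid, Drug.ADALIMUMAB, d, 71, 40.0, 5, Route.SUBCUTANEOUS)
    add_case(pid, Drug.ADALIMUMAB, [Flag.NONADHERENT_OR_SWITCH])

    pid = "eta_mpr_capped"  # 420 supplied days, ratio capped at 1.0
    for d in range(0, 301, 50):
        fill(pid, Drug.ETANERCEPT, d, 60, 50.0, 8, Route.SUBCUTANEOUS)
    add_case(pid, Drug.ETANERCEPT, [])

    # --- oral glucocorticoid dose ratio at exactly 120% ---------------------
    pid = "gc_120pct"  # 900 mg pre-index vs 1080 mg pre-outcome: passes
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 180)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 216, anchor=outcome)
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "gc_121pct"  # 1081 mg pre-outcome: strict > 120% fails
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 180)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 216.2, anchor=outcome)
    add_case(pid, Drug.ETANERCEPT, [Flag.GC_DOSE_INCREASE])

    pid = "gc_naive_30d"  # naive user, exactly 30 days supplied: passes
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, 150, 30, 5.0, 30)
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "gc_naive_31d"
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, 150, 31, 5.0, 31)
    add_case(pid, Drug.ETANERCEPT, [Flag.GC_INITIATION])

    pid = "gc_naive_pre90"  # 40 days supplied but before index + 90: passes
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, 30, 40, 5.0, 40)
    add_case(pid, Drug.ETANERCEPT, [])

    # --- infliximab round-up and infusion-count rules -----------------------
    pid = "ifx_roundup_flag"  # 300 -> 500 mg: round-up difference 200
    for k, d in enumerate(_infusion_schedule_days(Drug.INFLIXIMAB, 360)):
        infuse(pid, Drug.INFLIXIMAB, d, 500.0 if k == 7 else 300.0)
    add_case(pid, Drug.INFLIXIMAB, [Flag.BIOLOGIC_DOSE_ESCALATION])

    pid = "ifx_roundup_edge"  # 290 -> 300 mg: both round up to 300
    for k, d in enumerate(_infusion_schedule_days(Drug.INFLIXIMAB, 360)):
        infuse(pid, Drug.INFLIXIMAB, d, 290.0 if k == 0 else 300.0)
    add_case(pid, Drug.INFLIXIMAB, [])

    pid = "ifx_count_over"  # 10 infusions vs 8 expected: > 120%
    for d in _infusion_schedule_days(Drug.INFLIXIMAB, 360) + [180, 294]:
        infuse(pid, Drug.INFLIXIMAB, d, 300.0)
    add_case(pid, Drug.INFLIXIMAB, [Flag.BIOLOGIC_DOSE_ESCALATION])

    pid = "ifx_missing_one"  # 7 of 8 expected infusions: not adherent
    for d in _infusion_schedule_days(Drug.INFLIXIMAB, 360)[:-1]:
        infuse(pid, Drug.INFLIXIMAB, d, 300.0)
    add_case(pid, Drug.INFLIXIMAB, [Flag.NONADHERENT_OR_SWITCH])

    # --- abatacept one-missed-infusion allowance ----------------------------
    pid = "aba_miss_one"  # 12 of 13 monthly infusions: allowance applies
    for d in _infusion_schedule_days(Drug.ABATACEPT, 360)[:-1]:
        infuse(pid, Drug.ABATACEPT, d, 750.0)
    add_case(pid, Drug.ABATACEPT, [])

    pid = "aba_miss_two"  # 11 of 13: fails
    for d in _infusion_schedule_days(Drug.ABATACEPT, 360)[:-2]:
        infuse(pid, Drug.ABATACEPT, d, 750.0)
    add_case(pid, Drug.ABATACEPT, [Flag.NONADHERENT_OR_SWITCH])

    pid = "aba_dose_up_100"  # last dose 100 mg above the first
    sched = _infusion_schedule_days(Drug.ABATACEPT, 360)
    for k, d in enumerate(sched):
        infuse(pid, Drug.ABATACEPT, d, 850.0 if k == len(sched) - 1 else 750.0)
    add_case(pid, Drug.ABATACEPT, [Flag.BIOLOGIC_DOSE_ESCALATION])

    pid = "aba_dose_up_99"  # 99 mg above: passes
    for k, d in enumerate(sched):
        infuse(pid, Drug.ABATACEPT, d, 849.0 if k == len(sched) - 1 else 750.0)
    add_case(pid, Drug.ABATACEPT, [])

    # --- joint-injection unique-day rule ------------------------------------
    pid = "inj_one_day"  # three injections, one calendar day: passes
    adherent_supply(pid, Drug.ETANERCEPT)
    for _ in range(3):
        procedures.append(ProcedureEvent(pid, index + timedelta(days=150)))
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "inj_two_days"
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in (150, 240):
        procedures.append(ProcedureEvent(pid, index + timedelta(days=d)))
    add_case(pid, Drug.ETANERCEPT, [Flag.EXCESS_JOINT_INJECTIONS])

    pid = "inj_pre_window"  # both days before index + 90: passes
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in (50, 89):
        procedures.append(ProcedureEvent(pid, index + timedelta(days=d)))
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "inj_boundary_days"  # day 90 and the outcome date are both inside
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in (90, 360):
        procedures.append(ProcedureEvent(pid, index + timedelta(days=d)))
    add_case(pid, Drug.ETANERCEPT, [Flag.EXCESS_JOINT_INJECTIONS])

    # --- biologic switch/add and new-DMARD rules ----------------------------
    pid = "eta_switch_add"
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in (150, 178, 206):
        fill(pid, Drug.ADALIMUMAB, d, 28, 40.0, 2, Route.SUBCUTANEOUS)
    add_case(pid, Drug.ETANERCEPT, [Flag.BIOLOGIC_SWITCH_OR_ADD])

    pid = "eta_other_bio_prevalent"  # second biologic in continuous use
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in range(-196, 341, 28):
        fill(pid, Drug.ADALIMUMAB, d, 28, 40.0, 2, Route.SUBCUTANEOUS)
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "eta_new_dmard"
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in (120, 148, 176):
        fill(pid, Drug.METHOTREXATE, d, 28, 2.5, 84)
    add_case(pid, Drug.ETANERCEPT, [Flag.NEW_DMARD_ADDED])

    pid = "eta_dmard_prevalent"  # methotrexate already in use pre-index
    adherent_supply(pid, Drug.ETANERCEPT)
    for d in range(-100, 341, 28):
        fill(pid, Drug.METHOTREXATE, d, 28, 2.5, 84)
    add_case(pid, Drug.ETANERCEPT, [])

    pid = "hcq_dmard_episode"  # DMARD episode: own index-day fill not "new"
    adherent_supply(pid, Drug.HYDROXYCHLOROQUINE)
    for d in range(-364, 341, 28):
        fill(pid, Drug.METHOTREXATE, d, 28, 2.5, 84)
    add_case(pid, Drug.HYDROXYCHLOROQUINE, [], EpisodeClass.DMARD)

    # --- rituximab: adherence and escalation not applicable -----------------
    pid = "rtx_bare"
    for d in (0, 14):
        infuse(pid, Drug.RITUXIMAB, d, 1000.0)
    add_case(pid, Drug.RITUXIMAB, [])

    # --- etanercept/adalimumab regimen escalation ---------------------------
    pid = "eta_escalated"  # 100 mg/week from day 112
    adherent_supply(pid, Drug.ETANERCEPT, escalate_from=112)
    add_case(pid, Drug.ETANERCEPT, [Flag.BIOLOGIC_DOSE_ESCALATION])

    pid = "ada_escalated"  # 40 mg/week from day 112
    adherent_supply(pid, Drug.ADALIMUMAB, escalate_from=112)
    add_case(pid, Drug.ADALIMUMAB, [Flag.BIOLOGIC_DOSE_ESCALATION])

    pid = "eta_standard"
    adherent_supply(pid, Drug.ETANERCEPT)
    add_case(pid, Drug.ETANERCEPT, [])

    # --- overlapping failures recorded jointly ------------------------------
    pid = "multi_gc_dmard"
    adherent_supply(pid, Drug.ETANERCEPT)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 180)
    fill(pid, Drug.ORAL_GLUCOCORTICOID, -100, 30, 5.0, 240, anchor=outcome)
    for d in (120, 148, 176):
        fill(pid, Drug.METHOTREXATE, d, 28, 2.5, 84)
    add_case(pid, Drug.ETANERCEPT, [Flag.GC_DOSE_INCREASE, Flag.NEW_DMARD_ADDED])

    truth = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "expected_flags": "|".join(sorted(f.value for f in flags)),
                "expected_algorithm_effective": not flags,
            }
            for pid, flags in expected.items()
        ]
    )
    return SyntheticCohort(
        fills=fills,
        infusions=infusions,
        procedures=procedures,
        visits=visits,
        episodes=episodes,
        truth=truth,
    )


def calibrate_misclassification(
    config: SimulationConfig,
    target_se: float,
    target_sp: float,
    tol: float = 0.01,
) -> SimulationConfig:
    """Rescale the component failure probabilities so the config-implied
    Se/Sp match the targets.

    Sensitivity depends only on responder probabilities (monotone
    decreasing in them) and specificity only on non-responder ones
    (monotone increasing), so each is solved by bisection on a common
    multiplier, capping individual probabilities at 0.995.  Raises when a
    target is unattainable under that cap to within `tol`.
    """
    for name, t in (("target_se", target_se), ("target_sp", target_sp)):
        if not 0.0 < t <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")

    def scaled(probs: dict[str, float], m: float) -> dict[str, float]:
        return {c: min(p * m, 0.995) for c, p in probs.items()}

    def solve(metric: str, target: float) -> float:
        def value(m: float) -> float:
            if metric == "se":
                cfg = replace(
                    config, responder_failure_probs=scaled(config.responder_failure_probs, m)
                )
                return implied_performance(cfg)[0]
            cfg = replace(
                config,
                nonresponder_failure_probs=scaled(config.nonresponder_failure_probs, m),
            )
            return implied_performance(cfg)[1]

        lo, hi = 0.0, 1.0
        # grow hi until the target is bracketed or the cap saturates
        for _ in range(60):
            v = value(hi)
            reached = v <= target if metric == "se" else v >= target
            if reached:
                break
            hi *= 2.0
            if hi > 1e6:
                break
        v_hi = value(hi)
        attainable = v_hi <= target + tol if metric == "se" else v_hi >= target - tol
        if not attainable:
            raise ValueError(
                f"target {metric}={target} infeasible: best attainable {v_hi:.4f}"
            )
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            v = value(mid)
            if (v > target) == (metric == "se"):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    m_se = solve("se", target_se)
    m_sp = solve("sp", target_sp)
    calibrated = replace(
        config,
        responder_failure_probs=scaled(config.responder_failure_probs, m_se),
        nonresponder_failure_probs=scaled(config.nonresponder_failure_probs, m_sp),
    )
    se, sp = implied_performance(calibrated)
    if abs(se - target_se) > tol or abs(sp - target_sp) > tol:
        raise ValueError(
            f"calibration did not converge: implied Se={se:.4f}, Sp={sp:.4f}"
        )
    return calibrated
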