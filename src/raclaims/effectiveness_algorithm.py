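"""The claims-based effectiveness classifier.

An episode is classified *effective* when every condition holds over the
year between the index date and the outcome visit:

* high adherence to the index drug (MPR >= 80% or the expected number of
  infusions; see :mod:`raclaims.adherence`),
* no initiation of a different biologic agent,
* no addition of a nonbiologic DMARD the patient was not already taking in
  the 6 months before the index date,
* no escalation of the biologic dose (drug-specific rules below),
* glucocorticoid injections on at most one unique calendar day from
  index + 90 days through the outcome visit,
* no oral glucocorticoid initiation (> 30 days supplied after index + 90
  days, for patients GC-naive at index) or dose increase (cumulative
  prednisone-equivalent mg in the 6 months before the outcome visit more
  than 120% of the 6 months before the index date, for prevalent users).

Failing conditions are recorded as flags; the flags are not mutually
exclusive, and an episode is effective exactly when no flag fires.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from datetime import timedelta
from typing import Sequence

import numpy as np

from .adherence import expected_infusion_count, is_highly_adherent
from .data_model import (
    BIOLOGICS,
    DMARDS,
    AlgorithmResult,
    Drug,
    Flag,
    InfusionEvent,
    PharmacyFill,
    ProcedureEvent,
    TreatmentEpisode,
)
from .episode_builder import LOOKBACK_DAYS, find_initiations


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds of the effectiveness rule, in one place.

    The etanercept/adalimumab escalation thresholds translate the prohibited
    regimens (etanercept 50 mg twice weekly; adalimumab 40 mg weekly) into
    mean weekly dose bounds that claims can measure: dispensed strength x
    quantity spread over days supply.  Standard dosing is etanercept 50 mg
    weekly and adalimumab 40 mg every other week, so the bounds sit midway
    between the standard and escalated regimens.
    """

    mpr_threshold: float = 0.80
    lookback_days: int = LOOKBACK_DAYS
    injection_window_offset_days: int = 90
    max_injection_days: int = 1
    gc_naive_max_days: int = 30
    gc_dose_ratio: float = 1.2
    gc_window_days: int = 183
    etanercept_weekly_mg_limit: float = 75.0
    adalimumab_weekly_mg_limit: float = 30.0
    escalation_window_days: int = 60
    infusion_count_ratio: float = 1.2
    dose_round_mg: int = 100
    truncate_mpr_at_window_end: bool = False


DEFAULT_CONFIG = AlgorithmConfig()


def _patient_fills(fills: Sequence[PharmacyFill], pid: str) -> list[PharmacyFill]:
    return [f for f in fills if f.patient_id == pid]


def check_biologic_switch_or_add(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> bool:
    """True when a biologic other than the index drug is newly initiated in
    (index, outcome].  Continuation of a biologic already in use before the
    index date is not a switch."""
    pid = episode.patient_id
    pfills = _patient_fills(fills, pid)
    pinfusions = [i for i in infusions if i.patient_id == pid]
    for drug in BIOLOGICS - {episode.index_drug}:
        for ipid, d in find_initiations(pfills, pinfusions, drug, config.lookback_days):
            if episode.index_date < d <= episode.outcome_date:
                return True
    return False


def check_new_dmard(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> bool:
    """True when a nonbiologic DMARD the patient was not taking in the
    6 months up to and including the index date is filled in (index, outcome].

    The pre-index window includes the index date itself, so a DMARD course
    whose first fill lands on the index date (e.g. the index drug of a DMARD
    episode) does not count as an addition.
    """
    pid = episode.patient_id
    lookback_start = episode.index_date - timedelta(days=config.lookback_days)
    already_taking = set()
    added = set()
    for f in fills:
        if f.patient_id != pid or f.drug not in DMARDS:
            continue
        if lookback_start <= f.fill_date <= episode.index_date:
            already_taking.add(f.drug)
        elif episode.index_date < f.fill_date <= episode.outcome_date:
            added.add(f.drug)
    return bool(added - already_taking)


def _round_up(dose_mg: float, step: int) -> float:
    return math.ceil(dose_mg / step) * step


def _daily_dose_series(
    episode: TreatmentEpisode, fills: Sequence[PharmacyFill]
) -> np.ndarray:
    """Daily dose (mg/day) of the index drug over [index, outcome]."""
    n_days = (episode.outcome_date - episode.index_date).days + 1
    daily = np.zeros(n_days)
    for f in fills:
        if f.patient_id != episode.patient_id or f.drug != episode.index_drug:
            continue
        if not episode.index_date <= f.fill_date <= episode.outcome_date:
            continue
        if f.days_supply <= 0:
            continue
        start = (f.fill_date - episode.index_date).days
        stop = min(start + f.days_supply, n_days)
        daily[start:stop] += f.daily_dose_mg
    return daily


def check_dose_escalation(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> bool:
    """Drug-specific prohibition on increasing the biologic dose.

    etanercept / adalimumab
        Flag when the mean weekly dose over any sliding 60-day window of the
        episode exceeds the configured limit.
    infliximab
        Flag when first and last administered doses, each rounded up to the
        nearest 100 mg, differ by >= 100 mg, or when the number of infusions
        exceeds 120% of the count expected from a 0/2/6-week load plus
        8-weekly maintenance.
    abatacept
        Flag when the last dose exceeds the first by >= 100 mg.
    rituximab
        Never flagged (criterion not applicable).
    """
    drug = episode.index_drug
    if drug not in BIOLOGICS:
        raise ValueError(f"dose-escalation rule applies to biologics, not {drug.value}")
    if drug == Drug.RITUXIMAB:
        return False
    if drug in (Drug.ETANERCEPT, Drug.ADALIMUMAB):
        limit = (
            config.etanercept_weekly_mg_limit
            if drug == Drug.ETANERCEPT
            else config.adalimumab_weekly_mg_limit
        )
        daily = _daily_dose_series(episode, fills)
        w = config.escalation_window_days
        if len(daily) < w:
            return bool(daily.mean() * 7.0 > limit) if len(daily) else False
        kernel = np.ones(w) / w
        window_means = np.convolve(daily, kernel, mode="valid")
        return bool(np.any(window_means * 7.0 > limit))
    doses = sorted(
        (
            (i.date, i.dose_mg)
            for i in infusions
            if i.patient_id == episode.patient_id
            and i.drug == drug
            and episode.index_date <= i.date <= episode.outcome_date
        ),
    )
    if not doses:
        return False
    first, last = doses[0][1], doses[-1][1]
    if drug == Drug.INFLIXIMAB:
        if _round_up(last, config.dose_round_mg) - _round_up(
            first, config.dose_round_mg
        ) >= config.dose_round_mg:
            return True
        expected = expected_infusion_count(
            drug, episode.index_date, episode.outcome_date, schedule="escalation"
        )
        return len(doses) > config.infusion_count_ratio * expected
    # abatacept: plain difference, no rounding
    return last - first >= config.dose_round_mg


def check_injections(
    episode: TreatmentEpisode,
    procedures: Sequence[ProcedureEvent],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> bool:
    """True when glucocorticoid injections occur on more than one unique
    calendar day in [index + 90 days, outcome], inclusive."""
    window_start = episode.index_date + timedelta(
        days=config.injection_window_offset_days
    )
    days = {
        p.date
        for p in procedures
        if p.patient_id == episode.patient_id
        and window_start <= p.date <= episode.outcome_date
    }
    return len(days) > config.max_injection_days


def check_oral_glucocorticoid(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> Flag | None:
    """Oral glucocorticoid initiation / dose-increase prohibition.

    Patients with no oral GC fill in the 6 months before the index date are
    GC-naive: they fail (``GC_INITIATION``) when more than 30 days of oral
    glucocorticoids are supplied between index + 90 days and the outcome
    visit.  Prevalent users fail (``GC_DOSE_INCREASE``) when the cumulative
    prednisone-equivalent dose in the 6 months before the outcome visit
    exceeds 120% of the cumulative dose in the 6 months before the index
    date; exactly 120% passes.  A prevalent user with zero cumulative
    pre-index milligrams is treated as naive (degenerate denominator).
    """
    pid = episode.patient_id
    gc = [
        f
        for f in fills
        if f.patient_id == pid and f.drug == Drug.ORAL_GLUCOCORTICOID
    ]
    w = config.gc_window_days
    pre_index = [
        f
        for f in gc
        if episode.index_date - timedelta(days=w) <= f.fill_date < episode.index_date
    ]
    pre_index_mg = sum(f.total_mg for f in pre_index)
    if not pre_index or pre_index_mg == 0:
        window_start = episode.index_date + timedelta(
            days=config.injection_window_offset_days
        )
        days = sum(
            f.days_supply
            for f in gc
            if window_start <= f.fill_date <= episode.outcome_date
        )
        return Flag.GC_INITIATION if days > config.gc_naive_max_days else None
    pre_outcome_mg = sum(
        f.total_mg
        for f in gc
        if episode.outcome_date - timedelta(days=w)
        <= f.fill_date
        < episode.outcome_date
    )
    if pre_outcome_mg > config.gc_dose_ratio * pre_index_mg:
        return Flag.GC_DOSE_INCREASE
    return None


def classify_effectiveness(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    procedures: Sequence[ProcedureEvent],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> AlgorithmResult:
    """Run every component of the effectiveness rule on one episode.

    All violated conditions are recorded; the episode is effective only if
    every condition passes.
    """
    flags: set[Flag] = set()
    adherence = is_highly_adherent(
        episode,
        fills,
        infusions,
        mpr_threshold=config.mpr_threshold,
        truncate_at_window_end=config.truncate_mpr_at_window_end,
    )
    if not adherence.adherent:
        flags.add(Flag.NONADHERENT_OR_SWITCH)
    if check_biologic_switch_or_add(episode, fills, infusions, config):
        flags.add(Flag.BIOLOGIC_SWITCH_OR_ADD)
    if check_new_dmard(episode, fills, config):
        flags.add(Flag.NEW_DMARD_ADDED)
    if episode.index_drug in BIOLOGICS and check_dose_escalation(
        episode, fills, infusions, config
    ):
        flags.add(Flag.BIOLOGIC_DOSE_ESCALATION)
    if check_injections(episode, procedures, config):
        flags.add(Flag.EXCESS_JOINT_INJECTIONS)
    gc_flag = check_oral_glucocorticoid(episode, fills, config)
    if gc_flag is not None:
        flags.add(gc_flag)
    return AlgorithmResult(
        episode=episode, effective=not flags, flags=frozenset(flags)
    )


def classify_cohort(
    episodes: Sequence[TreatmentEpisode],
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    procedures: Sequence[ProcedureEvent],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> list[AlgorithmResult]:
    """Classify every episode, grouping streams per patient for speed."""
    fills_by: dict[str, list[PharmacyFill]] = defaultdict(list)
    for f in fills:
        fills_by[f.patient_id].append(f)
    inf_by: dict[str, list[InfusionEvent]] = defaultdict(list)
    for i in infusions:
        inf_by[i.patient_id].append(i)
    proc_by: dict[str, list[ProcedureEvent]] = defaultdict(list)
    for p in procedures:
        proc_by[p.patient_id].append(p)
    return [
        classify_effectiveness(
            ep,
            fills_by.get(ep.patient_id, []),
            inf_by.get(ep.patient_id, []),
            proc_by.get(ep.patient_id, []),
            config,
        )
        for ep in episodes
    ]
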