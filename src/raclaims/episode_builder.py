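"""Construct eligible new-user treatment episodes from claims and visits.

A treatment episode starts on the index date: the first fill or infusion of a
drug with no use of that same drug in the preceding 6 months (183 days).
Eligibility additionally requires

* an "active user" oral fill of any duration 6-12 months before the index
  date (evidence the patient obtains medications through the system),
* optionally a registry visit within 31 days of the index date (baseline),
* a registry outcome visit 10-14 calendar months after the index date
  (nearest the 1-year anniversary when several qualify); episodes with no
  such visit carry no clinical gold standard and are dropped.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from datetime import date, timedelta
from typing import Iterable, Sequence

from dateutil.relativedelta import relativedelta

from .data_model import (
    BIOLOGICS,
    Drug,
    EpisodeClass,
    InfusionEvent,
    PharmacyFill,
    RegistryVisit,
    Route,
    TreatmentEpisode,
)

LOOKBACK_DAYS = 183
BASELINE_WINDOW_DAYS = 31
ACTIVE_USER_WINDOW = (365, 183)  # days before index, [far, near]
OUTCOME_WINDOW_MONTHS = (10, 14)


def _drug_event_dates(
    fills: Iterable[PharmacyFill], infusions: Iterable[InfusionEvent], drug: Drug
) -> dict[str, list[date]]:
    """Per-patient sorted dates of any use (fill or infusion) of `drug`."""
    by_patient: dict[str, list[date]] = defaultdict(list)
    for f in fills:
        if f.drug == drug:
            by_patient[f.patient_id].append(f.fill_date)
    for inf in infusions:
        if inf.drug == drug:
            by_patient[inf.patient_id].append(inf.date)
    for dates in by_patient.values():
        dates.sort()
    return by_patient


def find_initiations(
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    drug: Drug,
    lookback_days: int = LOOKBACK_DAYS,
) -> list[tuple[str, date]]:
    """Find new initiations of `drug`: use with no same-drug event in the
    open interval (index - lookback_days, index).

    A patient can initiate the same drug more than once if the uses are
    separated by at least `lookback_days`.
    """
    if not isinstance(drug, Drug):
        raise ValueError(f"unknown drug {drug!r}")
    initiations = []
    for pid, dates in _drug_event_dates(fills, infusions, drug).items():
        prev: date | None = None
        for d in dates:
            if prev is None or (d - prev).days >= lookback_days:
                initiations.append((pid, d))
            prev = d
    initiations.sort(key=lambda t: (t[0], t[1]))
    return initiations


def _nearest_visit(
    visits: Sequence[RegistryVisit], target: date, lo: date, hi: date
) -> RegistryVisit | None:
    """Visit in [lo, hi] nearest to `target`; earlier wins ties."""
    best = None
    best_key = None
    for v in visits:
        if lo <= v.date <= hi:
            key = (abs((v.date - target).days), v.date)
            if best_key is None or key < best_key:
                best, best_key = v, key
    return best


def build_episodes(
    initiations: Sequence[tuple[str, date]],
    fills: Sequence[PharmacyFill],
    visits: Sequence[RegistryVisit],
    index_drug: Drug,
    episode_class: EpisodeClass,
    require_baseline: bool = True,
    baseline_window_days: int = BASELINE_WINDOW_DAYS,
) -> tuple[list[TreatmentEpisode], Counter]:
    """Apply the eligibility predicates to candidate initiations.

    Returns the eligible episodes plus a tally of exclusion reasons
    (``no_baseline_visit``, ``not_active_user``, ``no_outcome_visit``).
    """
    visits_by_patient: dict[str, list[RegistryVisit]] = defaultdict(list)
    for v in visits:
        visits_by_patient[v.patient_id].append(v)
    oral_fills_by_patient: dict[str, list[date]] = defaultdict(list)
    for f in fills:
        if f.route == Route.ORAL:
            oral_fills_by_patient[f.patient_id].append(f.fill_date)

    episodes: list[TreatmentEpisode] = []
    exclusions: Counter = Counter()
    for pid, index_date in initiations:
        pvisits = visits_by_patient.get(pid, [])

        baseline = _nearest_visit(
            pvisits,
            index_date,
            index_date - timedelta(days=baseline_window_days),
            index_date + timedelta(days=baseline_window_days),
        )
        if require_baseline and baseline is None:
            exclusions["no_baseline_visit"] += 1
            continue

        far, near = ACTIVE_USER_WINDOW
        lo, hi = index_date - timedelta(days=far), index_date - timedelta(days=near)
        if not any(lo <= d <= hi for d in oral_fills_by_patient.get(pid, [])):
            exclusions["not_active_user"] += 1
            continue

        outcome = _nearest_visit(
            pvisits,
            index_date + relativedelta(months=12),
            index_date + relativedelta(months=OUTCOME_WINDOW_MONTHS[0]),
            index_date + relativedelta(months=OUTCOME_WINDOW_MONTHS[1]),
        )
        if outcome is None:
            exclusions["no_outcome_visit"] += 1
            continue

        episodes.append(
            TreatmentEpisode(
                patient_id=pid,
                index_drug=index_drug,
                index_date=index_date,
                episode_class=episode_class,
                outcome_visit=outcome,
                baseline_visit=baseline,
            )
        )
    return episodes, exclusions


def find_biologic_episodes(
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    visits: Sequence[RegistryVisit],
    require_baseline: bool = True,
) -> tuple[list[TreatmentEpisode], Counter]:
    """New-user episodes for every biologic agent."""
    episodes: list[TreatmentEpisode] = []
    exclusions: Counter = Counter()
    for drug in sorted(BIOLOGICS, key=lambda d: d.value):
        inits = find_initiations(fills, infusions, drug)
        eps, excl = build_episodes(
            inits, fills, visits, drug, EpisodeClass.BIOLOGIC, require_baseline
        )
        episodes.extend(eps)
        exclusions.update(excl)
    episodes.sort(key=lambda e: (e.patient_id, e.index_date, e.index_drug.value))
    return episodes, exclusions


def find_dmard_episodes(
    fills: Sequence[PharmacyFill],
    visits: Sequence[RegistryVisit],
    require_baseline: bool = True,
) -> tuple[list[TreatmentEpisode], Counter]:
    """New-user episodes of LEF/SSZ/HCQ among prior-or-current MTX users.

    Methotrexate anchors RA therapy and is usually continued regardless of
    response, so MTX starts themselves never define an episode; instead any
    MTX fill on or before the candidate index date qualifies the patient.
    """
    mtx_first_fill: dict[str, date] = {}
    for f in fills:
        if f.drug == Drug.METHOTREXATE:
            cur = mtx_first_fill.get(f.patient_id)
            if cur is None or f.fill_date < cur:
                mtx_first_fill[f.patient_id] = f.fill_date

    episodes: list[TreatmentEpisode] = []
    exclusions: Counter = Counter()
    for drug in (Drug.LEFLUNOMIDE, Drug.SULFASALAZINE, Drug.HYDROXYCHLOROQUINE):
        inits = [
            (pid, d)
            for pid, d in find_initiations(fills, [], drug)
            if pid in mtx_first_fill and mtx_first_fill[pid] <= d
        ]
        eps, excl = build_episodes(
            inits, fills, visits, drug, EpisodeClass.DMARD, require_baseline
        )
        episodes.extend(eps)
        exclusions.update(excl)
    episodes.sort(key=lambda e: (e.patient_id, e.index_date, e.index_drug.value))
    return episodes, exclusions


def one_episode_per_patient(
    episodes: Sequence[TreatmentEpisode],
) -> list[TreatmentEpisode]:
    """Keep one episode per patient: earliest index date, then first drug
    alphabetically on ties (conservative within-person de-duplication)."""
    chosen: dict[str, TreatmentEpisode] = {}
    for ep in episodes:
        cur = chosen.get(ep.patient_id)
        if cur is None or (ep.index_date, ep.index_drug.value) < (
            cur.index_date,
            cur.index_drug.value,
        ):
            chosen[ep.patient_id] = ep
    return sorted(chosen.values(), key=lambda e: (e.patient_id, e.index_date))
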