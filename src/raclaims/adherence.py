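"""High-adherence determination for the index drug of a treatment episode.

For drugs dispensed through the pharmacy (etanercept, adalimumab and all
oral medications) adherence is a medication possession ratio (MPR): total
days supplied over the observation window divided by window length, capped
at 1.0; high adherence is MPR >= 0.80.

For infused biologics adherence is counted in administrations against the
labelled schedule:

* infliximab — loading doses at weeks 0, 2, 6 and 14, then every 8 weeks;
  the observed count must reach the expected count;
* abatacept — once monthly (every 30 days); one missed infusion is allowed;
* rituximab — dosed as infrequent cycles, so the criterion does not apply
  and every episode counts as adherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

from .data_model import (
    Drug,
    InfusionEvent,
    MPR_DRUGS,
    PharmacyFill,
    TreatmentEpisode,
)

MPR_THRESHOLD = 0.80

#: Infusion-day offsets (days from index) defining each schedule.  The
#: infliximab adherence schedule carries the week-14 loading dose; the
#: dose-escalation expectation (see effectiveness_algorithm) loads at
#: weeks 0/2/6 only.
INFLIXIMAB_LOAD_DAYS = (0, 14, 42, 98)
INFLIXIMAB_ESCALATION_LOAD_DAYS = (0, 14, 42)
INFLIXIMAB_MAINTENANCE_INTERVAL = 56
ABATACEPT_INTERVAL = 30


@dataclass(frozen=True)
class AdherenceResult:
    episode: TreatmentEpisode
    adherent: bool
    mpr: float | None = None
    expected_infusions: int | None = None
    observed_infusions: int | None = None

    def __post_init__(self) -> None:
        if self.mpr is not None and not 0.0 <= self.mpr <= 1.0:
            raise ValueError("mpr must be in [0, 1]")


def compute_mpr(
    fills: Sequence[PharmacyFill],
    start: date,
    end: date,
    truncate_at_window_end: bool = False,
) -> float:
    """Medication possession ratio over [start, end).

    Sums days_supply of fills dispensed in [start, end) and divides by the
    window length, capping at 1.0.  With ``truncate_at_window_end`` the
    contribution of each fill is clipped to the days remaining in the
    window (the stricter numerator variant); by default supply overrunning
    the window still counts and only the cap bounds the ratio.
    """
    window = (end - start).days
    if window <= 0:
        raise ValueError("end must be after start")
    total = 0
    for f in fills:
        if start <= f.fill_date < end:
            supply = f.days_supply
            if truncate_at_window_end:
                supply = min(supply, (end - f.fill_date).days)
            total += supply
    return min(total / window, 1.0)


def scheduled_infusion_days(drug: Drug, schedule: str = "adherence") -> tuple:
    if drug == Drug.INFLIXIMAB:
        load = (
            INFLIXIMAB_LOAD_DAYS
            if schedule == "adherence"
            else INFLIXIMAB_ESCALATION_LOAD_DAYS
        )
        return load, INFLIXIMAB_MAINTENANCE_INTERVAL
    if drug == Drug.ABATACEPT:
        return (0,), ABATACEPT_INTERVAL
    raise ValueError(f"no infusion schedule defined for {drug.value}")


def expected_infusion_count(
    drug: Drug, start: date, end: date, schedule: str = "adherence"
) -> int:
    """Number of scheduled infusion days falling within [start, end].

    Day 0 (the index infusion) always counts, so a zero-length window
    expects exactly one dose.
    """
    if end < start:
        raise ValueError("end must be >= start")
    horizon = (end - start).days
    load, interval = scheduled_infusion_days(drug, schedule)
    count = sum(1 for d in load if d <= horizon)
    if load[-1] <= horizon:
        count += (horizon - load[-1]) // interval
    return count


def is_highly_adherent(
    episode: TreatmentEpisode,
    fills: Sequence[PharmacyFill],
    infusions: Sequence[InfusionEvent],
    mpr_threshold: float = MPR_THRESHOLD,
    truncate_at_window_end: bool = False,
) -> AdherenceResult:
    """Evaluate the high-adherence requirement for an episode's index drug."""
    drug = episode.index_drug
    start, end = episode.index_date, episode.outcome_date
    if drug == Drug.RITUXIMAB:
        return AdherenceResult(episode=episode, adherent=True)
    if drug in MPR_DRUGS:
        own = [
            f for f in fills if f.patient_id == episode.patient_id and f.drug == drug
        ]
        mpr = compute_mpr(own, start, end, truncate_at_window_end)
        return AdherenceResult(episode=episode, adherent=mpr >= mpr_threshold, mpr=mpr)
    # infused biologics with a defined schedule
    observed = sum(
        1
        for inf in infusions
        if inf.patient_id == episode.patient_id
        and inf.drug == drug
        and start <= inf.date <= end
    )
    expected = expected_infusion_count(drug, start, end)
    allowance = 1 if drug == Drug.ABATACEPT else 0
    return AdherenceResult(
        episode=episode,
        adherent=observed >= expected - allowance,
        expected_infusions=expected,
        observed_infusions=observed,
    )
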