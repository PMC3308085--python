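from datetime import date, timedelta

import pytest
from hypothesis import settings as hypothesis_settings

from raclaims.data_model import (
    Drug,
    EpisodeClass,
    PharmacyFill,
    RegistryVisit,
    Route,
    TreatmentEpisode,
)
from raclaims.synthetic_data import SimulationConfig, generate_cohort, generate_paper_fixture

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

INDEX = date(2006, 1, 5)
OUTCOME = INDEX + timedelta(days=360)


def make_visit(pid="p1", when=OUTCOME, tjc=4, sjc=3, esr=20.0, pg=40.0, phys=35.0):
    return RegistryVisit(pid, when, tjc, sjc, esr, pg, phys)


def make_episode(
    pid="p1",
    drug=Drug.ETANERCEPT,
    index=INDEX,
    outcome_visit=None,
    baseline_visit=None,
    episode_class=EpisodeClass.BIOLOGIC,
):
    if outcome_visit is None:
        outcome_visit = make_visit(pid, index + timedelta(days=360))
    return TreatmentEpisode(
        patient_id=pid,
        index_drug=drug,
        index_date=index,
        episode_class=episode_class,
        outcome_visit=outcome_visit,
        baseline_visit=baseline_visit,
    )


def make_fill(pid="p1", drug=Drug.ETANERCEPT, day=0, days_supply=28, strength=50.0,
              quantity=4, route=Route.SUBCUTANEOUS, anchor=INDEX):
    return PharmacyFill(
        patient_id=pid,
        drug=drug,
        fill_date=anchor + timedelta(days=day),
        days_supply=days_supply,
        strength_mg=strength,
        quantity=quantity,
        route=route,
    )


@pytest.fixture(scope="session")
def boundary_fixture():
    """The deterministic hand-audited boundary cohort."""
    return generate_paper_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(n_patients=400, seed=7))
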