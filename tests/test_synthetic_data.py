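from collections import defaultdict

import pytest

from raclaims.adherence import is_highly_adherent
from raclaims.effectiveness_algorithm import classify_cohort
from raclaims.gold_standard import evaluate_gold_standard
from raclaims.synthetic_data import (
    SimulationConfig,
    calibrate_misclassification,
    generate_cohort,
    implied_performance,
    visit_for_das28,
)
from raclaims.validation import confusion_matrix, performance_metrics


def gold_results(cohort):
    fills_by, inf_by = defaultdict(list), defaultdict(list)
    for f in cohort.fills:
        fills_by[f.patient_id].append(f)
    for i in cohort.infusions:
        inf_by[i.patient_id].append(i)
    out = []
    for ep in cohort.episodes:
        adherence = is_highly_adherent(ep, fills_by[ep.patient_id], inf_by[ep.patient_id])
        out.append(evaluate_gold_standard(ep, adherence))
    return out


class TestVisitConstruction:
    @pytest.mark.parametrize("target", [0.5, 1.5, 3.2, 4.9, 6.5, 8.2])
    def test_visit_hits_das28_target_exactly(self, target):
        import numpy as np
        from datetime import date
        from raclaims.gold_standard import das28_of_visit

        rng = np.random.default_rng(1)
        v = visit_for_das28("x", date(2006, 1, 1), target, rng)
        assert das28_of_visit(v) == pytest.approx(target, abs=1e-9)

    def test_out_of_range_target_rejected(self):
        import numpy as np
        from datetime import date

        with pytest.raises(ValueError):
            visit_for_das28("x", date(2006, 1, 1), 9.5, np.random.default_rng(0))


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        from raclaims.cli import write_cohort

        for sub in ("a", "b"):
            write_cohort(generate_cohort(SimulationConfig(n_patients=60, seed=11)),
                         tmp_path / sub)
        for name in ("fills.csv", "infusions.csv", "procedures.csv", "visits.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        c1 = generate_cohort(SimulationConfig(n_patients=60, seed=1))
        c2 = generate_cohort(SimulationConfig(n_patients=60, seed=2))
        assert c1.fills != c2.fills

    def test_noiseless_limit_all_effective(self):
        zero = {c: 0.0 for c in ("nonadherent", "switch", "new_dmard", "escalation", "injections", "gc")}
        cfg = SimulationConfig(
            n_patients=50,
            true_responder_prevalence=1.0,
            responder_failure_probs=zero,
            seed=5,
        )
        cohort = generate_cohort(cfg)
        algo = classify_cohort(cohort.episodes, cohort.fills,
                               cohort.infusions, cohort.procedures)
        gold = gold_results(cohort)
        assert all(r.effective for r in algo)
        assert all(r.effective for r in gold)

    def test_forced_failure_limit_none_effective(self):
        probs = {"nonadherent": 1.0, "switch": 0.0, "new_dmard": 1.0,
                 "escalation": 0.0, "injections": 0.0, "gc": 0.0}
        cfg = SimulationConfig(
            n_patients=50,
            true_responder_prevalence=0.0,
            nonresponder_failure_probs=probs,
            seed=5,
        )
        cohort = generate_cohort(cfg)
        algo = classify_cohort(cohort.episodes, cohort.fills, cohort.infusions,
                               cohort.procedures)
        gold = gold_results(cohort)
        assert not any(r.effective for r in algo)
        assert not any(r.effective for r in gold)

    def test_algorithm_matches_truth_table_exactly(self, small_cohort):
        """The generator's intended flags are exactly what the classifier sees."""
        results = classify_cohort(
            small_cohort.episodes,
            small_cohort.fills,
            small_cohort.infusions,
            small_cohort.procedures,
        )
        expected = dict(
            zip(small_cohort.truth.patient_id, small_cohort.truth.expected_flags)
        )
        for r in results:
            got = "|".join(sorted(f.value for f in r.flags))
            assert got == expected[r.episode.patient_id]

    def test_gold_standard_recovers_latent_responder(self, small_cohort):
        truth = dict(zip(small_cohort.truth.patient_id, small_cohort.truth.responder))
        for g in gold_results(small_cohort):
            assert g.effective == truth[g.episode.patient_id]

    def test_prevalence_converges(self):
        cfg = SimulationConfig(n_patients=5000, seed=13)
        cohort = generate_cohort(cfg)
        emp = cohort.truth.responder.mean()
        assert emp == pytest.approx(cfg.true_responder_prevalence, abs=0.02)


class TestImpliedPerformance:
    def test_zero_noise_limits(self):
        zero = {c: 0.0 for c in ("nonadherent", "switch", "new_dmard", "escalation", "injections", "gc")}
        cfg = SimulationConfig(responder_failure_probs=zero, nonresponder_failure_probs=zero)
        se, sp = implied_performance(cfg)
        assert se == 1.0 and sp == 0.0

    def test_empirical_matches_implied(self, small_cohort):
        cfg = SimulationConfig(n_patients=400, seed=7)
        se_i, sp_i = implied_performance(cfg)
        algo = classify_cohort(small_cohort.episodes, small_cohort.fills,
                               small_cohort.infusions, small_cohort.procedures)
        cm = confusion_matrix(algo, gold_results(small_cohort))
        pm = performance_metrics(cm)
        assert pm.se.point == pytest.approx(se_i, abs=0.08)
        assert pm.sp.point == pytest.approx(sp_i, abs=0.08)


class TestCalibration:
    def test_analytic_convergence(self):
        cfg = calibrate_misclassification(SimulationConfig(), 0.72, 0.91)
        se, sp = implied_performance(cfg)
        assert se == pytest.approx(0.72, abs=0.01)
        assert sp == pytest.approx(0.91, abs=0.01)

    def test_near_perfect_targets_give_near_zero_noise(self):
        cfg = calibrate_misclassification(SimulationConfig(), 1.0, 0.999, tol=0.02)
        assert all(p <= 1e-9 for p in cfg.responder_failure_probs.values())
        se, sp = implied_performance(cfg)
        assert se >= 0.999 and sp >= 0.98

    def test_midrange_targets_converge_or_report(self):
        cfg = calibrate_misclassification(SimulationConfig(), 0.5, 0.5)
        se, sp = implied_performance(cfg)
        assert (se, sp) == (pytest.approx(0.5, abs=0.01), pytest.approx(0.5, abs=0.01))

    def test_infeasible_target_reported(self):
        zero = {c: 0.0 for c in ("nonadherent", "switch", "new_dmard", "escalation", "injections", "gc")}
        cfg = SimulationConfig(nonresponder_failure_probs=zero)
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_misclassification(cfg, 0.72, 0.91)


class TestBoundaryFixture:
    def test_every_case_classifies_as_audited(self, boundary_fixture):
        fx = boundary_fixture
        results = classify_cohort(fx.episodes, fx.fills, fx.infusions, fx.procedures)
        expected = dict(zip(fx.truth.patient_id, fx.truth.expected_flags))
        assert len(results) == len(expected) >= 30
        for r in results:
            got = "|".join(sorted(f.value for f in r.flags))
            assert got == expected[r.episode.patient_id], r.episode.patient_id

    def test_mpr_boundary_cases(self, boundary_fixture):
        fx = boundary_fixture
        by_pid = {e.patient_id: e for e in fx.episodes}
        results = {
            r.episode.patient_id: r
            for r in classify_cohort(fx.episodes, fx.fills, fx.infusions, fx.procedures)
        }
        assert results["ada_mpr_080"].effective
        assert not results["ada_mpr_079"].effective
        assert results["gc_120pct"].effective
        assert not results["gc_121pct"].effective
        assert by_pid["ada_mpr_080"].index_drug.value == "adalimumab"

    def test_fixture_is_deterministic(self, boundary_fixture):
        from raclaims.synthetic_data import generate_paper_fixture

        again = generate_paper_fixture()
        assert again.fills == boundary_fixture.fills
        assert again.truth.equals(boundary_fixture.truth)
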