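"""Decision-tree cost model: unit-cost derivation, tree evaluation and
outcome tallies, all cross-checked against an explicit per-patient
enumeration of the observed cohort."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opmstage import (
    ChanceNode,
    CohortCounts,
    ConfusionTable,
    StrategyModel,
    TerminalNode,
    build_strategies,
    compare,
    derive_unit_costs,
    evaluate,
    strategy_expected_costs,
    tally_outcomes,
)
from opmstage import study


def enumerate_patients(table: ConfusionTable):
    """The cohort as explicit (pet, ref) patients, one tuple each."""
    patients = []
    patients += [(True, True)] * table.tp
    patients += [(True, False)] * table.fp
    patients += [(False, True)] * table.fn
    patients += [(False, False)] * table.tn
    return patients


def per_patient_cost(strategy_id, pet, ref, c):
    """Route one patient through a strategy's decision rules.

    Returns (cost, had_laparoscopy, had_gastrectomy) — the independent
    oracle for tree evaluation and tallies.
    """
    if strategy_id == "S1":
        return c.c_gast, False, True
    if strategy_id == "S2":
        # laparoscopy for all; ref-negatives proceed to gastrectomy
        return (c.c_lap + (0 if ref else c.c_gast), True, not ref)
    if strategy_id == "S3":
        # PET for all; PET-negatives proceed to gastrectomy
        return (c.c_pet + (0 if pet else c.c_gast), False, not pet)
    # S4: PET for all; PET-positives get arbitrating laparoscopy;
    # gastrectomy unless the arbiter (or nothing, for PET-negatives) says OPM
    if pet:
        return (c.c_pet + c.c_lap + (0 if ref else c.c_gast), True, not ref)
    return c.c_pet + c.c_gast, False, True


class TestDeriveUnitCosts:
    def test_back_derivation_matches_linear_system_oracle(self, study_counts):
        """Solve the 3x3 linear system with numpy as the independent oracle."""
        n, pet_neg, ref_neg = 109, 92, 93
        # unknowns (c_gast, c_pet, c_lap)
        A = np.array([
            [1.0, 0.0, 0.0],
            [pet_neg / n, 1.0, 0.0],
            [ref_neg / n, 0.0, 1.0],
        ])
        b = np.array([study.S1_TOTAL, study.S1_TOTAL + study.S3_DELTA,
                      study.S1_TOTAL + study.S2_DELTA])
        c_gast, c_pet, c_lap = np.linalg.solve(A, b)
        got = derive_unit_costs(study.S1_TOTAL, study.S3_DELTA, study.S2_DELTA, study_counts)
        assert got.c_gast == pytest.approx(c_gast, abs=1e-9)
        assert got.c_pet == pytest.approx(c_pet, abs=1e-9)
        assert got.c_lap == pytest.approx(c_lap, abs=1e-9)
        # frozen values from the pre-build solve
        assert got.c_pet == pytest.approx(761.927522935779, abs=1e-9)
        assert got.c_lap == pytest.approx(1653.608256880735, abs=1e-9)

    def test_half_negative_cohort_forces_pet_cost(self):
        # n = 2, one PET-negative: gastrectomy fraction 1/2, so
        # 60 = c_pet + 0.5 * 100 forces c_pet = 10
        counts = CohortCounts.from_table(ConfusionTable(1, 0, 1, 0))
        got = derive_unit_costs(100.0, -40.0, -50.0, counts)
        assert got.c_pet == pytest.approx(10.0)

    def test_free_pet_strategy_is_inconsistent(self, study_counts):
        # s3_delta = -s1 would require a negative PET cost
        with pytest.raises(ValueError, match="inconsistent aggregates"):
            derive_unit_costs(study.S1_TOTAL, -study.S1_TOTAL, study.S2_DELTA, study_counts)


class TestEvaluate:
    def test_single_terminal(self):
        m = StrategyModel("S1", TerminalNode(9550.50, {"gastrectomy"}))
        assert evaluate(m) == pytest.approx(9550.50)

    def test_two_branch_lottery(self):
        m = StrategyModel("S1", ChanceNode((
            (0.5, TerminalNode(0.0, {"gastrectomy"})),
            (0.5, TerminalNode(10.0, {"gastrectomy"})),
        )))
        assert evaluate(m) == pytest.approx(5.0)

    def test_s1_expected_cost_is_gastrectomy_cost(self, study_counts, derived_costs):
        s1 = build_strategies(study_counts, derived_costs)["S1"]
        assert evaluate(s1) == pytest.approx(9550.50, abs=0.005)

    def test_path_probabilities_sum_to_one(self, study_counts, derived_costs):
        for m in build_strategies(study_counts, derived_costs).values():
            assert sum(p for p, _ in m.paths()) == pytest.approx(1.0, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("strategy_id", ["S1", "S2", "S3", "S4"])
    def test_tree_equals_per_patient_enumeration(self, strategy_id, study_counts, derived_costs):
        """Expected tree cost and tallies must match the mean over an
        explicit routing of the 109 observed patients (to 1e-9)."""
        model = build_strategies(study_counts, derived_costs)[strategy_id]
        patients = enumerate_patients(study_counts.table)
        routed = [per_patient_cost(strategy_id, pet, ref, derived_costs)
                  for pet, ref in patients]
        mean_cost = sum(r[0] for r in routed) / len(routed)
        assert evaluate(model) == pytest.approx(mean_cost, abs=1e-9)

        out = tally_outcomes(model, study_counts)
        assert out.n_laparoscopy == pytest.approx(sum(r[1] for r in routed), abs=1e-9)
        assert out.n_gastrectomy == pytest.approx(sum(r[2] for r in routed), abs=1e-9)
        prevented = sum(1 for (pet, ref), r in zip(patients, routed) if ref and not r[2])
        missed = sum(1 for (pet, ref), r in zip(patients, routed) if ref and r[2])
        assert out.n_futile_gastrectomy_prevented == pytest.approx(prevented, abs=1e-9)
        assert out.n_missed_opm == pytest.approx(missed, abs=1e-9)


class TestTallies:
    def test_s4_operational_counts(self, study_counts, derived_costs):
        s4 = build_strategies(study_counts, derived_costs)["S4"]
        out = tally_outcomes(s4, study_counts)
        assert out.n_laparoscopy == pytest.approx(17.0, abs=1e-9)
        assert study_counts.n - out.n_laparoscopy == pytest.approx(92.0, abs=1e-9)
        assert out.n_futile_gastrectomy_prevented == pytest.approx(12.0, abs=1e-9)
        assert out.n_gastrectomy == pytest.approx(97.0, abs=1e-9)  # 92 PET-neg + 5 FP
        assert out.n_missed_opm == pytest.approx(4.0, abs=1e-9)

    def test_s2_spares_all_reference_positives(self, study_counts, derived_costs):
        s2 = build_strategies(study_counts, derived_costs)["S2"]
        out = tally_outcomes(s2, study_counts)
        assert out.n_futile_gastrectomy_prevented == pytest.approx(16.0, abs=1e-9)
        assert out.n_missed_opm == pytest.approx(0.0, abs=1e-9)


class TestCompare:
    def test_s2_minus_s3_reproduces_published_saving(self, study_counts, derived_costs):
        out = {k: tally_outcomes(v, study_counts)
               for k, v in build_strategies(study_counts, derived_costs).items()}
        assert compare(out["S2"], out["S3"]) == pytest.approx(979.30, abs=0.005)
        assert compare(out["S1"], out["S3"]) == pytest.approx(727.60, abs=0.005)

    def test_self_comparison_is_zero_and_antisymmetric(self, study_counts, derived_costs):
        out = {k: tally_outcomes(v, study_counts)
               for k, v in build_strategies(study_counts, derived_costs).items()}
        assert compare(out["S2"], out["S2"]) == 0.0
        assert compare(out["S2"], out["S3"]) == pytest.approx(-compare(out["S3"], out["S2"]))

    def test_cohort_size_mismatch_rejected(self, study_counts, derived_costs):
        out = tally_outcomes(build_strategies(study_counts, derived_costs)["S1"], study_counts)
        small = CohortCounts.from_table(ConfusionTable(1, 1, 1, 1))
        other = tally_outcomes(build_strategies(small, derived_costs)["S1"], small)
        with pytest.raises(ValueError, match="mismatch"):
            compare(out, other)

    @settings(max_examples=50, derandomize=True)
    @given(delta=st.floats(0.0, 5000.0))
    def test_translation_invariance_of_differences(self, delta, study_counts, derived_costs):
        """Adding a constant to every terminal cost shifts every strategy's
        expectation by that constant, leaving pairwise differences intact."""

        def shifted(model):
            def walk(node):
                if isinstance(node, TerminalNode):
                    return TerminalNode(node.cost + delta, node.labels)
                return ChanceNode(tuple((p, walk(ch)) for p, ch in node.branches))
            return StrategyModel(model.strategy_id, walk(model.root), model.description)

        models = build_strategies(study_counts, derived_costs)
        base = {k: evaluate(v) for k, v in models.items()}
        moved = {k: evaluate(shifted(v)) for k, v in models.items()}
        assert moved["S2"] - moved["S3"] == pytest.approx(base["S2"] - base["S3"], abs=1e-6)
        assert moved["S1"] - moved["S4"] == pytest.approx(base["S1"] - base["S4"], abs=1e-6)


class TestClosedForm:
    def test_zero_procedure_costs_give_zero_expected_cost(self):
        c = strategy_expected_costs(16 / 109, 0.75, 88 / 93, 0.0, 0.0, 0.0)
        assert all(v == 0.0 for v in c.values())

    def test_free_staging_orders_strategies_by_gastrectomy_fraction(self):
        # with c_pet = c_lap = 0 the cost is the gastrectomy fraction times
        # c_gast: S3 (92/109) < S2 (93/109) < S4 (97/109) here
        c = strategy_expected_costs(16 / 109, 0.75, 88 / 93, 0.0, 0.0, 9550.5)
        assert c["S3"] < c["S2"] < c["S4"] < c["S1"]
        assert c["S2"] == pytest.approx(93 / 109 * 9550.5)

    def test_closed_form_matches_tree_evaluation(self, study_counts, derived_costs):
        trees = build_strategies(study_counts, derived_costs)
        c = strategy_expected_costs(
            16 / 109, 0.75, 88 / 93,
            derived_costs.c_pet, derived_costs.c_lap, derived_costs.c_gast,
        )
        for sid, model in trees.items():
            assert c[sid] == pytest.approx(evaluate(model), abs=1e-9)
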