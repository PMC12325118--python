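"""Microsimulation engine and its deterministic expectation oracle."""

import numpy as np
import pytest

from thyrocea import (
    PatientRecord,
    classify_trajectory,
    cohort_expectation,
    compile_dynamics,
    simulate_cohort,
    step_patient,
)
from thyrocea.engine import classify_flags


def test_same_seed_bit_identical(cal_cfg):
    a = simulate_cohort(cal_cfg, "control", n=500, seed=7)
    b = simulate_cohort(cal_cfg, "control", n=500, seed=7)
    assert np.array_equal(a.cost, b.cost)
    assert np.array_equal(a.qaly, b.qaly)
    assert np.array_equal(a.classification, b.classification)


def test_step_patient_matches_vectorised_cohort(cal_cfg):
    """A step_patient loop and a one-patient cohort share the same law and
    random-number layout, so they are bit-identical under the same seed."""
    for arm in ("control", "digital"):
        dyn = compile_dynamics(cal_cfg, arm)
        vec = simulate_cohort(cal_cfg, arm, n=1, seed=123)
        rng = np.random.default_rng(123)
        p = PatientRecord(age=cal_cfg.cohort.start_age)
        for _ in range(cal_cfg.cohort.max_cycles):
            p = step_patient(p, dyn, arm, rng)
            if not p.alive:
                break
        assert p.discounted_cost == vec.cost[0]
        assert p.discounted_qaly == vec.qaly[0]


def test_step_dead_patient_rejected(cal_cfg):
    p = PatientRecord(age=50, alive=False)
    with pytest.raises(ValueError, match="dead"):
        step_patient(p, cal_cfg, "control", np.random.default_rng(0))


def test_unknown_state_rejected(cal_cfg):
    p = PatientRecord(age=40, state="limbo")
    with pytest.raises(ValueError, match="unknown state"):
        step_patient(p, cal_cfg, "control", np.random.default_rng(0))


def test_certain_death_ends_accrual(cal_cfg):
    cfg = cal_cfg.with_updates(**{"mortality.kind": "flat", "mortality.flat_q": 1.0})
    res = simulate_cohort(cfg, "control", n=50, seed=0)
    dyn = compile_dynamics(cfg, "control")
    # one cycle of accrual (acute care + one monitoring visit), then death
    assert np.allclose(res.cost, dyn.acute_cost + dyn.monitor_flat)
    assert np.allclose(res.qaly, dyn.u_atd)


def test_long_term_remission_absorbing_without_death(cal_cfg):
    cfg = cal_cfg.with_updates(**{
        "mortality.kind": "flat", "mortality.flat_q": 0.0,
        "cohort.start_state": "long_term_remission",
    })
    res = simulate_cohort(cfg, "control", n=20, seed=0)
    exp = cohort_expectation(cfg, "control")
    assert exp.occupancy["long_term_remission"].iloc[-1] == pytest.approx(1.0)
    assert np.all(res.classification == "long_term_remission")


def test_remission_window_completion_is_deterministic(cal_cfg):
    """Surviving the relapse-free window always confers long-term remission."""
    cfg = cal_cfg.with_updates(**{
        "mortality.kind": "flat", "mortality.flat_q": 0.0,
        "cohort.start_state": "remission",
        "parameters.relapse.base": 0.0,
        "parameters.relapse.low": 0.0,
        "parameters.relapse.high": 0.0,
        "parameters.relapse.horizon_years": None,
        "parameters.relapse.distribution": "fixed",
    })
    exp = cohort_expectation(cfg, "control")
    W = cfg.structure.remission_window_years
    assert exp.occupancy["remission"].iloc[W - 1] == pytest.approx(1.0)
    assert exp.occupancy["long_term_remission"].iloc[W] == pytest.approx(1.0)


class TestOracle:
    def test_occupancy_conserved_each_cycle(self, cal_cfg):
        for arm in ("control", "digital"):
            exp = cohort_expectation(cal_cfg, arm)
            assert np.allclose(exp.occupancy.sum(axis=1), 1.0, atol=1e-12)
            alive = 1.0 - exp.occupancy["dead"]
            assert np.all(np.diff(alive) <= 1e-12)

    def test_class_shares_sum_to_one(self, cal_cfg):
        exp = cohort_expectation(cal_cfg, "control")
        assert sum(exp.class_shares.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("arm", ["control", "digital"])
    def test_microsim_converges_to_oracle(self, cal_cfg, arm):
        """Core engine property: simulation means lie within 3 Monte-Carlo SE
        of the exact expectation, for economics and every occupancy share."""
        exp = cohort_expectation(cal_cfg, arm)
        sim = simulate_cohort(cal_cfg, arm, n=10_000, seed=2024)
        assert abs(sim.mean_cost - exp.expected_cost) < 3 * sim.se_cost
        assert abs(sim.mean_qaly - exp.expected_qaly) < 3 * sim.se_qaly
        for lab, p in exp.class_shares.items():
            se = max(np.sqrt(p * (1 - p) / sim.n), 1e-4)
            assert abs(sim.class_shares[lab] - p) < 3 * se, lab

    def test_qaly_bounded_by_life_years_and_horizon(self, cal_cfg):
        sim = simulate_cohort(cal_cfg, "control", n=2_000, seed=5)
        assert np.all(sim.qaly <= cal_cfg.cohort.max_cycles + 1e-12)
        exp = cohort_expectation(cal_cfg, "control")
        assert exp.expected_qaly <= exp.expected_life_years <= cal_cfg.cohort.max_cycles

    def test_cost_monotone_in_state_cost(self, cal_cfg):
        base = cohort_expectation(cal_cfg, "control").expected_cost
        bumped = cal_cfg.with_updates(**{
            "parameters.c_hypothyroid.base": 400.0,
            "parameters.c_hypothyroid.high": 500.0,
        })
        assert cohort_expectation(bumped, "control").expected_cost > base

    def test_discounting_monotone(self, cal_cfg):
        lo = cohort_expectation(
            cal_cfg, dynamics=compile_dynamics(cal_cfg, "control", {"discount_rate": 0.03})
        )
        hi = cohort_expectation(
            cal_cfg, dynamics=compile_dynamics(cal_cfg, "control", {"discount_rate": 0.05})
        )
        assert hi.expected_cost < lo.expected_cost
        assert hi.expected_qaly < lo.expected_qaly


class TestClassification:
    def test_single_category(self):
        hist = ["on_atd_initial", "remission", "long_term_remission"]
        assert classify_trajectory(hist) == "long_term_remission"

    def test_no_category_is_other(self):
        assert classify_trajectory(["on_atd_initial"]) == "other"

    def test_complication_takes_priority_by_default(self):
        hist = [("on_atd_initial", "tao"), ("remission", "tao"),
                ("long_term_remission", "tao")]
        assert classify_trajectory(hist) == "complication"

    @pytest.mark.parametrize(
        "priority",
        [
            ["complication", "hypothyroid", "long_term_remission", "relapse_on_long_term_atd"],
            ["hypothyroid", "complication", "relapse_on_long_term_atd", "long_term_remission"],
            ["long_term_remission", "relapse_on_long_term_atd", "complication", "hypothyroid"],
            ["relapse_on_long_term_atd", "long_term_remission", "hypothyroid", "complication"],
        ],
    )
    def test_first_match_wins_for_every_priority_order(self, priority):
        """Enumerating flag combinations: the label is always the first
        priority entry whose flag is set, else 'other'."""
        import itertools

        flag_names = ["complication", "hypothyroid", "long_term_remission",
                      "relapse_on_long_term_atd"]
        for bits in itertools.product([False, True], repeat=4):
            flags = dict(zip(flag_names, bits))
            got = classify_flags(flags["complication"], flags["hypothyroid"],
                                 flags["long_term_remission"],
                                 flags["relapse_on_long_term_atd"], priority)
            expected = next((lab for lab in priority if flags[lab]), "other")
            assert got == expected
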