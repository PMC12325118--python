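"""Synthetic mortality and the analytically solvable toy fixtures."""

import numpy as np
import pytest

from thyrocea import (
    LifeTable,
    MortalityModel,
    cohort_expectation,
    load_life_table,
    make_life_table,
    make_toy_config,
    toy_expected_values,
)
from thyrocea.population import MAX_AGE


class TestLifeTable:
    def test_gompertz_makeham_q40(self):
        lt = make_life_table(MortalityModel(5e-4, 3e-5, 0.095))
        a, b, eta = 5e-4, 3e-5, 0.095
        assert lt.q(40) == pytest.approx(1 - np.exp(-(a + b * np.exp(40 * eta))), abs=1e-12)
        assert lt.q(40) == pytest.approx(0.001839, abs=2e-6)

    def test_zero_hazard_limit(self):
        lt = make_life_table(MortalityModel(0.0, 1e-300, 1e-10))
        assert np.all(lt.qx[:-1] < 1e-12)
        assert lt.q(MAX_AGE) == 1.0

    def test_default_life_expectancy_plausible(self):
        e40 = make_life_table().life_expectancy(40)
        assert 38 < e40 < 48

    def test_survival_curve_monotone_and_closes(self):
        lt = make_life_table()
        s = lt.survival(0)
        assert np.all(np.diff(s) <= 1e-15)
        assert s[-1] == pytest.approx(0.0, abs=1e-12)
        assert lt.qx[-1] == 1.0

    def test_qx_nondecreasing_above_30(self):
        lt = make_life_table()
        assert np.all(np.diff(lt.qx[30:]) >= -1e-15)


class TestLoadLifeTable:
    def _write(self, tmp_path, ages, qx):
        p = tmp_path / "lt.csv"
        p.write_text("age,qx\n" + "\n".join(f"{a},{q}" for a, q in zip(ages, qx)))
        return p

    def test_extends_to_closure(self, tmp_path):
        p = self._write(tmp_path, range(101), [0.01] * 101)
        lt = load_life_table(p)
        assert lt.qx.shape == (MAX_AGE + 1,)
        assert lt.q(MAX_AGE) == 1.0
        assert lt.q(105) == 0.01  # carried forward

    def test_invalid_probability_rejected(self, tmp_path):
        p = self._write(tmp_path, range(101), [0.01] * 50 + [1.3] + [0.01] * 50)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            load_life_table(p)

    def test_nonmonotone_ages_rejected(self, tmp_path):
        p = self._write(tmp_path, [0, 2, 1], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="increasing"):
            load_life_table(p)

    def test_roundtrip_on_shared_ages(self, tmp_path):
        lt = make_life_table()
        p = tmp_path / "rt.csv"
        lt.to_frame().to_csv(p, index=False)
        again = load_life_table(p)
        assert np.allclose(again.qx, lt.qx)


class TestToyFixtures:
    def test_two_state_discounted_life_years(self, toy_two_state):
        """Geometric-series closed form: 1/(1 - (1-d)/(1+r)) = 7.2069."""
        cf = toy_expected_values("two_state")
        assert cf["life_years_discounted_infinite"] == pytest.approx(7.206897, abs=1e-6)
        exp = cohort_expectation(toy_two_state)
        assert exp.expected_qaly == pytest.approx(cf["life_years_discounted"], abs=1e-10)
        assert exp.expected_qaly == pytest.approx(7.2069, abs=1e-4)

    def test_two_state_zero_discount(self):
        cf = toy_expected_values("two_state", death_prob=0.1, discount_rate=0.0)
        # truncated at the closure age; the infinite-series value is 1/d = 10
        assert cf["life_years_discounted"] == pytest.approx(10.0, abs=1e-4)
        toy = make_toy_config("two_state", death_prob=0.1, discount_rate=0.0)
        assert cohort_expectation(toy).expected_qaly == pytest.approx(
            cf["life_years_discounted"], abs=1e-10
        )

    def test_three_state_closed_forms(self, toy_three_state):
        cf = toy_expected_values("three_state", death_prob=0.05, discount_rate=0.045,
                                 relapse_prob=0.2, relapse_cost=100.0,
                                 relapse_utility=0.8)
        exp = cohort_expectation(toy_three_state)
        assert exp.expected_qaly == pytest.approx(cf["qalys_discounted"], abs=1e-10)
        assert exp.expected_cost == pytest.approx(cf["cost_discounted"], abs=1e-10)

    def test_three_state_absorbing_start(self):
        """Zero transition out of the start state pins occupancy there."""
        toy = make_toy_config("three_state", relapse_prob=0.0, death_prob=0.0)
        exp = cohort_expectation(toy)
        occ = exp.occupancy
        # the remission window expires into long-term remission; together the
        # two remission states hold the whole cohort every cycle
        tot = occ["remission"] + occ["long_term_remission"]
        assert np.allclose(tot, 1.0, atol=1e-12)
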