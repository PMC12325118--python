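"""One-way DSA, threshold search, and probabilistic sensitivity analysis."""

import numpy as np
import pytest

from thyrocea import ceac, one_way_dsa, run_psa, threshold_fee
from thyrocea.sensitivity import oracle_icer


class TestOneWayDSA:
    def test_degenerate_range_has_zero_span(self, cal_cfg):
        cfg = cal_cfg.with_updates(**{
            "parameters.tao.low": 0.25, "parameters.tao.high": 0.25,
        })
        # low == high: skipped entirely (no range to vary)
        rows = one_way_dsa(cfg, params=["tao"])
        assert rows == []
        # explicit equal bounds on another parameter: span exactly 0
        cfg2 = cal_cfg.with_updates(**{
            "parameters.heart_failure.low": 0.016,
            "parameters.heart_failure.high": 0.016001,
        })
        rows2 = one_way_dsa(cfg2, params=["heart_failure"])
        assert rows2[0].span < 10.0

    def test_rows_sorted_by_span(self, cal_cfg):
        rows = one_way_dsa(cal_cfg, params=["subscription_monthly", "tao", "c_tft"])
        spans = [r.span for r in rows]
        assert spans == sorted(spans, reverse=True)

    def test_base_bounds_recover_base_icer(self, cal_cfg):
        """A 'range' collapsed onto the base value reproduces the base ICER."""
        _, _, base_icer = oracle_icer(cal_cfg)
        cfg = cal_cfg.with_updates(**{
            "parameters.relapse.low": 0.528, "parameters.relapse.high": 0.528001,
        })
        row = one_way_dsa(cfg, params=["relapse"])[0]
        assert row.icer_at_low == pytest.approx(base_icer, rel=1e-3)


class TestThresholdFee:
    def test_root_brackets_dominance(self, cal_cfg):
        fee = threshold_fee(cal_cfg, tol=0.005)
        assert fee is not None
        below = oracle_icer(cal_cfg, {"subscription_monthly": fee - 0.5})[0]
        above = oracle_icer(cal_cfg, {"subscription_monthly": fee + 0.5})[0]
        assert below < 0 < above

    def test_no_crossing_reported_as_none(self, cal_cfg):
        # an always-cheaper digital arm has no fee threshold below $200
        cfg = cal_cfg.with_updates(**{"structure.extra_annual_cost_control": 1e6})
        assert threshold_fee(cfg) is None

    def test_affine_shift_consistency(self, cal_cfg):
        """Adding an annual control-arm cost of 12*delta moves the threshold
        fee up by exactly delta (survival is arm-independent)."""
        base = threshold_fee(cal_cfg, tol=1e-3)
        delta = 4.0
        cfg = cal_cfg.with_updates(**{"structure.extra_annual_cost_control": 12 * delta})
        shifted = threshold_fee(cfg, tol=1e-3)
        assert shifted == pytest.approx(base + delta, abs=0.01)


class TestPSA:
    def test_degenerate_psa_equals_base_case(self, cal_cfg):
        """All distributions collapsed to fixed: one draw reproduces the
        base-case paired simulation exactly."""
        updates = {}
        for name, p in cal_cfg.parameters.items():
            if p.psa_fit() is not None:
                updates[f"parameters.{name}.distribution"] = "fixed"
        cfg = cal_cfg.with_updates(**updates)
        draws = run_psa(cfg, n_outer=1, n_inner=400, seed=77)
        rng = np.random.default_rng(77)
        inner_seed = int(rng.integers(0, 2**31 - 1))
        from thyrocea import simulate_cohort

        rc = simulate_cohort(cfg, "control", n=400, seed=inner_seed)
        rd = simulate_cohort(cfg, "digital", n=400, seed=inner_seed)
        assert draws.delta_cost[0] == pytest.approx(rd.mean_cost - rc.mean_cost)
        assert draws.delta_qaly[0] == pytest.approx(rd.mean_qaly - rc.mean_qaly)

    def test_reproducible_from_seed(self, cal_cfg):
        a = run_psa(cal_cfg, n_outer=5, n_inner=100, seed=3)
        b = run_psa(cal_cfg, n_outer=5, n_inner=100, seed=3)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)

    def test_sampled_parameter_means_recover_base(self, cal_cfg):
        draws = run_psa(cal_cfg, n_outer=400, n_inner=1, seed=11)
        for name in ("relapse", "c_tft", "u_tao", "subscription_monthly"):
            x = draws.sampled[name].to_numpy()
            se = x.std(ddof=1) / np.sqrt(x.size)
            assert abs(x.mean() - cal_cfg.value(name)) < 3.5 * se, name

    def test_ceac_consistent_with_draws(self, cal_cfg):
        draws = run_psa(cal_cfg, n_outer=30, n_inner=200, seed=5)
        wtp = np.array([0.0, 32255.0, 1e6])
        curve = ceac(draws.delta_cost, draws.delta_qaly, wtp)
        inmb = draws.delta_qaly * 32255.0 - draws.delta_cost
        assert curve[1] == pytest.approx(np.mean(inmb > 0))
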