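"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis and the subscription-fee threshold search use
the deterministic cohort-expectation oracle, so parameter rankings are free
of Monte-Carlo noise.  The probabilistic sensitivity analysis (PSA)
re-samples every non-fixed parameter from its moment-matched distribution
(beta for probabilities, utilities and test characteristics; gamma for
costs) and re-runs the paired microsimulation under common random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import cohort_expectation, compile_dynamics, simulate_cohort

log = logging.getLogger("thyrocea")

__all__ = ["TornadoRow", "one_way_dsa", "threshold_fee", "PSADraws", "run_psa"]

#: incremental effects below this are treated as zero (no defined ICER)
_EPS = 1e-9


def oracle_icer(config: ModelConfig, overrides: Optional[dict[str, float]] = None):
    """(dC, dE, ICER) between arms from the deterministic oracle."""
    rc = cohort_expectation(config, dynamics=compile_dynamics(config, "control", overrides))
    rd = cohort_expectation(config, dynamics=compile_dynamics(config, "digital", overrides))
    d_c = rd.expected_cost - rc.expected_cost
    d_e = rd.expected_qaly - rc.expected_qaly
    icer = d_c / d_e if abs(d_e) > _EPS else None
    return d_c, d_e, icer


@dataclass
class TornadoRow:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_dsa(config: ModelConfig, params: Optional[list[str]] = None) -> list[TornadoRow]:
    """One-way deterministic sensitivity analysis of the ICER.

    Each parameter is set to its low and high bound in turn with everything
    else at base value; rows come back sorted by ICER span, descending.
    Parameters without a range are skipped (logged).  Dominance shows up as
    a negative ICER (incremental cost below zero at positive incremental
    QALYs), which keeps tornado spans well defined.
    """
    if params is None:
        params = [name for name, p in config.parameters.items() if p.low < p.high]
    rows: list[TornadoRow] = []
    for name in params:
        p = config.parameters[name]
        if p.low >= p.high:
            log.info("DSA: parameter %s has no range; skipped", name)
            continue
        icers = []
        for bound in (p.low, p.high):
            d_c, d_e, _ = oracle_icer(config, overrides={name: bound})
            if abs(d_e) < _EPS:
                log.warning("DSA: parameter %s at %.4g gives ~zero incremental QALY", name, bound)
                icers.append(np.nan)
            else:
                icers.append(d_c / d_e)
        rows.append(TornadoRow(name, p.low, p.high, icers[0], icers[1]))
    rows.sort(key=lambda r: r.span, reverse=True)
    return rows


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "icer_low": r.icer_at_low,
                "icer_high": r.icer_at_high,
                "span": r.span,
            }
            for r in rows
        ]
    )


def threshold_fee(
    config: ModelConfig,
    lo: float = 0.0,
    hi: float = 200.0,
    tol: float = 0.01,
) -> Optional[float]:
    """Monthly subscription fee at which incremental cost crosses zero.

    Below the returned fee the digital arm is dominant (cost-saving at
    positive incremental QALYs).  Incremental cost is affine and strictly
    increasing in the fee under the oracle, so bisection on [lo, hi] finds
    the unique root; returns None when there is no sign change in range.
    """
    fee_name = config.intervention.monthly_fee_param

    def d_cost(fee: float) -> float:
        d_c, _, _ = oracle_icer(config, overrides={fee_name: fee})
        return d_c

    f_lo, f_hi = d_cost(lo), d_cost(hi)
    if f_lo > 0 or f_hi < 0:
        log.warning("threshold_fee: no zero crossing of incremental cost in [%g, %g]", lo, hi)
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if d_cost(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PSADraws:
    """Paired incremental outcomes across PSA repetitions."""

    n_outer: int
    n_inner: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    sampled: pd.DataFrame      # one row per draw: the sampled parameter values

    def to_frame(self) -> pd.DataFrame:
        out = self.sampled.copy()
        out.insert(0, "delta_qaly", self.delta_qaly)
        out.insert(0, "delta_cost", self.delta_cost)
        return out


def run_psa(
    config: ModelConfig,
    n_outer: int = 10_000,
    n_inner: int = 10_000,
    seed: int = 0,
) -> PSADraws:
    """Probabilistic sensitivity analysis.

    Every non-fixed parameter is drawn from its fitted distribution; both
    arms are re-simulated per draw with ``n_inner`` patients under common
    random numbers, and the incremental discounted cost and QALYs are
    recorded.  Fully reproducible from ``seed``.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    fits = {}
    for name, p in config.parameters.items():
        fit = p.psa_fit()
        if fit is not None:
            fits[name] = fit
    rng = np.random.default_rng(seed)
    d_c = np.empty(n_outer)
    d_e = np.empty(n_outer)
    sampled_rows = np.empty((n_outer, len(fits)))
    names = list(fits)
    for i in range(n_outer):
        overrides = {}
        for j, name in enumerate(names):
            x = float(fits[name].sample(rng))
            overrides[name] = x
            sampled_rows[i, j] = x
        inner_seed = int(rng.integers(0, 2**31 - 1))
        dyn_c = compile_dynamics(config, "control", overrides)
        dyn_d = compile_dynamics(config, "digital", overrides)
        rc = simulate_cohort(config, n=n_inner, seed=inner_seed, dynamics=dyn_c)
        rd = simulate_cohort(config, n=n_inner, seed=inner_seed, dynamics=dyn_d)
        d_c[i] = rd.mean_cost - rc.mean_cost
        d_e[i] = rd.mean_qaly - rc.mean_qaly
    return PSADraws(
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        delta_cost=d_c,
        delta_qaly=d_e,
        sampled=pd.DataFrame(sampled_rows, columns=names),
    )
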