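"""Discounting and cost-effectiveness statistics.

Outcomes are compared with the standard decision-analytic quantities:
incremental cost and effectiveness (dC, dE), the incremental
cost-effectiveness ratio ICER = dC/dE, and (incremental) net monetary
benefit NMB = E * WTP - C at a willingness-to-pay threshold per QALY.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import EconomicsSettings
from .engine import CohortResult

__all__ = ["discount_factor", "CEResult", "compare_arms", "ceac"]

#: incremental effects smaller than this are treated as zero for ICERs
ICER_EPS = 1e-9


def discount_factor(cycle: int, rate: float) -> float:
    """Discount factor ``(1 + rate)^-cycle`` for an annual cycle index."""
    if rate <= -1.0:
        raise ValueError("rate must be > -1")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float((1.0 + rate) ** (-cycle))


@dataclass
class CEResult:
    """Cost-effectiveness comparison of the digital arm vs control."""

    control_cost: float
    control_qaly: float
    digital_cost: float
    digital_qaly: float
    se_control_cost: float
    se_control_qaly: float
    se_digital_cost: float
    se_digital_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    digital_dominant: bool
    control_dominant: bool
    icer_undefined: bool
    nmb_control: float
    nmb_digital: float
    inmb: float
    wtp: float
    n: int

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "control_cost", "control_qaly", "digital_cost", "digital_qaly",
                "se_control_cost", "se_control_qaly", "se_digital_cost",
                "se_digital_qaly", "delta_cost", "delta_qaly", "icer",
                "digital_dominant", "control_dominant", "icer_undefined",
                "nmb_control", "nmb_digital", "inmb", "wtp", "n",
            )
        }


def _ce_from_means(
    c0: float, e0: float, c1: float, e1: float, wtp: float,
    se: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    n: int = 0,
) -> CEResult:
    d_c = c1 - c0
    d_e = e1 - e0
    digital_dom = d_c <= 0 and d_e >= 0 and (d_c < 0 or d_e > 0)
    control_dom = d_c >= 0 and d_e <= 0 and (d_c > 0 or d_e < 0)
    undefined = abs(d_e) < ICER_EPS
    icer = None if (undefined or digital_dom or control_dom) else d_c / d_e
    nmb0 = e0 * wtp - c0
    nmb1 = e1 * wtp - c1
    return CEResult(
        control_cost=c0, control_qaly=e0, digital_cost=c1, digital_qaly=e1,
        se_control_cost=se[0], se_control_qaly=se[1],
        se_digital_cost=se[2], se_digital_qaly=se[3],
        delta_cost=d_c, delta_qaly=d_e, icer=icer,
        digital_dominant=digital_dom, control_dominant=control_dom,
        icer_undefined=undefined,
        nmb_control=nmb0, nmb_digital=nmb1, inmb=nmb1 - nmb0, wtp=wtp, n=n,
    )


def compare_arms(
    control: "CohortResult | tuple[float, float]",
    digital: "CohortResult | tuple[float, float]",
    econ: EconomicsSettings,
) -> CEResult:
    """Cost-effectiveness statistics for two simulated (or expected) arms.

    Accepts :class:`~thyrocea.engine.CohortResult` objects or plain
    ``(mean_cost, mean_qaly)`` pairs (e.g. from the expectation oracle).
    """
    if isinstance(control, tuple):
        c0, e0 = control
        c1, e1 = digital
        return _ce_from_means(c0, e0, c1, e1, econ.wtp)
    return _ce_from_means(
        control.mean_cost, control.mean_qaly,
        digital.mean_cost, digital.mean_qaly,
        econ.wtp,
        se=(control.se_cost, control.se_qaly, digital.se_cost, digital.se_qaly),
        n=min(control.n, digital.n),
    )


def ceac(delta_cost: np.ndarray, delta_qaly: np.ndarray, wtp_grid: np.ndarray) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of PSA draws in which
    the digital arm has positive incremental net monetary benefit.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_qaly, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need matched, non-empty (delta cost, delta QALY) draws")
    inmb = de[None, :] * wtp_grid[:, None] - dc[None, :]
    return (inmb > 0).mean(axis=1)
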