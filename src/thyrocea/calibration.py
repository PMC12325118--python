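"""Calibration of the structural parameters the inputs leave implicit.

Two quantities are not identified by the published inputs: the annual
chance of regaining remission while on long-term ATD (control arm), and the
strength of the digital intervention's effect, expressed as the multiplier
pair (theta_r on subsequent remission, theta_p on relapse).  Both are
resolved by fitting the deterministic oracle's lifetime classification
shares to target state-occupancy shares.  Economic outcomes (costs, QALYs,
ICER) never enter the loss, so they remain genuine out-of-sample
predictions of the calibrated model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .config import ModelConfig
from .engine import cohort_expectation, compile_dynamics

__all__ = [
    "DEFAULT_TARGETS",
    "CalibrationResult",
    "calibrate_control",
    "calibrate_digital",
    "calibrated_config",
]

#: published state-occupancy shares used as calibration targets
DEFAULT_TARGETS = {
    "control_ltr": 0.1748,
    "digital_ltr": 0.2268,
    "digital_relapse": 0.1787,
}

#: summed squared share error above which a fit is flagged unconverged
LOSS_TOL = 1e-4

_BOUNDS_S = (0.0, 0.5)
_BOUNDS_THETA_R = (1.0, 5.0)
_BOUNDS_THETA_P = (0.2, 1.0)


@dataclass
class CalibrationResult:
    fitted: dict[str, float]
    loss: float
    targets: dict[str, float]
    residuals: dict[str, float]
    converged: bool
    predictions: dict[str, float] = field(default_factory=dict)


def _control_shares(config: ModelConfig, s: float) -> dict[str, float]:
    dyn = compile_dynamics(config, "control", overrides={"subsequent_remission_prob": s})
    return cohort_expectation(config, dynamics=dyn).class_shares


def calibrate_control(
    config: ModelConfig,
    target_ltr_share: float = DEFAULT_TARGETS["control_ltr"],
) -> CalibrationResult:
    """Fit the subsequent-remission probability to a long-term-remission share.

    Golden-section (bounded scalar) search on [0, 0.5] minimising the
    squared error between the oracle-predicted long-term-remission
    classification share and the target; deterministic.  If the target is
    unattainable within bounds the best boundary value is returned with
    ``converged = False``.
    """
    if not 0.0 < target_ltr_share < 1.0:
        raise ValueError("target share must lie in (0, 1)")

    def loss(s: float) -> float:
        share = _control_shares(config, s)["long_term_remission"]
        return (share - target_ltr_share) ** 2

    res = minimize_scalar(
        loss, bounds=_BOUNDS_S, method="bounded", options={"xatol": 1e-4}
    )
    candidates = [(float(res.x), float(res.fun))]
    for b in _BOUNDS_S:
        candidates.append((b, loss(b)))
    s_best, l_best = min(candidates, key=lambda t: t[1])
    shares = _control_shares(config, s_best)
    return CalibrationResult(
        fitted={"subsequent_remission_prob": s_best},
        loss=l_best,
        targets={"long_term_remission": target_ltr_share},
        residuals={"long_term_remission": shares["long_term_remission"] - target_ltr_share},
        converged=l_best <= LOSS_TOL,
        predictions={k: v for k, v in shares.items()},
    )


def _digital_shares(config: ModelConfig, theta_r: float, theta_p: float) -> dict[str, float]:
    cfg = config.model_copy(deep=True)
    cfg.intervention.effect_remission_uplift = theta_r
    cfg.intervention.effect_relapse_multiplier = theta_p
    return cohort_expectation(cfg, arm="digital").class_shares


def calibrate_digital(
    config: ModelConfig,
    target_ltr_share: float = DEFAULT_TARGETS["digital_ltr"],
    target_relapse_share: float = DEFAULT_TARGETS["digital_relapse"],
) -> CalibrationResult:
    """Fit the effect multipliers (theta_r, theta_p) to digital-arm shares.

    Coarse grid search over the bounded box followed by a local
    Nelder-Mead refinement (bounds enforced by clipping); deterministic.
    The control arm (its subsequent-remission probability) must already be
    calibrated into ``config``.
    """

    def loss_vec(theta_r: float, theta_p: float) -> float:
        sh = _digital_shares(config, theta_r, theta_p)
        return (
            (sh["long_term_remission"] - target_ltr_share) ** 2
            + (sh["relapse_on_long_term_atd"] - target_relapse_share) ** 2
        )

    grid_r = np.linspace(*_BOUNDS_THETA_R, 9)
    grid_p = np.linspace(*_BOUNDS_THETA_P, 9)
    best = None
    for tr in grid_r:
        for tp in grid_p:
            l = loss_vec(tr, tp)
            if best is None or l < best[2]:
                best = (tr, tp, l)
    tr0, tp0, _ = best

    def clipped(x) -> tuple[float, float]:
        return (
            float(np.clip(x[0], *_BOUNDS_THETA_R)),
            float(np.clip(x[1], *_BOUNDS_THETA_P)),
        )

    res = minimize(
        lambda x: loss_vec(*clipped(x)),
        x0=[tr0, tp0],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200},
    )
    theta_r, theta_p = clipped(res.x)
    l_final = loss_vec(theta_r, theta_p)
    # keep the grid optimum unless refinement strictly improves on it (ties
    # can occur on flat directions, e.g. a remission uplift with nothing to
    # uplift)
    if best[2] <= l_final:
        theta_r, theta_p, l_final = best
    shares = _digital_shares(config, theta_r, theta_p)
    return CalibrationResult(
        fitted={"effect_remission_uplift": theta_r, "effect_relapse_multiplier": theta_p},
        loss=l_final,
        targets={
            "long_term_remission": target_ltr_share,
            "relapse_on_long_term_atd": target_relapse_share,
        },
        residuals={
            "long_term_remission": shares["long_term_remission"] - target_ltr_share,
            "relapse_on_long_term_atd": shares["relapse_on_long_term_atd"]
            - target_relapse_share,
        },
        converged=l_final <= LOSS_TOL,
        predictions=dict(shares),
    )


def calibrated_config(
    config: ModelConfig | None = None,
    targets: dict[str, float] | None = None,
) -> tuple[ModelConfig, dict[str, CalibrationResult]]:
    """Run the full calibration chain and return the calibrated config.

    Control first (subsequent-remission probability), then the digital
    effect multipliers with the control fit frozen in.
    """
    from .config import default_config

    cfg = (config or default_config()).model_copy(deep=True)
    t = {**DEFAULT_TARGETS, **(targets or {})}
    ctrl = calibrate_control(cfg, t["control_ltr"])
    cfg.structure.subsequent_remission_prob = ctrl.fitted["subsequent_remission_prob"]
    dig = calibrate_digital(cfg, t["digital_ltr"], t["digital_relapse"])
    cfg.intervention.effect_remission_uplift = dig.fitted["effect_remission_uplift"]
    cfg.intervention.effect_relapse_multiplier = dig.fitted["effect_relapse_multiplier"]
    return cfg, {"control": ctrl, "digital": dig}
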