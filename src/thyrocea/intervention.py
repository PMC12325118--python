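"""The digital-monitoring arm: test characteristics and monitoring economics.

The wearable/mobile monitoring solution acts on the disease course through
two interpretable, calibratable multipliers: ``effect_relapse_multiplier``
(theta_p) scales the annual relapse probability, and
``effect_remission_uplift`` (theta_r) scales the chance of regaining
remission while on long-term ATD.  In addition, relapses are caught early
with probability equal to the device sensitivity and restart a short ATD
course instead of moving to long-term ATD.  Economically, the digital arm
pays a monthly subscription for life, a scheduled confirmatory
thyroid-function-test (TFT) visit each year (optionally reduced by a
visit-cost-reduction scenario), and a false-positive extra visit with
probability (1 - specificity) while in non-hyperthyroid states.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import InterventionSpec, ModelConfig
from .engine import HYPOTHYROID, LONG_TERM_REMISSION, REMISSION, STATE_NAMES

__all__ = ["InterventionSpec", "apply_digital_effects", "annual_monitoring_cost"]

_NON_HYPER = {
    STATE_NAMES[REMISSION],
    STATE_NAMES[LONG_TERM_REMISSION],
    STATE_NAMES[HYPOTHYROID],
}


def apply_digital_effects(config: ModelConfig, spec: Optional[InterventionSpec] = None) -> ModelConfig:
    """Return the digital-arm model configuration.

    The returned config carries ``spec`` as its intervention block; all
    clinical parameters other than the two effect multipliers and the
    early-detection routing are untouched.  Simulate it with
    ``simulate_cohort(cfg, arm="digital")``.
    """
    out = config.model_copy(deep=True)
    if spec is not None:
        out.intervention = spec
    return out


def annual_monitoring_cost(
    arm: str,
    config: ModelConfig,
    state: str,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monitoring cost accrued by one alive patient in one annual cycle.

    Control: one full-fee TFT visit.  Digital: twelve monthly subscription
    fees plus one scheduled TFT visit at ``fee * (1 - visit_cost_reduction)``,
    plus — in non-hyperthyroid states — a false-positive extra visit at the
    full fee with probability (1 - specificity).
    """
    if state not in STATE_NAMES or state == "dead":
        raise ValueError(f"not an alive state: {state!r}")
    iv = config.intervention
    tft = config.value(config.structure.tft_fee_param)
    if arm == "control":
        return tft
    if arm != "digital":
        raise ValueError(f"unknown arm {arm!r}")
    fee = iv.monthly_fee if iv.monthly_fee is not None else config.value(iv.monthly_fee_param)
    spec_ = iv.specificity if iv.specificity is not None else config.value(iv.specificity_param)
    cost = 12.0 * fee + tft * (1.0 - iv.visit_cost_reduction)
    if state in _NON_HYPER:
        rng = rng or np.random.default_rng()
        if rng.random() < 1.0 - spec_:
            cost += tft
    return cost
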