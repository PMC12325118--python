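"""Model definition: parameters, economics settings, structural rules.

Every quantity the model consumes — transition probabilities with the time
window they were observed over, utility weights, annual costs in 2022 USD,
test characteristics, the discount rate — is declared as a
:class:`ParameterSpec` carrying its base value, plausible range and the
distribution family used for probabilistic sensitivity analysis (beta for
probabilities/utilities/test characteristics, gamma for costs).  The default
parameter set (:func:`default_config`) encodes the South Korean
hyperthyroidism inputs the model was built around.
"""

from __future__ import annotations

import hashlib
import logging
import math
from enum import Enum
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

log = logging.getLogger("thyrocea")

__all__ = [
    "ParameterRole",
    "ParameterSpec",
    "DistributionFit",
    "EconomicsSettings",
    "CohortSettings",
    "MortalitySettings",
    "StructuralRules",
    "InterventionSpec",
    "ModelConfig",
    "prob_to_annual",
    "fit_beta",
    "fit_gamma",
    "default_config",
    "load_config",
    "save_config",
    "config_digest",
]

# ---------------------------------------------------------------------------
# parameter specifications


class ParameterRole(str, Enum):
    transition_probability = "transition_probability"
    test_characteristic = "test_characteristic"
    utility = "utility"
    annual_cost = "annual_cost"
    one_time_cost = "one_time_cost"
    rate = "rate"


_PROB_LIKE = {
    ParameterRole.transition_probability,
    ParameterRole.test_characteristic,
    ParameterRole.utility,
}
_COST_LIKE = {ParameterRole.annual_cost, ParameterRole.one_time_cost}


class ParameterSpec(BaseModel):
    """One model input with its uncertainty description.

    ``horizon_years`` is the time window a transition probability was
    observed over (e.g. 5% treatment failure over 1.5 years); cycle-aligned
    annual probabilities are derived with :func:`prob_to_annual`.
    """

    name: str
    role: ParameterRole
    base: float
    low: float
    high: float
    horizon_years: Optional[float] = None
    distribution: str = Field(pattern="^(beta|gamma|uniform|fixed)$")

    @model_validator(mode="after")
    def _check(self) -> "ParameterSpec":
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"parameter {self.name!r}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.role in _PROB_LIKE:
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError(
                    f"parameter {self.name!r}: probabilities and utilities "
                    f"must lie in [0, 1]"
                )
        if self.role in _COST_LIKE and self.low < 0:
            raise ValueError(f"parameter {self.name!r}: costs must be >= 0")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ValueError(f"parameter {self.name!r}: horizon_years must be > 0")
        return self

    @property
    def annual(self) -> float:
        """Base value converted to a per-cycle (annual) probability."""
        if self.horizon_years is None or self.horizon_years == 1.0:
            return self.base
        return prob_to_annual(self.base, self.horizon_years)

    def psa_fit(self) -> Optional["DistributionFit"]:
        """Fitted PSA distribution, or None for fixed/degenerate inputs."""
        if self.distribution == "fixed" or self.low == self.high:
            return None
        if self.distribution == "beta":
            return fit_beta(self.base, self.low, self.high, name=self.name)
        if self.distribution == "gamma":
            return fit_gamma(self.base, self.low, self.high, name=self.name)
        if self.distribution == "uniform":
            # degenerate bounds (e.g. a perfect reference test) act as fixed
            if self.base in (0.0, 1.0):
                return None
            return DistributionFit(family="uniform", shape1=self.low, shape2=self.high)
        return None


class DistributionFit(BaseModel):
    """Moment-matched sampling distribution for one parameter."""

    family: str = Field(pattern="^(beta|gamma|uniform)$")
    shape1: float  # beta alpha / gamma shape k / uniform low
    shape2: float  # beta beta  / gamma scale theta / uniform high

    @model_validator(mode="after")
    def _positive(self) -> "DistributionFit":
        if self.family in ("beta", "gamma") and (self.shape1 <= 0 or self.shape2 <= 0):
            raise ValueError("distribution shape values must be > 0")
        return self

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.shape1 / (self.shape1 + self.shape2)
        if self.family == "gamma":
            return self.shape1 * self.shape2
        return 0.5 * (self.shape1 + self.shape2)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.shape1, self.shape2, size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape1, self.shape2, size=size)
        return rng.uniform(self.shape1, self.shape2, size=size)


# ---------------------------------------------------------------------------
# conversions and moment fits


def prob_to_annual(p: float, t: float) -> float:
    """Convert a probability observed over ``t`` years to an annual one.

    Assumes a constant hazard over the observation window:
    ``p_annual = 1 - (1 - p)**(1/t)``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"horizon must be > 0, got {t}")
    if t == 1.0:
        return p
    return 1.0 - (1.0 - p) ** (1.0 / t)


#: ranges are read as central 95% intervals, so sd = range / (2 * 1.96)
RANGE_TO_SD = 3.92


def fit_beta(mean: float, low: float, high: float, name: str = "?") -> DistributionFit:
    """Method-of-moments beta fit with sd taken from the stated range."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"parameter {name!r}: beta mean must lie in (0, 1)")
    if not low < high:
        raise ValueError(f"parameter {name!r}: need low < high")
    sd = (high - low) / RANGE_TO_SD
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"parameter {name!r}: implied variance {var:.3g} too large for a "
            f"beta distribution with mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return DistributionFit(family="beta", shape1=mean * nu, shape2=(1.0 - mean) * nu)


def fit_gamma(mean: float, low: float, high: float, name: str = "?") -> DistributionFit:
    """Method-of-moments gamma fit with sd taken from the stated range."""
    if mean <= 0:
        raise ValueError(f"parameter {name!r}: gamma mean must be > 0")
    if not low < high:
        raise ValueError(f"parameter {name!r}: need low < high")
    sd = (high - low) / RANGE_TO_SD
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return DistributionFit(family="gamma", shape1=shape, shape2=scale)


# ---------------------------------------------------------------------------
# settings blocks


class EconomicsSettings(BaseModel):
    discount_rate: float = 0.045
    wtp: float = 32255.0
    currency_label: str = "USD 2022"

    @model_validator(mode="after")
    def _check(self) -> "EconomicsSettings":
        if not 0.0 <= self.discount_rate <= 0.2:
            raise ValueError("discount_rate must lie in [0, 0.2]")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        return self


class CohortSettings(BaseModel):
    start_age: int = 40
    n: int = 10_000
    max_cycles: int = 70
    cycle_length_years: float = 1.0
    start_state: str = "on_atd_initial"

    @model_validator(mode="after")
    def _check(self) -> "CohortSettings":
        if self.max_cycles * self.cycle_length_years < 1.0:
            raise ValueError("max_cycles * cycle_length_years must be >= 1")
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        return self


class MortalitySettings(BaseModel):
    """Background mortality source.

    ``gompertz_makeham`` is the synthetic parametric default; ``flat`` gives
    a constant annual death probability (used by the toy fixtures); ``file``
    reads a two-column (age, qx) CSV, e.g. a national life table.
    """

    kind: str = Field(default="gompertz_makeham", pattern="^(gompertz_makeham|flat|file)$")
    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_eta: float = 0.095
    flat_q: float = 0.1
    path: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "MortalitySettings":
        if self.kind == "gompertz_makeham":
            if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_eta <= 0:
                raise ValueError("Gompertz-Makeham parameters out of range")
        if self.kind == "flat" and not 0.0 <= self.flat_q <= 1.0:
            raise ValueError("flat_q must lie in [0, 1]")
        if self.kind == "file" and not self.path:
            raise ValueError("mortality kind 'file' requires a path")
        return self


COMPLICATION_TYPES = [
    "tao",
    "atrial_fibrillation",
    "heart_failure",
    "osteoporosis",
    "fracture",
    "thyroid_cancer",
]

STATES = [
    "on_atd_initial",
    "on_atd_retreat",
    "remission",
    "long_term_remission",
    "relapse_on_long_term_atd",
    "hypothyroid",
    "dead",
]

CLASSIFICATION_LABELS = [
    "complication",
    "hypothyroid",
    "long_term_remission",
    "relapse_on_long_term_atd",
    "other",
]


class StructuralRules(BaseModel):
    """Wiring of the disease course, with parameter bindings by name."""

    atd_course_years: int = 2
    remission_window_years: int = 5
    atd_failure_param: str = "atd_failure"
    relapse_param: str = "relapse"
    hypothyroidism_param: str = "hypothyroidism"
    complication_params: dict[str, str] = Field(
        default_factory=lambda: {c: c for c in COMPLICATION_TYPES}
    )
    complication_cost_params: dict[str, str] = Field(
        default_factory=lambda: {c: f"c_{c}" for c in COMPLICATION_TYPES}
    )
    complication_utility_params: dict[str, str] = Field(
        default_factory=lambda: {c: f"u_{c}" for c in COMPLICATION_TYPES}
    )
    acute_cost_param: str = "c_acute_initial"
    atd_cost_param: str = "c_atd_annual"
    hypothyroid_cost_param: str = "c_hypothyroid"
    tft_fee_param: str = "c_tft"
    atd_utility_param: str = "u_hyperthyroid_atd"
    hypothyroid_utility_param: str = "u_hypothyroid"
    remission_utility_param: str = "u_remission"
    #: annual chance, while on long-term ATD after relapse, of regaining
    #: remission; the single calibratable control-arm structural parameter
    subsequent_remission_prob: float = 0.1
    #: ATD treatment failure (-> definitive therapy -> hypothyroid) also
    #: applies while on long-term ATD after relapse
    atd_failure_in_relapse: bool = True
    classification_priority: list[str] = Field(
        default_factory=lambda: [
            "complication",
            "hypothyroid",
            "long_term_remission",
            "relapse_on_long_term_atd",
        ]
    )
    #: lump annual costs added to every alive cycle of one arm (diagnostics
    #: and consistency checks; both default to zero)
    extra_annual_cost_control: float = 0.0
    extra_annual_cost_digital: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "StructuralRules":
        if not 0.0 <= self.subsequent_remission_prob <= 1.0:
            raise ValueError("subsequent_remission_prob must lie in [0, 1]")
        if self.atd_course_years < 1 or self.remission_window_years < 1:
            raise ValueError("course and window lengths must be >= 1 year")
        bad = [c for c in self.classification_priority if c not in CLASSIFICATION_LABELS]
        if bad:
            raise ValueError(f"unknown classification labels: {bad}")
        return self


class InterventionSpec(BaseModel):
    """Digital-monitoring arm description.

    ``sensitivity``/``specificity``/``monthly_fee`` default to the bound
    Table-style parameters (``digital_sensitivity`` etc.); explicit values
    here override the parameter set.  ``effect_remission_uplift`` (theta_r)
    multiplies the subsequent-remission probability and
    ``effect_relapse_multiplier`` (theta_p) multiplies the annual relapse
    probability; both are resolved by calibration, not assumed.
    """

    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    monthly_fee: Optional[float] = None
    visit_cost_reduction: float = 0.0
    effect_remission_uplift: float = 1.0
    effect_relapse_multiplier: float = 1.0
    sensitivity_param: str = "digital_sensitivity"
    specificity_param: str = "digital_specificity"
    monthly_fee_param: str = "subscription_monthly"

    @model_validator(mode="after")
    def _check(self) -> "InterventionSpec":
        for v, nm in ((self.sensitivity, "sensitivity"), (self.specificity, "specificity")):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.monthly_fee is not None and self.monthly_fee < 0:
            raise ValueError("monthly_fee must be >= 0")
        if not 0.0 <= self.visit_cost_reduction <= 1.0:
            raise ValueError("visit_cost_reduction must lie in [0, 1]")
        if self.effect_remission_uplift < 1.0:
            raise ValueError("effect_remission_uplift must be >= 1")
        if not 0.0 < self.effect_relapse_multiplier <= 1.0:
            raise ValueError("effect_relapse_multiplier must lie in (0, 1]")
        return self


class ModelConfig(BaseModel):
    states: list[str] = Field(default_factory=lambda: list(STATES))
    complication_types: list[str] = Field(default_factory=lambda: list(COMPLICATION_TYPES))
    parameters: dict[str, ParameterSpec] = Field(default_factory=dict)
    economics: EconomicsSettings = Field(default_factory=EconomicsSettings)
    structure: StructuralRules = Field(default_factory=StructuralRules)
    intervention: InterventionSpec = Field(default_factory=InterventionSpec)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    mortality: MortalitySettings = Field(default_factory=MortalitySettings)

    @field_validator("parameters", mode="before")
    @classmethod
    def _name_params(cls, v):
        if isinstance(v, dict):
            out = {}
            for k, spec in v.items():
                if isinstance(spec, dict) and "name" not in spec:
                    spec = {**spec, "name": k}
                out[k] = spec
            return out
        return v

    @model_validator(mode="after")
    def _fill_and_check(self) -> "ModelConfig":
        # Table-default parameters fill any the user omitted
        defaults = table_defaults()
        for k, spec in defaults.items():
            self.parameters.setdefault(k, spec)
        s = self.structure
        refs = [
            s.atd_failure_param,
            s.relapse_param,
            s.hypothyroidism_param,
            s.acute_cost_param,
            s.atd_cost_param,
            s.hypothyroid_cost_param,
            s.tft_fee_param,
            s.atd_utility_param,
            s.hypothyroid_utility_param,
            s.remission_utility_param,
            self.intervention.sensitivity_param,
            self.intervention.specificity_param,
            self.intervention.monthly_fee_param,
            *s.complication_params.values(),
            *s.complication_cost_params.values(),
            *s.complication_utility_params.values(),
        ]
        missing = sorted({r for r in refs if r not in self.parameters})
        if missing:
            raise ValueError(f"structure references unknown parameters: {missing}")
        if self.cohort.start_state not in self.states:
            raise ValueError(f"unknown start state {self.cohort.start_state!r}")
        return self

    # -- convenience accessors ------------------------------------------
    def p(self, name: str) -> ParameterSpec:
        return self.parameters[name]

    def value(self, name: str) -> float:
        return self.parameters[name].base

    def annual(self, name: str) -> float:
        return self.parameters[name].annual

    def with_updates(self, **kwargs) -> "ModelConfig":
        """Deep copy with dotted-path overrides, e.g.
        ``with_updates(**{"parameters.relapse.base": 0.4})``."""
        data = self.model_dump()
        for path, val in kwargs.items():
            keys = path.split(".")
            node = data
            for k in keys[:-1]:
                node = node[k]
            node[keys[-1]] = val
        return ModelConfig.model_validate(data)


# ---------------------------------------------------------------------------
# default (base-case) parameter set


def _p(name, role, base, low, high, dist, horizon=None) -> ParameterSpec:
    return ParameterSpec(
        name=name, role=role, base=base, low=low, high=high,
        distribution=dist, horizon_years=horizon,
    )


def table_defaults() -> dict[str, ParameterSpec]:
    """The base-case parameter set (2022 USD, South Korean inputs)."""
    tp = ParameterRole.transition_probability
    tc = ParameterRole.test_characteristic
    ut = ParameterRole.utility
    ac = ParameterRole.annual_cost
    oc = ParameterRole.one_time_cost
    rt = ParameterRole.rate
    items = [
        # epidemiology / transition probabilities
        _p("prevalence_hyperthyroidism", tp, 0.072, 0.0576, 0.0864, "beta"),
        _p("atd_failure", tp, 0.05, 0.04, 0.06, "beta", horizon=1.5),
        _p("hypothyroidism", tp, 0.029, 0.0232, 0.0348, "beta", horizon=10.2),
        _p("relapse", tp, 0.528, 0.4224, 0.6336, "beta", horizon=3.73),
        _p("tao", tp, 0.25, 0.20, 0.30, "beta"),
        _p("atrial_fibrillation", tp, 0.043, 0.03, 0.05, "beta"),
        _p("heart_failure", tp, 0.016, 0.011, 0.021, "beta"),
        _p("osteoporosis", tp, 0.0159, 0.0109, 0.0209, "beta"),
        _p("fracture", tp, 0.033, 0.028, 0.038, "beta"),
        _p("thyroid_cancer", tp, 0.0123, 0.009, 0.02, "beta"),
        # test characteristics
        _p("digital_sensitivity", tc, 0.8713, 0.784, 0.958, "beta"),
        _p("digital_specificity", tc, 0.8378, 0.754, 0.9215, "beta"),
        _p("tft_sensitivity", tc, 1.0, 1.0, 1.0, "fixed"),
        _p("tft_specificity", tc, 1.0, 1.0, 1.0, "fixed"),
        # utility weights
        _p("u_thyroid_cancer", ut, 0.897, 0.852, 0.941, "beta"),
        _p("u_hypothyroid", ut, 0.9479, 0.902, 0.997, "beta"),
        _p("u_tao", ut, 0.84, 0.798, 0.882, "beta"),
        _p("u_hyperthyroid_atd", ut, 0.86, 0.817, 0.903, "beta"),
        _p("u_osteoporosis", ut, 0.91, 0.8645, 0.9555, "beta"),
        _p("u_fracture", ut, 0.83, 0.7885, 0.8715, "beta"),
        _p("u_atrial_fibrillation", ut, 0.81, 0.729, 0.891, "beta"),
        _p("u_heart_failure", ut, 0.78, 0.702, 0.858, "beta"),
        _p("u_remission", ut, 1.0, 1.0, 1.0, "fixed"),
        # annual and one-time costs (2022 USD)
        _p("c_acute_initial", oc, 1125.15, 1012.64, 1237.67, "gamma"),
        _p("c_tao", ac, 386.77, 367.44, 406.11, "gamma"),
        _p("c_atrial_fibrillation", ac, 150.54, 143.02, 158.07, "gamma"),
        _p("c_heart_failure", ac, 439.63, 417.65, 461.61, "gamma"),
        _p("c_osteoporosis", ac, 208.49, 198.07, 218.91, "gamma"),
        _p("c_fracture", ac, 347.41, 330.04, 364.78, "gamma"),
        _p("c_thyroid_cancer", ac, 149.23, 141.77, 156.69, "gamma"),
        _p("c_hypothyroid", ac, 250.37, 225.34, 275.41, "gamma"),
        _p("c_atd_annual", ac, 48.87, 43.98, 53.76, "gamma"),
        _p("subscription_monthly", ac, 30.0, 10.0, 50.0, "gamma"),
        _p("c_tft", ac, 92.44, 64.71, 120.17, "gamma"),
        # economics
        _p("discount_rate", rt, 0.045, 0.03, 0.05, "fixed"),
    ]
    return {spec.name: spec for spec in items}


def default_config() -> ModelConfig:
    """The packaged base-case model configuration."""
    return ModelConfig(parameters=table_defaults())


# ---------------------------------------------------------------------------
# (de)serialization


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration from a YAML/JSON file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def config_digest(config: ModelConfig) -> str:
    """Stable SHA-256 digest of a configuration (for run manifests)."""
    blob = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
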