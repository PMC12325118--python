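"""Background mortality and analytically solvable toy fixtures.

The disease model needs an external input — age-specific all-cause mortality.
Because the original national life table is an external dataset, this module
ships a synthetic parametric stand-in: a Gompertz-Makeham hazard
``mu(x) = a + b * exp(eta * x)`` whose defaults are calibrated qualitatively
to modern East-Asian longevity (residual life expectancy at 40 of roughly
43 years).  A CSV hook (:func:`load_life_table`) accepts a real life table
with 1-year ages.

The toy model configurations (:func:`make_toy_config`) are miniature
versions of the disease model whose expected discounted life years, QALYs
and costs have closed forms (:func:`toy_expected_values`); they are the
independent oracle for the simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, MortalitySettings, default_config

__all__ = [
    "MAX_AGE",
    "LifeTable",
    "MortalityModel",
    "make_life_table",
    "load_life_table",
    "life_table_for",
    "make_toy_config",
    "toy_expected_values",
]

#: table closure age: death is certain at this age
MAX_AGE = 110


@dataclass(frozen=True)
class MortalityModel:
    """Gompertz-Makeham hazard mu(x) = a + b * exp(eta * x)."""

    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_eta: float = 0.095

    def __post_init__(self):
        if self.makeham_a < 0 or self.gompertz_b <= 0 or self.gompertz_eta <= 0:
            raise ValueError("Gompertz-Makeham parameters out of range")

    def hazard(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.makeham_a + self.gompertz_b * np.exp(self.gompertz_eta * age)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx for integer ages 0..MAX_AGE."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.shape != qx.shape:
            raise ValueError("ages and qx must have equal length")
        if not np.array_equal(ages, np.arange(0, MAX_AGE + 1)):
            raise ValueError(f"life table must cover integer ages 0..{MAX_AGE}")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError(f"life table must close with qx({MAX_AGE}) = 1")

    def q(self, age: int) -> float:
        """Death probability at an integer age (certain beyond the table)."""
        if age >= MAX_AGE:
            return 1.0
        return float(self.qx[age])

    def survival(self, from_age: int = 0) -> np.ndarray:
        """S(k): probability of surviving k further years from ``from_age``."""
        q = self.qx[from_age:]
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    def life_expectancy(self, age: int = 0) -> float:
        """Expected residual whole years of life at ``age``."""
        return float(self.survival(age)[1:].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def make_life_table(model: MortalityModel | None = None) -> LifeTable:
    """Build a full life table from a parametric mortality model.

    qx(x) = 1 - exp(-mu(x)) under a piecewise-constant hazard per year of
    age, with closure (qx = 1) at the terminal age.
    """
    model = model or MortalityModel()
    ages = np.arange(0, MAX_AGE + 1)
    qx = 1.0 - np.exp(-model.hazard(ages))
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def load_life_table(path) -> LifeTable:
    """Read a (age, qx) CSV with a header row; 1-year ages required.

    Ages missing at the old end are extrapolated to closure by carrying the
    last observed qx forward and forcing qx = 1 at the terminal age.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("life table CSV needs (age, qx) columns")
    ages = df.iloc[:, 0].to_numpy(dtype=float)
    qx = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("life table ages must be strictly increasing")
    if np.any(ages != np.round(ages)):
        raise ValueError("life table requires integer (1-year) ages")
    if np.any((qx < 0) | (qx > 1)):
        raise ValueError("life table qx values must lie in [0, 1]")
    ages = ages.astype(int)
    if ages[0] != 0 or np.any(np.diff(ages) != 1):
        raise ValueError("life table must start at age 0 with consecutive ages")
    full_q = np.empty(MAX_AGE + 1)
    upto = min(ages[-1], MAX_AGE)
    full_q[: upto + 1] = qx[: upto + 1]
    full_q[upto + 1 :] = qx[upto] if upto < MAX_AGE else 1.0
    full_q[MAX_AGE] = 1.0
    return LifeTable(ages=np.arange(0, MAX_AGE + 1), qx=full_q)


def life_table_for(settings: MortalitySettings) -> LifeTable:
    """Resolve the life table named by a config mortality block."""
    if settings.kind == "gompertz_makeham":
        return make_life_table(
            MortalityModel(settings.makeham_a, settings.gompertz_b, settings.gompertz_eta)
        )
    if settings.kind == "flat":
        qx = np.full(MAX_AGE + 1, settings.flat_q)
        qx[-1] = 1.0
        return LifeTable(ages=np.arange(0, MAX_AGE + 1), qx=qx)
    return load_life_table(settings.path)


# ---------------------------------------------------------------------------
# toy fixtures


def make_toy_config(
    kind: str,
    death_prob: float = 0.1,
    discount_rate: float = 0.045,
    relapse_prob: float = 0.2,
    relapse_cost: float = 100.0,
    relapse_utility: float = 0.8,
) -> ModelConfig:
    """Miniature model configurations with closed-form expectations.

    ``two_state``: a single alive state (long-term remission, utility 1, no
    costs) and death at a constant annual probability — expected discounted
    life years are a geometric series.

    ``three_state``: start in remission with a constant annual relapse
    probability; relapse is absorbing apart from death and carries its own
    cost and utility; surviving the relapse-free window moves the patient to
    long-term remission.
    """
    if kind not in ("two_state", "three_state"):
        raise ValueError(f"unknown toy kind {kind!r}")
    cfg = default_config()
    zeroed = {}
    # strip every clinical event except the ones the toy exercises
    for name in (
        "atd_failure",
        "hypothyroidism",
        "tao",
        "atrial_fibrillation",
        "heart_failure",
        "osteoporosis",
        "fracture",
        "thyroid_cancer",
    ):
        zeroed[f"parameters.{name}.base"] = 0.0
        zeroed[f"parameters.{name}.low"] = 0.0
        zeroed[f"parameters.{name}.high"] = 0.0
        zeroed[f"parameters.{name}.distribution"] = "fixed"
        zeroed[f"parameters.{name}.horizon_years"] = None
    for name in ("c_acute_initial", "c_atd_annual", "c_hypothyroid", "c_tft",
                 "subscription_monthly"):
        zeroed[f"parameters.{name}.base"] = 0.0
        zeroed[f"parameters.{name}.low"] = 0.0
        zeroed[f"parameters.{name}.high"] = 0.0
        zeroed[f"parameters.{name}.distribution"] = "fixed"
    relapse_p = relapse_prob if kind == "three_state" else 0.0
    overrides = {
        "parameters.relapse.base": relapse_p,
        "parameters.relapse.low": relapse_p,
        "parameters.relapse.high": relapse_p,
        "parameters.relapse.horizon_years": None,
        "parameters.relapse.distribution": "fixed",
        "parameters.c_atd_annual.base": relapse_cost,
        "parameters.c_atd_annual.low": relapse_cost,
        "parameters.c_atd_annual.high": relapse_cost,
        "parameters.u_hyperthyroid_atd.base": relapse_utility,
        "parameters.u_hyperthyroid_atd.low": relapse_utility,
        "parameters.u_hyperthyroid_atd.high": relapse_utility,
        "parameters.u_hyperthyroid_atd.distribution": "fixed",
        "economics.discount_rate": discount_rate,
        "structure.subsequent_remission_prob": 0.0,
        "cohort.start_age": 0,
        "cohort.max_cycles": MAX_AGE,
        "cohort.start_state": (
            "long_term_remission" if kind == "two_state" else "remission"
        ),
        "mortality.kind": "flat",
        "mortality.flat_q": death_prob,
    }
    return cfg.with_updates(**{**zeroed, **overrides})


def toy_expected_values(
    kind: str,
    death_prob: float = 0.1,
    discount_rate: float = 0.045,
    relapse_prob: float = 0.2,
    relapse_cost: float = 100.0,
    relapse_utility: float = 0.8,
    window: int = 5,
    max_cycles: int = MAX_AGE,
) -> dict[str, float]:
    """Closed-form expectations for the toy configurations.

    Derived directly from geometric series (not from the engine): accrual
    happens at the start of each annual cycle with discount factor
    ``(1+r)^-k``, death is drawn after accrual, so the expected discounted
    years in an absorbing alive state are ``sum_k ((1-d)/(1+r))^k``.
    """
    d, r, p = death_prob, discount_rate, relapse_prob
    nu = 1.0 / (1.0 + r)
    x = (1.0 - d) * nu

    def geo(q, n):  # sum_{k=0}^{n-1} q^k
        if q == 1.0:
            return float(n)
        return (1.0 - q ** n) / (1.0 - q)

    if kind == "two_state":
        ly = geo(x, max_cycles)
        return {
            "life_years_discounted": ly,
            "qalys_discounted": ly,
            "cost_discounted": 0.0,
            "life_years_discounted_infinite": 1.0 / (1.0 - x) if x < 1 else np.inf,
        }
    if kind != "three_state":
        raise ValueError(f"unknown toy kind {kind!r}")
    y = (1.0 - d) * (1.0 - p) * nu
    # remission occupancy: cycles 0..window-1 with survival and no relapse
    rem = geo(y, window)
    # long-term remission: entered at cycle `window` by the relapse-free
    ltr_mass = ((1.0 - d) * (1.0 - p)) ** window
    ltr = ltr_mass * nu ** window * geo(x, max_cycles - window)
    # relapse entered at cycle j+1 after a relapse event during cycle j
    rel = 0.0
    for j in range(window):
        mass = ((1.0 - d) * (1.0 - p)) ** j * (1.0 - d) * p
        rel += mass * nu ** (j + 1) * geo(x, max_cycles - j - 1)
    return {
        "life_years_discounted": rem + ltr + rel,
        "qalys_discounted": rem + ltr + relapse_utility * rel,
        "cost_discounted": relapse_cost * rel,
        "remission_years_discounted": rem,
        "ltr_years_discounted": ltr,
        "relapse_years_discounted": rel,
    }
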