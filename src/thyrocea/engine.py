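"""Patient-level simulation of the hyperthyroidism disease course.

The disease model is a discrete-time semi-Markov process with annual cycles.
Patients start on an initial antithyroid-drug (ATD) course; treatment
failure routes to definitive therapy (modelled as lifelong hypothyroidism),
completion routes to remission.  Remission carries a relapse risk for a
fixed window of years; surviving the window relapse-free confers long-term
remission (absorbing apart from death).  Relapses either restart a short
ATD course (when caught early by digital monitoring) or move to long-term
ATD, from which an annual subsequent-remission chance applies.  Major
complications are tagged during active-disease states and add an annual
cost and a utility decrement for life.  Background mortality acts on every
state through an age-indexed life table.

Two evaluation routes are provided for the same process:

* :func:`simulate_cohort` — stochastic microsimulation, vectorised over
  patients, reproducible from a seed, with a fixed per-cycle random-number
  layout so that both arms can share patient-level streams (common random
  numbers).
* :func:`cohort_expectation` — the exact expectation of the identical
  process, obtained by expanding the clocks into tunnel states and
  propagating the state-occupancy distribution.  Microsimulation means must
  converge to this oracle; it also powers the deterministic sensitivity and
  threshold analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import CLASSIFICATION_LABELS, COMPLICATION_TYPES, ModelConfig, prob_to_annual
from .population import MAX_AGE, life_table_for

__all__ = [
    "ATD_INITIAL",
    "ATD_RETREAT",
    "REMISSION",
    "LONG_TERM_REMISSION",
    "RELAPSE",
    "HYPOTHYROID",
    "DEAD",
    "STATE_NAMES",
    "Dynamics",
    "compile_dynamics",
    "PatientRecord",
    "step_patient",
    "CohortResult",
    "simulate_cohort",
    "classify_flags",
    "classify_trajectory",
    "ExpectationResult",
    "cohort_expectation",
]

ATD_INITIAL = 0
ATD_RETREAT = 1
REMISSION = 2
LONG_TERM_REMISSION = 3
RELAPSE = 4
HYPOTHYROID = 5
DEAD = 6

STATE_NAMES = [
    "on_atd_initial",
    "on_atd_retreat",
    "remission",
    "long_term_remission",
    "relapse_on_long_term_atd",
    "hypothyroid",
    "dead",
]
_STATE_CODE = {n: i for i, n in enumerate(STATE_NAMES)}

#: per-cycle uniform-draw layout, identical in both arms so that common
#: random numbers give identical trajectories under a null intervention
#: 0 death | 1..6 complication draws | 7 primary transition | 8 secondary
#: (induced hypothyroidism / relapse detection) | 9 subsequent remission |
#: 10 false-positive monitoring visit
N_DRAWS = 11


# ---------------------------------------------------------------------------
# compiled arm dynamics


@dataclass
class Dynamics:
    """Plain-number view of one arm of a :class:`ModelConfig`."""

    arm: str
    course_years: int
    window: int
    p_fail: float
    p_fail_relapse: float
    p_ih: float                      # ATD-induced hypothyroidism, annual
    p_rel: float                     # annual relapse probability (arm-effective)
    detect: float                    # P(relapse caught early) -> retreat course
    s: float                         # subsequent-remission probability (arm-effective)
    hz_initial: np.ndarray           # complication hazards on the initial course
    hz_active: np.ndarray            # complication hazards in other active states
    acute_cost: float
    atd_cost: float
    hypo_cost: float
    compl_cost: np.ndarray           # length 7, index 0 = none
    monitor_flat: float              # per alive cycle
    fp_prob: float                   # extra-visit probability in non-hyperthyroid states
    fp_fee: float
    extra_cost: float
    u_atd: float
    u_hypo: float
    u_rem: float
    compl_util: np.ndarray           # length 7, index 0 = 1.0
    discount_rate: float
    start_age: int
    max_cycles: int
    start_state: int
    qx: np.ndarray                   # indexed by age, closure at MAX_AGE
    priority: list[str] = field(default_factory=lambda: list(CLASSIFICATION_LABELS[:-1]))

    @property
    def state_cost(self) -> np.ndarray:
        out = np.zeros(len(STATE_NAMES))
        out[ATD_INITIAL] = self.atd_cost
        out[ATD_RETREAT] = self.atd_cost
        out[RELAPSE] = self.atd_cost
        out[HYPOTHYROID] = self.hypo_cost
        return out

    @property
    def state_util(self) -> np.ndarray:
        out = np.zeros(len(STATE_NAMES))
        out[ATD_INITIAL] = out[ATD_RETREAT] = out[RELAPSE] = self.u_atd
        out[REMISSION] = out[LONG_TERM_REMISSION] = self.u_rem
        out[HYPOTHYROID] = self.u_hypo
        return out

    def q_at(self, age: int) -> float:
        if age >= MAX_AGE:
            return 1.0
        return float(self.qx[age])


def _clamp01(x: float, what: str) -> float:
    if x < 0.0 or x > 1.0:
        import logging

        logging.getLogger("thyrocea").warning(
            "%s = %.4f outside [0, 1]; clamped", what, x
        )
        return min(max(x, 0.0), 1.0)
    return x


def compile_dynamics(
    config: ModelConfig,
    arm: str = "control",
    overrides: Optional[dict[str, float]] = None,
) -> Dynamics:
    """Resolve one arm of the model into plain transition/accrual numbers.

    ``overrides`` maps parameter names (plus the pseudo-names
    ``discount_rate``, ``subsequent_remission_prob``) to replacement base
    values — the fast path used by sensitivity analyses.
    """
    if arm not in ("control", "digital"):
        raise ValueError(f"unknown arm {arm!r}")
    ov = overrides or {}
    params = config.parameters
    st = config.structure
    iv = config.intervention

    def val(name: str) -> float:
        return float(ov.get(name, params[name].base))

    def annual(name: str) -> float:
        spec = params[name]
        base = val(name)
        if spec.horizon_years in (None, 1.0):
            return base
        return prob_to_annual(base, spec.horizon_years)

    p_fail = annual(st.atd_failure_param)
    p_ih = annual(st.hypothyroidism_param)
    p_rel = annual(st.relapse_param)
    s = st.subsequent_remission_prob
    if "subsequent_remission_prob" in ov:
        s = float(ov["subsequent_remission_prob"])
    detect = 0.0
    sens = iv.sensitivity if iv.sensitivity is not None else val(iv.sensitivity_param)
    spec_ = iv.specificity if iv.specificity is not None else val(iv.specificity_param)
    fee = iv.monthly_fee if iv.monthly_fee is not None else val(iv.monthly_fee_param)
    tft = val(st.tft_fee_param)
    if arm == "digital":
        p_rel = _clamp01(p_rel * iv.effect_relapse_multiplier, "digital relapse probability")
        s = _clamp01(s * iv.effect_remission_uplift, "digital subsequent-remission probability")
        detect = sens
        monitor_flat = 12.0 * fee + tft * (1.0 - iv.visit_cost_reduction)
        fp_prob = 1.0 - spec_
        extra = st.extra_annual_cost_digital
    else:
        monitor_flat = tft
        fp_prob = 0.0
        extra = st.extra_annual_cost_control

    # thyroid-associated orbitopathy: one-time risk spread over the first
    # `course_years` active years; other complications: annual incidences
    # in every active-disease state
    cy = st.atd_course_years
    p_tao = val(st.complication_params["tao"])
    h_tao = 1.0 - (1.0 - p_tao) ** (1.0 / cy) if p_tao < 1.0 else 1.0
    hz_initial = np.zeros(len(COMPLICATION_TYPES))
    hz_active = np.zeros(len(COMPLICATION_TYPES))
    for j, c in enumerate(COMPLICATION_TYPES):
        if c == "tao":
            hz_initial[j] = h_tao
            hz_active[j] = 0.0
        else:
            hz_initial[j] = hz_active[j] = val(st.complication_params[c])

    compl_cost = np.zeros(len(COMPLICATION_TYPES) + 1)
    compl_util = np.ones(len(COMPLICATION_TYPES) + 1)
    for j, c in enumerate(COMPLICATION_TYPES):
        compl_cost[j + 1] = val(st.complication_cost_params[c])
        compl_util[j + 1] = val(st.complication_utility_params[c])

    rate = float(ov.get("discount_rate", config.economics.discount_rate))
    lt = life_table_for(config.mortality)
    return Dynamics(
        arm=arm,
        course_years=cy,
        window=st.remission_window_years,
        p_fail=p_fail,
        p_fail_relapse=p_fail if st.atd_failure_in_relapse else 0.0,
        p_ih=p_ih,
        p_rel=p_rel,
        detect=detect,
        s=s,
        hz_initial=hz_initial,
        hz_active=hz_active,
        acute_cost=val(st.acute_cost_param),
        atd_cost=val(st.atd_cost_param),
        hypo_cost=val(st.hypothyroid_cost_param),
        compl_cost=compl_cost,
        monitor_flat=monitor_flat,
        fp_prob=fp_prob,
        fp_fee=tft,
        extra_cost=extra,
        u_atd=val(st.atd_utility_param),
        u_hypo=val(st.hypothyroid_utility_param),
        u_rem=val(st.remission_utility_param),
        compl_util=compl_util,
        discount_rate=rate,
        start_age=config.cohort.start_age,
        max_cycles=config.cohort.max_cycles,
        start_state=_STATE_CODE[config.cohort.start_state],
        qx=lt.qx,
        priority=list(st.classification_priority),
    )


# ---------------------------------------------------------------------------
# microsimulation


def _new_cohort_arrays(dyn: Dynamics, n: int) -> dict:
    state = np.full(n, dyn.start_state, dtype=np.int8)
    return {
        "state": state,
        "yis": np.zeros(n, dtype=np.int16),
        "rfy": np.zeros(n, dtype=np.int16),
        "compl": np.zeros(n, dtype=np.int8),
        "ever_hypo": state == HYPOTHYROID,
        "ever_ltr": state == LONG_TERM_REMISSION,
        "ever_rel": state == RELAPSE,
        "disc_cost": np.zeros(n),
        "disc_qaly": np.zeros(n),
    }


def _cycle_step(S: dict, dyn: Dynamics, k: int, u: np.ndarray) -> None:
    """Advance every patient by one annual cycle (in place).

    Order of events: accrual at cycle start (full-cycle, no half-cycle
    correction), death draw, complication draw, state transition.
    ``u`` has shape (N_DRAWS, n).
    """
    state = S["state"]
    alive = state != DEAD
    df = (1.0 + dyn.discount_rate) ** (-k)

    # --- accrual -------------------------------------------------------
    cost = dyn.state_cost[state]
    first_year = alive & (state == ATD_INITIAL) & (S["yis"] == 0)
    cost[first_year] = dyn.acute_cost
    cost += dyn.compl_cost[S["compl"]]
    cost += dyn.monitor_flat + dyn.extra_cost
    if dyn.fp_prob > 0.0:
        nonhyper = (state == REMISSION) | (state == LONG_TERM_REMISSION) | (
            state == HYPOTHYROID
        )
        cost += dyn.fp_fee * (nonhyper & (u[10] < dyn.fp_prob))
    util = np.minimum(dyn.state_util[state], dyn.compl_util[S["compl"]])
    S["disc_cost"] += np.where(alive, cost, 0.0) * df
    S["disc_qaly"] += np.where(alive, util, 0.0) * df

    # --- death ---------------------------------------------------------
    q = dyn.q_at(dyn.start_age + k)
    dies = alive & (u[0] < q)
    state[dies] = DEAD
    alive = alive & ~dies

    # --- complication onset (active-disease states only) --------------
    st0 = state.copy()
    active = alive & (S["compl"] == 0) & (
        (st0 == ATD_INITIAL) | (st0 == ATD_RETREAT) | (st0 == RELAPSE)
    )
    if active.any():
        on_initial = st0 == ATD_INITIAL
        for j in range(len(COMPLICATION_TYPES)):
            hz = np.where(on_initial, dyn.hz_initial[j], dyn.hz_active[j])
            hit = active & (S["compl"] == 0) & (u[1 + j] < hz)
            S["compl"][hit] = j + 1

    # --- transitions (based on the pre-transition state) ---------------
    # ATD courses: failure or induced hypothyroidism -> hypothyroid;
    # completing the course -> remission with a fresh relapse-free clock
    on_course = alive & ((st0 == ATD_INITIAL) | (st0 == ATD_RETREAT))
    fail = on_course & (u[7] < dyn.p_fail)
    ih = on_course & ~fail & (u[8] < dyn.p_ih)
    to_hypo = fail | ih
    state[to_hypo] = HYPOTHYROID
    S["ever_hypo"] |= to_hypo
    stay = on_course & ~to_hypo
    done = stay & (S["yis"] + 1 >= dyn.course_years)
    state[done] = REMISSION
    S["rfy"][done] = 0
    S["yis"][done] = 0
    S["yis"][stay & ~done] += 1

    # remission: relapse draw within the window; relapse-free window
    # completion -> long-term remission; early-detected relapse -> retreat
    in_rem = alive & (st0 == REMISSION)
    ltr_now = in_rem & (S["rfy"] >= dyn.window)
    at_risk = in_rem & ~ltr_now
    ev = at_risk & (u[7] < dyn.p_rel)
    det = ev & (u[8] < dyn.detect)
    state[det] = ATD_RETREAT
    S["yis"][det] = 0
    missed = ev & ~det
    state[missed] = RELAPSE
    S["ever_rel"] |= missed
    no_ev = at_risk & ~ev
    S["rfy"][no_ev] += 1
    ltr_now = ltr_now | (no_ev & (S["rfy"] >= dyn.window))
    state[ltr_now] = LONG_TERM_REMISSION
    S["ever_ltr"] |= ltr_now

    # long-term ATD after relapse: failure / induced hypothyroidism ->
    # hypothyroid, else an annual subsequent-remission chance
    in_rel = alive & (st0 == RELAPSE)
    fail_r = in_rel & (u[7] < dyn.p_fail_relapse)
    ih_r = in_rel & ~fail_r & (u[8] < dyn.p_ih)
    to_hypo_r = fail_r | ih_r
    state[to_hypo_r] = HYPOTHYROID
    S["ever_hypo"] |= to_hypo_r
    rem_again = in_rel & ~to_hypo_r & (u[9] < dyn.s)
    state[rem_again] = REMISSION
    S["rfy"][rem_again] = 0


# ---------------------------------------------------------------------------
# scalar patient API


@dataclass
class PatientRecord:
    """One simulated patient between cycles."""

    age: int
    alive: bool = True
    state: str = "on_atd_initial"
    complication: Optional[str] = None
    years_in_state: int = 0
    relapse_free_years: int = 0
    ever_hypothyroid: bool = False
    ever_long_term_remission: bool = False
    ever_relapse: bool = False
    discounted_cost: float = 0.0
    discounted_qaly: float = 0.0


def step_patient(
    p: PatientRecord,
    config: ModelConfig | Dynamics,
    arm: str = "control",
    rng: Optional[np.random.Generator] = None,
) -> PatientRecord:
    """Advance one patient by one annual cycle.

    Consumes exactly :data:`N_DRAWS` uniforms from ``rng`` in the same
    layout as the vectorised cohort path, so a one-patient cohort and a
    ``step_patient`` loop with the same seed are bit-identical.
    """
    if not p.alive:
        raise ValueError("cannot step a dead patient")
    dyn = config if isinstance(config, Dynamics) else compile_dynamics(config, arm)
    if p.state not in STATE_NAMES:
        raise ValueError(f"unknown state {p.state!r}")
    rng = rng or np.random.default_rng()
    k = p.age - dyn.start_age
    S = {
        "state": np.array([_STATE_CODE[p.state]], dtype=np.int8),
        "yis": np.array([p.years_in_state], dtype=np.int16),
        "rfy": np.array([p.relapse_free_years], dtype=np.int16),
        "compl": np.array(
            [0 if p.complication is None else COMPLICATION_TYPES.index(p.complication) + 1],
            dtype=np.int8,
        ),
        "ever_hypo": np.array([p.ever_hypothyroid]),
        "ever_ltr": np.array([p.ever_long_term_remission]),
        "ever_rel": np.array([p.ever_relapse]),
        "disc_cost": np.array([p.discounted_cost]),
        "disc_qaly": np.array([p.discounted_qaly]),
    }
    u = rng.random((N_DRAWS, 1))
    _cycle_step(S, dyn, k, u)
    code = int(S["state"][0])
    return PatientRecord(
        age=p.age + 1,
        alive=code != DEAD,
        state=STATE_NAMES[code],
        complication=None if S["compl"][0] == 0 else COMPLICATION_TYPES[S["compl"][0] - 1],
        years_in_state=int(S["yis"][0]),
        relapse_free_years=int(S["rfy"][0]),
        ever_hypothyroid=bool(S["ever_hypo"][0]),
        ever_long_term_remission=bool(S["ever_ltr"][0]),
        ever_relapse=bool(S["ever_rel"][0]),
        discounted_cost=float(S["disc_cost"][0]),
        discounted_qaly=float(S["disc_qaly"][0]),
    )


# ---------------------------------------------------------------------------
# trajectory classification


def classify_flags(
    had_complication, ever_hypothyroid, ever_long_term_remission, ever_relapse,
    priority: Optional[list[str]] = None,
):
    """Lifetime classification from ever-experienced flags.

    Accepts scalars or boolean arrays; returns label(s).  Exactly one label
    is assigned: the first category in ``priority`` the patient ever
    experienced, else ``"other"``.
    """
    priority = priority or CLASSIFICATION_LABELS[:-1]
    flags = {
        "complication": np.asarray(had_complication),
        "hypothyroid": np.asarray(ever_hypothyroid),
        "long_term_remission": np.asarray(ever_long_term_remission),
        "relapse_on_long_term_atd": np.asarray(ever_relapse),
    }
    shape = flags["complication"].shape
    out = np.full(shape, "other", dtype=object)
    unset = np.ones(shape, dtype=bool)
    for label in priority:
        hit = unset & flags[label].astype(bool)
        out[hit] = label
        unset &= ~hit
    if shape == ():
        return str(out[()])
    return out


def classify_trajectory(history, priority: Optional[list[str]] = None) -> str:
    """Classify a complete simulated history.

    ``history`` is an iterable of (state_name, complication) pairs — one per
    cycle — or of plain state names (no complications).
    """
    states, compls = [], []
    for item in history:
        if isinstance(item, str):
            states.append(item)
            compls.append(None)
        else:
            st, c = item
            states.append(st)
            compls.append(c)
    return classify_flags(
        any(c is not None for c in compls),
        "hypothyroid" in states,
        "long_term_remission" in states,
        "relapse_on_long_term_atd" in states,
        priority,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortResult:
    arm: str
    n: int
    seed: int
    cost: np.ndarray
    qaly: np.ndarray
    classification: np.ndarray      # label per patient

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def se_cost(self) -> float:
        return float(self.cost.std(ddof=1) / np.sqrt(self.n))

    @property
    def se_qaly(self) -> float:
        return float(self.qaly.std(ddof=1) / np.sqrt(self.n))

    @property
    def class_shares(self) -> dict[str, float]:
        return {
            lab: float(np.mean(self.classification == lab))
            for lab in CLASSIFICATION_LABELS
        }

    def class_share_se(self, label: str) -> float:
        p = self.class_shares[label]
        return float(np.sqrt(p * (1.0 - p) / self.n))

    def summary(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_qaly": self.mean_qaly,
            "se_qaly": self.se_qaly,
            "class_shares": self.class_shares,
        }


def simulate_cohort(
    config: ModelConfig,
    arm: str = "control",
    n: Optional[int] = None,
    seed: int = 0,
    dynamics: Optional[Dynamics] = None,
) -> CohortResult:
    """Simulate a cohort of patients through their disease course.

    With the same ``seed`` the result is bit-identical.  Running both arms
    with the same seed gives common random numbers: the per-cycle draw
    layout is fixed, so patients experience identical shocks wherever the
    arms' parameters coincide.
    """
    dyn = dynamics if dynamics is not None else compile_dynamics(config, arm)
    n = int(n if n is not None else config.cohort.n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    S = _new_cohort_arrays(dyn, n)
    for k in range(dyn.max_cycles):
        if not (S["state"] != DEAD).any():
            break
        u = rng.random((N_DRAWS, n))
        _cycle_step(S, dyn, k, u)
    labels = classify_flags(
        S["compl"] > 0, S["ever_hypo"], S["ever_ltr"], S["ever_rel"], dyn.priority
    )
    return CohortResult(
        arm=dyn.arm, n=n, seed=seed,
        cost=S["disc_cost"], qaly=S["disc_qaly"], classification=labels,
    )


# ---------------------------------------------------------------------------
# deterministic cohort-expectation oracle


@dataclass
class ExpectationResult:
    arm: str
    expected_cost: float
    expected_qaly: float
    class_shares: dict[str, float]
    occupancy: pd.DataFrame          # cycle x macro-state, rows sum to 1
    discounted_alive_years: float
    expected_life_years: float


def _enumerate_substates(cy: int, W: int):
    """Tunnel-expanded clinical substates (clocks and ever-relapse flag)."""
    subs = []
    for y in range(cy):
        subs.append(("AI", y, 0))
    for e in (0, 1):
        for y in range(cy):
            subs.append(("AR", y, e))
    for e in (0, 1):
        for j in range(W):
            subs.append(("REM", j, e))
    subs.append(("LTR", None, 0))
    subs.append(("LTR", None, 1))
    subs.append(("REL", None, 1))
    subs.append(("HYP", None, 0))
    subs.append(("HYP", None, 1))
    return subs


_MACRO = {
    "AI": "on_atd_initial",
    "AR": "on_atd_retreat",
    "REM": "remission",
    "LTR": "long_term_remission",
    "REL": "relapse_on_long_term_atd",
    "HYP": "hypothyroid",
}


def cohort_expectation(
    config: ModelConfig,
    arm: str = "control",
    dynamics: Optional[Dynamics] = None,
) -> ExpectationResult:
    """Exact expected outcomes of the simulated process.

    Expands the semi-Markov clocks (ATD course year, relapse-free years,
    ever-relapsed flag, complication tag) into a finite Markov state space
    and propagates the occupancy distribution over the horizon, accruing
    discounted expected costs and QALYs with the same event ordering as the
    microsimulation (accrual, death, complication onset, transition).
    """
    dyn = dynamics if dynamics is not None else compile_dynamics(config, arm)
    cy, W = dyn.course_years, dyn.window
    subs = _enumerate_substates(cy, W)
    nc = len(subs)
    idx = {s: i for i, s in enumerate(subs)}
    ncomp = len(COMPLICATION_TYPES)
    nx = nc * (ncomp + 1)

    # clinical transition matrix (survival-conditional, complication-free)
    s_clin = np.zeros((nc, nc))
    ph_course = dyn.p_fail + (1.0 - dyn.p_fail) * dyn.p_ih
    ph_rel = dyn.p_fail_relapse + (1.0 - dyn.p_fail_relapse) * dyn.p_ih
    p_rem_back = (1.0 - ph_rel) * dyn.s
    for i, (kind, clock, e) in enumerate(subs):
        if kind in ("AI", "AR"):
            s_clin[i, idx[("HYP", None, e)]] += ph_course
            nxt = ("REM", 0, e) if clock + 1 >= cy else (kind, clock + 1, e)
            s_clin[i, idx[nxt]] += 1.0 - ph_course
        elif kind == "REM":
            ev = dyn.p_rel
            s_clin[i, idx[("AR", 0, e)]] += ev * dyn.detect
            s_clin[i, idx[("REL", None, 1)]] += ev * (1.0 - dyn.detect)
            nxt = ("LTR", None, e) if clock + 1 >= W else ("REM", clock + 1, e)
            s_clin[i, idx[nxt]] += 1.0 - ev
        elif kind == "REL":
            s_clin[i, idx[("HYP", None, 1)]] += ph_rel
            s_clin[i, idx[("REM", 0, 1)]] += p_rem_back
            s_clin[i, i] += 1.0 - ph_rel - p_rem_back
        else:  # LTR, HYP absorbing apart from death
            s_clin[i, i] = 1.0
    S = np.kron(s_clin, np.eye(ncomp + 1))

    # complication-onset matrix: sequential first-hit draws, listed order
    C = np.eye(nx)
    for i, (kind, clock, e) in enumerate(subs):
        if kind not in ("AI", "AR", "REL"):
            continue
        hz = dyn.hz_initial if kind == "AI" else dyn.hz_active
        base = i * (ncomp + 1)
        remaining = 1.0
        C[base, base] = 0.0
        for j in range(ncomp):
            C[base, base + j + 1] = remaining * hz[j]
            remaining *= 1.0 - hz[j]
        C[base, base] = remaining
    T = C @ S

    # death buckets by classification priority
    def bucket(sub, comp) -> str:
        kind, clock, e = sub
        flags = {
            "complication": comp > 0,
            "hypothyroid": kind == "HYP",
            "long_term_remission": kind == "LTR",
            "relapse_on_long_term_atd": e == 1,
        }
        for label in dyn.priority:
            if flags[label]:
                return label
        return "other"

    bucket_idx = np.array(
        [
            CLASSIFICATION_LABELS.index(bucket(sub, comp))
            for sub in subs
            for comp in range(ncomp + 1)
        ]
    )
    bucket_onehot = np.zeros((nx, len(CLASSIFICATION_LABELS)))
    bucket_onehot[np.arange(nx), bucket_idx] = 1.0

    # accrual vectors
    cost_vec = np.zeros(nx)
    util_vec = np.zeros(nx)
    for i, (kind, clock, e) in enumerate(subs):
        if kind == "AI":
            base_cost = dyn.acute_cost if clock == 0 else dyn.atd_cost
            u = dyn.u_atd
        elif kind == "AR":
            base_cost, u = dyn.atd_cost, dyn.u_atd
        elif kind == "REL":
            base_cost, u = dyn.atd_cost, dyn.u_atd
        elif kind == "HYP":
            base_cost, u = dyn.hypo_cost, dyn.u_hypo
        else:
            base_cost, u = 0.0, dyn.u_rem
        nonhyper = kind in ("REM", "LTR", "HYP")
        for comp in range(ncomp + 1):
            j = i * (ncomp + 1) + comp
            c = base_cost + dyn.compl_cost[comp] + dyn.monitor_flat + dyn.extra_cost
            if nonhyper:
                c += dyn.fp_prob * dyn.fp_fee
            cost_vec[j] = c
            util_vec[j] = min(u, dyn.compl_util[comp])

    start_map = {
        ATD_INITIAL: ("AI", 0, 0),
        ATD_RETREAT: ("AR", 0, 0),
        REMISSION: ("REM", 0, 0),
        LONG_TERM_REMISSION: ("LTR", None, 0),
        RELAPSE: ("REL", None, 1),
        HYPOTHYROID: ("HYP", None, 0),
    }
    v = np.zeros(nx)
    v[idx[start_map[dyn.start_state]] * (ncomp + 1)] = 1.0
    dead = np.zeros(len(CLASSIFICATION_LABELS))

    nu = 1.0 / (1.0 + dyn.discount_rate)
    exp_cost = exp_qaly = alive_disc = life_years = 0.0
    macro_names = [_MACRO[k] for k in ("AI", "AR", "REM", "LTR", "REL", "HYP")]
    macro_of = np.array(
        [macro_names.index(_MACRO[sub[0]]) for sub in subs for _ in range(ncomp + 1)]
    )
    occ_rows = []
    for k in range(dyn.max_cycles):
        df = nu ** k
        tot = v.sum()
        exp_cost += df * float(v @ cost_vec)
        exp_qaly += df * float(v @ util_vec)
        alive_disc += df * tot
        life_years += tot
        occ = np.bincount(macro_of, weights=v, minlength=len(macro_names))
        occ_rows.append(np.concatenate([occ, [dead.sum()]]))
        q = dyn.q_at(dyn.start_age + k)
        dead += q * (v @ bucket_onehot)
        v = (1.0 - q) * (v @ T)
    # survivors at the horizon keep their classification
    shares = dead + v @ bucket_onehot
    occupancy = pd.DataFrame(
        occ_rows, columns=macro_names + ["dead"],
    )
    occupancy.index.name = "cycle"
    return ExpectationResult(
        arm=dyn.arm,
        expected_cost=exp_cost,
        expected_qaly=exp_qaly,
        class_shares={lab: float(shares[i]) for i, lab in enumerate(CLASSIFICATION_LABELS)},
        occupancy=occupancy,
        discounted_alive_years=alive_disc,
        expected_life_years=life_years,
    )
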