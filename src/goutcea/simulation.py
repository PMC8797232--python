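"""One-year, daily-cycle patient-level Markov engine and its exact oracle.

A simulated patient enters the model on urate-lowering therapy (ULT) and,
in the base case, in the middle of a gout flare.  On day 0 the patient is
assigned once to the on-target branch (serum urate < 0.36 mmol/L, with
probability depending on the ULT) or the off-target branch; the branch is
fixed for the whole year.  On every flare-free day a new flare starts with
the branch-specific daily hazard (onset the next day, by default in severe
pain).  A flare lasts exactly seven days, during which the pain state
evolves daily under the transition matrix of the chosen anti-inflammatory
drug, then the patient returns to the no-flare state; flares cannot nest,
and an episode that would overrun the horizon is truncated at day 364.

Costs (ULT drug every day, flare drug on flare days, per-state "other"
costs) are discounted at 4 %/year, utility at 1.5 %/year, with daily
factors (1+r)^(-day/365).  QALYs accrue as the state utility weight / 365
per day, minus a constant daily decrement in the off-target branch.

:func:`expected_outcomes_exact` propagates the exact day-indexed state
distribution (no-flare plus pain-state x flare-day) and serves as the
dynamic-programming oracle for the microsimulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterDraw, ParameterError
from .states import N_PAIN_STATES, NO_FLARE, PAIN_STATE_NAMES, FLARE_DRUGS, PainState, ULT_OPTIONS, ULT_DRUG_COST_KEY

__all__ = [
    "Strategy",
    "SimConfig",
    "CohortOutcome",
    "CohortExpectation",
    "SimulationError",
    "assign_branch",
    "daily_flare_hazard",
    "step_flare",
    "accrue_day",
    "simulate_patient",
    "simulate_cohort",
    "expected_outcomes_exact",
    "discount_factors",
    "draw_cohort_uniforms",
]


class SimulationError(ValueError):
    """Invalid simulation configuration or state."""


@dataclass(frozen=True)
class Strategy:
    """A (ULT, flare drug) treatment combination; fixed for the horizon."""

    ult: str
    flare_drug: str

    def __post_init__(self) -> None:
        if self.ult not in ULT_OPTIONS:
            raise SimulationError(f"unknown ULT {self.ult!r}")
        if self.flare_drug not in FLARE_DRUGS:
            raise SimulationError(f"unknown flare drug {self.flare_drug!r}")

    @property
    def name(self) -> str:
        return f"{self.ult}+{self.flare_drug}"

    @classmethod
    def parse(cls, name: str) -> "Strategy":
        ult, _, drug = name.partition("+")
        return cls(ult, drug)


@dataclass(frozen=True)
class SimConfig:
    """Structural run options (as opposed to numeric model parameters)."""

    entry_with_flare: bool = True
    onset_state: PainState = PainState.SEVERE_PAIN
    #: Optional distribution over onset states; overrides ``onset_state``.
    onset_distribution: tuple[float, float, float, float] | None = None
    flare_hazard_multiplier: float = 1.0
    #: Flare drug is costed on each flare day; override to shorten dosing.
    flare_drug_days: int | None = None

    def __post_init__(self) -> None:
        if self.flare_hazard_multiplier < 0:
            raise SimulationError("flare hazard multiplier must be >= 0")
        if self.onset_distribution is not None:
            d = np.asarray(self.onset_distribution, float)
            if d.shape != (N_PAIN_STATES,) or np.any(d < 0) or abs(d.sum() - 1) > 1e-9:
                raise SimulationError("onset distribution must be a probability 4-vector")

    def onset_probs(self) -> np.ndarray:
        if self.onset_distribution is not None:
            return np.asarray(self.onset_distribution, float)
        probs = np.zeros(N_PAIN_STATES)
        probs[int(self.onset_state)] = 1.0
        return probs


@dataclass(frozen=True)
class CohortOutcome:
    """Monte-Carlo mean discounted cost and QALY over a simulated cohort."""

    strategy: Strategy
    mean_cost: float
    mean_qaly: float
    n: int
    draw_index: int = 0
    se_cost: float = 0.0
    se_qaly: float = 0.0
    mean_flares: float = 0.0


@dataclass(frozen=True)
class CohortExpectation:
    """Exact expected discounted cost/QALY at fixed parameters (oracle)."""

    strategy: Strategy
    cost: float
    qaly: float
    expected_flares: float


def discount_factors(rate: float, horizon_days: int) -> np.ndarray:
    """Daily discount factors (1+r)^(-day/365); day 0 is undiscounted."""
    days = np.arange(horizon_days)
    return (1.0 + rate) ** (-days / 365.0)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def assign_branch(
    strategy: Strategy, p_target: float, rng: np.random.Generator | int | None = None
) -> bool:
    """Assign the patient to the on-target branch (True) once, at entry."""
    if not 0.0 <= p_target <= 1.0:
        raise SimulationError(f"p_target outside [0,1]: {p_target}")
    if strategy.ult == "no_ult" and p_target != 0.0:
        raise SimulationError("no_ult patients cannot reach the serum-urate target")
    rng = np.random.default_rng(rng)
    return bool(rng.random() < p_target)


def daily_flare_hazard(
    on_target: bool,
    ult_present: bool,
    draw: ParameterDraw,
    multiplier: float = 1.0,
) -> float:
    """Branch-specific daily probability that a new flare starts."""
    if on_target and not ult_present:
        raise SimulationError("on-target branch is unreachable without ULT")
    if on_target:
        p = draw.daily_flare_prob["on_target_ult"]
    elif ult_present:
        p = draw.daily_flare_prob["off_target_ult"]
    else:
        p = draw.daily_flare_prob["off_target_no_ult"]
    return min(p * multiplier, 1.0)


def step_flare(
    state: PainState, matrix: np.ndarray, rng: np.random.Generator | int | None = None
) -> PainState:
    """One daily pain-state transition under a row-stochastic matrix."""
    matrix = np.asarray(matrix, float)
    row = matrix[int(state)]
    if abs(row.sum() - 1.0) > 1e-9:
        raise SimulationError("transition matrix row does not sum to 1")
    rng = np.random.default_rng(rng)
    return PainState(int(np.searchsorted(np.cumsum(row), rng.random(), side="right")))


def accrue_day(
    state: int,
    on_target: bool,
    strategy: Strategy,
    draw: ParameterDraw,
    day: int,
    config: SimConfig = SimConfig(),
) -> tuple[float, float]:
    """Discounted (cost, quality-adjusted life-years) accrued on one day.

    ``state`` is a pain state during a flare or ``NO_FLARE``.  No-flare
    days accrue the no-pain utility weight and the configured no-flare
    daily other cost; flare days additionally accrue the flare drug cost.
    ULT drug cost accrues every day (unless no ULT).  Off-target patients
    lose a constant daily utility decrement.
    """
    if not 0 <= day < draw.horizon_days:
        raise SimulationError(f"day index {day} outside horizon")
    df_c = (1.0 + draw.discount_rate_costs) ** (-day / 365.0)
    df_u = (1.0 + draw.discount_rate_utility) ** (-day / 365.0)
    in_flare = state != NO_FLARE
    cost = draw.no_flare_cost if not in_flare else float(draw.state_cost[state])
    if in_flare:
        cost += draw.daily_drug_cost[strategy.flare_drug]
    ult_key = ULT_DRUG_COST_KEY[strategy.ult]
    if ult_key is not None:
        cost += draw.daily_drug_cost[ult_key]
    utility = (
        float(draw.utility[PainState.NO_PAIN]) if not in_flare else float(draw.utility[state])
    )
    if not on_target:
        utility -= draw.off_target_annual_disutility
    return cost * df_c, utility / 365.0 * df_u


# ---------------------------------------------------------------------------
# Vectorized cohort engine
# ---------------------------------------------------------------------------


def draw_cohort_uniforms(
    n: int, horizon_days: int, rng: np.random.Generator | int | None
) -> dict[str, np.ndarray]:
    """Pre-draw the uniform variates a cohort consumes.

    Reusing the same block across strategies implements common random
    numbers: branch assignment, flare-onset days and within-flare
    transitions then react identically to parameter differences only.
    """
    rng = np.random.default_rng(rng)
    return {
        "branch": rng.random(n),
        "onset": rng.random((n, horizon_days)),
        "transition": rng.random((n, horizon_days)),
        "onset_state": rng.random(n),
    }


def _simulate_cohort_arrays(
    strategy: Strategy,
    draw: ParameterDraw,
    config: SimConfig,
    uniforms: dict[str, np.ndarray],
    record_trajectory: bool = False,
):
    horizon = draw.horizon_days
    flare_len = draw.flare_duration_days
    n = uniforms["branch"].shape[0]
    matrix = draw.transition[strategy.flare_drug]
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0  # guard against rounding

    p_target = draw.p_target[strategy.ult]
    ult_present = strategy.ult != "no_ult"
    if not ult_present and p_target != 0.0:
        raise SimulationError("no_ult patients cannot reach the serum-urate target")
    on_target = uniforms["branch"] < p_target
    mult = config.flare_hazard_multiplier
    h_on = daily_flare_hazard(True, True, draw, mult) if ult_present else 0.0
    h_off = daily_flare_hazard(False, ult_present, draw, mult)
    hazard = np.where(on_target, h_on, h_off)

    onset_probs = config.onset_probs()
    onset_cum = np.cumsum(onset_probs)
    onset_states = np.searchsorted(onset_cum, uniforms["onset_state"], side="right").astype(
        np.int64
    )
    onset_states = np.minimum(onset_states, N_PAIN_STATES - 1)

    df_c = discount_factors(draw.discount_rate_costs, horizon)
    df_u = discount_factors(draw.discount_rate_utility, horizon)

    state_cost = np.append(draw.state_cost, draw.no_flare_cost)  # indexed by state code
    util = np.append(draw.utility, draw.utility[PainState.NO_PAIN])
    flare_drug_cost = draw.daily_drug_cost[strategy.flare_drug]
    ult_key = ULT_DRUG_COST_KEY[strategy.ult]
    ult_cost = draw.daily_drug_cost[ult_key] if ult_key is not None else 0.0
    drug_days = config.flare_drug_days if config.flare_drug_days is not None else flare_len
    dis_annual = draw.off_target_annual_disutility
    off_mask = ~on_target

    state = np.full(n, NO_FLARE, dtype=np.int64)
    flare_day = np.zeros(n, dtype=np.int64)
    if config.entry_with_flare:
        state = onset_states.copy()
    flares = np.full(n, 1 if config.entry_with_flare else 0, dtype=np.int64)

    cost = np.zeros(n)
    qaly = np.zeros(n)
    trajectory = None
    if record_trajectory:
        trajectory = {
            "state": np.empty((n, horizon), dtype=np.int64),
            "flare_day": np.empty((n, horizon), dtype=np.int64),
            "cost": np.empty((n, horizon)),
            "qald": np.empty((n, horizon)),
        }

    onset_u = uniforms["onset"]
    trans_u = uniforms["transition"]
    for day in range(horizon):
        in_flare = state != NO_FLARE
        day_cost = state_cost[state] + ult_cost
        day_cost += flare_drug_cost * (in_flare & (flare_day < drug_days))
        disc_cost = df_c[day] * day_cost
        disc_qald = df_u[day] * (util[state] - dis_annual * off_mask) / 365.0
        cost += disc_cost
        qaly += disc_qald
        if record_trajectory:
            trajectory["state"][:, day] = state
            trajectory["flare_day"][:, day] = np.where(in_flare, flare_day, 0)
            trajectory["cost"][:, day] = disc_cost
            trajectory["qald"][:, day] = disc_qald
        if day == horizon - 1:
            break
        # next-day state
        u = trans_u[:, day]
        rows = cum[np.where(in_flare, state, 0)]
        nxt = (u[:, None] > rows).sum(axis=1)
        ending = in_flare & (flare_day == flare_len - 1)
        starting = (~in_flare) & (onset_u[:, day] < hazard)
        new_state = np.where(in_flare & ~ending, nxt, NO_FLARE)
        new_state = np.where(starting, onset_states, new_state)
        flare_day = np.where(in_flare & ~ending, flare_day + 1, 0)
        flares += starting
        state = new_state

    return cost, qaly, flares, on_target, trajectory


def simulate_cohort(
    strategy: Strategy,
    draw: ParameterDraw,
    n_patients: int,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | int | None = None,
    uniforms: dict[str, np.ndarray] | None = None,
) -> CohortOutcome:
    """Simulate ``n_patients`` independent patients and average outcomes.

    Pass a pre-drawn ``uniforms`` block (see :func:`draw_cohort_uniforms`)
    to share common random numbers across strategies.
    """
    if n_patients < 1:
        raise SimulationError("need at least one patient")
    if uniforms is None:
        uniforms = draw_cohort_uniforms(n_patients, draw.horizon_days, rng)
    cost, qaly, flares, _, _ = _simulate_cohort_arrays(strategy, draw, config, uniforms)
    n = len(cost)
    return CohortOutcome(
        strategy=strategy,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        n=n,
        draw_index=draw.draw_index,
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_flares=float(flares.mean()),
    )


@dataclass(frozen=True)
class PatientTrajectory:
    """Day-by-day record for a single simulated patient."""

    strategy: Strategy
    on_target: bool
    states: np.ndarray  # state code per day (0..3 pain, 4 no-flare)
    flare_day_index: np.ndarray
    daily_cost: np.ndarray  # discounted
    daily_qald: np.ndarray  # discounted quality-adjusted life-days (in years)

    @property
    def total_cost(self) -> float:
        return float(self.daily_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.daily_qald.sum())

    def to_frame(self, patient_id: int = 0) -> pd.DataFrame:
        horizon = len(self.states)
        labels = list(PAIN_STATE_NAMES) + ["no_flare"]
        return pd.DataFrame(
            {
                "patient_id": patient_id,
                "day": np.arange(horizon),
                "branch": "on_target" if self.on_target else "off_target",
                "state": [labels[s] for s in self.states],
                "cost": self.daily_cost,
                "qald": self.daily_qald,
            }
        )


def simulate_patient(
    strategy: Strategy,
    draw: ParameterDraw,
    config: SimConfig = SimConfig(),
    rng: np.random.Generator | int | None = None,
) -> PatientTrajectory:
    """Simulate a single patient, returning the full daily trajectory."""
    uniforms = draw_cohort_uniforms(1, draw.horizon_days, rng)
    _, _, _, on_target, traj = _simulate_cohort_arrays(
        strategy, draw, config, uniforms, record_trajectory=True
    )
    return PatientTrajectory(
        strategy=strategy,
        on_target=bool(on_target[0]),
        states=traj["state"][0],
        flare_day_index=traj["flare_day"][0],
        daily_cost=traj["cost"][0],
        daily_qald=traj["qald"][0],
    )


# ---------------------------------------------------------------------------
# Exact cohort expectation (dynamic-programming oracle)
# ---------------------------------------------------------------------------


def _branch_expectation(
    strategy: Strategy,
    draw: ParameterDraw,
    config: SimConfig,
    hazard: float,
    on_target: bool,
) -> tuple[float, float, float]:
    """Exact expectation for one serum-urate branch.

    State space: index 0 = no flare; 1 + k*4 + s = pain state s on flare
    day k (k = 0..flare_len-1).  The distribution over this space is
    propagated day by day; cost/utility accrue from the distribution
    before each transition.
    """
    horizon = draw.horizon_days
    flare_len = draw.flare_duration_days
    matrix = draw.transition[strategy.flare_drug]
    n_states = 1 + flare_len * N_PAIN_STATES
    idx = lambda k, s: 1 + k * N_PAIN_STATES + s  # noqa: E731

    transition = np.zeros((n_states, n_states))
    onset_probs = config.onset_probs()
    transition[0, 0] = 1.0 - hazard
    for s in range(N_PAIN_STATES):
        transition[0, idx(0, s)] = hazard * onset_probs[s]
    for k in range(flare_len):
        for s in range(N_PAIN_STATES):
            if k == flare_len - 1:
                transition[idx(k, s), 0] = 1.0
            else:
                for s2 in range(N_PAIN_STATES):
                    transition[idx(k, s), idx(k + 1, s2)] = matrix[s, s2]

    drug_days = config.flare_drug_days if config.flare_drug_days is not None else flare_len
    flare_drug_cost = draw.daily_drug_cost[strategy.flare_drug]
    ult_key = ULT_DRUG_COST_KEY[strategy.ult]
    ult_cost = draw.daily_drug_cost[ult_key] if ult_key is not None else 0.0
    dis = draw.off_target_annual_disutility if not on_target else 0.0

    cost_vec = np.empty(n_states)
    util_vec = np.empty(n_states)
    cost_vec[0] = draw.no_flare_cost + ult_cost
    util_vec[0] = draw.utility[PainState.NO_PAIN] - dis
    for k in range(flare_len):
        for s in range(N_PAIN_STATES):
            c = draw.state_cost[s] + ult_cost
            if k < drug_days:
                c += flare_drug_cost
            cost_vec[idx(k, s)] = c
            util_vec[idx(k, s)] = draw.utility[s] - dis

    dist = np.zeros(n_states)
    if config.entry_with_flare:
        for s in range(N_PAIN_STATES):
            dist[idx(0, s)] = onset_probs[s]
    else:
        dist[0] = 1.0

    df_c = discount_factors(draw.discount_rate_costs, horizon)
    df_u = discount_factors(draw.discount_rate_utility, horizon)
    exp_cost = 0.0
    exp_qaly = 0.0
    exp_flares = 1.0 if config.entry_with_flare else 0.0
    for day in range(horizon):
        exp_cost += df_c[day] * float(dist @ cost_vec)
        exp_qaly += df_u[day] * float(dist @ util_vec) / 365.0
        if day < horizon - 1:
            exp_flares += dist[0] * hazard
            dist = dist @ transition
    return exp_cost, exp_qaly, exp_flares


def expected_outcomes_exact(
    strategy: Strategy, draw: ParameterDraw, config: SimConfig = SimConfig()
) -> CohortExpectation:
    """Exact expected discounted cost and QALY at fixed parameters.

    Mixes the two serum-urate branches by the strategy's target-attainment
    probability; within each branch the day-indexed state distribution is
    propagated exactly.  Serves as the test oracle for the microsimulation
    and for scenario contracts.
    """
    p_target = draw.p_target[strategy.ult]
    ult_present = strategy.ult != "no_ult"
    if not ult_present and p_target != 0.0:
        raise SimulationError("no_ult patients cannot reach the serum-urate target")
    mult = config.flare_hazard_multiplier
    parts = []
    weights = []
    if p_target > 0.0:
        h_on = daily_flare_hazard(True, True, draw, mult)
        parts.append(_branch_expectation(strategy, draw, config, h_on, on_target=True))
        weights.append(p_target)
    if p_target < 1.0:
        h_off = daily_flare_hazard(False, ult_present, draw, mult)
        parts.append(_branch_expectation(strategy, draw, config, h_off, on_target=False))
        weights.append(1.0 - p_target)
    cost = sum(w * p[0] for w, p in zip(weights, parts))
    qaly = sum(w * p[1] for w, p in zip(weights, parts))
    flares = sum(w * p[2] for w, p in zip(weights, parts))
    return CohortExpectation(strategy=strategy, cost=cost, qaly=qaly, expected_flares=flares)
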