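"""Model inputs: distributions, probability conversions, cost preprocessing.

This module owns every numeric input of the decision model: the
target-attainment probability per urate-lowering therapy (ULT), branch
specific daily flare probabilities, per-pain-state utility weights and
daily "other" (healthcare + productivity) costs, daily drug prices, and
discount rates.  It also provides the probabilistic-sensitivity-analysis
(PSA) sampling layer that turns a :class:`ParameterTable` into one
:class:`ParameterDraw`, and the preprocessing used to estimate per-state
daily costs from patient-level cost observations (3-standard-deviation
outlier screening, exponential/gamma component fits).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .states import (
    N_PAIN_STATES,
    PAIN_STATE_NAMES,
    PainState,
    ULT_OPTIONS,
    pain_state_from_name,
)

__all__ = [
    "DistributionSpec",
    "ParameterTable",
    "ParameterDraw",
    "StateCostEstimate",
    "ParameterError",
    "fit_beta_from_mean_sd",
    "annual_to_daily_probability",
    "daily_to_annual_probability",
    "remove_cost_outliers",
    "estimate_state_costs",
    "sample_parameter_draw",
    "load_parameter_table",
    "read_cost_observations",
    "write_cost_observations",
]

#: Branch keys for the daily flare hazard.
FLARE_BRANCHES = ("on_target_ult", "off_target_ult", "off_target_no_ult")

#: Published row label per branch key.
_BRANCH_LABELS = {
    "on_target_ult": "SUA on target with ULT",
    "off_target_ult": "SUA not on target with ULT",
    "off_target_no_ult": "SUA not on target with no ULT",
}

_ULT_LABELS = {
    "allopurinol200": "Allopurinol 200 mg",
    "allopurinol300": "Allopurinol 300 mg",
    "febuxostat80": "Febuxostat 80 mg",
    "no_ult": "No ULT",
}

_STATE_LABELS = {
    PainState.NO_PAIN: "No pain",
    PainState.MILD_PAIN: "Mild pain",
    PainState.MODERATE_PAIN: "Moderate pain",
    PainState.SEVERE_PAIN: "Severe pain",
}


class ParameterError(ValueError):
    """Invalid or infeasible model-parameter specification."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

_FAMILIES = {
    "beta_mean_sd",
    "beta_shape",
    "gamma_shape_scale",
    "exponential_rate",
    "dirichlet",
    "point",
}


@dataclass(frozen=True)
class DistributionSpec:
    """One univariate (or Dirichlet) uncertainty distribution.

    ``family`` is one of ``beta_mean_sd``, ``beta_shape``,
    ``gamma_shape_scale``, ``exponential_rate``, ``dirichlet`` or
    ``point``; ``params`` holds the named parameters of that family.
    """

    family: str
    params: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown distribution family {self.family!r}")
        self.validate()

    def _p(self, key: str) -> float:
        try:
            return float(self.params[key])
        except KeyError:
            raise ParameterError(
                f"{self.family} spec {self.name!r} missing parameter {key!r}"
            ) from None

    def validate(self) -> None:
        f = self.family
        if f == "beta_mean_sd":
            mu, sd = self._p("mu"), self._p("sigma")
            if not 0.0 < mu < 1.0:
                raise ParameterError(f"beta mean must lie in (0,1): {self.name!r}")
            if sd <= 0.0 or sd * sd >= mu * (1.0 - mu):
                raise ParameterError(
                    f"beta sd infeasible for {self.name!r}: need 0 < sigma^2 "
                    f"< mu(1-mu) = {mu * (1 - mu):.6g}, got sigma = {sd}"
                )
        elif f == "beta_shape":
            if self._p("alpha") <= 0 or self._p("beta") <= 0:
                raise ParameterError(f"beta shapes must be positive: {self.name!r}")
        elif f == "gamma_shape_scale":
            if self._p("alpha") <= 0 or self._p("beta") <= 0:
                raise ParameterError(f"gamma parameters must be positive: {self.name!r}")
        elif f == "exponential_rate":
            if self._p("lambda") <= 0:
                raise ParameterError(f"exponential rate must be positive: {self.name!r}")
        elif f == "dirichlet":
            alpha = np.asarray(self.params["alpha"], dtype=float)
            if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
                raise ParameterError(f"dirichlet concentrations must be positive: {self.name!r}")
        elif f == "point":
            self._p("value")

    def mean(self) -> float:
        f = self.family
        if f == "beta_mean_sd":
            return self._p("mu")
        if f == "beta_shape":
            a, b = self._p("alpha"), self._p("beta")
            return a / (a + b)
        if f == "gamma_shape_scale":
            return self._p("alpha") * self._p("beta")
        if f == "exponential_rate":
            return 1.0 / self._p("lambda")
        if f == "point":
            return self._p("value")
        raise ParameterError(f"mean() not defined for family {f!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        f = self.family
        if f == "beta_mean_sd":
            shape = fit_beta_from_mean_sd(self._p("mu"), self._p("sigma"), name=self.name)
            return rng.beta(shape._p("alpha"), shape._p("beta"), size=size)
        if f == "beta_shape":
            return rng.beta(self._p("alpha"), self._p("beta"), size=size)
        if f == "gamma_shape_scale":
            return rng.gamma(self._p("alpha"), self._p("beta"), size=size)
        if f == "exponential_rate":
            return rng.exponential(1.0 / self._p("lambda"), size=size)
        if f == "dirichlet":
            return rng.dirichlet(np.asarray(self.params["alpha"], dtype=float), size=size)
        if f == "point":
            v = self._p("value")
            return v if size is None else np.full(size, v)
        raise ParameterError(f"cannot sample family {f!r}")


def fit_beta_from_mean_sd(mean: float, sd: float, name: str = "") -> DistributionSpec:
    """Method-of-moments beta shapes from a mean and standard deviation.

    Solves ``alpha/(alpha+beta) = mean`` and
    ``var = alpha*beta / ((alpha+beta)^2 (alpha+beta+1)) = sd^2``.

    Raises
    ------
    ParameterError
        If ``mean`` is outside (0, 1) or ``sd^2 >= mean*(1-mean)`` (the
        Bernoulli variance bound), naming the offending parameter.
    """
    label = name or "beta parameter"
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"{label}: beta mean must lie strictly in (0,1), got {mean}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if sd <= 0.0 or var >= bound:
        raise ParameterError(
            f"{label}: infeasible beta variance {var:.6g} (must be < mean(1-mean) = {bound:.6g})"
        )
    nu = bound / var - 1.0
    return DistributionSpec(
        "beta_shape", {"alpha": mean * nu, "beta": (1.0 - mean) * nu}, name=name
    )


# ---------------------------------------------------------------------------
# Probability conversions
# ---------------------------------------------------------------------------


def annual_to_daily_probability(p_annual: float, days: int = 365) -> float:
    """Convert an annual event probability to a per-day probability.

    Assumes a constant hazard over the year: ``p_day = 1 - (1-p_annual)^(1/days)``.
    """
    if not 0.0 <= p_annual < 1.0:
        raise ParameterError(f"annual probability must lie in [0,1), got {p_annual}")
    if days < 1:
        raise ParameterError(f"days must be >= 1, got {days}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / days)


def daily_to_annual_probability(p_daily: float, days: int = 365) -> float:
    """Inverse of :func:`annual_to_daily_probability`."""
    if not 0.0 <= p_daily <= 1.0:
        raise ParameterError(f"daily probability must lie in [0,1], got {p_daily}")
    if days < 1:
        raise ParameterError(f"days must be >= 1, got {days}")
    return 1.0 - (1.0 - p_daily) ** days


# ---------------------------------------------------------------------------
# Cost observations
# ---------------------------------------------------------------------------

COST_COLUMNS = ("patient_id", "pain_state", "productivity_cost", "healthcare_cost")


def _validate_cost_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = set(COST_COLUMNS) - set(obs.columns)
    if missing:
        raise ParameterError(f"cost observations missing columns {sorted(missing)}")
    if len(obs) == 0:
        raise ParameterError("cost observation set is empty")
    states = obs["pain_state"].map(lambda s: pain_state_from_name(str(s)))
    if (obs[["productivity_cost", "healthcare_cost"]] < 0).any().any():
        raise ParameterError("cost observations must be non-negative")
    out = obs.copy()
    out["pain_state"] = [PAIN_STATE_NAMES[s] for s in states]
    return out


def read_cost_observations(path: str | Path) -> pd.DataFrame:
    """Read a (patient_id, pain_state, productivity_cost, healthcare_cost) CSV."""
    return _validate_cost_observations(pd.read_csv(path))


def write_cost_observations(obs: pd.DataFrame, path: str | Path) -> None:
    _validate_cost_observations(obs).to_csv(path, index=False)


def remove_cost_outliers(obs: pd.DataFrame, by_state: bool = True) -> pd.DataFrame:
    """Single-pass 3-standard-deviation outlier screen on total daily cost.

    An observation is dropped iff its total cost (productivity + healthcare)
    deviates from its stratum mean by strictly more than three stratum
    standard deviations (population SD).  Strata are pain states when
    ``by_state`` is true, otherwise the whole set.  Order is preserved; the
    pass is evaluated once on the input statistics (re-invoke explicitly to
    screen again).
    """
    obs = _validate_cost_observations(obs).reset_index(drop=True)
    total = obs["productivity_cost"].to_numpy(float) + obs["healthcare_cost"].to_numpy(float)
    keep = np.ones(len(obs), dtype=bool)
    if by_state:
        groups = [g.to_numpy() for _, g in obs.groupby("pain_state", sort=False).groups.items()]
    else:
        groups = [np.arange(len(obs))]
    for rows in groups:
        values = total[rows]
        mean = values.mean()
        sd = values.std(ddof=0)
        keep[rows] = np.abs(values - mean) <= 3.0 * sd
    return obs.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class StateCostEstimate:
    """Daily-cost summary for one pain state."""

    state: PainState
    point: float  # mean total daily cost
    productivity: DistributionSpec  # exponential_rate, MLE
    healthcare: DistributionSpec  # gamma_shape_scale, method of moments


def estimate_state_costs(obs: pd.DataFrame) -> dict[PainState, StateCostEstimate]:
    """Per-pain-state daily cost point estimates and component distribution fits.

    The point estimate is the mean total daily cost.  The productivity
    component is fitted as an exponential by maximum likelihood
    (``lambda = 1/mean``); the healthcare component as a gamma by the
    method of moments (``alpha = mean^2/var``, ``beta = var/mean``,
    population variance).  Expects outliers to have been screened already.
    """
    obs = _validate_cost_observations(obs)
    present = set(obs["pain_state"])
    absent = [n for n in PAIN_STATE_NAMES if n not in present]
    if absent:
        raise ParameterError(f"no cost observations for pain state(s): {absent}")
    out: dict[PainState, StateCostEstimate] = {}
    for name, group in obs.groupby("pain_state", sort=False):
        state = pain_state_from_name(str(name))
        prod = group["productivity_cost"].to_numpy(float)
        care = group["healthcare_cost"].to_numpy(float)
        if prod.mean() <= 0 or care.mean() <= 0:
            raise ParameterError(f"degenerate (all-zero) cost component for state {name}")
        var = care.var(ddof=0)
        if var <= 0:
            raise ParameterError(f"zero-variance healthcare costs for state {name}")
        out[state] = StateCostEstimate(
            state=state,
            point=float((prod + care).mean()),
            productivity=DistributionSpec(
                "exponential_rate", {"lambda": 1.0 / prod.mean()}, name=f"{name}.productivity"
            ),
            healthcare=DistributionSpec(
                "gamma_shape_scale",
                {"alpha": care.mean() ** 2 / var, "beta": var / care.mean()},
                name=f"{name}.healthcare",
            ),
        )
    return {s: out[s] for s in PainState}


# ---------------------------------------------------------------------------
# Parameter table and PSA draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostComponentSpec:
    """Two-component daily-cost uncertainty for one pain state.

    ``productivity`` (exponential) and ``healthcare`` (gamma) supply the
    *relative* uncertainty; sampled totals are rescaled so their mean equals
    the operative daily point estimate (``scale`` is that constant).
    """

    productivity: DistributionSpec
    healthcare: DistributionSpec
    point: float

    @property
    def component_mean(self) -> float:
        return self.productivity.mean() + self.healthcare.mean()

    @property
    def scale(self) -> float:
        return self.point / self.component_mean

    def sample(self, rng: np.random.Generator) -> float:
        total = self.productivity.sample(rng) + self.healthcare.sample(rng)
        return float(self.scale * total)


@dataclass(frozen=True)
class ParameterTable:
    """Point estimates plus uncertainty specifications for every model input."""

    p_target: dict[str, float]
    p_target_dist: dict[str, DistributionSpec | None]
    daily_flare_prob: dict[str, float]
    daily_flare_prob_sd: dict[str, float | None]
    utility: dict[PainState, float]
    utility_dist: dict[PainState, DistributionSpec | None]
    daily_other_cost: dict[PainState, float]
    daily_other_cost_dist: dict[PainState, CostComponentSpec | None]
    daily_drug_cost: dict[str, float]
    discount_rate_costs: float = 0.04
    discount_rate_utility: float = 0.015
    horizon_days: int = 365
    flare_duration_days: int = 7
    off_target_annual_disutility: float = 0.05
    no_flare_daily_cost: float | None = None  # None -> no_pain daily other cost

    def __post_init__(self) -> None:
        for ult in ULT_OPTIONS:
            if ult not in self.p_target:
                raise ParameterError(f"missing target-attainment probability for {ult}")
            if not 0.0 <= self.p_target[ult] <= 1.0:
                raise ParameterError(f"p_target[{ult}] outside [0,1]")
        for branch in FLARE_BRANCHES:
            p = self.daily_flare_prob.get(branch)
            if p is None or not 0.0 <= p <= 1.0:
                raise ParameterError(f"invalid daily flare probability for {branch}")
        for s in PainState:
            if not 0.0 <= self.utility[s] <= 1.0:
                raise ParameterError(f"utility[{s.name}] outside [0,1]")
            if self.daily_other_cost[s] < 0:
                raise ParameterError(f"negative daily other cost for {s.name}")
        if any(c < 0 for c in self.daily_drug_cost.values()):
            raise ParameterError("negative drug cost")
        if self.horizon_days < self.flare_duration_days:
            raise ParameterError("horizon shorter than flare duration")

    @property
    def resolved_no_flare_daily_cost(self) -> float:
        if self.no_flare_daily_cost is not None:
            return self.no_flare_daily_cost
        return self.daily_other_cost[PainState.NO_PAIN]

    def replace(self, **kwargs: Any) -> "ParameterTable":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ParameterDraw:
    """One realization of every stochastic model input (plus fixed inputs).

    Produced by :func:`sample_parameter_draw`; consumed by the simulation
    engine and the exact cohort-expectation oracle.  Deterministic runs use
    a draw whose stochastic entries sit at their point estimates.
    """

    p_target: dict[str, float]
    daily_flare_prob: dict[str, float]
    utility: np.ndarray  # (4,) per pain state
    state_cost: np.ndarray  # (4,) daily other cost per pain state
    no_flare_cost: float
    daily_drug_cost: dict[str, float]
    transition: dict[str, np.ndarray]  # per flare drug, 4x4 row-stochastic
    discount_rate_costs: float
    discount_rate_utility: float
    horizon_days: int
    flare_duration_days: int
    off_target_annual_disutility: float
    draw_index: int = 0

    def __post_init__(self) -> None:
        for key, p in {**self.p_target, **self.daily_flare_prob}.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"drawn probability {key!r} outside [0,1]: {p}")
        u = np.asarray(self.utility, float)
        if u.shape != (N_PAIN_STATES,) or np.any(u < 0) or np.any(u > 1):
            raise ParameterError("drawn utilities must be a 4-vector in [0,1]")
        c = np.asarray(self.state_cost, float)
        if c.shape != (N_PAIN_STATES,) or np.any(c < 0) or self.no_flare_cost < 0:
            raise ParameterError("drawn costs must be non-negative")
        for drug, m in self.transition.items():
            m = np.asarray(m, float)
            if m.shape != (N_PAIN_STATES, N_PAIN_STATES):
                raise ParameterError(f"transition matrix for {drug} must be 4x4")
            if np.any(m < 0) or np.any(m > 1):
                raise ParameterError(f"transition matrix for {drug} has entries outside [0,1]")
            if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
                raise ParameterError(f"transition matrix for {drug} is not row-stochastic")


def _flare_prob_complement_spec(point: float, sd: float, name: str) -> DistributionSpec:
    # The published beta describes the complement q = 1 - p_daily with the
    # printed sd; its mean is rescaled so that 1 - E[q] equals the printed
    # point estimate.
    return fit_beta_from_mean_sd(1.0 - point, sd, name=name)


def sample_parameter_draw(
    table: ParameterTable,
    transition_posteriors: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    transition_matrices: Mapping[str, np.ndarray] | None = None,
    psa: bool = True,
    draw_index: int = 0,
) -> ParameterDraw:
    """Draw one PSA realization of the model parameters.

    Parameters
    ----------
    table
        Point estimates and distribution specifications.
    transition_posteriors
        Per-flare-drug 4x4 Dirichlet concentration matrices.  In a PSA each
        row of each matrix is sampled from its Dirichlet; deterministically
        the posterior mean is used.
    transition_matrices
        Fixed per-drug transition matrices, used as-is for any drug without
        a posterior (e.g. a published matrix).
    psa
        When false, every stochastic entry is returned at its point
        estimate (and posteriors collapse to their means).

    Probabilities stay in [0, 1] by construction (beta/Dirichlet draws);
    nothing is truncated.  Fixed inputs (drug prices, no-ULT attainment)
    are returned at their point estimates.  Deterministic given ``rng``.
    """
    from .evidence import posterior_mean_matrix, sample_transition_matrix  # local: avoid cycle

    rng = np.random.default_rng(rng)
    transition_posteriors = dict(transition_posteriors or {})
    transition_matrices = dict(transition_matrices or {})

    p_target: dict[str, float] = {}
    for ult in ULT_OPTIONS:
        spec = table.p_target_dist.get(ult)
        if psa and spec is not None:
            p_target[ult] = float(spec.sample(rng))
        else:
            p_target[ult] = table.p_target[ult]

    flare: dict[str, float] = {}
    for branch in FLARE_BRANCHES:
        point = table.daily_flare_prob[branch]
        sd = table.daily_flare_prob_sd.get(branch)
        if psa and sd is not None:
            q = _flare_prob_complement_spec(point, sd, name=f"daily_flare_prob.{branch}").sample(rng)
            flare[branch] = float(1.0 - q)
        else:
            flare[branch] = point

    utility = np.empty(N_PAIN_STATES)
    for s in PainState:
        spec = table.utility_dist.get(s)
        if psa and spec is not None:
            utility[s] = spec.sample(rng)
        else:
            utility[s] = table.utility[s]

    state_cost = np.empty(N_PAIN_STATES)
    for s in PainState:
        comp = table.daily_other_cost_dist.get(s)
        if psa and comp is not None:
            state_cost[s] = comp.sample(rng)
        else:
            state_cost[s] = table.daily_other_cost[s]

    if table.no_flare_daily_cost is not None:
        no_flare_cost = table.no_flare_daily_cost
    else:
        no_flare_cost = float(state_cost[PainState.NO_PAIN])

    transition: dict[str, np.ndarray] = {}
    for drug, post in transition_posteriors.items():
        post = np.asarray(post, float)
        if psa:
            transition[drug] = sample_transition_matrix(post, rng)
        else:
            transition[drug] = posterior_mean_matrix(post)
    for drug, m in transition_matrices.items():
        if drug not in transition:
            transition[drug] = np.asarray(m, float)

    return ParameterDraw(
        p_target=p_target,
        daily_flare_prob=flare,
        utility=utility,
        state_cost=state_cost,
        no_flare_cost=no_flare_cost,
        daily_drug_cost=dict(table.daily_drug_cost),
        transition=transition,
        discount_rate_costs=table.discount_rate_costs,
        discount_rate_utility=table.discount_rate_utility,
        horizon_days=table.horizon_days,
        flare_duration_days=table.flare_duration_days,
        off_target_annual_disutility=table.off_target_annual_disutility,
        draw_index=draw_index,
    )


# ---------------------------------------------------------------------------
# Loading the bundled / user-provided input table
# ---------------------------------------------------------------------------


def _dist_from_entry(entry: Mapping[str, Any] | None, name: str) -> DistributionSpec | None:
    if entry is None:
        return None
    family = entry.get("family")
    if family == "beta_mean_sd":
        return DistributionSpec("beta_mean_sd", {"mu": entry["mu"], "sigma": entry["sigma"]}, name)
    if family == "beta_shape":
        return DistributionSpec(
            "beta_shape", {"alpha": entry["alpha"], "beta": entry["beta"]}, name
        )
    raise ParameterError(f"unsupported distribution family {family!r} for {name!r}")


def load_parameter_table(source: str | Path | Mapping[str, Any] | None = None) -> ParameterTable:
    """Build a :class:`ParameterTable` from YAML/JSON or the bundled fixture.

    ``source`` may be a path, an already-parsed mapping, or ``None`` for the
    bundled table of published inputs.  Keys mirror the published input
    table's row names.
    """
    if source is None:
        text = (
            importlib.resources.files("goutcea.data")
            .joinpath("model_inputs.yaml")
            .read_text(encoding="utf-8")
        )
        raw = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping):
        raise ParameterError("parameter file must contain a mapping at top level")

    def section(label: str) -> Mapping[str, Any]:
        try:
            return raw[label]
        except KeyError:
            raise ParameterError(f"parameter table missing section {label!r}") from None

    def get_row(sec: Mapping[str, Any], sec_label: str, label: str) -> Mapping[str, Any]:
        try:
            return sec[label]
        except KeyError:
            raise ParameterError(
                f"parameter table section {sec_label!r} missing row {label!r}"
            ) from None

    ult_sec = section("Probability SUA < 0.36 mmol/L")
    p_target, p_target_dist = {}, {}
    for ult, label in _ULT_LABELS.items():
        row = get_row(ult_sec, "Probability SUA < 0.36 mmol/L", label)
        p_target[ult] = float(row["point"])
        p_target_dist[ult] = _dist_from_entry(row.get("distribution"), f"p_target.{ult}")

    flare_sec = section("Daily flare probability")
    flare, flare_sd = {}, {}
    for branch in FLARE_BRANCHES:
        row = get_row(flare_sec, "Daily flare probability", _BRANCH_LABELS[branch])
        flare[branch] = float(row["point"])
        dist = row.get("distribution")
        if dist is None:
            flare_sd[branch] = None
        elif dist.get("family") == "beta_complement":
            flare_sd[branch] = float(dist["sigma"])
        else:
            raise ParameterError(
                f"daily flare probability for {branch!r} must use beta_complement"
            )

    util_sec = section("Quality adjusted life days")
    utility, utility_dist = {}, {}
    for s, label in _STATE_LABELS.items():
        row = get_row(util_sec, "Quality adjusted life days", label)
        utility[s] = float(row["point"])
        utility_dist[s] = _dist_from_entry(row.get("distribution"), f"utility.{label}")

    cost_sec = section("Daily other costs (in euros)")
    cost, cost_dist = {}, {}
    for s, label in _STATE_LABELS.items():
        row = get_row(cost_sec, "Daily other costs (in euros)", label)
        cost[s] = float(row["point"])
        dist = row.get("distribution")
        if dist is None:
            cost_dist[s] = None
        elif dist.get("family") == "exp_plus_gamma":
            cost_dist[s] = CostComponentSpec(
                productivity=DistributionSpec(
                    "exponential_rate", {"lambda": dist["lambda"]}, f"cost.{label}.productivity"
                ),
                healthcare=DistributionSpec(
                    "gamma_shape_scale",
                    {"alpha": dist["alpha"], "beta": dist["beta"]},
                    f"cost.{label}.healthcare",
                ),
                point=cost[s],
            )
        else:
            raise ParameterError(f"daily other cost for {label!r} must use exp_plus_gamma")

    drug_sec = section("Daily drug costs (in euros)")
    drug_cost = {label.lower(): float(row["point"]) for label, row in drug_sec.items()}

    disc = raw.get("Discounting", {})
    structure = raw.get("Model structure", {})
    return ParameterTable(
        p_target=p_target,
        p_target_dist=p_target_dist,
        daily_flare_prob=flare,
        daily_flare_prob_sd=flare_sd,
        utility=utility,
        utility_dist=utility_dist,
        daily_other_cost=cost,
        daily_other_cost_dist=cost_dist,
        daily_drug_cost=drug_cost,
        discount_rate_costs=float(disc.get("costs_per_year", 0.04)),
        discount_rate_utility=float(disc.get("utility_per_year", 0.015)),
        horizon_days=int(structure.get("horizon_days", 365)),
        flare_duration_days=int(structure.get("flare_duration_days", 7)),
        off_target_annual_disutility=float(structure.get("off_target_annual_disutility", 0.05)),
        no_flare_daily_cost=(
            None
            if structure.get("no_flare_daily_cost") is None
            else float(structure["no_flare_daily_cost"])
        ),
    )
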