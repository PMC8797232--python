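"""Incremental cost-effectiveness analysis on top of the microsimulation.

The probabilistic sensitivity analysis (PSA) is two-level: an outer loop
draws one :class:`~goutcea.parameters.ParameterDraw` per replication and an
inner cohort of patients is simulated for every strategy under common
random numbers.  The per-draw strategy means feed the incremental analysis
(ICERs with strict and extended dominance on the efficiency frontier, plus
the pairwise comparisons decision makers usually read) and the
cost-effectiveness acceptability curves (CEACs) over a willingness-to-pay
grid, via net monetary benefit NMB = wtp * QALY - cost.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .parameters import ParameterTable, sample_parameter_draw
from .simulation import (
    SimConfig,
    Strategy,
    draw_cohort_uniforms,
    simulate_cohort,
)

__all__ = [
    "PsaResult",
    "run_psa",
    "incremental_analysis",
    "pairwise_comparison",
    "net_monetary_benefit",
    "compute_ceac",
    "run_scenario",
    "EconomicsError",
    "DEFAULT_WTP_GRID",
]


class EconomicsError(ValueError):
    """Invalid economic-analysis input."""


#: Default willingness-to-pay grid: EUR 0 to 80,000/QALY in steps of 1,000.
#: The upper end matches the highest Dutch disease-burden WTP threshold.
DEFAULT_WTP_GRID = np.arange(0, 80_001, 1_000)


@dataclass(frozen=True)
class PsaResult:
    """Per-(strategy, outer draw) mean cost and QALY, plus run metadata."""

    draws: pd.DataFrame  # columns: strategy, draw, cost, qaly, flares
    n_outer: int
    n_inner: int
    seed: int

    def __post_init__(self) -> None:
        required = {"strategy", "draw", "cost", "qaly"}
        if not required <= set(self.draws.columns):
            raise EconomicsError(f"PSA table needs columns {sorted(required)}")
        counts = self.draws.groupby("strategy", sort=False)["draw"].count()
        if counts.nunique() > 1:
            raise EconomicsError("PSA grid must be rectangular over strategies x draws")
        if (self.draws["cost"] < 0).any():
            raise EconomicsError("negative costs in PSA result")

    def strategy_means(self) -> pd.DataFrame:
        """Mean cost/QALY per strategy over outer draws."""
        return (
            self.draws.groupby("strategy", sort=False)[["cost", "qaly"]]
            .mean()
            .reset_index()
        )


def run_psa(
    strategies: Sequence[Strategy],
    table: ParameterTable,
    transition_posteriors: Mapping[str, np.ndarray] | None = None,
    *,
    transition_matrices: Mapping[str, np.ndarray] | None = None,
    n_outer: int = 2000,
    n_inner: int = 200,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    psa: bool = True,
) -> PsaResult:
    """Run the two-level PSA.

    Each outer replication draws one parameter set shared by all
    strategies, then simulates an inner cohort of ``n_inner`` patients per
    strategy with common random numbers, so that between-strategy
    differences reflect parameters rather than simulation noise.
    Reproducible given ``seed``.  With ``psa=False`` parameters stay at
    their point estimates (a deterministic run; use ``n_outer=1``).
    """
    if n_outer < 1 or n_inner < 1:
        raise EconomicsError("n_outer and n_inner must be >= 1")
    if not strategies:
        raise EconomicsError("no strategies given")
    ss = np.random.SeedSequence(seed)
    param_ss, sim_ss = ss.spawn(2)
    param_children = param_ss.spawn(n_outer)
    sim_children = sim_ss.spawn(n_outer)

    records = []
    for d in range(n_outer):
        draw = sample_parameter_draw(
            table,
            transition_posteriors,
            np.random.default_rng(param_children[d]),
            transition_matrices=transition_matrices,
            psa=psa,
            draw_index=d,
        )
        uniforms = draw_cohort_uniforms(
            n_inner, draw.horizon_days, np.random.default_rng(sim_children[d])
        )
        for strat in strategies:
            out = simulate_cohort(strat, draw, n_inner, config, uniforms=uniforms)
            records.append(
                {
                    "strategy": strat.name,
                    "draw": d,
                    "cost": out.mean_cost,
                    "qaly": out.mean_qaly,
                    "flares": out.mean_flares,
                }
            )
    return PsaResult(
        draws=pd.DataFrame.from_records(records),
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Incremental analysis
# ---------------------------------------------------------------------------


def _as_means_frame(means) -> pd.DataFrame:
    if isinstance(means, PsaResult):
        means = means.strategy_means()
    df = pd.DataFrame(means).copy()
    required = {"strategy", "cost", "qaly"}
    if not required <= set(df.columns):
        raise EconomicsError(f"mean outcomes need columns {sorted(required)}")
    if df["strategy"].duplicated().any():
        raise EconomicsError("duplicate strategies in mean outcomes")
    return df


def incremental_analysis(means) -> pd.DataFrame:
    """Efficiency-frontier incremental analysis of mean outcomes.

    ``means`` is a table (strategy, cost, qaly) or a :class:`PsaResult`.
    Strategies are ordered by mean cost.  A strategy is strictly dominated
    if another costs no more and yields no less QALY (one strictly);
    extended dominance removes frontier members whose incremental ICER
    exceeds that of the next more effective option.  ICERs are computed
    between adjacent frontier members; dominated rows report increments
    against the nearest cheaper frontier member.  Exact cost+QALY ties are
    broken deterministically by strategy name and flagged.

    Returns a table with columns strategy, cost, qaly, delta_cost,
    delta_qaly, icer, label (reference / icer / dominated /
    extended_dominated), tie.
    """
    df = _as_means_frame(means)
    if len(df) < 2:
        raise EconomicsError("incremental analysis needs at least two strategies")
    df = df.sort_values(["cost", "qaly", "strategy"], ascending=[True, False, True]).reset_index(
        drop=True
    )

    n = len(df)
    cost = df["cost"].to_numpy(float)
    qaly = df["qaly"].to_numpy(float)
    tie = np.zeros(n, dtype=bool)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if cost[i] == cost[j] and qaly[i] == qaly[j]:
                # deterministic tie-break: later name loses
                if df.loc[j, "strategy"] < df.loc[i, "strategy"]:
                    dominated[i] = True
                    tie[i] = True
            elif cost[j] <= cost[i] and qaly[j] >= qaly[i]:
                dominated[i] = True

    frontier = [i for i in range(n) if not dominated[i]]
    extended = np.zeros(n, dtype=bool)
    # iteratively enforce increasing ICERs along the frontier
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[k - 1], frontier[k], frontier[k + 1]
            icer_mid = (cost[mid] - cost[lo]) / (qaly[mid] - qaly[lo])
            icer_hi = (cost[hi] - cost[mid]) / (qaly[hi] - qaly[mid])
            if icer_mid > icer_hi:
                extended[mid] = True
                frontier.pop(k)
                changed = True
                break

    label = np.empty(n, dtype=object)
    delta_cost = np.full(n, np.nan)
    delta_qaly = np.full(n, np.nan)
    icer = np.full(n, np.nan)
    for pos, i in enumerate(frontier):
        if pos == 0:
            label[i] = "reference"
        else:
            prev = frontier[pos - 1]
            delta_cost[i] = cost[i] - cost[prev]
            delta_qaly[i] = qaly[i] - qaly[prev]
            icer[i] = delta_cost[i] / delta_qaly[i]
            label[i] = "icer"
    for i in range(n):
        if label[i] is not None:
            continue
        label[i] = "extended_dominated" if extended[i] else "dominated"
        cheaper = [j for j in frontier if cost[j] <= cost[i] and j != i]
        if cheaper:
            comp = cheaper[-1]
            delta_cost[i] = cost[i] - cost[comp]
            delta_qaly[i] = qaly[i] - qaly[comp]

    out = df.copy()
    out["delta_cost"] = delta_cost
    out["delta_qaly"] = delta_qaly
    out["icer"] = icer
    out["label"] = label
    out["tie"] = tie
    return out


def pairwise_comparison(means, comparator: str) -> pd.DataFrame:
    """Pairwise increments and ICERs of every strategy against one comparator.

    Reported alongside the frontier analysis because published tables often
    quote pairwise ICERs even where dominance applies.  ``icer`` is NaN
    when the strategy (weakly) dominates or is dominated by the comparator;
    the ``label`` column then says which.
    """
    df = _as_means_frame(means).set_index("strategy")
    if comparator not in df.index:
        raise EconomicsError(f"comparator {comparator!r} not among strategies")
    base = df.loc[comparator]
    rows = []
    for strat, row in df.iterrows():
        if strat == comparator:
            continue
        dc = row["cost"] - base["cost"]
        de = row["qaly"] - base["qaly"]
        if dc >= 0 and de <= 0 and (dc > 0 or de < 0):
            label, value = "dominated", np.nan
        elif dc <= 0 and de >= 0 and (dc < 0 or de > 0):
            label, value = "dominant", np.nan
        else:
            label, value = "icer", dc / de
        rows.append(
            {
                "strategy": strat,
                "comparator": comparator,
                "delta_cost": dc,
                "delta_qaly": de,
                "icer": value,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def net_monetary_benefit(cost, qaly, wtp) -> np.ndarray | float:
    """NMB = wtp * qaly - cost (vectorized over any input)."""
    wtp = np.asarray(wtp, float)
    if np.any(wtp < 0):
        raise EconomicsError("willingness-to-pay must be non-negative")
    return wtp * np.asarray(qaly, float) - np.asarray(cost, float)


def compute_ceac(
    psa: PsaResult | pd.DataFrame,
    wtp_grid: np.ndarray | None = None,
    pairwise_comparator: str | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each willingness-to-pay, a strategy's acceptability is the fraction
    of outer draws in which it attains the strictly highest net monetary
    benefit; exact ties split their probability mass equally, so the
    curves sum to one at every grid point.

    With ``pairwise_comparator`` set, curves are pairwise instead: the
    probability that each strategy's NMB beats that single comparator
    (ties count half).  Pairwise curves do not sum to one.
    """
    df = psa.draws if isinstance(psa, PsaResult) else pd.DataFrame(psa)
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, float)
    cost = df.pivot(index="draw", columns="strategy", values="cost")
    qaly = df.pivot(index="draw", columns="strategy", values="qaly")
    strategies = list(cost.columns)
    c = cost.to_numpy()
    q = qaly.to_numpy()
    n_draws = c.shape[0]
    if n_draws < 1:
        raise EconomicsError("CEAC needs at least one draw")
    if pairwise_comparator is not None and pairwise_comparator not in strategies:
        raise EconomicsError(f"comparator {pairwise_comparator!r} not among strategies")
    records = []
    for wtp in wtp_grid:
        nmb = wtp * q - c
        if pairwise_comparator is None:
            best = nmb.max(axis=1, keepdims=True)
            winners = nmb == best
            share = winners / winners.sum(axis=1, keepdims=True)
            probs = share.mean(axis=0)
        else:
            ref = nmb[:, strategies.index(pairwise_comparator)][:, None]
            probs = ((nmb > ref) + 0.5 * (nmb == ref)).mean(axis=0)
        for s, p in zip(strategies, probs):
            records.append({"strategy": s, "wtp": wtp, "probability": p})
    return pd.DataFrame(records)


def run_scenario(
    strategies: Sequence[Strategy],
    table: ParameterTable,
    transition_posteriors: Mapping[str, np.ndarray] | None = None,
    *,
    transition_matrices: Mapping[str, np.ndarray] | None = None,
    base_config: SimConfig = SimConfig(),
    entry_with_flare: bool | None = None,
    flare_hazard_multiplier: float | None = None,
    scenario_id: str = "scenario",
    n_outer: int = 2000,
    n_inner: int = 200,
    wtp_grid: np.ndarray | None = None,
    seed: int = 0,
    psa: bool = True,
) -> dict:
    """Re-run the full analysis under structural overrides.

    Supported overrides mirror the published scenarios: patients entering
    without an active flare, and uniformly increased daily flare hazards.
    Returns the same result schema as the base analysis, tagged with
    ``scenario_id``.
    """
    config = base_config
    if entry_with_flare is not None:
        config = replace(config, entry_with_flare=entry_with_flare)
    if flare_hazard_multiplier is not None:
        if flare_hazard_multiplier < 1.0:
            raise EconomicsError("scenario hazard multipliers must be >= 1")
        config = replace(config, flare_hazard_multiplier=flare_hazard_multiplier)
    psa_result = run_psa(
        strategies,
        table,
        transition_posteriors,
        transition_matrices=transition_matrices,
        n_outer=n_outer,
        n_inner=n_inner,
        config=config,
        seed=seed,
        psa=psa,
    )
    return {
        "scenario_id": scenario_id,
        "config": config,
        "psa": psa_result,
        "incremental": incremental_analysis(psa_result),
        "ceac": compute_ceac(psa_result, wtp_grid),
    }
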