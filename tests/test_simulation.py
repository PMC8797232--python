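"""Markov engine: branch assignment, flare episodes, accrual, exact oracle."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from goutcea import SimConfig, Strategy, expected_outcomes_exact, simulate_cohort, simulate_patient
from goutcea.simulation import (
    NO_FLARE,
    SimulationError,
    accrue_day,
    assign_branch,
    daily_flare_hazard,
    discount_factors,
    draw_cohort_uniforms,
    step_flare,
)
from goutcea.states import PainState

from conftest import make_draw

SEV = PainState.SEVERE_PAIN


class TestBranchAssignment:
    def test_no_ult_always_off_target(self):
        strat = Strategy("no_ult", "naproxen")
        assert not any(assign_branch(strat, 0.0, rng=i) for i in range(50))

    def test_certain_target(self):
        strat = Strategy("febuxostat80", "naproxen")
        assert all(assign_branch(strat, 1.0, rng=i) for i in range(50))

    def test_binomial_fraction_matches_published_rate(self):
        rng = np.random.default_rng(0)
        strat = Strategy("febuxostat80", "naproxen")
        n = 100_000
        frac = np.mean([assign_branch(strat, 0.729, rng) for _ in range(n)])
        assert abs(frac - 0.729) < 3 * np.sqrt(0.729 * 0.271 / n)


class TestDailyFlareHazard:
    def test_published_branch_hazards(self):
        draw = make_draw()
        assert daily_flare_hazard(True, True, draw) == 0.000716
        assert daily_flare_hazard(False, True, draw) == 0.001222
        assert daily_flare_hazard(False, False, draw) == 0.001637

    def test_scenario_multiplier_scales_exactly(self):
        draw = make_draw()
        assert daily_flare_hazard(False, False, draw, multiplier=2.0) == pytest.approx(
            2 * 0.001637, rel=1e-15
        )

    def test_on_target_without_ult_unreachable(self):
        with pytest.raises(SimulationError):
            daily_flare_hazard(True, False, make_draw())


class TestStepFlare:
    def test_identity_matrix_keeps_state(self):
        for s in PainState:
            assert step_flare(s, np.eye(4), rng=0) == s

    def test_degenerate_row_forces_severe(self):
        m = np.tile([0.0, 0.0, 0.0, 1.0], (4, 1))
        assert step_flare(PainState.NO_PAIN, m, rng=3) == SEV

    def test_multinomial_frequencies(self):
        row = np.array([0.5, 0.3, 0.15, 0.05])
        m = np.tile(row, (4, 1))
        rng = np.random.default_rng(8)
        draws = np.array([int(step_flare(PainState.MILD_PAIN, m, rng)) for _ in range(100_000)])
        freq = np.bincount(draws, minlength=4) / len(draws)
        se = np.sqrt(row * (1 - row) / len(draws))
        assert np.all(np.abs(freq - row) < 3 * se)


class TestAccrueDay:
    def test_day_zero_is_undiscounted(self):
        draw = make_draw()
        cost, qald = accrue_day(NO_FLARE, True, Strategy("no_ult", "naproxen"), draw, 0)
        assert cost == pytest.approx(19.95)
        assert qald == pytest.approx(0.86 / 365)

    def test_severe_flare_day_on_anakinra_febuxostat(self):
        draw = make_draw()
        cost, _ = accrue_day(int(SEV), True, Strategy("febuxostat80", "anakinra"), draw, 0)
        assert cost == pytest.approx(33.4 + 1.03 + 134.32)

    def test_off_target_disutility(self):
        draw = make_draw()
        _, on = accrue_day(NO_FLARE, True, Strategy("febuxostat80", "naproxen"), draw, 0)
        _, off = accrue_day(NO_FLARE, False, Strategy("febuxostat80", "naproxen"), draw, 0)
        assert on - off == pytest.approx(0.05 / 365)

    def test_discounting_convention(self):
        draw = make_draw()
        strat = Strategy("no_ult", "naproxen")
        c0, u0 = accrue_day(NO_FLARE, False, strat, draw, 0)
        c1, u1 = accrue_day(NO_FLARE, False, strat, draw, 364)
        assert c1 / c0 == pytest.approx(1.04 ** (-364 / 365))
        assert u1 / u0 == pytest.approx(1.015 ** (-364 / 365))


def _episodes(states):
    """(start, length) of every flare episode in a daily state sequence."""
    episodes = []
    start = None
    for day, s in enumerate(states):
        if s != NO_FLARE and start is None:
            start = day
        elif s == NO_FLARE and start is not None:
            episodes.append((start, day - start))
            start = None
    if start is not None:
        episodes.append((start, len(states) - start))
    return episodes


class TestSimulatePatient:
    def test_closed_form_without_flares(self):
        draw = make_draw(
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.0
            ),
            discount_rate_costs=0.0,
            discount_rate_utility=0.0,
            off_target_annual_disutility=0.0,
        )
        strat = Strategy("febuxostat80", "naproxen")
        traj = simulate_patient(strat, draw, SimConfig(entry_with_flare=False), rng=0)
        assert traj.total_qaly == pytest.approx(0.86, rel=1e-12)
        assert traj.total_cost == pytest.approx(365 * (1.03 + 19.95), rel=1e-12)

    def test_entry_flare_identity_matrix_absorbs_severe(self):
        draw = make_draw(
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.0
            )
        )
        traj = simulate_patient(Strategy("no_ult", "naproxen"), draw, SimConfig(), rng=0)
        assert list(traj.states[:7]) == [int(SEV)] * 7
        assert traj.states[7] == NO_FLARE
        assert list(traj.flare_day_index[:7]) == list(range(7))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_structure_any_seed(self, seed, point_draw):
        traj = simulate_patient(
            Strategy("no_ult", "naproxen"), point_draw, SimConfig(), rng=seed
        )
        assert len(traj.states) == 365
        episodes = _episodes(traj.states)
        assert episodes[0][0] == 0  # entry flare
        # every episode lasts exactly 7 days except a truncated final one
        for start, length in episodes:
            if start + 7 <= 365:
                assert length == 7
            else:
                assert length == 365 - start

    def test_daily_accrual_matches_accrue_day(self, point_draw):
        strat = Strategy("allopurinol300", "colchicine")
        traj = simulate_patient(strat, point_draw, SimConfig(), rng=5)
        for day in (0, 1, 6, 7, 100, 364):
            c, q = accrue_day(
                int(traj.states[day]), traj.on_target, strat, point_draw, day
            )
            assert traj.daily_cost[day] == pytest.approx(c, rel=1e-12)
            assert traj.daily_qald[day] == pytest.approx(q, rel=1e-12)

    def test_totals_are_sum_of_days(self, point_draw):
        traj = simulate_patient(Strategy("febuxostat80", "anakinra"), point_draw, rng=2)
        assert traj.total_cost == pytest.approx(traj.daily_cost.sum())
        assert traj.total_qaly == pytest.approx(traj.daily_qald.sum())


class TestSimulateCohort:
    def test_single_patient_equals_trajectory(self, point_draw):
        strat = Strategy("no_ult", "prednisone")
        out = simulate_cohort(strat, point_draw, 1, rng=77)
        traj = simulate_patient(strat, point_draw, rng=77)
        assert out.mean_cost == pytest.approx(traj.total_cost, rel=1e-12)
        assert out.mean_qaly == pytest.approx(traj.total_qaly, rel=1e-12)

    def test_common_random_numbers_make_equal_strategies_identical(self, point_draw):
        # equalize the parameters that differ between the two ULTs
        draw = dataclasses.replace(
            point_draw,
            p_target={**point_draw.p_target, "allopurinol300": 0.729},
            daily_drug_cost={**point_draw.daily_drug_cost, "allopurinol": 1.03},
        )
        uniforms = draw_cohort_uniforms(500, 365, np.random.default_rng(3))
        a = simulate_cohort(Strategy("allopurinol300", "naproxen"), draw, 500, uniforms=uniforms)
        b = simulate_cohort(Strategy("febuxostat80", "naproxen"), draw, 500, uniforms=uniforms)
        assert a.mean_cost == b.mean_cost
        assert a.mean_qaly == b.mean_qaly

    def test_oracle_equivalence_smoke(self, point_draw):
        strat = Strategy("allopurinol300", "naproxen")
        out = simulate_cohort(strat, point_draw, 20_000, rng=11)
        exact = expected_outcomes_exact(strat, point_draw)
        assert abs(out.mean_cost - exact.cost) < 4 * out.se_cost
        assert abs(out.mean_qaly - exact.qaly) < 4 * out.se_qaly


def brute_force_expectation(strategy, draw, config):
    """Exhaustive enumeration over flare-onset outcomes (deterministic matrix).

    Independent oracle for tiny horizons: walks the day tree, branching only
    on the Bernoulli onset decision of each flare-free day, and accrues
    per-day cost/utility via accrue_day.  Requires a 0/1 transition matrix.
    """
    matrix = draw.transition[strategy.flare_drug]
    assert np.all((matrix == 0) | (matrix == 1)), "enumeration needs a degenerate matrix"
    onset = int(config.onset_state)
    results = []  # (probability, cost, qaly, flares)

    def walk(day, state, flare_day, p, cost, qaly, flares, hazard, on_target):
        if day == draw.horizon_days:
            results.append((p, cost, qaly, flares))
            return
        c, q = accrue_day(state, on_target, strategy, draw, day, config)
        cost, qaly = cost + c, qaly + q
        if state != NO_FLARE:
            if flare_day == draw.flare_duration_days - 1:
                walk(day + 1, NO_FLARE, 0, p, cost, qaly, flares, hazard, on_target)
            else:
                nxt = int(np.argmax(matrix[state]))
                walk(day + 1, nxt, flare_day + 1, p, cost, qaly, flares, hazard, on_target)
        else:
            if day == draw.horizon_days - 1:  # an onset decided today never materializes
                walk(day + 1, state, 0, p, cost, qaly, flares, hazard, on_target)
                return
            walk(day + 1, onset, 0, p * hazard, cost, qaly, flares + 1, hazard, on_target)
            walk(day + 1, NO_FLARE, 0, p * (1 - hazard), cost, qaly, flares, hazard, on_target)

    for on_target, weight in ((True, draw.p_target[strategy.ult]),
                              (False, 1 - draw.p_target[strategy.ult])):
        if weight == 0:
            continue
        h = daily_flare_hazard(on_target, strategy.ult != "no_ult", draw,
                               config.flare_hazard_multiplier)
        start_state = onset if config.entry_with_flare else NO_FLARE
        walk(0, start_state, 0, weight, 0.0, 0.0, 1 if config.entry_with_flare else 0, h,
             on_target)

    cost = sum(p * c for p, c, _, _ in results)
    qaly = sum(p * q for p, _, q, _ in results)
    flares = sum(p * f for p, _, _, f in results)
    total_p = sum(p for p, _, _, _ in results)
    assert total_p == pytest.approx(1.0, abs=1e-12)
    return cost, qaly, flares


class TestExactOracle:
    def test_matches_enumeration_on_toy_horizon(self):
        draw = make_draw(
            horizon_days=3,
            flare_duration_days=2,
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.5
            ),
        )
        config = SimConfig(entry_with_flare=False)
        for ult in ("no_ult", "febuxostat80"):
            strat = Strategy(ult, "naproxen")
            exact = expected_outcomes_exact(strat, draw, config)
            cost, qaly, flares = brute_force_expectation(strat, draw, config)
            assert exact.cost == pytest.approx(cost, rel=1e-12)
            assert exact.qaly == pytest.approx(qaly, rel=1e-12)
            assert exact.expected_flares == pytest.approx(flares, rel=1e-12)

    def test_matches_enumeration_with_entry_flare(self):
        draw = make_draw(
            horizon_days=5,
            flare_duration_days=3,
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.3
            ),
        )
        config = SimConfig(entry_with_flare=True)
        strat = Strategy("allopurinol300", "colchicine")
        exact = expected_outcomes_exact(strat, draw, config)
        cost, qaly, flares = brute_force_expectation(strat, draw, config)
        assert exact.cost == pytest.approx(cost, rel=1e-12)
        assert exact.qaly == pytest.approx(qaly, rel=1e-12)
        assert exact.expected_flares == pytest.approx(flares, rel=1e-12)

    def test_closed_form_zero_hazard(self):
        draw = make_draw(
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.0
            ),
            off_target_annual_disutility=0.0,
        )
        exact = expected_outcomes_exact(
            Strategy("no_ult", "naproxen"), draw, SimConfig(entry_with_flare=False)
        )
        df_u = discount_factors(0.015, 365)
        df_c = discount_factors(0.04, 365)
        assert exact.qaly == pytest.approx(0.86 * df_u.sum() / 365, rel=1e-12)
        assert exact.cost == pytest.approx(19.95 * df_c.sum(), rel=1e-12)
        assert exact.expected_flares == 0.0

    def test_hazard_monotonicity(self, point_draw):
        strat = Strategy("febuxostat80", "naproxen")
        results = [
            expected_outcomes_exact(strat, point_draw, SimConfig(flare_hazard_multiplier=m))
            for m in (1.0, 2.0, 5.0)
        ]
        costs = [r.cost for r in results]
        qalys = [r.qaly for r in results]
        assert costs == sorted(costs)
        assert qalys == sorted(qalys, reverse=True)

    def test_zero_discount_equals_undiscounted_sums(self):
        # with both rates at 0 and no flares, totals are plain sums
        draw = make_draw(
            discount_rate_costs=0.0,
            discount_rate_utility=0.0,
            off_target_annual_disutility=0.0,
            daily_flare_prob=dict.fromkeys(
                ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.0
            ),
        )
        strat = Strategy("allopurinol300", "naproxen")
        exact = expected_outcomes_exact(strat, draw, SimConfig(entry_with_flare=False))
        assert exact.qaly == pytest.approx(0.86, rel=1e-12)
        assert exact.cost == pytest.approx(365 * (19.95 + 0.13), rel=1e-12)
        # discounting strictly reduces both totals
        discounted = expected_outcomes_exact(
            Strategy("allopurinol300", "naproxen"),
            make_draw(
                off_target_annual_disutility=0.0,
                daily_flare_prob=dict.fromkeys(
                    ("on_target_ult", "off_target_ult", "off_target_no_ult"), 0.0
                ),
            ),
            SimConfig(entry_with_flare=False),
        )
        assert discounted.qaly < exact.qaly
        assert discounted.cost < exact.cost
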