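"""Shared fixtures: the bundled input table, stand-in matrices, toy draws."""

from __future__ import annotations

import numpy as np
import pytest

from goutcea import make_paper_fixture, sample_parameter_draw
from goutcea.parameters import ParameterDraw
from goutcea.states import FLARE_DRUGS


@pytest.fixture(scope="session")
def fixture_inputs():
    """(ParameterTable, per-drug matrices, provenance) from the bundle."""
    return make_paper_fixture()


@pytest.fixture(scope="session")
def table(fixture_inputs):
    return fixture_inputs[0]


@pytest.fixture(scope="session")
def matrices(fixture_inputs):
    return fixture_inputs[1]


@pytest.fixture(scope="session")
def point_draw(table, matrices):
    """Deterministic draw: every parameter at its point estimate."""
    return sample_parameter_draw(table, transition_matrices=matrices, psa=False)


DEFAULT_UTILITY = np.array([0.86, 0.77, 0.70, 0.61])
DEFAULT_STATE_COST = np.array([19.95, 32.39, 58.08, 134.32])
DEFAULT_DRUG_COST = {
    "colchicine": 0.61,
    "naproxen": 0.21,
    "prednisone": 0.26,
    "anakinra": 33.4,
    "allopurinol": 0.13,
    "febuxostat": 1.03,
}


def make_draw(**overrides) -> ParameterDraw:
    """Hand-built parameter draw for closed-form and toy-horizon tests."""
    identity = np.eye(4)
    defaults = dict(
        p_target={
            "allopurinol200": 0.457,
            "allopurinol300": 0.480,
            "febuxostat80": 0.729,
            "no_ult": 0.0,
        },
        daily_flare_prob={
            "on_target_ult": 0.000716,
            "off_target_ult": 0.001222,
            "off_target_no_ult": 0.001637,
        },
        utility=DEFAULT_UTILITY.copy(),
        state_cost=DEFAULT_STATE_COST.copy(),
        no_flare_cost=19.95,
        daily_drug_cost=dict(DEFAULT_DRUG_COST),
        transition={drug: identity.copy() for drug in FLARE_DRUGS},
        discount_rate_costs=0.04,
        discount_rate_utility=0.015,
        horizon_days=365,
        flare_duration_days=7,
        off_target_annual_disutility=0.05,
    )
    defaults.update(overrides)
    return ParameterDraw(**defaults)
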