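"""Synthetic ground-truth data generators.

The original model was populated from patient-level clinical-trial data
that cannot be redistributed.  This module generates every input the
pipeline consumes from known ground truth — flare-trial pain panels, ULT
arm summaries, per-patient cost observations — so estimation, simulation
and economics can be exercised (and their recovery properties tested)
end-to-end without any external data.  It also exposes the bundled table
of published point estimates/distributions together with per-drug
transition matrices (the published naproxen supplement if present, else
documented synthetic stand-ins).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .parameters import ParameterTable, load_parameter_table
from .states import FLARE_DRUGS, N_PAIN_STATES, PAIN_STATE_NAMES, PainState

__all__ = [
    "GroundTruth",
    "generate_flare_panel",
    "generate_ult_trials",
    "generate_cost_observations",
    "make_paper_fixture",
    "load_synthetic_matrices",
    "S1_MATRIX_FILENAME",
]

#: Place the published supplementary naproxen matrix (4x4 CSV with
#: pain-state labelled header) under this name in a fixtures directory to
#: have :func:`make_paper_fixture` use it instead of the synthetic stand-in.
S1_MATRIX_FILENAME = "s1_naproxen_matrix.csv"


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters for a synthetic end-to-end experiment."""

    transition: dict[str, np.ndarray]
    p_target: dict[str, float]
    daily_flare_prob: dict[str, float]
    utility: dict[PainState, float]
    state_cost_params: dict[PainState, tuple[float, float, float]]  # (lambda, alpha, beta)
    seed: int = 0

    def __post_init__(self) -> None:
        for drug, m in self.transition.items():
            m = np.asarray(m, float)
            if m.shape != (N_PAIN_STATES, N_PAIN_STATES) or np.any(m < 0):
                raise ValueError(f"invalid truth matrix for {drug}")
            if np.max(np.abs(m.sum(axis=1) - 1)) > 1e-9:
                raise ValueError(f"truth matrix for {drug} not row-stochastic")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_flare_panel(
    truth_matrix: np.ndarray,
    n_patients: int,
    days: int = 7,
    onset_distribution: np.ndarray | None = None,
    seed: int | np.random.Generator | None = 0,
    trial_id: str = "synthetic_trial",
) -> pd.DataFrame:
    """Simulate a flare-trial panel of daily pain states.

    Each patient draws an onset state (default: all start in severe pain,
    matching the simulation's default flare onset) and then evolves for
    ``days`` days under the ground-truth transition matrix.  Returns a
    (trial_id, patient_id, day, pain_state) table; reproducible by seed.
    """
    if n_patients < 1 or days < 2:
        raise ValueError("need n_patients >= 1 and days >= 2")
    matrix = np.asarray(truth_matrix, float)
    rng = np.random.default_rng(seed)
    if onset_distribution is None:
        onset = np.full(n_patients, int(PainState.SEVERE_PAIN))
    else:
        onset_distribution = np.asarray(onset_distribution, float)
        onset = rng.choice(N_PAIN_STATES, size=n_patients, p=onset_distribution)
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0
    states = np.empty((n_patients, days), dtype=np.int64)
    states[:, 0] = onset
    for t in range(1, days):
        u = rng.random(n_patients)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "patient_id": np.repeat(np.arange(n_patients), days),
            "day": np.tile(np.arange(days), n_patients),
            "pain_state": [PAIN_STATE_NAMES[s] for s in states.ravel()],
        }
    )


def generate_ult_trials(
    true_rates: dict[str, float],
    n_per_arm: int = 200,
    n_trials: int = 5,
    reference: str = "febuxostat40",
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Simulate ULT arm summaries with a shared reference arm in every trial.

    Non-reference treatments are spread round-robin over trials (each trial
    randomizes the reference plus one other arm, as in the adjusted
    indirect comparison design).  Responders are binomial at the true
    per-arm target-attainment rates.
    """
    if reference not in true_rates:
        raise ValueError(f"true_rates must include the reference arm {reference!r}")
    if any(not 0 <= r <= 1 for r in true_rates.values()):
        raise ValueError("rates must lie in [0,1]")
    if n_per_arm < 1 or n_trials < 1:
        raise ValueError("need n_per_arm >= 1 and n_trials >= 1")
    rng = np.random.default_rng(seed)
    others = [t for t in true_rates if t != reference]
    rows = []
    for i in range(n_trials):
        tid = f"trial_{i:03d}"
        arms = [reference] + ([others[i % len(others)]] if others else [])
        for arm in arms:
            rows.append(
                {
                    "trial_id": tid,
                    "arm": arm,
                    "n": n_per_arm,
                    "responders": int(rng.binomial(n_per_arm, true_rates[arm])),
                }
            )
    return pd.DataFrame(rows)


def generate_cost_observations(
    state_params: dict[PainState, tuple[float, float, float]],
    n_per_state: int = 100,
    outlier_fraction: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-patient daily cost observations with injected outliers.

    ``state_params`` maps each pain state to (exponential rate ``lambda``
    for the productivity component, gamma shape ``alpha`` and scale
    ``beta`` for the healthcare component).  A fraction of observations is
    designated outliers and inflated x50 on both components.  Returns the
    observation table and a sidecar flag table (patient_id, is_outlier)
    for test assertions.
    """
    if not 0.0 <= outlier_fraction <= 0.1:
        raise ValueError("outlier fraction must lie in [0, 0.1]")
    if n_per_state < 1:
        raise ValueError("need n_per_state >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    flags = []
    pid = 0
    for state in PainState:
        lam, alpha, beta = state_params[state]
        if lam <= 0 or alpha <= 0 or beta <= 0:
            raise ValueError(f"invalid cost parameters for {state.name}")
        prod = rng.exponential(1.0 / lam, size=n_per_state)
        care = rng.gamma(alpha, beta, size=n_per_state)
        n_out = int(round(outlier_fraction * n_per_state))
        outlier_idx = rng.choice(n_per_state, size=n_out, replace=False) if n_out else []
        is_out = np.zeros(n_per_state, dtype=bool)
        is_out[list(outlier_idx)] = True
        prod = np.where(is_out, prod * 50.0, prod)
        care = np.where(is_out, care * 50.0, care)
        for k in range(n_per_state):
            rows.append(
                {
                    "patient_id": pid,
                    "pain_state": PAIN_STATE_NAMES[state],
                    "productivity_cost": prod[k],
                    "healthcare_cost": care[k],
                }
            )
            flags.append({"patient_id": pid, "is_outlier": bool(is_out[k])})
            pid += 1
    return pd.DataFrame(rows), pd.DataFrame(flags)


# ---------------------------------------------------------------------------
# Published-input fixture
# ---------------------------------------------------------------------------


def load_synthetic_matrices() -> dict[str, np.ndarray]:
    """Load the bundled synthetic stand-in transition matrices per drug."""
    text = (
        importlib.resources.files("goutcea.data")
        .joinpath("synthetic_flare_matrices.yaml")
        .read_text(encoding="utf-8")
    )
    raw = yaml.safe_load(text)
    out = {}
    for drug in FLARE_DRUGS:
        m = np.asarray(raw[drug], float)
        if m.shape != (N_PAIN_STATES, N_PAIN_STATES):
            raise ValueError(f"malformed synthetic matrix for {drug}")
        out[drug] = m / m.sum(axis=1, keepdims=True)
    return out


def make_paper_fixture(
    fixtures_dir: str | Path | None = None,
) -> tuple[ParameterTable, dict[str, np.ndarray], dict[str, str]]:
    """The published input table plus per-drug transition matrices.

    Returns ``(table, matrices, provenance)``.  The parameter table is the
    bundled transcription of the published inputs.  If the published
    supplementary naproxen matrix has been placed in ``fixtures_dir`` (as
    ``s1_naproxen_matrix.csv``) it is used and marked ``published``;
    otherwise the bundled synthetic stand-in is substituted and every
    matrix is marked ``synthetic`` so downstream manifests can record that
    the run is not a published-data run.
    """
    from .evidence import read_matrix_csv

    table = load_parameter_table()
    matrices = load_synthetic_matrices()
    provenance = {drug: "synthetic" for drug in FLARE_DRUGS}
    if fixtures_dir is not None:
        s1 = Path(fixtures_dir) / S1_MATRIX_FILENAME
        if s1.exists():
            matrix = read_matrix_csv(s1)
            if np.any(matrix < 0) or np.max(np.abs(matrix.sum(axis=1) - 1)) > 1e-6:
                raise ValueError(f"malformed supplementary matrix file {s1}")
            matrices["naproxen"] = matrix / matrix.sum(axis=1, keepdims=True)
            provenance["naproxen"] = "published"
    return table, matrices, provenance
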