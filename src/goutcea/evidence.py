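"""Evidence synthesis for the decision model.

Two estimation problems feed the simulation:

*  Daily pain-state transition matrices per flare drug, estimated from
   patient-level trial panels (daily 4-level pain scores over up to seven
   days).  Observed consecutive-day transition counts are combined with a
   noninformative Dirichlet prior of 0.5 per cell; deterministic runs use
   posterior means, the PSA samples rows from the posterior.  Where two
   trials inform the same drug, row-normalized probabilities are pooled
   entry-wise by inverse variance and renormalized (pooling the raw counts
   is available behind a switch).

*  Target-attainment probabilities per urate-lowering therapy, from trial
   arm summaries (responders/n) via adjusted indirect comparison against a
   shared reference arm: within-trial log-odds contrasts, inverse-variance
   pooled across trials, back-transformed at the pooled reference rate.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .states import N_PAIN_STATES, PAIN_STATE_NAMES, pain_state_from_name

__all__ = [
    "TransitionCountMatrix",
    "EfficacyEstimate",
    "EvidenceError",
    "count_transitions",
    "dirichlet_posterior",
    "posterior_mean_matrix",
    "sample_transition_matrix",
    "pool_inverse_variance",
    "adjusted_indirect_comparison",
    "synthesize_ult_efficacy",
    "pool_transition_posteriors",
    "read_panel",
    "read_arm_summaries",
    "write_matrix_csv",
    "read_matrix_csv",
]


class EvidenceError(ValueError):
    """Invalid evidence-synthesis input."""


@dataclass(frozen=True)
class TransitionCountMatrix:
    """4x4 consecutive-day transition counts pooled over patients."""

    counts: np.ndarray
    trial_id: str = ""
    drug: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_PAIN_STATES, N_PAIN_STATES):
            raise EvidenceError("transition counts must be 4x4")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise EvidenceError("transition counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EfficacyEstimate:
    """Absolute target-attainment probability with its standard error."""

    treatment: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0:
            raise EvidenceError(f"estimate for {self.treatment} outside [0,1]")
        if self.se < 0:
            raise EvidenceError(f"negative se for {self.treatment}")


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------


def count_transitions(
    panel: pd.DataFrame | Iterable[Sequence[int]],
    trial_id: str = "",
    drug: str = "",
) -> TransitionCountMatrix:
    """Count consecutive-day pain-state transitions pooled over patients.

    ``panel`` is either a (trial_id, patient_id, day, pain_state) table or
    an iterable of per-patient state sequences.  Entry (i, j) of the result
    is the number of (day t in state i, day t+1 in state j) pairs; days
    must be consecutive within a patient, so the total count equals the sum
    of (sequence length - 1).
    """
    if isinstance(panel, pd.DataFrame):
        if len(panel) == 0:
            raise EvidenceError("empty panel")
        sequences = []
        for _, g in panel.groupby("patient_id", sort=False):
            g = g.sort_values("day")
            days = g["day"].to_numpy()
            if np.any(np.diff(days) != 1):
                raise EvidenceError(
                    f"non-consecutive days for patient {g['patient_id'].iloc[0]!r}"
                )
            sequences.append([int(pain_state_from_name(str(s))) for s in g["pain_state"]])
    else:
        sequences = [list(seq) for seq in panel]
    if not sequences:
        raise EvidenceError("empty panel")
    counts = np.zeros((N_PAIN_STATES, N_PAIN_STATES), dtype=np.int64)
    for seq in sequences:
        if len(seq) < 2:
            raise EvidenceError("every patient sequence needs at least 2 days")
        arr = np.asarray(seq, dtype=np.int64)
        if np.any(arr < 0) or np.any(arr >= N_PAIN_STATES):
            raise EvidenceError("pain states must lie in 0..3")
        np.add.at(counts, (arr[:-1], arr[1:]), 1)
    return TransitionCountMatrix(counts, trial_id=trial_id, drug=drug)


def dirichlet_posterior(
    counts: TransitionCountMatrix | np.ndarray, prior: float = 0.5
) -> np.ndarray:
    """Per-row Dirichlet posterior concentrations: counts + a flat prior.

    The default prior of 0.5 per cell avoids empty cells under data
    sparsity while staying noninformative.
    """
    if prior < 0:
        raise EvidenceError("prior must be non-negative")
    c = counts.counts if isinstance(counts, TransitionCountMatrix) else np.asarray(counts, float)
    if c.shape != (N_PAIN_STATES, N_PAIN_STATES):
        raise EvidenceError("counts must be 4x4")
    if np.any(c < 0):
        raise EvidenceError("negative transition counts")
    return c.astype(float) + prior


def posterior_mean_matrix(posterior: np.ndarray) -> np.ndarray:
    """Row-normalize Dirichlet concentrations into a transition matrix."""
    post = np.asarray(posterior, dtype=float)
    if post.shape != (N_PAIN_STATES, N_PAIN_STATES):
        raise EvidenceError("posterior must be 4x4")
    row_sums = post.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0) or not np.all(np.isfinite(post)) or np.any(post < 0):
        raise EvidenceError("posterior concentrations must be non-negative and finite")
    return post / row_sums


def sample_transition_matrix(
    posterior: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Sample each row of a transition matrix from its Dirichlet posterior."""
    post = np.asarray(posterior, dtype=float)
    if post.shape != (N_PAIN_STATES, N_PAIN_STATES):
        raise EvidenceError("posterior must be 4x4")
    rng = np.random.default_rng(rng)
    return np.vstack([rng.dirichlet(row) for row in post])


def pool_transition_posteriors(
    posteriors: Sequence[np.ndarray],
    totals_per_row: Sequence[np.ndarray] | None = None,
    method: str = "probabilities",
) -> np.ndarray:
    """Pool two or more per-trial Dirichlet posteriors for the same drug.

    ``method="probabilities"`` (default): posterior-mean probabilities are
    pooled entry-wise by inverse variance, using the Dirichlet-mean variance
    m(1-m)/(n0+1) per entry (a binomial-style approximation), then each row
    is renormalized and converted back to concentrations at the combined
    row mass.  ``method="counts"``: concentrations are summed minus the
    duplicated prior, i.e. counts are pooled before the posterior step.
    """
    mats = [np.asarray(p, float) for p in posteriors]
    if not mats:
        raise EvidenceError("no posteriors to pool")
    if len(mats) == 1:
        return mats[0]
    if method == "counts":
        prior_cells = 0.5 * (len(mats) - 1)
        return np.sum(mats, axis=0) - prior_cells
    if method != "probabilities":
        raise EvidenceError(f"unknown pooling method {method!r}")
    pooled = np.empty((N_PAIN_STATES, N_PAIN_STATES))
    combined_mass = np.sum([m.sum(axis=1) for m in mats], axis=0)
    for i in range(N_PAIN_STATES):
        for j in range(N_PAIN_STATES):
            ests = []
            for m in mats:
                n0 = m[i].sum()
                mean = m[i, j] / n0
                var = mean * (1 - mean) / (n0 + 1)
                ests.append((mean, np.sqrt(max(var, 1e-12))))
            pooled[i, j] = pool_inverse_variance(ests)[0]
    pooled /= pooled.sum(axis=1, keepdims=True)
    return pooled * combined_mass[:, None]


# ---------------------------------------------------------------------------
# Pooling and indirect comparison
# ---------------------------------------------------------------------------


def pool_inverse_variance(estimates: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Fixed-effect inverse-variance pooling of (value, se) pairs."""
    if not estimates:
        raise EvidenceError("nothing to pool")
    values = np.array([e[0] for e in estimates], float)
    ses = np.array([e[1] for e in estimates], float)
    if np.any(ses <= 0):
        raise EvidenceError("all standard errors must be positive")
    w = 1.0 / ses**2
    return float(np.sum(w * values) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def adjusted_indirect_comparison(
    arm_a: tuple[float, float],
    arm_b: tuple[float, float],
    reference_a: str | None = None,
    reference_b: str | None = None,
) -> tuple[float, float]:
    """Bucher adjusted indirect comparison of A vs B via a common reference.

    Both inputs are (effect, se) contrasts of a treatment against the same
    reference on an additive scale (here: log-odds).  The indirect contrast
    is A - B with se = sqrt(se_A^2 + se_B^2).
    """
    if reference_a is not None and reference_b is not None and reference_a != reference_b:
        raise EvidenceError(
            f"contrasts use different reference treatments: {reference_a!r} vs {reference_b!r}"
        )
    (ea, sa), (eb, sb) = arm_a, arm_b
    if sa < 0 or sb < 0:
        raise EvidenceError("standard errors must be non-negative")
    return ea - eb, float(np.hypot(sa, sb))


def _logit_and_se(responders: float, n: float) -> tuple[float, float]:
    # Woolf logit se; 0.5 added to both cells on the boundary (continuity).
    r = float(responders)
    if r == 0 or r == n:
        r, n = r + 0.5, n + 1.0
    p = r / n
    return float(logit(p)), float(np.sqrt(1.0 / r + 1.0 / (n - r)))


def synthesize_ult_efficacy(
    trials: pd.DataFrame,
    reference: str = "febuxostat40",
    no_ult_label: str = "no_ult",
) -> dict[str, EfficacyEstimate]:
    """Meta-analyze target-attainment probabilities per ULT.

    ``trials`` is an arm-summary table (trial_id, arm, n, responders) in
    which every trial contributing a non-reference arm also randomized the
    reference treatment.  For each treatment, within-trial log-odds
    contrasts against the reference are pooled by inverse variance across
    trials and back-transformed to an absolute probability anchored at the
    inverse-variance-pooled reference-arm rate, with a delta-method se.
    Placebo / no-ULT is fixed at (0, 0): no untreated patient reaches the
    serum-urate target.
    """
    required = {"trial_id", "arm", "n", "responders"}
    if not required <= set(trials.columns):
        raise EvidenceError(f"arm summaries need columns {sorted(required)}")
    if ((trials["responders"] < 0) | (trials["responders"] > trials["n"])).any():
        raise EvidenceError("responders must lie in [0, n]")
    if (trials["n"] <= 0).any():
        raise EvidenceError("arm sizes must be positive")

    ref_rows = trials[trials["arm"] == reference]
    if len(ref_rows) == 0:
        raise EvidenceError(f"no arms found for reference treatment {reference!r}")
    ref_logits = [_logit_and_se(r.responders, r.n) for r in ref_rows.itertuples()]
    ref_logit, ref_se = pool_inverse_variance(ref_logits)

    out: dict[str, EfficacyEstimate] = {}
    by_trial = {tid: g.set_index("arm") for tid, g in trials.groupby("trial_id")}
    for treatment in trials["arm"].unique():
        if treatment == reference:
            continue
        if treatment == no_ult_label:
            out[treatment] = EfficacyEstimate(treatment, 0.0, 0.0)
            continue
        contrasts = []
        for tid, g in by_trial.items():
            if treatment not in g.index:
                continue
            if reference not in g.index:
                raise EvidenceError(
                    f"trial {tid!r} has arm {treatment!r} but no reference arm {reference!r}"
                )
            lt, st = _logit_and_se(g.loc[treatment, "responders"], g.loc[treatment, "n"])
            lr, sr = _logit_and_se(g.loc[reference, "responders"], g.loc[reference, "n"])
            contrasts.append(adjusted_indirect_comparison((lt, st), (lr, sr)))
        if not contrasts:
            raise EvidenceError(f"treatment {treatment!r} never co-randomized with reference")
        d, d_se = pool_inverse_variance(contrasts)
        p = float(expit(ref_logit + d))
        se = p * (1.0 - p) * float(np.hypot(d_se, ref_se))
        out[treatment] = EfficacyEstimate(treatment, p, se)
    if no_ult_label not in out:
        out[no_ult_label] = EfficacyEstimate(no_ult_label, 0.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a flare-trial panel CSV (trial_id, patient_id, day, pain_state)."""
    panel = pd.read_csv(path)
    missing = {"trial_id", "patient_id", "day", "pain_state"} - set(panel.columns)
    if missing:
        raise EvidenceError(f"panel missing columns {sorted(missing)}")
    return panel


def read_arm_summaries(path: str | Path) -> pd.DataFrame:
    """Read a ULT arm-summary CSV (trial_id, arm, n, responders)."""
    return pd.read_csv(path)


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 4x4 matrix as CSV with pain-state labelled rows/columns."""
    pd.DataFrame(
        np.asarray(matrix, float), index=PAIN_STATE_NAMES, columns=PAIN_STATE_NAMES
    ).to_csv(path, index_label="from_state")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != list(PAIN_STATE_NAMES) or list(df.index) != list(PAIN_STATE_NAMES):
        raise EvidenceError(f"malformed matrix file {path}: expected pain-state labels")
    return df.to_numpy(float)
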