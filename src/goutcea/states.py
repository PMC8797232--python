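"""Health states and treatment labels for the gout decision model.

A simulated patient is, on any given day, either between flares
(``NO_FLARE``) or inside a seven-day flare episode, during which they
occupy one of four mutually exclusive ordinal pain states.  The pain
states index rows and columns of the per-drug daily transition matrices;
the no-flare marker never appears in those matrices.
"""

from __future__ import annotations

import enum


class PainState(enum.IntEnum):
    """Ordinal pain level reported during a gout flare."""

    NO_PAIN = 0
    MILD_PAIN = 1
    MODERATE_PAIN = 2
    SEVERE_PAIN = 3


#: Canonical ordering used by every 4x4 matrix and 4-vector in the package.
PAIN_STATES: tuple[PainState, ...] = tuple(PainState)

PAIN_STATE_NAMES: tuple[str, ...] = (
    "no_pain",
    "mild_pain",
    "moderate_pain",
    "severe_pain",
)

N_PAIN_STATES = 4

#: Sentinel state code used only by the simulation engine for days with no
#: active flare.  Deliberately not a member of :class:`PainState`.
NO_FLARE = 4

#: Urate-lowering therapy options.  ``no_ult`` patients never reach the
#: serum-urate target and carry no ULT drug cost.
ULT_OPTIONS: tuple[str, ...] = (
    "allopurinol200",
    "allopurinol300",
    "febuxostat80",
    "no_ult",
)

#: Anti-inflammatory options for treating a flare episode.
FLARE_DRUGS: tuple[str, ...] = ("naproxen", "colchicine", "prednisone", "anakinra")

#: Maps each ULT option to the drug-price row it draws its daily cost from.
ULT_DRUG_COST_KEY: dict[str, str | None] = {
    "allopurinol200": "allopurinol",
    "allopurinol300": "allopurinol",
    "febuxostat80": "febuxostat",
    "no_ult": None,
}


def pain_state_from_name(name: str) -> PainState:
    """Resolve a pain-state label (``"mild_pain"`` or ``"Mild pain"``) to the enum."""
    key = name.strip().lower().replace(" ", "_")
    if not key.endswith("_pain") and key != "no_pain":
        key = key + "_pain" if key in ("mild", "moderate", "severe") else key
    try:
        return PainState(PAIN_STATE_NAMES.index(key))
    except ValueError:
        raise ValueError(f"unknown pain state {name!r}") from None
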