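"""Run configuration, validation, result writers and manifests.

A run is fully described by a :class:`RunConfig` (strategies, PSA sizes,
seed, structural overrides, WTP grid, output directory) validated against
a strict schema — unknown keys are rejected so typos cannot silently fall
back to defaults.  Results are written as deterministic CSVs plus a JSON
manifest carrying the seed, a hash of the effective configuration and the
transition-matrix provenance, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import PsaResult, compute_ceac, incremental_analysis
from .simulation import SimConfig, Strategy
from .states import FLARE_DRUGS

__all__ = ["RunConfig", "ConfigError", "load_config", "write_results", "read_results"]


class ConfigError(ValueError):
    """Invalid run configuration."""


#: Default strategy grid: the three ULT options compared in the base case
#: (no ULT, allopurinol 300 mg, febuxostat 80 mg) crossed with the four
#: flare drugs.
DEFAULT_STRATEGIES: tuple[str, ...] = tuple(
    f"{ult}+{drug}"
    for ult in ("no_ult", "allopurinol300", "febuxostat80")
    for drug in FLARE_DRUGS
)

_KNOWN_KEYS = {
    "strategies",
    "parameter_source",
    "fixtures_dir",
    "n_outer",
    "n_inner",
    "seed",
    "discount_rate_costs",
    "discount_rate_utility",
    "wtp_max",
    "wtp_step",
    "entry_with_flare",
    "flare_hazard_multiplier",
    "off_target_annual_disutility",
    "no_flare_daily_cost",
    "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted description of one analysis run."""

    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    parameter_source: str = "fixture"  # "fixture" or a path to a YAML/JSON table
    fixtures_dir: str | None = None  # optional dir holding the published matrix
    n_outer: int = 2000
    n_inner: int = 200
    seed: int = 20220128
    discount_rate_costs: float | None = None  # None -> parameter table value
    discount_rate_utility: float | None = None
    wtp_max: float = 80_000.0
    wtp_step: float = 1_000.0
    entry_with_flare: bool = True
    flare_hazard_multiplier: float = 1.0
    off_target_annual_disutility: float | None = None
    no_flare_daily_cost: float | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        problems = []
        if self.n_outer < 1:
            problems.append(f"n_outer must be >= 1 (got {self.n_outer})")
        if self.n_inner < 1:
            problems.append(f"n_inner must be >= 1 (got {self.n_inner})")
        if not 0 <= self.seed < 2**31:
            problems.append("seed must lie in [0, 2^31)")
        if self.wtp_max < 0 or self.wtp_step <= 0:
            problems.append("wtp grid requires wtp_max >= 0 and wtp_step > 0")
        if self.flare_hazard_multiplier < 0:
            problems.append("flare_hazard_multiplier must be >= 0")
        for r in (self.discount_rate_costs, self.discount_rate_utility):
            if r is not None and r < 0:
                problems.append("discount rates must be >= 0")
        if not self.strategies:
            problems.append("strategy list is empty")
        for s in self.strategies:
            try:
                Strategy.parse(s)
            except Exception as exc:
                problems.append(f"bad strategy {s!r}: {exc}")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def strategy_objects(self) -> list[Strategy]:
        return [Strategy.parse(s) for s in self.strategies]

    @property
    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)

    @property
    def undiscounted(self) -> bool:
        return self.discount_rate_costs == 0.0 and self.discount_rate_utility == 0.0

    def sim_config(self) -> SimConfig:
        return SimConfig(
            entry_with_flare=self.entry_with_flare,
            flare_hazard_multiplier=self.flare_hazard_multiplier,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["strategies"] = list(self.strategies)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(source: str | Path | dict | None = None, **overrides: Any) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or defaults).

    An empty/absent file yields the all-defaults base case.  Unknown keys
    and invalid values raise :class:`ConfigError` listing every offending
    key.  ``overrides`` (e.g. from CLI flags) are applied after the file
    and validated together with it.
    """
    raw: dict[str, Any] = {}
    if isinstance(source, dict):
        raw = dict(source)
    elif source is not None:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        raw = loaded
    raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "strategies" in raw:
        raw["strategies"] = tuple(raw["strategies"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_results(
    results: dict[str, Any], out_dir: str | Path, config: RunConfig | None = None
) -> dict[str, Path]:
    """Write analysis outputs as CSVs plus a JSON run manifest.

    ``results`` may contain ``psa`` (:class:`PsaResult`), ``incremental``
    and ``ceac`` tables, and ``provenance`` metadata.  Field order and
    float formatting are fixed, so identical inputs reproduce identical
    bytes.  Returns the mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    psa = results.get("psa")
    if psa is not None:
        df = psa.draws if isinstance(psa, PsaResult) else pd.DataFrame(psa)
        path = out / "psa_draws.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["psa_draws"] = path
    if results.get("incremental") is not None:
        path = out / "incremental.csv"
        results["incremental"].to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["incremental"] = path
    if results.get("ceac") is not None:
        path = out / "ceac.csv"
        results["ceac"].to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["ceac"] = path

    manifest: dict[str, Any] = {
        "package": "goutcea",
        "version": __version__,
        "scenario_id": results.get("scenario_id", "base_case"),
        "provenance": results.get("provenance", {}),
        "artifacts": {k: p.name for k, p in written.items()},
    }
    if isinstance(psa, PsaResult):
        manifest["n_outer"] = psa.n_outer
        manifest["n_inner"] = psa.n_inner
        manifest["master_seed"] = psa.seed
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["config_sha256"] = config.hash()
        manifest["undiscounted"] = config.undiscounted
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written["manifest"] = path
    return written


def read_results(out_dir: str | Path) -> dict[str, Any]:
    """Read back a results directory written by :func:`write_results`."""
    out = Path(out_dir)
    results: dict[str, Any] = {}
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        results["manifest"] = json.loads(manifest_path.read_text(encoding="utf-8"))
    for name in ("psa_draws", "incremental", "ceac"):
        path = out / f"{name}.csv"
        if path.exists():
            results[name] = pd.read_csv(path)
    return results
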