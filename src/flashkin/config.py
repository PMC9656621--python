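"""Run configuration: YAML schema, validation and provenance records."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .beam import BeamSchedule, GValueSet, default_gvalues, pulses_for
from .ntcp import NTCPModel
from .reaction_network import (
    ReactionSystem,
    biological_system,
    load_reaction_system,
    water_system,
)

__all__ = ["RunConfig", "load_config", "provenance_record"]


class ConfigError(ValueError):
    """The run configuration violates the schema."""


@dataclass
class RunConfig:
    """Validated run configuration (one simulation)."""

    medium: str = "biological"
    species_table: str | None = None
    reaction_table: str | None = None
    o2_percent: float = 3.8
    clamp_o2: bool = True
    t_end: float | None = None
    seed: int = 0
    g_values: dict[str, float] | None = None
    beam: dict[str, Any] = field(default_factory=dict)
    ntcp: dict[str, Any] = field(default_factory=dict)
    tolerances: dict[str, float] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    # -- builders --------------------------------------------------------
    def build_system(self) -> ReactionSystem:
        if self.species_table or self.reaction_table:
            if not (self.species_table and self.reaction_table):
                raise ConfigError(
                    "species_table and reaction_table must be given together"
                )
            return load_reaction_system(self.species_table, self.reaction_table)
        if self.medium == "biological":
            return biological_system()
        if self.medium == "water_only":
            return water_system()
        raise ConfigError(f"unknown medium {self.medium!r}")

    def build_schedule(self) -> BeamSchedule:
        b = self.beam
        try:
            dose = float(b["dose_Gy"])
            rate = float(b["mean_dose_rate_Gy_s"])
        except KeyError as exc:
            raise ConfigError(f"beam block missing key {exc}") from exc
        mode = b.get("mode", "continuous")
        if mode == "continuous":
            return BeamSchedule.continuous(dose, rate)
        width = float(b.get("pulse_width_s", 1.8e-6))
        if mode == "semi_continuous":
            return BeamSchedule.semi_continuous(dose, rate, width)
        if mode != "pulsed":
            raise ConfigError(f"unknown beam mode {mode!r}")
        if "n_pulses" in b:
            return BeamSchedule.pulsed(dose, rate, width, int(b["n_pulses"]))
        if "frequency_Hz" in b:
            return pulses_for(rate, dose, float(b["frequency_Hz"]), width)
        raise ConfigError("pulsed beam needs n_pulses or frequency_Hz")

    def build_gvalues(self) -> GValueSet:
        if self.g_values:
            return GValueSet({k: float(v) for k, v in self.g_values.items()})
        return default_gvalues(self.medium)

    def build_ntcp_model(self) -> NTCPModel:
        return NTCPModel(
            gamma=float(self.ntcp.get("gamma", 1000.0)),
            auc50=float(self.ntcp.get("auc50", 0.1682)),
        )

    @property
    def rtol(self) -> float:
        return float(self.tolerances.get("rtol", 1e-6))

    @property
    def atol(self) -> float:
        return float(self.tolerances.get("atol", 1e-12))


_KNOWN_KEYS = {
    "medium", "species_table", "reaction_table", "o2_percent", "clamp_o2",
    "t_end", "seed", "g_values", "beam", "ntcp", "tolerances", "output",
}


def load_config(path: str | Path) -> RunConfig:
    """Read and schema-check a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "beam" not in raw:
        raise ConfigError(f"{path}: missing required 'beam' block")
    cfg = RunConfig(
        medium=raw.get("medium", "biological"),
        species_table=raw.get("species_table"),
        reaction_table=raw.get("reaction_table"),
        o2_percent=float(raw.get("o2_percent", 3.8)),
        clamp_o2=bool(raw.get("clamp_o2", True)),
        t_end=(None if raw.get("t_end") is None else float(raw["t_end"])),
        seed=int(raw.get("seed", 0)),
        g_values=raw.get("g_values"),
        beam=raw.get("beam", {}),
        ntcp=raw.get("ntcp", {}),
        tolerances=raw.get("tolerances", {}),
        raw=raw,
    )
    # fail fast on structural problems
    cfg.build_schedule()
    if not 0.0 <= cfg.o2_percent <= 100.0:
        raise ConfigError("o2_percent must be in [0, 100]")
    return cfg


def provenance_record(cfg: RunConfig) -> dict:
    """Config echo + version + seed, written next to every output."""
    from . import __version__

    return {
        "package": "flashkin",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.raw,
    }
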