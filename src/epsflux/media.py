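"""Growth-medium definitions as exchange-reaction uptake limits.

A medium lists, per exchange reaction, the maximal uptake rate in
mmol/gDW/h.  Applying a medium sets the exchange lower bound to minus that
limit (uptake is negative exchange flux) and closes uptake for every
exchange not listed; secretion stays open up to a large finite cap.

Two presets mirror the study conditions: ``minimal`` (glucose as sole
carbon source plus inorganic nitrogen, phosphate, sulfate, magnesium,
oxygen, water, protons) and ``fermentation`` (minimal plus all 20
proteinogenic amino acids, each capped at 0.01 mmol/gDW/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: conventional finite cap used for unconstrained fluxes
DEFAULT_FLUX_CAP = 1000.0
#: default glucose uptake limit in the presets, mmol/gDW/h
DEFAULT_GLUCOSE_UPTAKE = 10.0
#: amino-acid uptake cap used in the fermentation medium, mmol/gDW/h
AMINO_ACID_UPTAKE = 0.01

AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)


def amino_acid_exchange(aa: str) -> str:
    return f"EX_{aa}__L_e"


GLUCOSE_EXCHANGE = "EX_glc__D_e"
NITROGEN_EXCHANGE = "EX_nh4_e"

_INORGANIC = {
    NITROGEN_EXCHANGE: 10.0,
    "EX_pi_e": 10.0,
    "EX_so4_e": 10.0,
    "EX_mg2_e": 10.0,
    "EX_o2_e": DEFAULT_FLUX_CAP,
    "EX_h2o_e": DEFAULT_FLUX_CAP,
    "EX_h_e": DEFAULT_FLUX_CAP,
}


class MediumError(ValueError):
    pass


@dataclass(frozen=True)
class MediumDefinition:
    """Named set of uptake limits (mmol/gDW/h, all non-negative)."""

    name: str
    uptake_limits: dict[str, float] = field(default_factory=dict)
    unconstrained_secretion: bool = True
    secretion_cap: float = DEFAULT_FLUX_CAP

    def __post_init__(self) -> None:
        for rid, limit in self.uptake_limits.items():
            if limit < 0:
                raise MediumError(f"negative uptake limit for {rid}: {limit}")

    def with_limit(self, exchange_id: str, limit: float) -> "MediumDefinition":
        """Return a copy with one uptake limit added or overridden."""
        limits = dict(self.uptake_limits)
        limits[exchange_id] = float(limit)
        return replace(self, uptake_limits=limits)

    def without(self, exchange_id: str) -> "MediumDefinition":
        limits = {k: v for k, v in self.uptake_limits.items() if k != exchange_id}
        return replace(self, uptake_limits=limits)


def minimal_medium(glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE) -> MediumDefinition:
    limits = {GLUCOSE_EXCHANGE: glucose_uptake, **_INORGANIC}
    return MediumDefinition("minimal", limits)


def fermentation_medium(
    glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE,
    amino_acid_uptake: float = AMINO_ACID_UPTAKE,
) -> MediumDefinition:
    base = minimal_medium(glucose_uptake)
    limits = dict(base.uptake_limits)
    for aa in AMINO_ACIDS:
        limits[amino_acid_exchange(aa)] = amino_acid_uptake
    return MediumDefinition("fermentation", limits)


_PRESETS = {
    "minimal": minimal_medium,
    "fermentation": fermentation_medium,
}


def load_medium(config: str | Path | Mapping) -> MediumDefinition:
    """Build a medium from a preset name, a config mapping, or a YAML file.

    A config mapping has the layout::

        base: minimal            # optional preset to start from
        name: my-medium          # optional
        uptake_limits:           # per-exchange overrides / additions
          EX_glc__D_e: 0.506

    Raises :class:`MediumError` for unknown presets or negative limits.
    """
    if isinstance(config, str) and config in _PRESETS:
        return _PRESETS[config]()
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise MediumError(f"unknown medium preset or missing file: {config!r}")
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise MediumError(f"cannot interpret medium config {config!r}")

    base_name = config.get("base")
    if base_name is not None:
        if base_name not in _PRESETS:
            raise MediumError(f"unknown base medium preset {base_name!r}")
        limits = dict(_PRESETS[base_name]().uptake_limits)
    else:
        limits = {}
    for rid, limit in (config.get("uptake_limits") or {}).items():
        limits[rid] = float(limit)
    return MediumDefinition(
        name=str(config.get("name", base_name or "custom")),
        uptake_limits=limits,
        unconstrained_secretion=bool(config.get("unconstrained_secretion", True)),
        secretion_cap=float(config.get("secretion_cap", DEFAULT_FLUX_CAP)),
    )
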