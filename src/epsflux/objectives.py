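"""Biomass and EPS target pseudo-reactions from measured compositions.

The biomass equation drains macromolecular precursors in proportions
measured per gram dry weight: a mass fraction w (g/gDW) of a precursor
with residue molar mass M (g/mol) becomes a molar coefficient
1000*w/M (mmol/gDW).  Growth-associated maintenance adds an ATP
hydrolysis term.  The EPS target drains activated nucleotide-sugar
donors in the measured monosaccharide mole ratios (normalized to 1 mmol
of total monosaccharide per unit product), releasing the corresponding
nucleoside di-/monophosphates.

Numeric compositions are data, not code: defaults shipped here are
documented placeholders with the expected qualitative shape (glucose-
dominated EPS, protein/glucan-dominated biomass) and every number can be
overridden from a config mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core import Reaction

MACROMOLECULES = (
    "protein", "dna", "rna", "lipid", "glucan", "chitin", "small_molecules",
)

EPS_SUGARS = (
    "glucose", "galactose", "mannose", "xylose", "arabinose", "fucose", "rhamnose",
)

#: monosaccharide -> (activated donor metabolite, released nucleotide)
DEFAULT_DONOR_MAP: dict[str, tuple[str, str]] = {
    "glucose": ("udpg_c", "udp_c"),
    "galactose": ("udpgal_c", "udp_c"),
    "mannose": ("gdpman_c", "gdp_c"),
    "xylose": ("udpxyl_c", "udp_c"),
    "arabinose": ("udparab_c", "udp_c"),
    "fucose": ("gdpfuc_c", "gdp_c"),
    "rhamnose": ("dtdprmn_c", "dtdp_c"),
}

_TOL = 1e-6


class CompositionError(ValueError):
    pass


def _check_unit_sum(mapping: Mapping[str, float], what: str, target: float = 1.0) -> None:
    total = sum(mapping.values())
    if any(v < 0 for v in mapping.values()):
        raise CompositionError(f"{what} contains negative entries")
    if abs(total - target) > _TOL * max(1.0, target):
        raise CompositionError(f"{what} sums to {total}, expected {target}")


@dataclass
class BiomassComposition:
    """Macromolecular composition of one gram of dry cell mass."""

    mass_fractions: dict[str, float]
    amino_acid_mole_fractions: dict[str, float] = field(default_factory=dict)
    nucleotide_mole_fractions: dict[str, float] = field(default_factory=dict)
    rna_dna_ratio: float = 6.0
    gam_atp: float = 40.0  # mmol ATP/gDW, growth-associated maintenance

    def __post_init__(self) -> None:
        unknown = set(self.mass_fractions) - set(MACROMOLECULES)
        if unknown:
            raise CompositionError(f"unknown macromolecule classes: {sorted(unknown)}")
        _check_unit_sum(self.mass_fractions, "biomass mass fractions")
        if self.amino_acid_mole_fractions:
            _check_unit_sum(self.amino_acid_mole_fractions, "amino-acid mole fractions")
        if self.nucleotide_mole_fractions:
            _check_unit_sum(self.nucleotide_mole_fractions, "nucleotide mole fractions")
        if self.gam_atp < 0:
            raise CompositionError("growth-associated maintenance ATP must be >= 0")

    @classmethod
    def default(cls) -> "BiomassComposition":
        # placeholder composition with a realistic fungal shape; override
        # with measured data via from_config for any real analysis
        return cls(
            mass_fractions={
                "protein": 0.38,
                "dna": 0.01,
                "rna": 0.06,
                "lipid": 0.10,
                "glucan": 0.26,
                "chitin": 0.06,
                "small_molecules": 0.13,
            }
        )

    @classmethod
    def from_config(cls, config: Mapping) -> "BiomassComposition":
        return cls(
            mass_fractions=dict(config["mass_fractions"]),
            amino_acid_mole_fractions=dict(config.get("amino_acid_mole_fractions", {})),
            nucleotide_mole_fractions=dict(config.get("nucleotide_mole_fractions", {})),
            rna_dna_ratio=float(config.get("rna_dna_ratio", 6.0)),
            gam_atp=float(config.get("gam_atp", 40.0)),
        )


@dataclass
class EpsComposition:
    """Monosaccharide mole percentages of the exopolysaccharide (sum 100)."""

    mole_percent: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.mole_percent) - set(EPS_SUGARS)
        if unknown:
            raise CompositionError(f"unknown EPS monosaccharides: {sorted(unknown)}")
        _check_unit_sum(self.mole_percent, "EPS mole percentages", target=100.0)
        largest = max(self.mole_percent, key=self.mole_percent.get)
        if largest != "glucose":
            raise CompositionError(
                f"glucose must be the dominant EPS monosaccharide, got {largest!r}"
            )

    @classmethod
    def default(cls) -> "EpsComposition":
        # glucose-dominated, fucose/rhamnose-poor placeholder profile
        return cls(
            mole_percent={
                "glucose": 55.0,
                "galactose": 15.0,
                "mannose": 12.0,
                "xylose": 8.0,
                "arabinose": 5.0,
                "fucose": 3.0,
                "rhamnose": 2.0,
            }
        )

    @property
    def mole_fractions(self) -> dict[str, float]:
        return {k: v / 100.0 for k, v in self.mole_percent.items()}


#: default energy metabolite ids for the maintenance term
DEFAULT_ENERGY_IDS = {
    "atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c", "h": "h_c",
}


def build_biomass_reaction(
    composition: BiomassComposition,
    precursor_registry: Mapping[str, tuple[str, float]],
    biomass_metabolite: str = "biomass_c",
    energy_ids: Mapping[str, str] | None = None,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Assemble the biomass pseudo-reaction (flux unit: 1/h).

    ``precursor_registry`` maps each macromolecule class with non-zero
    mass fraction to ``(metabolite_id, residue_molar_mass_g_per_mol)``.
    The molar coefficients invert exactly back to the input mass
    fractions (see :func:`mass_fractions_from_reaction`).
    """
    energy = dict(DEFAULT_ENERGY_IDS, **(energy_ids or {}))
    stoich: dict[str, float] = {}
    for macro, fraction in composition.mass_fractions.items():
        if fraction == 0:
            continue
        if macro not in precursor_registry:
            raise CompositionError(f"no precursor mapping for {macro!r}")
        met_id, molar_mass = precursor_registry[macro]
        if molar_mass <= 0:
            raise CompositionError(f"molar mass for {macro!r} must be positive")
        stoich[met_id] = stoich.get(met_id, 0.0) - 1000.0 * fraction / molar_mass
    if composition.gam_atp > 0:
        stoich[energy["atp"]] = stoich.get(energy["atp"], 0.0) - composition.gam_atp
        stoich[energy["h2o"]] = stoich.get(energy["h2o"], 0.0) - composition.gam_atp
        stoich[energy["adp"]] = stoich.get(energy["adp"], 0.0) + composition.gam_atp
        stoich[energy["pi"]] = stoich.get(energy["pi"], 0.0) + composition.gam_atp
        stoich[energy["h"]] = stoich.get(energy["h"], 0.0) + composition.gam_atp
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        reaction_id, stoich, lower_bound=0.0, upper_bound=1000.0,
        name="biomass objective", subsystem="other",
    )


def mass_fractions_from_reaction(
    reaction: Reaction,
    precursor_registry: Mapping[str, tuple[str, float]],
) -> dict[str, float]:
    """Invert a biomass reaction back to g/gDW mass fractions."""
    by_met = {met: (macro, mass) for macro, (met, mass) in precursor_registry.items()}
    out: dict[str, float] = {}
    for met, coeff in reaction.stoichiometry.items():
        if coeff < 0 and met in by_met:
            macro, mass = by_met[met]
            out[macro] = out.get(macro, 0.0) + (-coeff) * mass / 1000.0
    return out


def build_eps_reaction(
    eps: EpsComposition,
    nucleotide_sugar_registry: Mapping[str, tuple[str, str]] | None = None,
    eps_metabolite: str = "eps_c",
    reaction_id: str = "EPS",
) -> Reaction:
    """Assemble the EPS target pseudo-reaction.

    Consumes one mmol of activated donor total, split in the composition's
    mole ratios, releasing the matching nucleotide per donor and producing
    one unit of polysaccharide.  The stoichiometry is homogeneous of
    degree one in the composition (scaling all percentages cancels in the
    normalization).
    """
    registry = dict(DEFAULT_DONOR_MAP, **(nucleotide_sugar_registry or {}))
    stoich: dict[str, float] = {}
    for sugar, fraction in eps.mole_fractions.items():
        if fraction == 0:
            continue
        if sugar not in registry:
            raise CompositionError(f"no nucleotide-sugar donor mapped for {sugar!r}")
        donor, released = registry[sugar]
        stoich[donor] = stoich.get(donor, 0.0) - fraction
        stoich[released] = stoich.get(released, 0.0) + fraction
    # keep accumulated coefficients on the shortest-decimal double so they
    # survive text serialization round trips exactly
    stoich = {m: round(c, 12) for m, c in stoich.items()}
    stoich[eps_metabolite] = stoich.get(eps_metabolite, 0.0) + 1.0
    return Reaction(
        reaction_id, stoich, lower_bound=0.0, upper_bound=1000.0,
        name="EPS production target", subsystem="GB",
    )
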