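"""Seeded toy metabolic models with planted, analytically known truth.

Each generated model is a compartment-free core carbon network: carbon-
source exchanges feed kinase/catabolism steps into a lumped energy module
(a rational ATP yield per substrate), which drives a biomass pseudo-
reaction; optionally, a nucleotide-sugar branch reproduces the canonical
exopolysaccharide precursor topology (glucose-6-P <-> fructose-6-P,
glucose-1-P <-> glucose-6-P, activation to UDP-glucose / GDP-mannose /
dTDP-glucose, the 4-epimerase, dehydrogenase/decarboxylase and
deoxysugar steps) ending in an EPS target reaction over all seven
donors.  GPR rules include isozyme pairs (OR) and enzyme complexes
(AND); a configurable number of uniquely catalysed steps on the biomass
path plants known essential genes.

Because every yield is a small rational number and the topology is a
tree of linear routes, the maximal growth and EPS rates have closed
forms, and gene essentiality follows structurally from single-knockout
GPR falsification over the required-reaction sets — truths independent
of any LP solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MetabolicModel, Metabolite, Reaction, find_dead_ends
from .deletion import ESSENTIALITY_THRESHOLD
from .fba import apply_medium, solve_fba
from .gpr import GprRule
from .media import AMINO_ACIDS, amino_acid_exchange, fermentation_medium, minimal_medium
from .objectives import EpsComposition, build_eps_reaction
from .phenotypes import CALL_GROWTH, CALL_NO_GROWTH, GrowthCall

#: ATP consumed per unit biomass in toy models
BIOMASS_ATP = 20.0
#: candidate non-glucose carbon sources, in deterministic order
CARBON_POOL = ("gal", "man", "fru", "xyl", "arab", "rmn", "fuc", "suc", "malt", "lac")
#: reactions eligible for planted isozyme pairs, in assignment order
ISOZYME_CANDIDATES = ("PMI", "GALE", "GLK", "ENERGY", "UPT_nh4")


class ToySpecError(ValueError):
    pass


@dataclass(frozen=True)
class ToyModelSpec:
    """Generation parameters; the seed fully determines the output."""

    n_carbon_sources: int = 3
    include_eps_pathway: bool = True
    n_isozyme_pairs: int = 2
    n_planted_essential: int = 2
    inject_gap: bool = False
    seed: int = 0
    include_amino_acids: bool = True
    screen_truth: bool = False  # run the overexpression screen at generation

    def __post_init__(self) -> None:
        if self.n_carbon_sources < 1:
            raise ToySpecError("need at least one carbon source (glucose)")
        if self.n_carbon_sources - 1 > len(CARBON_POOL):
            raise ToySpecError("too many carbon sources requested")
        if self.n_isozyme_pairs < 0 or self.n_planted_essential < 0:
            raise ToySpecError("counts must be >= 0")
        n_cand = len(ISOZYME_CANDIDATES) if self.include_eps_pathway else 3
        if self.n_isozyme_pairs > n_cand:
            raise ToySpecError(
                f"at most {n_cand} isozyme pairs available for this topology"
            )


@dataclass
class ToyModelTruth:
    """Planted ground truth emitted with each generated model."""

    essential_genes_growth: set[str] = field(default_factory=set)
    essential_genes_eps: set[str] | None = None
    expected_phenotype_calls: list[GrowthCall] = field(default_factory=list)
    analytic_max_growth: float = 0.0
    analytic_max_eps: float | None = None
    top_overexpression_target: str | None = None
    gap_metabolite: str | None = None
    atp_yield: float = 0.0


class _Builder:
    def __init__(self) -> None:
        self.model = MetabolicModel(id="toy")
        self.isozyme_map: dict[str, str] = {}

    def met(self, mid: str) -> str:
        if mid not in self.model.metabolites:
            self.model.add_metabolite(Metabolite(mid))
        return mid

    def rxn(self, rid, stoich, lb=0.0, ub=1000.0, gpr="", subsystem="other"):
        for m in stoich:
            self.met(m)
        self.model.add_reaction(
            Reaction(rid, dict(stoich), lb, ub, gpr=GprRule.from_string(gpr),
                     subsystem=subsystem)
        )

    def gpr_for(self, rid: str) -> str:
        """Single gene g_<rid>, or an OR pair when planted as isozymes."""
        if rid in self.isozyme_map:
            return self.isozyme_map[rid]
        return f"g_{rid}"


def generate_toy_model(spec: ToyModelSpec, verify: bool = True):
    """Generate ``(model, truth)`` for a toy-model specification.

    With ``verify=True`` (default) the closed-form optima are re-checked
    against the LP engine and the model is checked gap-free, so a
    generator/solver disagreement fails loudly at generation time.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    truth = ToyModelTruth()

    # planted isozyme pairs on the first n candidate reactions
    candidates = [
        c for c in ISOZYME_CANDIDATES
        if spec.include_eps_pathway or c in ("GLK", "ENERGY", "UPT_nh4")
    ]
    for rid in candidates[: spec.n_isozyme_pairs]:
        b.isozyme_map[rid] = f"g_{rid}_1 or g_{rid}_2"

    atp_yield = float(rng.choice([6, 8, 10, 12]))
    truth.atp_yield = atp_yield

    # --- glucose backbone -------------------------------------------------
    b.rxn("EX_glc__D_e", {"glc__D_e": -1}, -10, 1000, subsystem="ER")
    b.rxn("UPT_glc", {"glc__D_e": -1, "glc__D_c": 1}, 0, 1000,
          gpr="g_UPT_glc", subsystem="TR")
    b.rxn("GLK", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1}, 0, 1000,
          gpr=b.gpr_for("GLK"), subsystem="CM")
    b.rxn("ENERGY", {"g6p_c": -1, "atp_c": atp_yield}, 0, 1000,
          gpr=b.gpr_for("ENERGY"), subsystem="EM")

    # --- inorganic nutrients ---------------------------------------------
    b.rxn("EX_nh4_e", {"nh4_e": -1}, -10, 1000, subsystem="ER")
    b.rxn("UPT_nh4", {"nh4_e": -1, "nh4_c": 1}, 0, 1000,
          gpr=b.gpr_for("UPT_nh4"), subsystem="TR")
    b.rxn("EX_pi_e", {"pi_e": -1}, -10, 1000, subsystem="ER")
    b.rxn("UPT_pi", {"pi_e": -1, "pi_c": 1}, 0, 1000,
          gpr="g_UPT_pi", subsystem="TR")

    # --- extra carbon sources, one optionally left without a route -------
    others = list(CARBON_POOL[: spec.n_carbon_sources - 1])
    negative_carbon = None
    if len(others) >= 2:
        negative_carbon = others[int(rng.integers(len(others)))]
    carbon_calls = [GrowthCall("glc__D", "carbon", CALL_GROWTH)]
    for s in others:
        b.rxn(f"EX_{s}_e", {f"{s}_e": -1}, 0, 1000, subsystem="ER")
        if s == negative_carbon:
            carbon_calls.append(GrowthCall(s, "carbon", CALL_NO_GROWTH))
            continue
        y_s = float(rng.choice([6, 8, 12]))
        b.rxn(f"UPT_{s}", {f"{s}_e": -1, f"{s}_c": 1}, 0, 1000,
              gpr=f"g_UPT_{s}", subsystem="TR")
        b.rxn(f"CAT_{s}", {f"{s}_c": -1, "atp_c": y_s}, 0, 1000,
              gpr=f"g_CAT_{s}", subsystem="CM")
        carbon_calls.append(GrowthCall(s, "carbon", CALL_GROWTH))

    # --- amino acids: uptake + deamination to ammonium and energy --------
    nitrogen_calls = [GrowthCall("nh4", "nitrogen", CALL_GROWTH)]
    negative_aa = None
    if spec.include_amino_acids:
        negative_aa = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
        for aa in AMINO_ACIDS:
            ex_id = amino_acid_exchange(aa)
            b.rxn(ex_id, {f"{aa}__L_e": -1}, 0, 1000, subsystem="ER")
            if aa == negative_aa:
                nitrogen_calls.append(GrowthCall(aa, "nitrogen", CALL_NO_GROWTH))
                continue
            k_aa = float(rng.choice([1, 2, 3]))
            b.rxn(f"UPT_{aa}", {f"{aa}__L_e": -1, f"{aa}__L_c": 1}, 0, 1000,
                  gpr=f"g_UPT_{aa}", subsystem="TR")
            b.rxn(f"DEAM_{aa}", {f"{aa}__L_c": -1, "nh4_c": 1, "atp_c": k_aa},
                  0, 1000, gpr=f"g_DEAM_{aa}", subsystem="AM")
            nitrogen_calls.append(GrowthCall(aa, "nitrogen", CALL_GROWTH))

    # --- nucleotide-sugar branch and EPS target --------------------------
    eps_required: list[str] = []
    if spec.include_eps_pathway:
        rev = (-1000, 1000)
        b.rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, *rev, gpr="g_GPI", subsystem="CM")
        b.rxn("PGM", {"g1p_c": -1, "g6p_c": 1}, *rev, gpr="g_PGM", subsystem="CM")
        b.rxn("UGP", {"g1p_c": -1, "atp_c": -1, "udpg_c": 1}, 0, 1000,
              gpr="g_UGP", subsystem="GB")
        b.rxn("GALE", {"udpg_c": -1, "udpgal_c": 1}, *rev,
              gpr=b.gpr_for("GALE"), subsystem="GB")
        b.rxn("UGDH", {"udpg_c": -1, "udpglcur_c": 1}, 0, 1000,
              gpr="g_UGDH", subsystem="GB")
        b.rxn("UXS", {"udpglcur_c": -1, "udpxyl_c": 1}, 0, 1000,
              gpr="g_UXS", subsystem="GB")
        b.rxn("UXE", {"udpxyl_c": -1, "udparab_c": 1}, *rev,
              gpr="g_UXE", subsystem="GB")
        b.rxn("PMI", {"f6p_c": -1, "m6p_c": 1}, *rev,
              gpr=b.gpr_for("PMI"), subsystem="CM")
        b.rxn("PMM", {"m6p_c": -1, "m1p_c": 1}, *rev, gpr="g_PMM", subsystem="CM")
        b.rxn("GMP", {"m1p_c": -1, "atp_c": -1, "gdpman_c": 1}, 0, 1000,
              gpr="g_GMP", subsystem="GB")
        b.rxn("FUCS", {"gdpman_c": -1, "gdpfuc_c": 1}, 0, 1000,
              gpr="g_GMDS and g_TSTA3", subsystem="GB")
        b.rxn("RFFH", {"g1p_c": -1, "atp_c": -1, "dtdpg_c": 1}, 0, 1000,
              gpr="g_RFFH", subsystem="GB")
        b.rxn("RHMS", {"dtdpg_c": -1, "dtdprmn_c": 1}, 0, 1000,
              gpr="g_RFBC and g_TGDS", subsystem="GB")
        eps_rxn = build_eps_reaction(EpsComposition.default())
        for m in eps_rxn.stoichiometry:
            b.met(m)
        b.model.add_reaction(eps_rxn)
        b.rxn("SK_eps", {"eps_c": -1}, 0, 1000, subsystem="ER")
        for ndp in ("udp_c", "gdp_c", "dtdp_c"):
            b.rxn(f"DM_{ndp}", {ndp: -1}, 0, 1000, subsystem="ER")
        eps_required = [
            "UPT_glc", "GLK", "ENERGY", "PGI", "PGM", "UGP", "GALE", "UGDH",
            "UXS", "UXE", "PMI", "PMM", "GMP", "FUCS", "RFFH", "RHMS",
            "EPS", "SK_eps",
        ]

    # --- biomass with a planted essential chain --------------------------
    demand = {"atp_c": -BIOMASS_ATP, "nh4_c": -1.0, "pi_c": -0.2}
    chain_rxns = []
    if spec.n_planted_essential:
        b.rxn("ESS_1", {**demand, "pre_1_c": 1}, 0, 1000,
              gpr="g_ess_1", subsystem="CM")
        chain_rxns.append("ESS_1")
        for i in range(2, spec.n_planted_essential + 1):
            b.rxn(f"ESS_{i}", {f"pre_{i-1}_c": -1, f"pre_{i}_c": 1}, 0, 1000,
                  gpr=f"g_ess_{i}", subsystem="CM")
            chain_rxns.append(f"ESS_{i}")
        b.rxn("BIOMASS", {f"pre_{spec.n_planted_essential}_c": -1, "biomass_c": 1},
              0, 1000, subsystem="other")
    else:
        b.rxn("BIOMASS", {**demand, "biomass_c": 1}, 0, 1000, subsystem="other")
    b.rxn("SK_biomass", {"biomass_c": -1}, 0, 1000, subsystem="ER")

    model = b.model
    model.biomass_reaction_id = "BIOMASS"
    model.eps_reaction_id = "EPS" if spec.include_eps_pathway else None
    model.validate()

    # --- structural truths ------------------------------------------------
    growth_required = ["UPT_glc", "GLK", "ENERGY", "UPT_nh4", "UPT_pi",
                       "BIOMASS", "SK_biomass", *chain_rxns]
    truth.essential_genes_growth = _structurally_essential(model, growth_required)
    if spec.include_eps_pathway:
        truth.essential_genes_eps = _structurally_essential(
            model, sorted(set(growth_required) | set(eps_required))
        )
    truth.expected_phenotype_calls = carbon_calls + nitrogen_calls

    # --- analytic optima (closed forms from the rational yields) ---------
    glc = 10.0
    net_atp = atp_yield - 1.0  # GLK invests one ATP per glucose
    truth.analytic_max_growth = min(
        glc * net_atp / BIOMASS_ATP,
        10.0,          # ammonium uptake limit / 1 per unit biomass
        10.0 / 0.2,    # phosphate
    )
    if spec.include_eps_pathway:
        # every donor costs 1 glucose backbone + 2 ATP of activation
        truth.analytic_max_eps = glc * net_atp / (net_atp + 2.0)

    if verify:
        _verify_truth(model, truth, spec)

    if spec.screen_truth and spec.include_eps_pathway:
        from .overexpression import screen_targets

        medium = (fermentation_medium() if spec.include_amino_acids
                  else minimal_medium())
        records = screen_targets(model, medium)
        selected = [r for r in records if r.selected]
        truth.top_overexpression_target = (
            selected[0].reaction if selected else records[0].reaction
        )

    if spec.inject_gap:
        model, gap = inject_gap(model, spec.seed)
        truth.gap_metabolite = gap

    return model, truth


def _structurally_essential(model: MetabolicModel, required: list[str]) -> set[str]:
    """Genes whose single knockout falsifies the GPR of a required reaction."""
    out = set()
    rules = [model.reactions[rid].gpr for rid in required]
    for gene in model.genes:
        ko = frozenset({gene})
        if any(rule and not rule.evaluate(ko) for rule in rules):
            out.add(gene)
    return out


def _verify_truth(model: MetabolicModel, truth: ToyModelTruth, spec: ToyModelSpec) -> None:
    dead = find_dead_ends(model)
    if dead:
        raise AssertionError(f"generated model has unintended dead ends: {sorted(dead)}")
    on_minimal = apply_medium(model, minimal_medium(), missing="ignore")
    sol = solve_fba(on_minimal)
    if not sol.optimal or abs(sol.objective_value - truth.analytic_max_growth) > 1e-8:
        raise AssertionError(
            f"analytic max growth {truth.analytic_max_growth} disagrees with "
            f"LP ({sol.objective_value}, {sol.status})"
        )
    if spec.include_eps_pathway:
        eps = solve_fba(on_minimal, "EPS")
        if not eps.optimal or abs(eps.objective_value - truth.analytic_max_eps) > 1e-8:
            raise AssertionError(
                f"analytic max EPS {truth.analytic_max_eps} disagrees with "
                f"LP ({eps.objective_value}, {eps.status})"
            )


def inject_gap(model: MetabolicModel, seed: int) -> tuple[MetabolicModel, str]:
    """Remove all consumers of one internal metabolite, planting a dead end.

    The metabolite is chosen (seeded) so that exactly one new dead end
    appears and wild-type growth on minimal medium stays positive; a
    candidate whose removal would starve the biomass path is skipped.
    """
    rng = np.random.default_rng(seed)
    baseline_dead = find_dead_ends(model)
    internal = [
        mid for mid in model.metabolites
        if not mid.endswith("_e") and mid not in ("biomass_c",)
    ]
    order = list(rng.permutation(len(internal)))
    for idx in order:
        mid = internal[idx]
        consumers = [
            rid for rid, rxn in model.reactions.items()
            if not rxn.is_exchange and (
                (rxn.stoichiometry.get(mid, 0) < 0 and rxn.upper_bound > 0)
                or (rxn.stoichiometry.get(mid, 0) > 0 and rxn.lower_bound < 0)
            )
        ]
        if not consumers:
            continue
        candidate = MetabolicModel(
            metabolites=list(model.metabolites.values()),
            reactions=[r.copy() for r in model.reactions.values()
                       if r.id not in consumers],
            biomass_reaction_id=model.biomass_reaction_id,
            eps_reaction_id=(model.eps_reaction_id
                             if model.eps_reaction_id not in consumers else None),
            id=model.id,
        )
        if candidate.biomass_reaction_id in consumers:
            continue
        new_dead = find_dead_ends(candidate) - baseline_dead
        if new_dead != {mid}:
            continue
        sol = solve_fba(apply_medium(candidate, minimal_medium(), missing="ignore"))
        if not sol.optimal or sol.objective_value <= ESSENTIALITY_THRESHOLD:
            continue
        return candidate, mid
    raise ValueError("no metabolite can be gapped without side effects")


def phenotype_truth_table(
    model: MetabolicModel,
    truth: ToyModelTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write per-role truth tables in the substrate/in_vivo/in_silico layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for role in ("carbon", "nitrogen"):
        calls = [c for c in truth.expected_phenotype_calls if c.role == role]
        if not calls:
            continue
        df = pd.DataFrame(
            {
                "substrate": [c.substrate for c in calls],
                "in_vivo": [c.call for c in calls],
                "in_silico": [c.call for c in calls],
            }
        )
        path = out_dir / f"toy_{role}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[role] = path
    return paths
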