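"""End-to-end analysis pipeline and consolidated report.

``run_full_analysis`` chains the study workflow over one model: model
statistics, phenotype matching against truth tables, a quantitative
growth check under a measured substrate-uptake constraint, essentiality
screens per medium and objective, the amino-acid supplementation scan,
and the overexpression screen.  The report is a plain JSON-serializable
dict; every section carries a ``source`` key naming the operation that
produced its numbers.  Percentages are rounded to one decimal for
display and raw values retained.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from .core import MetabolicModel
from .deletion import (
    essential_for_product,
    essential_genes,
    single_gene_deletion,
    subsystem_percentages,
)
from .fba import apply_medium, solve_fba
from .media import (
    AMINO_ACIDS,
    GLUCOSE_EXCHANGE,
    amino_acid_exchange,
    fermentation_medium,
    minimal_medium,
)
from .overexpression import screen_targets
from .phenotypes import load_truth_table, matching_rate_from_table, supplementation_scan

#: defaults from chemostat measurements: maximal specific growth rate and
#: the matching sugar consumption rate
DEFAULT_EXPERIMENTAL_MU = 0.076  # 1/h
DEFAULT_GLUCOSE_UPTAKE = 0.506  # mmol/gDW/h


def growth_rate_deviation(mu_pred: float, mu_exp: float) -> float:
    """Signed percent deviation of predicted vs experimental growth, 1 decimal."""
    if mu_exp == 0:
        raise ValueError("experimental growth rate must be non-zero")
    return round(100.0 * (mu_pred - mu_exp) / mu_exp, 1)


def _round1(x: float) -> float:
    return round(float(x), 1)


def model_statistics(model: MetabolicModel) -> dict[str, Any]:
    n_rxn = len(model.reactions)
    subsystem_counts: dict[str, int] = {}
    for rxn in model.reactions.values():
        subsystem_counts[rxn.subsystem] = subsystem_counts.get(rxn.subsystem, 0) + 1
    gene_associated = sum(1 for r in model.reactions.values() if r.gpr)
    return {
        "source": "model_statistics",
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "reactions": n_rxn,
        "gene_associated_reactions": gene_associated,
        "subsystem_percentages": {
            sub: _round1(100.0 * c / n_rxn)
            for sub, c in sorted(subsystem_counts.items())
        },
    }


def run_full_analysis(
    model: MetabolicModel, config: Mapping[str, Any] | None = None
) -> dict[str, Any]:
    """Run the full validation-and-screening workflow; return the report.

    Config keys (all optional): ``experimental_growth_rate`` (1/h),
    ``glucose_uptake`` (mmol/gDW/h), ``phenotype_tables`` (mapping role ->
    truth-table path or packaged name), ``biomass_fraction`` (for product
    essentiality), ``fold`` and ``eps_imposition`` (overexpression screen),
    ``supplement_uptake`` (mmol/gDW/h).
    """
    cfg = dict(config or {})
    mu_exp = float(cfg.get("experimental_growth_rate", DEFAULT_EXPERIMENTAL_MU))
    uptake = float(cfg.get("glucose_uptake", DEFAULT_GLUCOSE_UPTAKE))
    report: dict[str, Any] = {"model": model.id}

    report["model_stats"] = model_statistics(model)

    phenotype: dict[str, Any] = {"source": "phenotype_matching_rate", "tables": {}}
    for role, table_ref in dict(cfg.get("phenotype_tables", {})).items():
        table = load_truth_table(table_ref)
        phenotype["tables"][role] = {
            "n_substrates": int(len(table)),
            "matching_rate_pct": matching_rate_from_table(table),
        }
    report["phenotype"] = phenotype

    minimal = minimal_medium()
    constrained = minimal.with_limit(GLUCOSE_EXCHANGE, uptake)
    sol = solve_fba(apply_medium(model, constrained, missing="ignore"))
    mu_pred = sol.objective_value if sol.optimal else 0.0
    report["growth"] = {
        "source": "solve_fba",
        "glucose_uptake_mmol_gDW_h": uptake,
        "predicted_growth_rate_per_h": mu_pred,
        "experimental_growth_rate_per_h": mu_exp,
        "deviation_pct": growth_rate_deviation(mu_pred, mu_exp),
        "status": sol.status,
    }

    fermentation = fermentation_medium()
    ess_section: dict[str, Any] = {"source": "single_gene_deletion"}
    for med_name, medium in (("minimal", minimal), ("fermentation", fermentation)):
        records = single_gene_deletion(model, medium)
        ess = essential_genes(records)
        entry = {
            "essential_genes": len(ess),
            "pct_of_total": _round1(100.0 * len(ess) / max(len(model.genes), 1)),
            "subsystem_percentages": {
                k: _round1(v)
                for k, v in subsystem_percentages(records, model).items()
            },
        }
        if model.eps_reaction_id is not None:
            eps_records = essential_for_product(
                model, medium,
                biomass_fraction=float(cfg.get("biomass_fraction", 0.5)),
            )
            eps_ess = essential_genes(eps_records)
            entry["essential_genes_for_product"] = len(eps_ess)
            entry["product_subsystem_percentages"] = {
                k: _round1(v)
                for k, v in subsystem_percentages(eps_records, model).items()
            }
        ess_section[med_name] = entry
    report["essentiality"] = ess_section

    if model.eps_reaction_id is not None:
        supplements = [amino_acid_exchange(aa) for aa in AMINO_ACIDS]
        scan = supplementation_scan(
            model, minimal, supplements,
            uptake=float(cfg.get("supplement_uptake", 0.01)),
        )
        report["supplementation"] = {
            "source": "supplementation_scan",
            "ranking": [
                {
                    "supplement": r.supplement,
                    "status": r.status,
                    "biomass_rate": r.biomass_rate,
                    "eps_rate": r.eps_rate,
                    "pct_increase_biomass": _round1(r.pct_increase_biomass),
                    "pct_increase_eps": _round1(r.pct_increase_eps),
                }
                for r in scan
            ],
        }
        records = screen_targets(
            model, fermentation,
            fold=float(cfg.get("fold", 2.0)),
            eps_imposition=float(cfg.get("eps_imposition", 0.1)),
        )
        report["overexpression"] = {
            "source": "screen_targets",
            "ranking": [
                {
                    "reaction": r.reaction,
                    "genes": list(r.genes),
                    "status": r.status,
                    "f_biomass": r.f_biomass if r.status == "optimal" else None,
                    "f_eps": r.f_eps if r.status == "optimal" else None,
                    "f_ph": r.f_ph if r.status == "optimal" else None,
                    "selected": r.selected,
                }
                for r in records
            ],
        }
    return report


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
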