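"""Single-gene-deletion essentiality screening.

Deleting a gene falsifies its leaf in every GPR rule; any reaction whose
rule evaluates false loses its catalyst and is constrained to zero flux.
A gene is essential when the re-solved objective (growth, or product
formation under a minimum-growth constraint) drops to zero — numerically,
below a small floor above LP tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MetabolicModel
from .fba import FbaError, apply_medium, solve_fba
from .media import MediumDefinition

#: objectives below this are "zero growth" / "zero production"
ESSENTIALITY_THRESHOLD = 1e-6


@dataclass
class DeletionRecord:
    gene: str
    disabled_reactions: list[str] = field(default_factory=list)
    objective_value: float = 0.0
    ratio_to_wt: float = 0.0
    essential: bool = False
    status: str = "optimal"


def _disabled_by(model: MetabolicModel, gene: str) -> list[str]:
    ko = frozenset({gene})
    return [
        rid
        for rid, rxn in model.reactions.items()
        if rxn.gpr and not rxn.gpr.evaluate(ko)
    ]


def _knockout(model: MetabolicModel, disabled: list[str]) -> MetabolicModel:
    new = model.copy()
    for rid in disabled:
        new.reactions[rid].lower_bound = 0.0
        new.reactions[rid].upper_bound = 0.0
    return new


def single_gene_deletion(
    model: MetabolicModel,
    medium: MediumDefinition | None = None,
    objective_id: str | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> list[DeletionRecord]:
    """Delete each gene in turn and re-solve FBA; one record per gene.

    Requires a feasible wild type with objective above the essentiality
    threshold; aborts with a diagnostic otherwise.  Records are returned
    in sorted gene order (the essential set does not depend on order).
    """
    work = apply_medium(model, medium, missing="ignore") if medium else model.copy()
    objective_id = objective_id or work.biomass_reaction_id
    wt = solve_fba(work, objective_id)
    if not wt.optimal:
        raise FbaError(f"wild-type FBA is {wt.status}; cannot screen deletions")
    if wt.objective_value <= threshold:
        raise FbaError("wild-type objective is zero; essentiality is undefined")

    records = []
    for gene in sorted(work.genes):
        disabled = _disabled_by(work, gene)
        if not disabled:
            records.append(
                DeletionRecord(gene, [], wt.objective_value, 1.0, False)
            )
            continue
        sol = solve_fba(_knockout(work, disabled), objective_id)
        if sol.optimal:
            obj = sol.objective_value
            records.append(
                DeletionRecord(
                    gene, disabled, obj, obj / wt.objective_value,
                    obj < threshold, sol.status,
                )
            )
        else:
            records.append(
                DeletionRecord(gene, disabled, 0.0, 0.0, True, sol.status)
            )
    return records


def essential_for_product(
    model: MetabolicModel,
    medium: MediumDefinition | None,
    product_objective_id: str | None = None,
    biomass_fraction: float = 0.5,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> list[DeletionRecord]:
    """Essentiality for product formation under a minimum-growth constraint.

    Growth must first be pinned to a viable level: the biomass reaction
    gets a lower bound of ``biomass_fraction`` times the wild-type optimum
    before each knockout is evaluated against the product objective.  A
    knockout that makes the constrained problem infeasible (cells cannot
    grow) counts as essential.  ``biomass_fraction=0`` reduces to plain
    product essentiality.
    """
    work = apply_medium(model, medium, missing="ignore") if medium else model.copy()
    product_objective_id = product_objective_id or work.eps_reaction_id
    if product_objective_id is None:
        raise ValueError("no product objective reaction given")
    biomass_id = work.biomass_reaction_id
    mu = solve_fba(work, biomass_id)
    if not mu.optimal or mu.objective_value <= threshold:
        raise FbaError("wild-type growth is zero; cannot constrain biomass")
    work.reactions[biomass_id].lower_bound = biomass_fraction * mu.objective_value
    return single_gene_deletion(
        work, medium=None, objective_id=product_objective_id, threshold=threshold
    )


def essential_genes(records: list[DeletionRecord]) -> set[str]:
    return {r.gene for r in records if r.essential}


def subsystem_percentages(
    records: list[DeletionRecord], model: MetabolicModel
) -> dict[str, float]:
    """Distribution of essential genes across subsystems, summing to 100.

    A gene touching reactions in several subsystems is assigned to the
    subsystem carrying most of its reactions (ties break lexicographically)
    so the percentages form a partition.
    """
    ess = sorted(essential_genes(records))
    if not ess:
        return {}
    counts: dict[str, int] = {}
    for gene in ess:
        tally: dict[str, int] = {}
        for rxn in model.reactions.values():
            if gene in rxn.genes:
                tally[rxn.subsystem] = tally.get(rxn.subsystem, 0) + 1
        if not tally:
            continue
        best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        counts[best] = counts.get(best, 0) + 1
    total = sum(counts.values())
    return {sub: 100.0 * c / total for sub, c in sorted(counts.items())}
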