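"""Five-step overexpression screen for product-enhancing targets.

For each candidate reaction carrying non-zero wild-type flux, the screen
forces its flux to ``fold`` times the wild-type value, lets MOMA
redistribute the remaining fluxes, and scores the outcome with

    f_PH = f_biomass * f_EPS
         = (V_biomass,oe / V_biomass,wt) * (V_EPS,oe / V_EPS,wt)

A target is selected when it raises product formation (V_EPS,oe >
V_EPS,wt) and keeps f_PH above 1, i.e. the product gain is not paid for
by a proportionally larger growth loss.  Steps: (i) impose a minimum
product flux, (ii) compute a parsimonious wild-type reference on the
fermentation medium, (iii) amplify one reaction at a time, (iv) solve
MOMA against the reference, (v) rank by f_PH.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import MetabolicModel
from .fba import FLUX_EPS, FluxDistribution, FbaError, apply_medium, parsimonious_reference, solve_fba
from .media import MediumDefinition
from .moma import solve_moma


@dataclass
class OverexpressionRecord:
    """One screened reaction with all score components."""

    reaction: str
    fold: float
    V_biomass_wt: float
    V_biomass_oe: float
    V_eps_wt: float
    V_eps_oe: float
    status: str = "optimal"
    genes: tuple[str, ...] = ()

    @property
    def f_biomass(self) -> float:
        return self.V_biomass_oe / self.V_biomass_wt

    @property
    def f_eps(self) -> float:
        return self.V_eps_oe / self.V_eps_wt

    @property
    def f_ph(self) -> float:
        return self.f_biomass * self.f_eps

    @property
    def selected(self) -> bool:
        return (
            self.status == "optimal"
            and self.V_eps_oe > self.V_eps_wt
            and self.f_ph > 1.0
        )


def fold_ratio(value_oe: float, value_wt: float) -> float:
    """Specific overexpression ratio (e.g. f_EPS = V_EPS,oe / V_EPS,wt)."""
    return value_oe / value_wt


def overexpress_reaction(
    model: MetabolicModel, reaction_id: str, wt_flux: float, fold: float
) -> MetabolicModel:
    """Force a reaction to carry at least ``fold`` times its wild-type flux.

    Direction is preserved: positive wild-type flux raises the lower
    bound, negative lowers the upper bound.  Candidates with |wt_flux|
    below the flux floor are not valid overexpression targets.
    """
    if abs(wt_flux) <= FLUX_EPS:
        raise ValueError(
            f"reaction {reaction_id!r} carries no wild-type flux; "
            "zero-flux reactions are excluded from overexpression"
        )
    new = model.copy()
    rxn = new.reactions[reaction_id]
    target = fold * wt_flux
    if wt_flux > 0:
        rxn.lower_bound = target
        rxn.upper_bound = max(rxn.upper_bound, target)
    else:
        rxn.upper_bound = target
        rxn.lower_bound = min(rxn.lower_bound, target)
    return new


def screen_targets(
    model: MetabolicModel,
    medium: MediumDefinition,
    eps_id: str | None = None,
    biomass_id: str | None = None,
    fold: float = 2.0,
    eps_imposition: float = 0.1,
    exclude_boundary: bool = True,
) -> list[OverexpressionRecord]:
    """Run the overexpression screen; return records sorted by f_PH.

    ``eps_imposition`` is the fraction of the maximal product flux imposed
    as a lower bound on the product reaction before the wild-type
    reference is computed (the screen contract is the ranking, not the
    absolute flux level).  Ties in f_PH break by ascending reaction id.
    """
    eps_id = eps_id or model.eps_reaction_id
    biomass_id = biomass_id or model.biomass_reaction_id
    if eps_id is None:
        raise ValueError("model has no product (EPS) reaction to screen for")

    wt = apply_medium(model, medium, missing="ignore")

    # (i) impose a minimum product flux
    eps_max = solve_fba(wt, eps_id)
    if not eps_max.optimal or eps_max.objective_value <= FLUX_EPS:
        raise FbaError("product flux cannot be imposed: maximal product flux is zero")
    wt.reactions[eps_id].lower_bound = eps_imposition * eps_max.objective_value

    # (ii) wild-type reference on the medium, biomass-optimal, parsimonious
    reference = parsimonious_reference(wt, biomass_id)
    if not reference.optimal:
        raise FbaError("wild-type reference is infeasible under the imposed product flux")
    v_bio_wt = reference.fluxes[biomass_id]
    v_eps_wt = reference.fluxes[eps_id]
    if v_bio_wt <= FLUX_EPS or v_eps_wt <= FLUX_EPS:
        raise FbaError("wild-type biomass or product flux is zero; cannot form ratios")

    records: list[OverexpressionRecord] = []
    for rid, rxn in wt.reactions.items():
        if rid in (eps_id, biomass_id):
            continue
        if exclude_boundary and rxn.is_exchange:
            continue
        wt_flux = reference.fluxes[rid]
        if abs(wt_flux) <= FLUX_EPS:
            continue  # step (iii): only non-zero-flux reactions
        perturbed = overexpress_reaction(wt, rid, wt_flux, fold)
        sol = solve_moma(perturbed, reference, objective_id=biomass_id)
        if not sol.optimal:
            records.append(
                OverexpressionRecord(
                    rid, fold, v_bio_wt, float("nan"), v_eps_wt, float("nan"),
                    status=sol.status, genes=tuple(sorted(rxn.genes)),
                )
            )
            continue
        records.append(
            OverexpressionRecord(
                rid,
                fold,
                v_bio_wt,
                sol.fluxes[biomass_id],
                v_eps_wt,
                sol.fluxes[eps_id],
                status="optimal",
                genes=tuple(sorted(rxn.genes)),
            )
        )
    records.sort(
        key=lambda r: (
            -r.f_ph if r.status == "optimal" else float("inf"),
            r.reaction,
        )
    )
    return records
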