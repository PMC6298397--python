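"""Growth-phenotype screening and amino-acid supplementation scans.

Sole-source tests swap the default carbon (glucose) or nitrogen
(ammonium) source of a base medium for a single test substrate and call
growth "+" when the simulated growth rate clears a small threshold.
Matching rates compare such calls against experimental truth tables.
The supplementation scan measures how much one extra uptake route (an
amino acid at a fixed small uptake rate) raises the maximal growth and
product-formation rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import MetabolicModel
from .fba import FLUX_EPS, apply_medium, solve_fba
from .media import GLUCOSE_EXCHANGE, NITROGEN_EXCHANGE, MediumDefinition

GROWTH_THRESHOLD = FLUX_EPS

CALL_GROWTH = "+"
CALL_NO_GROWTH = "-"
CALL_UNTESTABLE = "untestable"


@dataclass
class GrowthCall:
    substrate: str
    role: str  # "carbon" | "nitrogen"
    call: str
    growth_rate: float = 0.0


@dataclass
class SupplementRecord:
    supplement: str
    biomass_rate: float
    eps_rate: float
    pct_increase_biomass: float
    pct_increase_eps: float
    status: str = "ok"  # ok | untestable


_ROLE_DEFAULT = {"carbon": GLUCOSE_EXCHANGE, "nitrogen": NITROGEN_EXCHANGE}


def sole_source_call(
    model: MetabolicModel,
    base_medium: MediumDefinition,
    substrate_exchange: str,
    role: str,
    substrate_name: str | None = None,
    threshold: float = GROWTH_THRESHOLD,
) -> GrowthCall:
    """Test growth with one substrate as the sole carbon or nitrogen source.

    The role's default source is removed from the base medium and the test
    substrate opened at the same uptake limit (qualitative calls are
    threshold-based and insensitive to the exact cap).  The other role's
    default source stays in place.  A substrate whose exchange reaction is
    absent from the model is "untestable", distinct from a clean "-".
    """
    if role not in _ROLE_DEFAULT:
        raise ValueError(f"role must be 'carbon' or 'nitrogen', got {role!r}")
    name = substrate_name or substrate_exchange
    default_exchange = _ROLE_DEFAULT[role]
    limit = base_medium.uptake_limits.get(default_exchange, 10.0)
    medium = base_medium.without(default_exchange).with_limit(substrate_exchange, limit)
    if substrate_exchange not in {r.id for r in model.exchanges}:
        return GrowthCall(name, role, CALL_UNTESTABLE, 0.0)
    sol = solve_fba(apply_medium(model, medium, missing="ignore"))
    rate = sol.objective_value if sol.optimal else 0.0
    call = CALL_GROWTH if sol.optimal and rate > threshold else CALL_NO_GROWTH
    return GrowthCall(name, role, call, rate if sol.optimal else 0.0)


def phenotype_matching_rate(
    in_vivo: Sequence[str | GrowthCall], in_silico: Sequence[str | GrowthCall]
) -> float:
    """Percent agreement between aligned +/− call lists, to one decimal."""
    if len(in_vivo) != len(in_silico):
        raise ValueError(
            f"call lists differ in length: {len(in_vivo)} vs {len(in_silico)}"
        )
    if not in_vivo:
        raise ValueError("cannot compute a matching rate on empty call lists")
    a = [c.call if isinstance(c, GrowthCall) else c for c in in_vivo]
    b = [c.call if isinstance(c, GrowthCall) else c for c in in_silico]
    agree = sum(x == y for x, y in zip(a, b))
    return round(100.0 * agree / len(a), 1)


def load_truth_table(path_or_name: str | Path) -> pd.DataFrame:
    """Load a phenotype truth table (substrate / in_vivo / in_silico TSV).

    Accepts a file path or the name of a packaged fixture
    (``table1_carbon`` or ``table2_nitrogen``, transcribed from published
    growth-validation tables).
    """
    path = Path(path_or_name)
    if not path.exists():
        ref = resources.files("epsflux.data") / f"{path_or_name}.tsv"
        if not ref.is_file():
            raise FileNotFoundError(f"no such truth table: {path_or_name!r}")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def matching_rate_from_table(table: pd.DataFrame) -> float:
    return phenotype_matching_rate(
        list(table["in_vivo"]), list(table["in_silico"])
    )


def supplementation_scan(
    model: MetabolicModel,
    medium: MediumDefinition,
    supplements: Iterable[str],
    uptake: float = 0.01,
    eps_id: str | None = None,
    min_biomass_fraction: float = 0.0,
) -> list[SupplementRecord]:
    """Measure biomass and product gains from single-supplement additions.

    For each supplement exchange id, the medium is extended by that uptake
    route at ``uptake`` mmol/gDW/h and the maximal growth rate and product
    rate are recomputed; percent increases are relative to the shared
    baseline on the unsupplemented medium.  With ``min_biomass_fraction``
    > 0 the product maximization additionally keeps growth at that
    fraction of the (per-medium) optimum.
    """
    eps_id = eps_id or model.eps_reaction_id
    if eps_id is None:
        raise ValueError("model has no product (EPS) reaction")
    biomass_id = model.biomass_reaction_id

    def rates(med: MediumDefinition) -> tuple[float, float]:
        applied = apply_medium(model, med, missing="ignore")
        bio = solve_fba(applied, biomass_id)
        mu = bio.objective_value if bio.optimal else 0.0
        if min_biomass_fraction > 0 and mu > FLUX_EPS:
            applied.reactions[biomass_id].lower_bound = min_biomass_fraction * mu
        eps = solve_fba(applied, eps_id)
        return mu, (eps.objective_value if eps.optimal else 0.0)

    base_mu, base_eps = rates(medium)
    exchange_ids = {r.id for r in model.exchanges}

    def pct(new: float, base: float) -> float:
        if base <= FLUX_EPS:
            return 0.0 if new <= FLUX_EPS else float("inf")
        return 100.0 * (new - base) / base

    records = []
    for supp in supplements:
        if supp not in exchange_ids:
            records.append(
                SupplementRecord(supp, 0.0, 0.0, 0.0, 0.0, status="untestable")
            )
            continue
        mu, eps = rates(medium.with_limit(supp, uptake))
        records.append(
            SupplementRecord(supp, mu, eps, pct(mu, base_mu), pct(eps, base_eps))
        )
    records.sort(
        key=lambda r: (-r.pct_increase_eps if r.status == "ok" else float("inf"), r.supplement)
    )
    return records
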