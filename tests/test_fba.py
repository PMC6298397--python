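"""FBA engine: analytic cases, oracle equivalence, LP properties."""

import numpy as np
import pytest

from conftest import tiny_spec
from epsflux.core import MetabolicModel, Metabolite, Reaction
from epsflux.fba import (
    apply_medium,
    parsimonious_reference,
    solve_fba,
    steady_state_residual,
)
from epsflux.media import MediumDefinition, minimal_medium
from epsflux.synthetic import generate_toy_model
from lp_oracle import enumerate_lp_max, model_arrays


def chain_model(glc_uptake=10.0):
    """EX_glc -> glc -> X, biomass drains 2 X per unit (yield 0.5/glc)."""
    mets = [Metabolite(m) for m in ("glc", "X", "bio")]
    rxns = [
        Reaction("EX_glc", {"glc": -1}, -glc_uptake, 1000),
        Reaction("R1", {"glc": -1, "X": 1}),
        Reaction("BIOMASS", {"X": -2, "bio": 1}),
        Reaction("SK_bio", {"bio": -1}),
    ]
    return MetabolicModel(mets, rxns, biomass_reaction_id="BIOMASS")


def test_linear_chain_yield():
    sol = solve_fba(chain_model())
    assert sol.optimal
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)


def test_zero_uptake_zero_growth():
    sol = solve_fba(chain_model(glc_uptake=0.0))
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_infeasible_status_propagated():
    m = MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [Reaction("R", {"A": -1, "B": 1}, 1, 2), Reaction("EX_B", {"B": -1})],
    )
    sol = solve_fba(m, "R")
    assert sol.status == "infeasible"
    assert not sol.optimal


def test_unbounded_status_propagated():
    m = MetabolicModel(
        [Metabolite("A")],
        [Reaction("IN", {"A": 1}, 0, np.inf), Reaction("OUT", {"A": -1}, 0, np.inf)],
    )
    sol = solve_fba(m, "OUT")
    assert sol.status == "unbounded"


def test_missing_objective_raises(tiny):
    with pytest.raises(KeyError):
        solve_fba(tiny[0], "NOPE")


@pytest.mark.parametrize("seed", range(20))
def test_objective_matches_vertex_enumeration(seed):
    """On 10-reaction toys, HiGHS agrees with brute-force vertex enumeration."""
    model, truth = generate_toy_model(tiny_spec(seed))
    applied = apply_medium(model, minimal_medium(), missing="ignore")
    sol = solve_fba(applied)
    oracle = enumerate_lp_max(*model_arrays(applied, "BIOMASS"))
    assert sol.objective_value == pytest.approx(oracle, abs=1e-8)
    assert sol.objective_value == pytest.approx(truth.analytic_max_growth, abs=1e-8)


def test_steady_state_residual_small(toy_model):
    applied = apply_medium(toy_model, minimal_medium(), missing="ignore")
    for objective in ("BIOMASS", "EPS"):
        sol = solve_fba(applied, objective)
        assert sol.optimal
        assert steady_state_residual(applied, sol) <= 1e-6


def test_relaxing_bounds_never_decreases_optimum(tiny):
    model, _ = tiny
    applied = apply_medium(model, minimal_medium(), missing="ignore")
    base = solve_fba(applied).objective_value
    for rid in applied.reactions:
        relaxed = applied.copy()
        relaxed.reactions[rid].lower_bound -= 1.0
        relaxed.reactions[rid].upper_bound += 1.0
        new = solve_fba(relaxed)
        assert new.optimal
        assert new.objective_value >= base - 1e-8


def test_doubling_glucose_doubles_growth(tiny):
    """Single-substrate network: maximal growth is linear in the uptake cap."""
    model, _ = tiny
    lo = solve_fba(apply_medium(
        model, minimal_medium(glucose_uptake=1.0), missing="ignore"))
    hi = solve_fba(apply_medium(
        model, minimal_medium(glucose_uptake=2.0), missing="ignore"))
    assert hi.objective_value == pytest.approx(2 * lo.objective_value, rel=1e-9)


class TestApplyMedium:
    def test_unlisted_uptakes_closed(self, tiny):
        model, _ = tiny
        applied = apply_medium(model, MediumDefinition("empty", {}))
        for ex in applied.exchanges:
            assert ex.lower_bound == 0
        assert solve_fba(applied).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_fermentation_opens_amino_acids(self, toy_model):
        from epsflux.media import fermentation_medium

        applied = apply_medium(toy_model, fermentation_medium(), missing="ignore")
        assert applied.reactions["EX_ala__L_e"].lower_bound == -0.01
        assert applied.reactions["EX_glc__D_e"].lower_bound == -10

    def test_non_exchange_reaction_rejected(self, tiny):
        model, _ = tiny
        with pytest.raises(ValueError, match="non-exchange"):
            apply_medium(model, MediumDefinition("bad", {"GLK": 1.0}))

    def test_internal_bounds_untouched(self, toy_model):
        applied = apply_medium(toy_model, minimal_medium(), missing="ignore")
        assert applied.reactions["PGI"].lower_bound == -1000
        assert applied.reactions["GLK"].upper_bound == 1000


class TestParsimonious:
    def test_futile_cycle_suppressed(self):
        mets = [Metabolite(m) for m in ("glc", "X", "bio")]
        rxns = [
            Reaction("EX_glc", {"glc": -1}, -10, 1000),
            Reaction("R1", {"glc": -1, "X": 1}),
            Reaction("CYCLE", {"X": -1, "glc": 1}, -1000, 1000),
            Reaction("BIOMASS", {"X": -2, "bio": 1}),
            Reaction("SK_bio", {"bio": -1}),
        ]
        m = MetabolicModel(mets, rxns, biomass_reaction_id="BIOMASS")
        ref = parsimonious_reference(m)
        # R1 and reverse-CYCLE are alternative glc->X routes; the loop
        # (both running the same direction) must carry zero net cycling,
        # i.e. the two fluxes never cancel each other
        net = ref.fluxes["R1"] - ref.fluxes["CYCLE"]
        assert abs(ref.fluxes["R1"]) + abs(ref.fluxes["CYCLE"]) == pytest.approx(
            abs(net), abs=1e-6
        )
        assert ref.objective_value >= 0.9998 * solve_fba(m).objective_value

    def test_parallel_paths_not_inflated(self):
        mets = [Metabolite(m) for m in ("A", "B")]
        rxns = [
            Reaction("EX_A", {"A": -1}, -10, 1000),
            Reaction("P1", {"A": -1, "B": 1}),
            Reaction("P2", {"A": -1, "B": 1}),
            Reaction("EX_B", {"B": -1}),
        ]
        m = MetabolicModel(mets, rxns, biomass_reaction_id="EX_B")
        ref = parsimonious_reference(m)
        # total |flux| equals single-path routing (10 in, 10 across, 10 out)
        # up to the 99.99% objective-retention floor
        total = sum(abs(v) for v in ref.fluxes.values())
        assert total == pytest.approx(30.0, rel=2e-4)
        assert ref.fluxes["P1"] + ref.fluxes["P2"] == pytest.approx(
            abs(ref.fluxes["P1"]) + abs(ref.fluxes["P2"]), abs=1e-8
        )

    def test_positive_lower_bounds_respected(self, toy_model):
        applied = apply_medium(toy_model, minimal_medium(), missing="ignore")
        applied.reactions["EPS"].lower_bound = 0.5
        ref = parsimonious_reference(applied)
        assert ref.fluxes["EPS"] >= 0.5 - 1e-8
        assert steady_state_residual(applied, ref) <= 1e-6


def test_cobra_cross_check(tmp_path, toy_model):
    """Independent oracle: cobrapy+GLPK reproduces the FBA optimum."""
    cobra = pytest.importorskip("cobra")
    from epsflux.io import write_sbml

    applied = apply_medium(toy_model, minimal_medium(), missing="ignore")
    path = tmp_path / "toy.xml"
    write_sbml(applied, path)
    cm = cobra.io.read_sbml_model(str(path))
    ours = solve_fba(applied)
    theirs = cm.optimize()
    assert theirs.objective_value == pytest.approx(ours.objective_value, abs=1e-6)
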