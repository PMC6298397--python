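"""Sole-source growth calls, matching rates, supplementation scans."""

import pytest

from epsflux.core import MetabolicModel, Metabolite, Reaction
from epsflux.media import MediumDefinition, minimal_medium
from epsflux.phenotypes import (
    CALL_GROWTH,
    CALL_NO_GROWTH,
    CALL_UNTESTABLE,
    load_truth_table,
    matching_rate_from_table,
    phenotype_matching_rate,
    sole_source_call,
    supplementation_scan,
)


class TestMatchingRate:
    def test_identical_lists(self):
        assert phenotype_matching_rate(["+", "-", "+"], ["+", "-", "+"]) == 100.0

    def test_one_disagreement_in_18(self):
        a = ["+"] * 17 + ["-"]
        b = ["+"] * 18
        assert phenotype_matching_rate(a, b) == 94.4

    def test_one_disagreement_in_22(self):
        a = ["+"] * 21 + ["-"]
        b = ["+"] * 22
        assert phenotype_matching_rate(a, b) == 95.5

    def test_symmetric(self):
        a, b = ["+", "-", "+", "+"], ["+", "+", "-", "+"]
        assert phenotype_matching_rate(a, b) == phenotype_matching_rate(b, a)

    def test_order_invariant_under_paired_permutation(self):
        pairs = [("+", "+"), ("-", "+"), ("+", "-"), ("-", "-")]
        rate = phenotype_matching_rate(*zip(*pairs))
        assert rate == phenotype_matching_rate(*zip(*reversed(pairs)))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            phenotype_matching_rate(["+"], ["+", "-"])

    def test_packaged_carbon_table(self):
        table = load_truth_table("table1_carbon")
        assert len(table) == 18
        assert matching_rate_from_table(table) == 94.4

    def test_packaged_nitrogen_table(self):
        table = load_truth_table("table2_nitrogen")
        assert len(table) == 22
        assert matching_rate_from_table(table) == 95.5


class TestSoleSource:
    def test_glucose_positive(self, toy_model):
        call = sole_source_call(
            toy_model, minimal_medium(), "EX_glc__D_e", "carbon", "glucose"
        )
        assert call.call == CALL_GROWTH
        assert call.growth_rate > 1e-6

    def test_substrate_without_route_negative(self, toy_model, toy_truth):
        negatives = [
            c for c in toy_truth.expected_phenotype_calls
            if c.role == "carbon" and c.call == CALL_NO_GROWTH
        ]
        assert negatives, "default toy plants one carbon-negative substrate"
        ex = f"EX_{negatives[0].substrate}_e"
        call = sole_source_call(toy_model, minimal_medium(), ex, "carbon")
        assert call.call == CALL_NO_GROWTH

    def test_missing_exchange_untestable(self, toy_model):
        call = sole_source_call(
            toy_model, minimal_medium(), "EX_inositol_e", "carbon"
        )
        assert call.call == CALL_UNTESTABLE

    def test_nitrogen_swap_keeps_glucose(self, toy_model):
        from epsflux.media import amino_acid_exchange

        aa_ok = next(
            aa for aa in ("ala", "gly", "ser")
            if f"UPT_{aa}" in toy_model.reactions
        )
        call = sole_source_call(
            toy_model, minimal_medium(), amino_acid_exchange(aa_ok), "nitrogen"
        )
        assert call.call == CALL_GROWTH

    def test_all_planted_calls_recovered(self, toy_model, toy_truth):
        from epsflux.media import amino_acid_exchange

        for truth_call in toy_truth.expected_phenotype_calls:
            if truth_call.role == "carbon":
                ex = ("EX_glc__D_e" if truth_call.substrate == "glc__D"
                      else f"EX_{truth_call.substrate}_e")
            else:
                ex = ("EX_nh4_e" if truth_call.substrate == "nh4"
                      else amino_acid_exchange(truth_call.substrate))
            call = sole_source_call(toy_model, minimal_medium(), ex, truth_call.role)
            assert call.call == truth_call.call, truth_call.substrate


class TestSupplementation:
    def test_percent_increases_non_negative(self, toy_model):
        from epsflux.media import AMINO_ACIDS, amino_acid_exchange

        records = supplementation_scan(
            toy_model, minimal_medium(),
            [amino_acid_exchange(a) for a in AMINO_ACIDS[:6]],
        )
        for r in records:
            if r.status == "ok":
                assert r.pct_increase_biomass >= -1e-6
                assert r.pct_increase_eps >= -1e-6

    def test_supplement_without_route_gives_zero(self, toy_model, toy_truth):
        from epsflux.media import amino_acid_exchange

        dead = [
            c.substrate for c in toy_truth.expected_phenotype_calls
            if c.role == "nitrogen" and c.call == CALL_NO_GROWTH
        ]
        assert dead
        (rec,) = supplementation_scan(
            toy_model, minimal_medium(), [amino_acid_exchange(dead[0])]
        )
        assert rec.pct_increase_biomass == pytest.approx(0.0, abs=1e-6)
        assert rec.pct_increase_eps == pytest.approx(0.0, abs=1e-6)

    def test_missing_exchange_untestable(self, toy_model):
        (rec,) = supplementation_scan(
            toy_model, minimal_medium(), ["EX_caviar_e"]
        )
        assert rec.status == "untestable"

    def test_direct_precursor_feed_matches_analytic_gain(self):
        """Supplement feeding the product precursor: gain is the uptake itself."""
        mets = [Metabolite(m) for m in ("A", "B", "P", "eps")]
        rxns = [
            Reaction("EX_A", {"A": -1}, 0, 1000),
            Reaction("EX_B", {"B": -1}, 0, 1000),
            Reaction("RA", {"A": -1, "P": 1}),
            Reaction("RB", {"B": -1, "P": 1}),
            Reaction("EPS", {"P": -1, "eps": 1}),
            Reaction("SK_eps", {"eps": -1}),
            Reaction("BIOMASS", {"P": -1}),
        ]
        m = MetabolicModel(
            mets, rxns, biomass_reaction_id="BIOMASS", eps_reaction_id="EPS"
        )
        medium = MediumDefinition("base", {"EX_A": 2.0})
        (rec,) = supplementation_scan(m, medium, ["EX_B"], uptake=0.5)
        # baseline EPS max = 2.0; with B open at 0.5 it is 2.5 -> +25%
        assert rec.eps_rate == pytest.approx(2.5, abs=1e-8)
        assert rec.pct_increase_eps == pytest.approx(25.0, abs=1e-6)

    def test_two_pool_supplement_ranks_at_least_single_pool(self, toy_model):
        """An energy-and-nitrogen route beats a nitrogen-only route for biomass."""
        m = toy_model.copy()
        # synthetic nitrogen-only supplement: uptake straight to ammonium
        m.add_metabolite(Metabolite("nonly_e"))
        m.add_reaction(Reaction("EX_nonly_e", {"nonly_e": -1}, 0, 1000))
        m.add_reaction(Reaction("NONLY", {"nonly_e": -1, "nh4_c": 1}))
        aa_ok = next(a for a in ("ala", "gly", "ser") if f"DEAM_{a}" in m.reactions)
        from epsflux.media import amino_acid_exchange

        records = {
            r.supplement: r
            for r in supplementation_scan(
                m, minimal_medium(), [amino_acid_exchange(aa_ok), "EX_nonly_e"]
            )
        }
        # the deaminated amino acid yields ammonium AND energy
        assert (
            records[amino_acid_exchange(aa_ok)].pct_increase_biomass
            >= records["EX_nonly_e"].pct_increase_biomass - 1e-9
        )
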