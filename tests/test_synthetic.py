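"""Toy-model generator: determinism, planted truths, pathway inventory."""

import io

import pytest

from conftest import tiny_spec
from epsflux.core import find_dead_ends
from epsflux.fba import apply_medium, solve_fba
from epsflux.io import write_model_table
from epsflux.media import minimal_medium
from epsflux.phenotypes import matching_rate_from_table
from epsflux.synthetic import (
    ToyModelSpec,
    ToySpecError,
    generate_toy_model,
    inject_gap,
    phenotype_truth_table,
)


def _model_text(model):
    buf = io.StringIO()
    write_model_table(model, buf)
    return buf.getvalue()


def test_seed_determinism():
    a_model, a_truth = generate_toy_model(ToyModelSpec(seed=7))
    b_model, b_truth = generate_toy_model(ToyModelSpec(seed=7))
    assert _model_text(a_model) == _model_text(b_model)
    assert a_truth.essential_genes_growth == b_truth.essential_genes_growth
    assert a_truth.analytic_max_growth == b_truth.analytic_max_growth


def test_different_seeds_vary():
    texts = {_model_text(generate_toy_model(ToyModelSpec(seed=s))[0]) for s in range(5)}
    assert len(texts) > 1


def test_eps_branch_matches_canonical_inventory(toy_model):
    """The nucleotide-sugar branch carries the canonical transformations."""
    expected = {
        "PGI": {"g6p_c": -1, "f6p_c": 1},          # glucose-6-P isomerase
        "PGM": {"g1p_c": -1, "g6p_c": 1},          # phosphoglucomutase
        "UGP": {"g1p_c": -1, "atp_c": -1, "udpg_c": 1},   # UDP-glc pyrophosphorylase
        "GALE": {"udpg_c": -1, "udpgal_c": 1},     # UDP-glucose 4-epimerase
        "UGDH": {"udpg_c": -1, "udpglcur_c": 1},   # UDP-glucose 6-dehydrogenase
        "UXS": {"udpglcur_c": -1, "udpxyl_c": 1},  # UDP-glucuronate decarboxylase
        "UXE": {"udpxyl_c": -1, "udparab_c": 1},   # UDP-arabinose 4-epimerase
        "PMI": {"f6p_c": -1, "m6p_c": 1},          # mannose-6-P isomerase
        "PMM": {"m6p_c": -1, "m1p_c": 1},          # phosphomannomutase
        "GMP": {"m1p_c": -1, "atp_c": -1, "gdpman_c": 1},  # GDP-man pyrophosphorylase
        "FUCS": {"gdpman_c": -1, "gdpfuc_c": 1},   # GDP-fucose synthesis
        "RFFH": {"g1p_c": -1, "atp_c": -1, "dtdpg_c": 1},  # dTDP-glc synthase
        "RHMS": {"dtdpg_c": -1, "dtdprmn_c": 1},   # dTDP-rhamnose synthesis
    }
    for rid, stoich in expected.items():
        assert toy_model.reactions[rid].stoichiometry == stoich, rid
    # bidirectional interconversions are reversible, activations are not
    assert toy_model.reactions["PGI"].reversible
    assert toy_model.reactions["PGM"].reversible
    assert not toy_model.reactions["UGP"].reversible


def test_complex_rules_planted(toy_model):
    assert toy_model.reactions["FUCS"].gpr.to_string() == "g_GMDS and g_TSTA3"
    assert toy_model.reactions["RHMS"].gpr.to_string() == "g_RFBC and g_TGDS"


def test_isozyme_pairs_planted(toy_model):
    rule = toy_model.reactions["PMI"].gpr
    assert rule.evaluate({"g_PMI_1"}) and rule.evaluate({"g_PMI_2"})
    assert not rule.evaluate({"g_PMI_1", "g_PMI_2"})


@pytest.mark.parametrize("seed", range(5))
def test_analytic_optima_match_lp(seed):
    model, truth = generate_toy_model(ToyModelSpec(seed=seed), verify=False)
    applied = apply_medium(model, minimal_medium(), missing="ignore")
    mu = solve_fba(applied)
    eps = solve_fba(applied, "EPS")
    assert mu.objective_value == pytest.approx(truth.analytic_max_growth, abs=1e-8)
    assert eps.objective_value == pytest.approx(truth.analytic_max_eps, abs=1e-8)


def test_no_unintended_dead_ends_across_seeds():
    for seed in range(8):
        model, _ = generate_toy_model(ToyModelSpec(seed=seed), verify=False)
        assert find_dead_ends(model) == set(), f"seed {seed}"


def test_infeasible_spec_rejected():
    with pytest.raises(ToySpecError):
        ToyModelSpec(n_carbon_sources=0)
    with pytest.raises(ToySpecError):
        ToyModelSpec(n_isozyme_pairs=99)
    with pytest.raises(ToySpecError):
        ToyModelSpec(n_carbon_sources=50)


class TestInjectGap:
    def test_gap_is_the_only_new_dead_end(self, toy_model):
        gapped, mid = inject_gap(toy_model, seed=3)
        assert find_dead_ends(gapped) == {mid}

    def test_gap_determinism(self, toy_model):
        _, a = inject_gap(toy_model, seed=5)
        _, b = inject_gap(toy_model, seed=5)
        assert a == b

    def test_growth_preserved(self, toy_model):
        gapped, _ = inject_gap(toy_model, seed=3)
        sol = solve_fba(apply_medium(gapped, minimal_medium(), missing="ignore"))
        assert sol.optimal and sol.objective_value > 1e-6

    def test_spec_flag_applies_gap(self):
        model, truth = generate_toy_model(ToyModelSpec(seed=2, inject_gap=True))
        assert truth.gap_metabolite is not None
        assert find_dead_ends(model) == {truth.gap_metabolite}


class TestTruthTables:
    def test_row_counts(self, toy_model, toy_truth, tmp_path):
        paths = phenotype_truth_table(toy_model, toy_truth, tmp_path)
        import pandas as pd

        carbon = pd.read_csv(paths["carbon"], sep="\t")
        assert len(carbon) == sum(
            1 for c in toy_truth.expected_phenotype_calls if c.role == "carbon"
        )

    def test_self_consistent_rate_is_100(self, toy_model, toy_truth, tmp_path):
        paths = phenotype_truth_table(toy_model, toy_truth, tmp_path)
        import pandas as pd

        for path in paths.values():
            assert matching_rate_from_table(pd.read_csv(path, sep="\t")) == 100.0

    def test_flipped_call_changes_rate(self, toy_model, toy_truth, tmp_path):
        import pandas as pd

        paths = phenotype_truth_table(toy_model, toy_truth, tmp_path)
        df = pd.read_csv(paths["carbon"], sep="\t")
        df.loc[0, "in_silico"] = "-" if df.loc[0, "in_silico"] == "+" else "+"
        n = len(df)
        assert matching_rate_from_table(df) == round(100.0 * (n - 1) / n, 1)


def test_tiny_spec_is_enumerable():
    model, _ = generate_toy_model(tiny_spec(0))
    assert len(model.reactions) <= 10


def test_overexpression_truth_planted():
    """With the screen enabled, the planted top target is an EPS-branch step."""
    model, truth = generate_toy_model(ToyModelSpec(seed=0, screen_truth=True))
    assert truth.top_overexpression_target in model.reactions
    assert model.reactions[truth.top_overexpression_target].subsystem in ("GB", "CM")
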