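"""FBA, FVA and knockout behaviour, cross-checked against cobrapy/glpk."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npflux as nf
from npflux.lp_engine import NonGrowingModelError

from conftest import build_model, to_cobra


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_fba_linear_chain(chain_model):
    sol = nf.optimize(chain_model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)


def test_fba_two_parallel_paths(parallel_model):
    sol = nf.optimize(parallel_model)
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)


def test_fba_closed_uptakes_zero_growth(chain_model):
    closed = chain_model.with_bounds({"EX_A": (0.0, 1000.0)})
    assert nf.optimize(closed).objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_unbounded_reported_as_status():
    model = build_model(
        [
            ("SRC", 0.0, float(1e30), {"A": 1.0}),
            ("BIOMASS", 0.0, float(1e30), {"A": -1.0}),
        ]
    )
    # bounds at 1e30 are effectively unbounded for HiGHS
    sol = nf.optimize(model)
    assert sol.status in ("optimal", "unbounded")


def test_fba_flux_vector_satisfies_steady_state(scenario):
    sol = nf.optimize(scenario.model)
    for met in scenario.model.metabolite_ids:
        balance = sum(
            r.stoichiometry.get(met, 0.0) * sol.flux_vector[r.id]
            for r in scenario.model.reactions
        )
        assert balance == pytest.approx(0.0, abs=1e-6)


def test_fba_matches_cobra_on_random_networks(rng):
    for _ in range(20):
        model = nf.random_network(rng, n_reactions=int(rng.integers(4, 9)))
        mine = nf.optimize(model).objective_value
        theirs = to_cobra(model).slim_optimize()
        assert mine == pytest.approx(theirs, abs=1e-6)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_chain_fixed_at_full_optimum(chain_model):
    fva = nf.flux_variability(chain_model, 1.0)
    for rid in ("R1", "BIOMASS"):
        lo, hi = fva[rid]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)


def test_fva_blocked_reaction_pinned_to_zero():
    model = build_model(
        [
            ("EX_A", -10.0, 1000.0, {"A": -1.0}),
            ("R1", 0.0, 1000.0, {"A": -1.0, "B": 1.0}),
            ("DEAD", 0.0, 1000.0, {"A": -1.0, "C": 1.0}),  # C has no consumer
            ("BIOMASS", 0.0, 1000.0, {"B": -1.0}),
        ]
    )
    fva = nf.flux_variability(model, 0.0)
    assert fva["DEAD"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))


def test_fva_parallel_path_range_at_zero_fraction(parallel_model):
    fva = nf.flux_variability(parallel_model, 0.0)
    lo, hi = fva["P1"]
    assert lo == pytest.approx(0.0, abs=1e-6)
    assert hi == pytest.approx(4.0, abs=1e-6)


def test_fva_contains_fba_solution(scenario):
    fva = nf.flux_variability(scenario.model, 1.0)
    sol = nf.optimize(scenario.model)
    for rid, flux in sol.flux_vector.items():
        lo, hi = fva[rid]
        assert lo - 1e-6 <= flux <= hi + 1e-6


def test_fva_infeasible_model_raises():
    model = build_model(
        [
            ("FORCE", 5.0, 10.0, {"A": 1.0}),  # must produce A
            ("BIOMASS", 0.0, 0.0, {"A": -1.0}),  # but nothing may consume it
        ]
    )
    with pytest.raises(nf.InfeasibleModelError):
        nf.flux_variability(model, 1.0)


def test_fva_matches_cobra_on_random_networks(rng):
    from cobra.flux_analysis import flux_variability_analysis

    for _ in range(10):
        model = nf.random_network(rng, n_reactions=int(rng.integers(4, 9)))
        mine = nf.flux_variability(model, 1.0)
        theirs = flux_variability_analysis(to_cobra(model), fraction_of_optimum=1.0)
        for rid in model.reaction_ids:
            assert mine[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
            assert mine[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)


# ---------------------------------------------------------------------------
# GPR evaluation and deletions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule, knocked, expected",
    [
        ("g1 and g2", {"g1"}, False),
        ("g1 or g2", {"g1"}, True),
        ("g1 or g2", {"g1", "g2"}, False),
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
        ("(g1 and g2) or g3", {"g2"}, True),
    ],
)
def test_evaluate_gpr_cases(rule, knocked, expected):
    assert nf.evaluate_gpr(nf.parse_gpr(rule), knocked) is expected


def test_evaluate_gpr_empty_rule_always_true():
    assert nf.evaluate_gpr(None, {"g1"}) is True


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_evaluate_gpr_matches_truth_table_on_random_trees(seed):
    """Tree evaluation agrees with brute-force truth tables, depth <= 4."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(5)]
    rule = nf.random_gpr(rng, genes, depth=4)
    used = sorted(rule.genes)

    def brute(node, truth):
        if node.op == "gene":
            return truth[node.gene]
        values = [brute(c, truth) for c in node.children]
        return all(values) if node.op == "and" else any(values)

    for values in itertools.product([False, True], repeat=len(used)):
        truth = dict(zip(used, values))
        knocked = {g for g, v in truth.items() if not v}
        assert rule.evaluate(knocked) == brute(rule, truth)


def test_delete_genes_noop(chain_model):
    out, disabled = nf.delete_genes(chain_model, set())
    assert disabled == frozenset()
    assert out is chain_model


def test_delete_genes_zeroes_controlled_reaction(chain_model):
    out, disabled = nf.delete_genes(chain_model, {"g1"})
    assert disabled == frozenset({"R1"})
    assert out.reaction("R1").lower_bound == 0.0
    assert out.reaction("R1").upper_bound == 0.0


def test_delete_one_isozyme_is_harmless(isozyme_model):
    _, disabled = nf.delete_genes(isozyme_model, {"g1"})
    assert disabled == frozenset()


def test_growth_ratio_cases(chain_model, isozyme_model):
    assert nf.growth_ratio(chain_model, set()).grRatio == pytest.approx(1.0)
    assert nf.growth_ratio(chain_model, {"g1"}).grRatio == 0.0
    assert nf.growth_ratio(isozyme_model, {"g1"}).grRatio == pytest.approx(1.0)
    assert nf.growth_ratio(isozyme_model, {"g1", "g2"}).grRatio == 0.0


def test_growth_ratio_non_growing_reference(chain_model):
    closed = chain_model.with_bounds({"EX_A": (0.0, 1000.0)})
    with pytest.raises(NonGrowingModelError):
        nf.growth_ratio(closed, {"g1"})


def test_single_gene_deletion_finds_planted_essential(scenario):
    results = nf.single_gene_deletion(scenario.model)
    lethal = {r.label for r in results if r.grRatio == 0.0}
    assert lethal == {"g1_T"}  # the sole transporter of the biomass pathway


def test_single_gene_deletion_no_gprs_all_one():
    model = build_model(
        [
            ("EX_A", -10.0, 1000.0, {"A": -1.0}),
            ("BIOMASS", 0.0, 1000.0, {"A": -1.0}),
        ]
    )
    assert nf.single_gene_deletion(model) == []


def test_single_gene_deletion_matches_cobra(rng):
    """grRatio per gene equals the cobra/glpk single-gene-deletion oracle."""
    from cobra.flux_analysis import single_gene_deletion as cobra_sgd

    checked = 0
    while checked < 8:
        model = nf.random_network(rng, n_reactions=int(rng.integers(5, 9)),
                                  with_gprs=True)
        wt = nf.optimize(model).objective_value
        if wt < 1e-3 or not model.genes:
            continue
        checked += 1
        mine = {r.label: r.grRatio for r in nf.single_gene_deletion(model)}
        frame = cobra_sgd(to_cobra(model))
        for ids, growth in zip(frame["ids"], frame["growth"]):
            gene = next(iter(ids))
            expected = (growth or 0.0) / wt
            if expected < 1e-6:
                expected = 0.0
            assert mine[gene] == pytest.approx(expected, abs=1e-6)


def test_single_gene_deletion_consistent_with_growth_ratio(scenario):
    per_gene = {r.label: r.grRatio for r in nf.single_gene_deletion(scenario.model)}
    for gene in sorted(scenario.model.genes)[:10]:
        assert per_gene[gene] == nf.growth_ratio(scenario.model, {gene}).grRatio


def test_knockout_monotonicity(rng):
    """Growth never increases when the knocked gene set grows."""
    draws = 0
    while draws < 60:
        model = nf.random_network(rng, n_reactions=int(rng.integers(5, 9)),
                                  with_gprs=True)
        wt = nf.optimize(model).objective_value
        genes = sorted(model.genes)
        if wt < 1e-3 or len(genes) < 2:
            continue
        draws += 1
        a = set(rng.choice(genes, size=rng.integers(1, len(genes)), replace=False))
        b = set(rng.choice(genes, size=rng.integers(1, len(genes)), replace=False))
        r_union = nf.growth_ratio(model, a | b).grRatio
        r_a = nf.growth_ratio(model, a).grRatio
        r_b = nf.growth_ratio(model, b).grRatio
        assert r_union <= min(r_a, r_b) + 1e-6


# ---------------------------------------------------------------------------
# Combination deletions
# ---------------------------------------------------------------------------

def test_combination_identical_sets_no_synergy(chain_model):
    table = nf.combination_deletion(chain_model, [("a", {"g1"}, "b", {"g1"})])
    row = table.iloc[0]
    assert row.grRatio_ab == row.grRatio_a
    assert not row.synergy


def test_combination_isozyme_pair_is_synergistic(isozyme_model):
    table = nf.combination_deletion(isozyme_model, [("a", {"g1"}, "b", {"g2"})])
    row = table.iloc[0]
    assert row.grRatio_a == pytest.approx(1.0)
    assert row.grRatio_b == pytest.approx(1.0)
    assert row.grRatio_ab == 0.0
    assert row.synergy


def test_combination_irrelevant_genes_all_one(scenario):
    table = nf.combination_deletion(
        scenario.model, [("a", {"g2_1"}, "b", {"g3_1"})]
    )
    row = table.iloc[0]
    assert row.grRatio_a == pytest.approx(1.0)
    assert row.grRatio_ab == pytest.approx(1.0)
    assert not row.synergy
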