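"""Model containers, GPR parsing, SBML/JSON round-trips, medium, tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npflux as nf
from npflux.model_core import ModelFormatError

from conftest import build_model


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, genes",
    [
        ("g1", {"g1"}),
        ("g1 and g2", {"g1", "g2"}),
        ("(g1 AND g2) OR g3", {"g1", "g2", "g3"}),
        ("((g1 and g2) or (g3 and g4))", {"g1", "g2", "g3", "g4"}),
    ],
)
def test_parse_gpr_collects_genes(text, genes):
    rule = nf.parse_gpr(text)
    assert rule.genes == frozenset(genes)


def test_parse_gpr_strips_transcript_suffixes():
    rule = nf.parse_gpr("100.1 and 200.2")
    assert rule.genes == frozenset({"100", "200"})


def test_parse_gpr_round_trips_through_to_string():
    text = "((g1 and g2) or g3) and g4"
    rule = nf.parse_gpr(text)
    again = nf.parse_gpr(rule.to_string())
    assert again == rule


@pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 g2 or"])
def test_parse_gpr_rejects_malformed(bad):
    with pytest.raises(ModelFormatError):
        nf.parse_gpr(bad)


def test_gpr_evaluation_matches_truth_table():
    """Tree evaluation equals brute-force enumeration over all assignments."""
    rule = nf.parse_gpr("((g1 and g2) or g3)")
    genes = sorted(rule.genes)
    for values in itertools.product([False, True], repeat=len(genes)):
        truth = dict(zip(genes, values))
        expected = (truth["g1"] and truth["g2"]) or truth["g3"]
        assert rule.evaluate_assignment(lambda g: truth[g]) == expected


# ---------------------------------------------------------------------------
# Model invariants
# ---------------------------------------------------------------------------

def test_model_rejects_undeclared_metabolites():
    with pytest.raises(ValueError, match="undeclared metabolite"):
        nf.MetabolicModel(
            "bad",
            [nf.Metabolite("A")],
            [nf.Reaction("R", stoichiometry={"A": -1, "ghost": 1})],
            objective_reaction_id="R",
        )


def test_model_rejects_missing_objective():
    with pytest.raises(ValueError, match="objective"):
        nf.MetabolicModel(
            "bad",
            [nf.Metabolite("A")],
            [nf.Reaction("R", stoichiometry={"A": -1})],
            objective_reaction_id="nope",
        )


def test_reaction_rejects_inverted_bounds():
    with pytest.raises(ValueError, match="bound"):
        nf.Reaction("R", lower_bound=5, upper_bound=-5)


def test_gpr_genes_registered_in_model(chain_model):
    assert "g1" in chain_model.genes


# ---------------------------------------------------------------------------
# SBML and JSON round-trips
# ---------------------------------------------------------------------------

def test_sbml_round_trip_toy_fixture(tmp_path, chain_model):
    path = tmp_path / "chain.xml"
    nf.write_sbml(chain_model, path)
    back = nf.read_sbml(path)
    assert len(back.reactions) == 3
    assert back.objective_reaction_id == "BIOMASS"
    assert back.structurally_equal(chain_model)


def test_sbml_round_trip_nested_gpr(tmp_path):
    model = build_model(
        [
            ("EX_A", -5.0, 5.0, {"A": -1.0}),
            ("R1", 0.0, 10.0, {"A": -1.0, "B": 1.0}, "(g1 and g2) or g3"),
            ("BIOMASS", 0.0, 10.0, {"B": -1.0}),
        ]
    )
    path = tmp_path / "m.xml"
    nf.write_sbml(model, path)
    back = nf.read_sbml(path)
    assert back.reaction("R1").gpr == model.reaction("R1").gpr


def test_sbml_round_trip_random_models(tmp_path, rng):
    for i in range(25):
        model = nf.random_network(rng, n_reactions=int(rng.integers(4, 10)),
                                  with_gprs=True)
        path = tmp_path / f"m{i}.xml"
        nf.write_sbml(model, path)
        back = nf.read_sbml(path)
        # GPR text may re-associate (a and b and c); compare semantics
        assert back.model_id == model.model_id
        assert back.reaction_ids == model.reaction_ids
        for rid in model.reaction_ids:
            a, b = model.reaction(rid), back.reaction(rid)
            assert a.stoichiometry == b.stoichiometry
            assert a.lower_bound == pytest.approx(b.lower_bound)
            assert a.upper_bound == pytest.approx(b.upper_bound)
            ga = a.gpr.genes if a.gpr else frozenset()
            gb = b.gpr.genes if b.gpr else frozenset()
            assert ga == gb


def test_sbml_subsystems_survive_round_trip(tmp_path, scenario):
    path = tmp_path / "toy.xml"
    nf.write_sbml(scenario.model, path)
    back = nf.read_sbml(path)
    assert back.structurally_equal(scenario.model)


def test_sbml_without_objective_raises(tmp_path):
    path = tmp_path / "noobj.xml"
    path.write_text(
        """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="m">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
    )
    with pytest.raises(ModelFormatError, match="objective"):
        nf.read_sbml(path)


def test_sbml_parse_error_names_file(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml this is not xml")
    with pytest.raises(ModelFormatError, match="broken.xml"):
        nf.read_sbml(path)


def test_json_round_trip(tmp_path, scenario):
    path = tmp_path / "toy.json"
    nf.write_json_model(scenario.model, path)
    back = nf.read_json_model(path)
    assert back.structurally_equal(scenario.model)


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------

def test_apply_medium_full_medium_is_identity(scenario):
    medium = nf.MediumComposition(m.id for m in scenario.model.metabolites)
    out = nf.apply_medium(scenario.model, medium)
    assert out.structurally_equal(scenario.model)


def test_apply_medium_empty_closes_every_uptake(scenario):
    out = nf.apply_medium(scenario.model, nf.MediumComposition([]))
    for rxn in out.exchange_reactions():
        (met, coef), = ((m, c) for m, c in rxn.stoichiometry.items() if c != 0)
        if coef < 0:
            assert rxn.lower_bound >= 0.0
        else:
            assert rxn.upper_bound <= 0.0


def test_apply_medium_selective(scenario):
    medium = nf.MediumComposition(["n1_e"])
    out = nf.apply_medium(scenario.model, medium)
    assert out.reaction("EX_n1").lower_bound == -10.0
    assert out.reaction("EX_n2").lower_bound == 0.0


def test_apply_medium_idempotent_and_never_widens(scenario):
    medium = nf.MediumComposition(["n1_e", "n3_e"])
    once = nf.apply_medium(scenario.model, medium)
    twice = nf.apply_medium(once, medium)
    assert twice.structurally_equal(once)
    for rxn in scenario.model.reactions:
        out = once.reaction(rxn.id)
        assert out.lower_bound >= rxn.lower_bound
        assert out.upper_bound <= rxn.upper_bound


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def test_read_tables_dedupes_and_counts(tmp_path):
    targets = tmp_path / "targets.tsv"
    targets.write_text(
        "drug_id\tgene_id\ndrugA\tg1\ndrugA\tg1\ndrugB\tg2\n"
    )
    medium = tmp_path / "medium.tsv"
    medium.write_text("metabolite_id\nglc_e\n")
    expr = tmp_path / "expr.tsv"
    expr.write_text("gene_id\tDMSO\ng1\t2.0\ng2\t-1.0\n")
    table, med, e = nf.read_tables(targets, medium, expr)
    assert len(table) == 2
    assert table.genes_for("drugA") == frozenset({"g1"})
    assert "glc_e" in med
    assert e.loc["g2", "DMSO"] == -1.0


def test_read_tables_empty_with_header(tmp_path):
    path = tmp_path / "targets.tsv"
    path.write_text("drug_id\tgene_id\n")
    assert len(nf.read_drug_targets(path)) == 0


def test_read_tables_schema_error(tmp_path):
    path = tmp_path / "targets.tsv"
    path.write_text("drug\tgene\nx\ty\n")
    with pytest.raises(ModelFormatError, match="drug_id"):
        nf.read_drug_targets(path)


def test_drug_target_class_and_restriction(tmp_path):
    path = tmp_path / "targets.tsv"
    path.write_text(
        "drug_id\tgene_id\tdrug_class\n"
        "np1\tg1\tnatural_product\n"
        "cd1\tg9\tcancer_drug\n"
    )
    table = nf.read_drug_targets(path)
    assert table.drugs_of_class("cancer_drug") == ["cd1"]
    restricted = table.restrict_to_genes({"g1"})
    assert restricted.genes_for("cd1") == frozenset()
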