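import numpy as np
import pytest

from npflux import (
    Metabolite,
    MetabolicModel,
    Reaction,
    ScenarioSpec,
    make_scenario,
    parse_gpr,
)


def build_model(reactions, model_id="fixture", objective="BIOMASS"):
    """Assemble a model from (id, lb, ub, stoich, gpr, subsystem) tuples,
    declaring every referenced metabolite."""
    mets = sorted({m for _, _, _, stoich, *_ in reactions for m in stoich})
    rxns = []
    for entry in reactions:
        rid, lb, ub, stoich = entry[:4]
        gpr = entry[4] if len(entry) > 4 else None
        subsystem = entry[5] if len(entry) > 5 else ""
        rxns.append(
            Reaction(
                id=rid,
                lower_bound=lb,
                upper_bound=ub,
                stoichiometry=stoich,
                gpr=parse_gpr(gpr) if isinstance(gpr, str) else gpr,
                subsystem=subsystem,
            )
        )
    return MetabolicModel(
        model_id=model_id,
        metabolites=[Metabolite(m) for m in mets],
        reactions=rxns,
        objective_reaction_id=objective,
    )


@pytest.fixture
def chain_model():
    """EX_A -(uptake 10)-> A -> B -> biomass: optimum 10, every reaction
    carries exactly 10 at the optimum."""
    return build_model(
        [
            ("EX_A", -10.0, 1000.0, {"A": -1.0}),
            ("R1", 0.0, 1000.0, {"A": -1.0, "B": 1.0}, "g1"),
            ("BIOMASS", 0.0, 1000.0, {"B": -1.0}),
        ]
    )


@pytest.fixture
def parallel_model():
    """Two routes A->B with capacities 4 and 6; optimum 10."""
    return build_model(
        [
            ("EX_A", -10.0, 1000.0, {"A": -1.0}),
            ("P1", 0.0, 4.0, {"A": -1.0, "B": 1.0}, "ga"),
            ("P2", 0.0, 6.0, {"A": -1.0, "B": 1.0}, "gb"),
            ("BIOMASS", 0.0, 1000.0, {"B": -1.0}),
        ]
    )


@pytest.fixture
def isozyme_model():
    """Essential reaction guarded by an OR pair: single knockouts harmless,
    the double knockout lethal."""
    return build_model(
        [
            ("EX_A", -10.0, 1000.0, {"A": -1.0}),
            ("R1", 0.0, 1000.0, {"A": -1.0, "B": 1.0}, "g1 or g2"),
            ("BIOMASS", 0.0, 1000.0, {"B": -1.0}),
        ]
    )


@pytest.fixture
def scenario():
    return make_scenario(ScenarioSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def to_cobra(model):
    """Independent-solver twin of a model, built with cobrapy (glpk)."""
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    cm.objective = model.objective_reaction_id
    return cm
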