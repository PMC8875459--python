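"""Synthetic study generator: toy networks, expression, targets, medium.

The generated scenario mirrors the shape of a treated-vs-control expression
study on one cell line: a control condition (all genes active), one
condition per natural product, a drug-target table covering both natural
products and reference cancer drugs, and a growth medium listing every
nutrient the network can import.

The toy network has ``n_pathways`` labelled pathways.  Each imports its own
nutrient through an exchange and a gene-controlled transporter and converts
it to a terminal product through parallel gene-controlled conversion
reactions (so the loss of one conversion does not silence the whole
pathway).  Pathway 1's product feeds the biomass reaction (growth requires
it); every other pathway ends in a demand exchange so that it can carry
flux.  GPRs mix single genes, OR isozyme pairs (transporters) and one AND
complex per pathway.

Planted signals:

* *essential products* — their targets in the drug-target table are the
  genes of the sole transporter feeding the biomass pathway, so knocking
  them out stops growth;
* *pathway shutdowns* — the product's expression condition scores that
  pathway's genes low, so context extraction drops the pathway and its
  presence rate collapses; the product also receives a target gene there.

All randomness flows from one seeded generator; identical specs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DrugTargetTable,
    GprRule,
    MediumComposition,
    Metabolite,
    MetabolicModel,
    Reaction,
    parse_gpr,
)

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "make_toy_network",
    "make_condition_data",
    "make_scenario",
    "random_network",
    "random_gpr",
]

#: expression score distributions: active ~ N(2, 0.5^2) clipped above the
#: high threshold, inactive ~ N(-2, 0.5^2) clipped below the low threshold
HIGH_MEAN, LOW_MEAN, SCORE_SD = 2.0, -2.0, 0.5
HIGH_CLIP, LOW_CLIP = 1.1, -0.1
CONTROL_CONDITION = "DMSO"


@dataclass(frozen=True)
class ScenarioSpec:
    n_pathways: int = 6
    reactions_per_pathway: int = 6
    n_products: int = 12
    n_reference_drugs: int = 4
    planted_essential_products: tuple[str, ...] = ("NP_01",)
    planted_pathway_shutdown: tuple[tuple[str, str], ...] = (("NP_02", "PATHWAY_3"),)
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("scenario needs at least one pathway")
        if self.reactions_per_pathway < 1:
            raise ValueError("scenario needs at least one reaction per pathway")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        labels = set(self.product_labels)
        missing = set(self.planted_essential_products) - labels
        missing |= {p for p, _ in self.planted_pathway_shutdown} - labels
        if missing:
            raise ValueError(f"planted products not generated: {sorted(missing)}")
        pathways = {f"PATHWAY_{i + 1}" for i in range(self.n_pathways)}
        bad = {p for _, p in self.planted_pathway_shutdown} - pathways
        if bad:
            raise ValueError(f"planted shutdown pathways not generated: {sorted(bad)}")

    @property
    def product_labels(self) -> tuple[str, ...]:
        return tuple(f"NP_{i + 1:02d}" for i in range(self.n_products))

    @property
    def cancer_drug_labels(self) -> tuple[str, ...]:
        return tuple(f"CD_{i + 1:02d}" for i in range(self.n_reference_drugs))


@dataclass(frozen=True)
class Scenario:
    spec: ScenarioSpec
    model: MetabolicModel
    expression: pd.DataFrame
    targets: DrugTargetTable
    medium: MediumComposition
    truth: Mapping[str, object] = field(default_factory=dict)


def _pathway_label(p: int) -> str:
    return f"PATHWAY_{p + 1}"


def make_toy_network(spec: ScenarioSpec) -> MetabolicModel:
    """Deterministic toy network for a scenario (independent of noise/seed)."""
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []

    biomass_inputs: dict[str, float] = {}
    for p in range(spec.n_pathways):
        label = _pathway_label(p)
        nutrient_e = f"n{p + 1}_e"
        metabolites.append(Metabolite(nutrient_e, f"nutrient {p + 1}", "e"))
        reactions.append(
            Reaction(
                id=f"EX_n{p + 1}",
                name=f"nutrient {p + 1} exchange",
                subsystem="EXCHANGE",
                lower_bound=-10.0,
                upper_bound=1000.0,
                stoichiometry={nutrient_e: -1.0},
            )
        )
        nutrient_c = f"n{p + 1}_c"
        terminal = f"w{p + 1}_c"
        metabolites.append(Metabolite(nutrient_c, f"nutrient {p + 1}", "c"))
        metabolites.append(Metabolite(terminal, f"product {p + 1}", "c"))
        # sole transporter of the biomass pathway is single-gene (the planted
        # essential target); other transporters are OR isozyme pairs
        if p == 0:
            transport_gpr = parse_gpr(f"g{p + 1}_T")
        else:
            transport_gpr = parse_gpr(f"g{p + 1}_Ta or g{p + 1}_Tb")
        reactions.append(
            Reaction(
                id=f"T_{p + 1}",
                name=f"nutrient {p + 1} transport",
                subsystem=label,
                lower_bound=0.0,
                upper_bound=1000.0,
                stoichiometry={nutrient_e: -1.0, nutrient_c: 1.0},
                gpr=transport_gpr,
            )
        )
        # parallel conversions: one AND complex, the rest single genes
        for i in range(max(1, spec.reactions_per_pathway - 1)):
            if i == 1:
                gpr = parse_gpr(f"g{p + 1}_{i + 1}a and g{p + 1}_{i + 1}b")
            else:
                gpr = parse_gpr(f"g{p + 1}_{i + 1}")
            reactions.append(
                Reaction(
                    id=f"R_{p + 1}_{i + 1}",
                    name=f"pathway {p + 1} conversion {i + 1}",
                    subsystem=label,
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    stoichiometry={nutrient_c: -1.0, terminal: 1.0},
                    gpr=gpr,
                )
            )
        if p == 0:
            biomass_inputs[terminal] = -1.0
        else:
            reactions.append(
                Reaction(
                    id=f"DM_p{p + 1}",
                    name=f"pathway {p + 1} product demand",
                    subsystem="EXCHANGE",
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    stoichiometry={terminal: -1.0},
                )
            )

    reactions.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            subsystem="BIOMASS",
            lower_bound=0.0,
            upper_bound=1000.0,
            stoichiometry=biomass_inputs,
        )
    )
    return MetabolicModel(
        model_id=f"toy_{spec.n_pathways}x{spec.reactions_per_pathway}",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )


def _pathway_genes(model: MetabolicModel, pathway: str) -> set[str]:
    return {
        g for r in model.reactions if r.subsystem == pathway for g in r.genes
    }


def _essential_target_genes(model: MetabolicModel, spec: ScenarioSpec) -> frozenset[str]:
    # the single-gene transporter feeding the biomass pathway
    return frozenset(model.reaction("T_1").genes)


def make_condition_data(
    model: MetabolicModel, spec: ScenarioSpec
) -> tuple[pd.DataFrame, DrugTargetTable, MediumComposition, dict]:
    """Expression, targets, medium and the planted-truth record for a toy
    network built from the same spec."""
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes)
    shutdown_of = dict(spec.planted_pathway_shutdown)
    conditions = [CONTROL_CONDITION, *spec.product_labels]

    def draw(active: bool) -> float:
        if active:
            return max(HIGH_CLIP, rng.normal(HIGH_MEAN, SCORE_SD))
        return min(LOW_CLIP, rng.normal(LOW_MEAN, SCORE_SD))

    columns: dict[str, list[float]] = {}
    for condition in conditions:
        low_genes: set[str] = set()
        if condition in shutdown_of:
            low_genes = _pathway_genes(model, shutdown_of[condition])
        scores = []
        for gene in genes:
            active = gene not in low_genes
            if condition != CONTROL_CONDITION and rng.random() < spec.noise_rate:
                active = not active
            scores.append(draw(active))
        columns[condition] = scores
    expression = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))

    essential_genes = _essential_target_genes(model, spec)
    non_essential_pathways = [
        _pathway_label(p) for p in range(1, spec.n_pathways)
    ] or [_pathway_label(0)]
    targets: dict[str, set[str]] = {}
    classes: dict[str, str] = {}
    for i, product in enumerate(spec.product_labels):
        classes[product] = "natural_product"
        if product in spec.planted_essential_products:
            targets[product] = set(essential_genes)
        elif product in shutdown_of:
            pathway_genes = sorted(_pathway_genes(model, shutdown_of[product]))
            targets[product] = {pathway_genes[0]}
        else:
            pathway = non_essential_pathways[i % len(non_essential_pathways)]
            pathway_genes = sorted(_pathway_genes(model, pathway))
            targets[product] = {pathway_genes[i % len(pathway_genes)]}
    for i, drug in enumerate(spec.cancer_drug_labels):
        classes[drug] = "cancer_drug"
        if i == 0:
            targets[drug] = set(essential_genes)
        else:
            pathway = non_essential_pathways[i % len(non_essential_pathways)]
            pathway_genes = sorted(_pathway_genes(model, pathway))
            targets[drug] = {pathway_genes[(2 * i) % len(pathway_genes)]}

    medium = MediumComposition(
        m.id for m in model.metabolites if m.compartment == "e"
    )
    truth = {
        "control_condition": CONTROL_CONDITION,
        "essential_products": sorted(spec.planted_essential_products),
        "essential_target_genes": sorted(essential_genes),
        "pathway_shutdowns": {p: s for p, s in spec.planted_pathway_shutdown},
        "growth_reference_drugs": [spec.cancer_drug_labels[0]]
        if spec.n_reference_drugs
        else [],
        "seed": spec.seed,
        "noise_rate": spec.noise_rate,
    }
    return expression, DrugTargetTable(targets, classes), medium, truth


def make_scenario(spec: ScenarioSpec) -> Scenario:
    model = make_toy_network(spec)
    expression, targets, medium, truth = make_condition_data(model, spec)
    return Scenario(spec, model, expression, targets, medium, truth)


# ---------------------------------------------------------------------------
# Random fixtures for oracle comparisons
# ---------------------------------------------------------------------------

def random_gpr(rng: np.random.Generator, genes: Sequence[str], depth: int = 2) -> GprRule:
    """A random AND/OR tree of bounded depth over the given gene pool."""
    if depth <= 0 or rng.random() < 0.4:
        return GprRule("gene", gene=str(rng.choice(genes)))
    op = "and" if rng.random() < 0.5 else "or"
    n_children = int(rng.integers(2, 4))
    children = tuple(random_gpr(rng, genes, depth - 1) for _ in range(n_children))
    return GprRule(op, children=children)


def random_network(
    rng: np.random.Generator,
    n_reactions: int = 8,
    with_gprs: bool = False,
) -> MetabolicModel:
    """A small random bounded network, always feasible (zero flux admissible)
    and never unbounded (finite bounds everywhere).

    Useful as a fixture family for comparing solvers and consistency
    checkers; some reactions are reversible, some dead ends arise naturally.
    """
    n_reactions = max(3, int(n_reactions))
    n_mets = int(rng.integers(2, max(3, n_reactions)))
    met_ids = [f"m{i}" for i in range(n_mets)]
    metabolites = [Metabolite(m, compartment="c") for m in met_ids]
    gene_pool = [f"g{i}" for i in range(max(3, n_reactions))]

    reactions: list[Reaction] = []
    # uptake feeding the network
    reactions.append(
        Reaction(
            id="EX_up",
            lower_bound=0.0,
            upper_bound=float(rng.uniform(1.0, 10.0)),
            stoichiometry={met_ids[0]: 1.0},
        )
    )
    for i in range(n_reactions - 2):
        a, b = rng.choice(n_mets, size=2, replace=False)
        reversible = rng.random() < 0.4
        gpr = random_gpr(rng, gene_pool) if with_gprs and rng.random() < 0.8 else None
        reactions.append(
            Reaction(
                id=f"R{i}",
                lower_bound=-float(rng.uniform(1.0, 10.0)) if reversible else 0.0,
                upper_bound=float(rng.uniform(1.0, 10.0)),
                stoichiometry={met_ids[a]: -1.0, met_ids[b]: 1.0},
                gpr=gpr,
            )
        )
    sink_met = met_ids[int(rng.integers(0, n_mets))]
    reactions.append(
        Reaction(
            id="BIOMASS",
            lower_bound=0.0,
            upper_bound=float(rng.uniform(5.0, 20.0)),
            stoichiometry={sink_met: -1.0},
        )
    )
    return MetabolicModel(
        model_id="random",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )
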