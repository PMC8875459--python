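"""Pathway-level views: target mapping and presence-rate alteration.

Pathways are the subsystem labels of the reference reconstruction.  For a
context model, a pathway's *presence rate* is the fraction of its reference
reactions retained in the context model; the alteration analysis compares
these rates between treatment models and the control model, excludes tiny
pathways (3 reactions or fewer by default) and ranks pathways by the
interquartile range of the differences across treatments.  Rows whose
absolute difference reaches the display threshold (0.1 by default) are
flagged for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import DrugTargetTable, MetabolicModel

__all__ = [
    "PathwayIndex",
    "PathwayAlteration",
    "UNASSIGNED",
    "MIN_PATHWAY_SIZE",
    "PLOT_THRESHOLD",
    "build_pathway_index",
    "count_pathway_targets",
    "presence_rates",
    "alteration_report",
]

UNASSIGNED = "UNASSIGNED"
#: pathways with at most this many reactions are dropped from the report
MIN_PATHWAY_SIZE = 3
#: minimum |presence-rate difference| to flag a row for display
PLOT_THRESHOLD = 0.1


@dataclass(frozen=True)
class PathwayIndex:
    """Subsystem -> reactions and gene -> reactions maps over a reference
    model (the role of a reaction-gene matrix plus subsystem labels)."""

    reactions_by_pathway: Mapping[str, frozenset[str]]
    reactions_by_gene: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "reactions_by_pathway",
            {p: frozenset(r) for p, r in self.reactions_by_pathway.items()},
        )
        object.__setattr__(
            self,
            "reactions_by_gene",
            {g: frozenset(r) for g, r in self.reactions_by_gene.items()},
        )

    @property
    def pathways(self) -> list[str]:
        return sorted(self.reactions_by_pathway)

    def pathway_of(self, reaction_id: str) -> str | None:
        for pathway, rxns in self.reactions_by_pathway.items():
            if reaction_id in rxns:
                return pathway
        return None

    def pathways_of_gene(self, gene: str) -> set[str]:
        out: set[str] = set()
        for rid in self.reactions_by_gene.get(gene, ()):
            p = self.pathway_of(rid)
            if p is not None:
                out.add(p)
        return out


@dataclass(frozen=True)
class PathwayAlteration:
    pathway: str
    treatment: str
    presence_rate_treatment: float
    presence_rate_control: float
    difference: float
    pathway_size: int
    iqr_across_products: float
    display: bool


def build_pathway_index(reference_model: MetabolicModel) -> PathwayIndex:
    """Index a reference model's subsystems and GPR gene-to-reaction links.

    Unlabelled reactions are grouped under :data:`UNASSIGNED`.
    """
    by_pathway: dict[str, set[str]] = {}
    by_gene: dict[str, set[str]] = {}
    for rxn in reference_model.reactions:
        by_pathway.setdefault(rxn.subsystem or UNASSIGNED, set()).add(rxn.id)
        for gene in rxn.genes:
            by_gene.setdefault(gene, set()).add(rxn.id)
    return PathwayIndex(by_pathway, by_gene)


def count_pathway_targets(
    index: PathwayIndex, targets: DrugTargetTable
) -> pd.DataFrame:
    """Per pathway: how many drugs of each class target it, and how many of
    its reactions are under gene control.

    A drug targets a pathway when at least one of its target genes controls
    at least one reaction there.
    """
    classes = sorted(set(targets.drug_class.values()) or {"drug"})
    gene_controlled: dict[str, set[str]] = {p: set() for p in index.pathways}
    for gene, rxns in index.reactions_by_gene.items():
        for rid in rxns:
            p = index.pathway_of(rid)
            if p is not None:
                gene_controlled[p].add(rid)

    rows = []
    for pathway in index.pathways:
        row: dict[str, object] = {
            "pathway": pathway,
            "n_reactions": len(index.reactions_by_pathway[pathway]),
            "n_gene_controlled_reactions": len(gene_controlled[pathway]),
        }
        for cls in classes:
            n = 0
            for drug in targets.drugs:
                if targets.drug_class.get(drug, "drug") != cls:
                    continue
                hit = any(
                    index.reactions_by_gene.get(g, frozenset())
                    & index.reactions_by_pathway[pathway]
                    for g in targets.genes_for(drug)
                )
                n += bool(hit)
            row[f"n_{cls}"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway").sort_index()


def presence_rates(
    context_model: MetabolicModel | Iterable[str], index: PathwayIndex
) -> dict[str, float]:
    """Fraction of each pathway's reference reactions present in the context
    model.  Pathways with no reference reactions are omitted."""
    if isinstance(context_model, MetabolicModel):
        present = set(context_model.reaction_ids)
    else:
        present = set(context_model)
    rates = {}
    for pathway, rxns in index.reactions_by_pathway.items():
        if rxns:
            rates[pathway] = len(rxns & present) / len(rxns)
    return rates


def alteration_report(
    treatment_models: Mapping[str, MetabolicModel],
    control_model: MetabolicModel,
    index: PathwayIndex,
    min_pathway_size: int = MIN_PATHWAY_SIZE,
    plot_threshold: float = PLOT_THRESHOLD,
) -> list[PathwayAlteration]:
    """Per-pathway presence-rate differences of each treatment vs control.

    Pathways with ``min_pathway_size`` reactions or fewer are excluded;
    remaining pathways are ordered by descending interquartile range of the
    differences across treatments (ties by label), then by treatment label.
    """
    if not treatment_models:
        raise ValueError("at least one treatment model is required")
    control = presence_rates(control_model, index)
    per_treatment = {
        label: presence_rates(model, index)
        for label, model in sorted(treatment_models.items())
    }
    sizes = {p: len(r) for p, r in index.reactions_by_pathway.items()}
    kept = [p for p in index.pathways if sizes[p] > min_pathway_size]

    diffs: dict[str, dict[str, float]] = {}
    for pathway in kept:
        diffs[pathway] = {
            label: rates.get(pathway, 0.0) - control.get(pathway, 0.0)
            for label, rates in per_treatment.items()
        }
    iqr = {
        pathway: float(
            np.subtract(*np.percentile(list(d.values()), [75, 25]))
        )
        for pathway, d in diffs.items()
    }
    ordered = sorted(kept, key=lambda p: (-iqr[p], p))
    report = []
    for pathway in ordered:
        for label in sorted(per_treatment):
            diff = diffs[pathway][label]
            report.append(
                PathwayAlteration(
                    pathway=pathway,
                    treatment=label,
                    presence_rate_treatment=per_treatment[label].get(pathway, 0.0),
                    presence_rate_control=control.get(pathway, 0.0),
                    difference=diff,
                    pathway_size=sizes[pathway],
                    iqr_across_products=iqr[pathway],
                    display=abs(diff) >= plot_threshold,
                )
            )
    return report
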