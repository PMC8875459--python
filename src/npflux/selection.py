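"""Candidate aggregation: four in silico steps to one verdict per product.

Each natural product picks up a flag from every step that nominates it:

1. **deletion** — knocking out its known targets in the control model stops
   growth (grRatio = 0);
2. **content dissimilarity** — its context model ranks in the top-k Jaccard
   dissimilarity to the control model;
3. **flux similarity** — it ranks in the combined top-k flux-range
   similarity to at least one reference cancer-drug model;
4. **pathway** — it has a known target gene in the pathway of interest and
   a nonzero presence-rate difference there.

Products flagged by at least ``min_steps`` steps are *selected* unless an
explicit exclusion (toxicity, prior evidence) removes them; products on the
inclusion list are kept on external evidence regardless of flag count;
everything else is rejected.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import context_builder, lp_engine, pathway_analysis, scoring
from .model_core import DrugTargetTable, MediumComposition, MetabolicModel

__all__ = [
    "SelectionConfig",
    "StepFlags",
    "CandidateTable",
    "PipelineResult",
    "pick_reference_drugs",
    "aggregate",
    "run_pipeline",
    "load_table2_flags",
]

STEP_NAMES = (
    "step1_deletion",
    "step2_dissimilarity",
    "step3_flux_similarity",
    "step4_pathway",
)


@dataclass(frozen=True)
class SelectionConfig:
    top_k_content: int = 5
    top_k_flux: int = 10
    reference_drug_dissimilarity_floor: float = 1e-4
    min_steps: int = 2
    exclude_list: Mapping[str, str] = field(default_factory=dict)
    include_list: Mapping[str, str] = field(default_factory=dict)
    pathway_of_interest: str | None = None
    #: minimum |presence-rate difference| in the pathway of interest for a
    #: step-4 flag; any nonzero difference counts by default
    step4_min_difference: float = 0.0
    control_condition: str = "DMSO"
    high_threshold: float = 1.0
    low_threshold: float = 0.0
    flux_epsilon: float = context_builder.FLUX_EPSILON
    epsilon: float = scoring.EPSILON
    fraction_of_optimum: float = 1.0

    def __post_init__(self) -> None:
        if self.top_k_content < 1 or self.top_k_flux < 1:
            raise ValueError("top-k values must be >= 1")
        object.__setattr__(self, "exclude_list", dict(self.exclude_list))
        object.__setattr__(self, "include_list", dict(self.include_list))


@dataclass(frozen=True)
class StepFlags:
    """Products nominated by each of the four steps."""

    step1_deletion: frozenset[str] = frozenset()
    step2_dissimilarity: frozenset[str] = frozenset()
    step3_flux_similarity: frozenset[str] = frozenset()
    step4_pathway: frozenset[str] = frozenset()

    def products(self) -> set[str]:
        return (
            set(self.step1_deletion)
            | set(self.step2_dissimilarity)
            | set(self.step3_flux_similarity)
            | set(self.step4_pathway)
        )

    def flags_for(self, product: str) -> dict[str, bool]:
        return {name: product in getattr(self, name) for name in STEP_NAMES}


@dataclass(frozen=True)
class CandidateRow:
    product: str
    step1_deletion: bool
    step2_dissimilarity: bool
    step3_flux_similarity: bool
    step4_pathway: bool
    n_steps: int
    verdict: str  # selected | excluded | included_by_evidence | rejected
    note: str = ""


class CandidateTable:
    """Per-product step flags plus final verdict."""

    def __init__(self, rows: Iterable[CandidateRow]):
        self.rows = sorted(rows, key=lambda r: r.product)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, product: str) -> CandidateRow:
        for r in self.rows:
            if r.product == product:
                return r
        raise KeyError(product)

    def with_verdict(self, *verdicts: str) -> list[CandidateRow]:
        return [r for r in self.rows if r.verdict in verdicts]

    @property
    def validated(self) -> list[str]:
        """Products advanced to experimental validation."""
        return [r.product for r in self.with_verdict("selected", "included_by_evidence")]

    @property
    def flagged(self) -> list[str]:
        return [r.product for r in self.rows if r.n_steps >= 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "product": r.product,
                    **{name: int(getattr(r, name)) for name in STEP_NAMES},
                    "n_steps": r.n_steps,
                    "verdict": r.verdict,
                    "note": r.note,
                }
                for r in self.rows
            ]
        ).set_index("product")


def pick_reference_drugs(
    cancer_drug_flux_scores: Mapping[str, float] | Iterable[tuple[str, float]],
    floor: float = 1e-4,
) -> list[str]:
    """Cancer drugs whose flux dissimilarity to control exceeds *floor*,
    ranked descending (ties alphabetical)."""
    if isinstance(cancer_drug_flux_scores, Mapping):
        items = list(cancer_drug_flux_scores.items())
    else:
        items = list(cancer_drug_flux_scores)
    above = [(d, s) for d, s in items if s > floor]
    return [d for d, _ in sorted(above, key=lambda pair: (-pair[1], pair[0]))]


def aggregate(step_outputs: StepFlags, config: SelectionConfig) -> CandidateTable:
    """Combine the four step nominations into verdicts.

    ``selected``: at least ``min_steps`` flags and not excluded.
    ``excluded``: on the exclusion list (reason recorded), whatever the flags.
    ``included_by_evidence``: on the inclusion list, whatever the flags.
    ``rejected``: everything else.
    """
    both = set(config.include_list) & set(config.exclude_list)
    if both:
        raise ValueError(
            f"products on both include and exclude lists: {sorted(both)}"
        )
    universe = step_outputs.products() | set(config.include_list)
    rows = []
    for product in sorted(universe):
        flags = step_outputs.flags_for(product)
        n_steps = sum(flags.values())
        if product in config.exclude_list:
            verdict, note = "excluded", config.exclude_list[product]
        elif product in config.include_list:
            verdict, note = "included_by_evidence", config.include_list[product]
        elif n_steps >= config.min_steps:
            verdict, note = "selected", ""
        else:
            verdict, note = "rejected", ""
        rows.append(CandidateRow(product=product, n_steps=n_steps,
                                 verdict=verdict, note=note, **flags))
    return CandidateTable(rows)


def load_table2_flags() -> StepFlags:
    """The published worked example: 23 candidate products with their four
    step flags, shipped as a packaged TSV."""
    with (importlib.resources.files("npflux") / "data" / "table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return StepFlags(
        **{
            name: frozenset(df.loc[df[name] == 1, "drug_id"])
            for name in STEP_NAMES
        }
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    candidates: CandidateTable
    deletion_results: pd.DataFrame
    content_scores: pd.DataFrame
    cancer_drug_scores: pd.DataFrame
    reference_drugs: list[str]
    flux_scores: pd.DataFrame
    pathway_report: pd.DataFrame
    context_models: dict[str, MetabolicModel]

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "candidate_table.tsv": self.candidates.to_frame(),
            "deletions.tsv": self.deletion_results,
            "content_scores.tsv": self.content_scores,
            "cancer_drug_scores.tsv": self.cancer_drug_scores,
            "flux_scores.tsv": self.flux_scores,
            "pathway_report.tsv": self.pathway_report,
        }
        for name, frame in tables.items():
            path = out_dir / name
            frame.to_csv(path, sep="\t", float_format="%.6f")
            written.append(path)
        return written


def run_pipeline(
    model: MetabolicModel,
    expression: pd.DataFrame,
    targets: DrugTargetTable,
    medium: MediumComposition | None,
    config: SelectionConfig,
) -> PipelineResult:
    """Execute the four-step workflow end to end.

    Builds one context model per expression condition, runs target-deletion
    growth prediction, content and flux-range scoring, and pathway
    alteration, then aggregates verdicts.  Deterministic for fixed inputs.
    """
    control = config.control_condition
    if control not in expression.columns:
        raise ValueError(f"control condition {control!r} not in expression table")
    products = [c for c in expression.columns if c != control]
    natural = targets.drugs_of_class("natural_product") or [
        d for d in targets.drugs if d in products
    ]
    cancer_drugs = targets.drugs_of_class("cancer_drug")
    model_targets = targets.restrict_to_genes(model.genes)

    models = context_builder.build_context_models(
        model,
        expression,
        medium,
        config.high_threshold,
        config.low_threshold,
        config.flux_epsilon,
    )
    control_model = models[control]

    # step 1: target knockout on the control model
    wt = lp_engine.optimize(control_model)
    deletion_rows = []
    step1 = set()
    for drug in natural:
        genes = model_targets.genes_for(drug) & control_model.genes
        result = lp_engine.growth_ratio(
            control_model, genes, label=drug, wild_type_objective=wt.objective_value
        )
        deletion_rows.append(
            {
                "label": drug,
                "wt_objective": result.wild_type_objective,
                "ko_objective": result.knockout_objective,
                "grRatio": result.grRatio,
                "n_disabled_reactions": len(result.disabled_reactions),
            }
        )
        if result.grRatio == 0.0:
            step1.add(drug)
    deletion_results = pd.DataFrame(
        deletion_rows,
        columns=["label", "wt_objective", "ko_objective", "grRatio",
                 "n_disabled_reactions"],
    ).set_index("label").sort_index()

    # step 2: reaction-content dissimilarity of product models vs control
    content_rows = []
    for product in products:
        if product not in models:
            continue
        score = scoring.jaccard_dissimilarity(
            models[product].reaction_ids, control_model.reaction_ids,
            model_id=product,
        )
        content_rows.append(
            {"product": product, "jaccard": score.jaccard,
             "dissimilarity": score.dissimilarity}
        )
    content_scores = pd.DataFrame(
        content_rows, columns=["product", "jaccard", "dissimilarity"]
    ).set_index("product").sort_index()
    step2 = set(
        scoring.rank_products(
            [(p, row["dissimilarity"]) for p, row in content_scores.iterrows()],
            "descending_dissimilarity",
            config.top_k_content,
        )
    )

    # step 3: flux-range similarity to reference cancer-drug models
    control_fva = lp_engine.flux_variability(control_model, config.fraction_of_optimum)
    drug_fvas: dict[str, lp_engine.FluxRangeTable] = {}
    drug_score_rows = []
    for drug in cancer_drugs:
        genes = model_targets.genes_for(drug) & control_model.genes
        ko_model, _ = lp_engine.delete_genes(control_model, genes)
        fva = lp_engine.flux_variability(ko_model, config.fraction_of_optimum)
        drug_fvas[drug] = fva
        score = scoring.flux_dissimilarity(fva, control_fva, config.epsilon, drug)
        drug_score_rows.append(
            {"drug": drug, "si": score.si, "dissimilarity": score.dissimilarity}
        )
    cancer_drug_scores = pd.DataFrame(
        drug_score_rows, columns=["drug", "si", "dissimilarity"]
    ).set_index("drug").sort_index()
    reference_drugs = pick_reference_drugs(
        dict(cancer_drug_scores["dissimilarity"]),
        config.reference_drug_dissimilarity_floor,
    )

    product_fvas = {
        p: lp_engine.flux_variability(models[p], config.fraction_of_optimum)
        for p in products
        if p in models
    }
    flux_rows = []
    step3: set[str] = set()
    for drug in reference_drugs:
        sims = []
        for product, fva in product_fvas.items():
            score = scoring.flux_dissimilarity(
                fva, drug_fvas[drug], config.epsilon, product
            )
            sims.append((product, score.si))
            flux_rows.append(
                {"reference_drug": drug, "product": product, "si": score.si}
            )
        step3 |= set(
            scoring.rank_products(sims, "descending_similarity", config.top_k_flux)
        )
    flux_scores = pd.DataFrame(
        flux_rows, columns=["reference_drug", "product", "si"]
    ).set_index(["reference_drug", "product"]).sort_index()

    # step 4: pathway alteration in the pathway of interest
    index = pathway_analysis.build_pathway_index(model)
    report = pathway_analysis.alteration_report(
        {p: models[p] for p in products if p in models}, control_model, index
    )
    pathway_report = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "treatment": r.treatment,
                "presence_rate_treatment": r.presence_rate_treatment,
                "presence_rate_control": r.presence_rate_control,
                "difference": r.difference,
                "pathway_size": r.pathway_size,
                "iqr_across_products": r.iqr_across_products,
                "display": r.display,
            }
            for r in report
        ]
    )
    step4: set[str] = set()
    if config.pathway_of_interest is not None:
        poi = config.pathway_of_interest
        poi_rxns = index.reactions_by_pathway.get(poi, frozenset())
        diffs = {
            r.treatment: r.difference for r in report if r.pathway == poi
        }
        for product in products:
            genes = model_targets.genes_for(product) if product in model_targets.targets else frozenset()
            has_target = any(
                index.reactions_by_gene.get(g, frozenset()) & poi_rxns
                for g in genes
            )
            if has_target and abs(diffs.get(product, 0.0)) > config.step4_min_difference:
                step4.add(product)

    flags = StepFlags(
        frozenset(step1), frozenset(step2), frozenset(step3), frozenset(step4)
    )
    candidates = aggregate(flags, config)
    return PipelineResult(
        candidates=candidates,
        deletion_results=deletion_results,
        content_scores=content_scores,
        cancer_drug_scores=cancer_drug_scores,
        reference_drugs=reference_drugs,
        flux_scores=flux_scores,
        pathway_report=pathway_report,
        context_models=models,
    )
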