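"""Flux balance analysis, flux variability analysis and gene knockouts.

All linear programs share the steady-state constraint S·v = 0 with box
bounds per reaction and are solved with the HiGHS solver behind
:func:`scipy.optimize.linprog`.  Knockouts follow GPR semantics: a reaction
is disabled when its boolean gene rule evaluates false with the knocked
genes set to false, mirroring the classical COBRA gene-deletion behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model_core import GprRule, MetabolicModel

__all__ = [
    "FluxSolution",
    "FluxRangeTable",
    "DeletionResult",
    "InfeasibleModelError",
    "NonGrowingModelError",
    "optimize",
    "flux_variability",
    "evaluate_gpr",
    "delete_genes",
    "growth_ratio",
    "single_gene_deletion",
    "combination_deletion",
]

#: solver feasibility/optimality tolerance
LP_TOLERANCE = 1e-9
#: grRatio values below this are reported as exactly 0 (growth arrest)
ZERO_GROWTH_TOLERANCE = 1e-6
#: default synergy margin for combination knockouts
SYNERGY_DELTA = 0.01


class InfeasibleModelError(RuntimeError):
    """The model admits no steady-state flux distribution within bounds."""


class NonGrowingModelError(RuntimeError):
    """The wild-type model has zero objective flux; growth ratios undefined."""


@dataclass(frozen=True)
class FluxSolution:
    objective_value: float
    flux_vector: Mapping[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRangeTable:
    """Per-reaction feasible flux ranges (vmin, vmax) from FVA."""

    ranges: Mapping[str, tuple[float, float]]
    fraction_of_optimum: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", dict(self.ranges))

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        return self.ranges[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.ranges

    def __len__(self) -> int:
        return len(self.ranges)

    @property
    def reaction_ids(self) -> set[str]:
        return set(self.ranges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, lo, hi) for r, (lo, hi) in self.ranges.items()],
            columns=["reaction_id", "vmin", "vmax"],
        ).set_index("reaction_id")


@dataclass(frozen=True)
class DeletionResult:
    label: str
    wild_type_objective: float
    knockout_objective: float
    grRatio: float
    disabled_reactions: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Core LP machinery
# ---------------------------------------------------------------------------

class _LpSystem:
    """Cached S·v = 0 system for repeated solves over one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = model.reaction_ids
        self.n = len(self.rxn_ids)
        met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoichiometry.items():
                if coef != 0:
                    rows.append(met_index[met])
                    cols.append(j)
                    vals.append(coef)
        self.S = csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), self.n)
        )
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])
        self.obj_col = self.rxn_ids.index(model.objective_reaction_id)

    def solve(
        self,
        c: np.ndarray,
        maximize: bool = True,
        extra_A_ub=None,
        extra_b_ub=None,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
    ):
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        res = linprog(
            c=-c if maximize else c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={
                "presolve": True,
                "primal_feasibility_tolerance": LP_TOLERANCE,
                "dual_feasibility_tolerance": LP_TOLERANCE,
            },
        )
        return res


def _status_name(scipy_status: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(scipy_status, "infeasible")


def optimize(model: MetabolicModel) -> FluxSolution:
    """Maximise flux through the objective reaction (FBA).

    Unboundedness is reported via ``status``, never raised.
    """
    system = _LpSystem(model)
    c = np.zeros(system.n)
    c[system.obj_col] = 1.0
    res = system.solve(c, maximize=True)
    status = _status_name(res.status)
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    fluxes = dict(zip(system.rxn_ids, res.x))
    return FluxSolution(float(res.x[system.obj_col]), fluxes, "optimal")


def flux_variability(
    model: MetabolicModel, fraction_of_optimum: float = 1.0
) -> FluxRangeTable:
    """Min/max feasible flux per reaction at ``objective >= fraction × optimum``.

    Solves two LPs per reaction.  Raises :class:`InfeasibleModelError` when
    the model itself is infeasible.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    system = _LpSystem(model)
    c_obj = np.zeros(system.n)
    c_obj[system.obj_col] = 1.0
    res = system.solve(c_obj, maximize=True)
    if res.status != 0:
        raise InfeasibleModelError(
            f"model {model.model_id!r} is {_status_name(res.status)}; FVA undefined"
        )
    optimum = float(res.x[system.obj_col])

    # objective >= fraction * optimum, expressed as -v_obj <= -fraction*optimum
    A_ub = np.zeros((1, system.n))
    A_ub[0, system.obj_col] = -1.0
    b_ub = np.array([-fraction_of_optimum * optimum])

    ranges: dict[str, tuple[float, float]] = {}
    c = np.zeros(system.n)
    for j, rid in enumerate(system.rxn_ids):
        c[j] = 1.0
        lo = system.solve(c, maximize=False, extra_A_ub=A_ub, extra_b_ub=b_ub)
        hi = system.solve(c, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
        c[j] = 0.0
        vmin = float(lo.x[j]) if lo.status == 0 else float("nan")
        vmax = float(hi.x[j]) if hi.status == 0 else float("nan")
        if vmin > vmax:  # numerical jitter on fixed reactions
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRangeTable(ranges, fraction_of_optimum)


# ---------------------------------------------------------------------------
# GPR evaluation and knockouts
# ---------------------------------------------------------------------------

def evaluate_gpr(rule: GprRule | None, knocked: Iterable[str]) -> bool:
    """Truth value of a GPR with the *knocked* genes false.

    An empty rule (no gene control) is always true.
    """
    if rule is None:
        return True
    return rule.evaluate(knocked)


def delete_genes(
    model: MetabolicModel, genes: Iterable[str]
) -> tuple[MetabolicModel, frozenset[str]]:
    """Knock out *genes*: every reaction whose GPR evaluates false gets
    bounds (0, 0).  Genes absent from the model are ignored.
    """
    knocked = set(genes)
    disabled = [
        r.id
        for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(knocked)
    ]
    if not disabled:
        return model, frozenset()
    new_bounds = {rid: (0.0, 0.0) for rid in disabled}
    return model.with_bounds(new_bounds), frozenset(disabled)


def growth_ratio(
    model: MetabolicModel,
    genes: Iterable[str],
    label: str | None = None,
    wild_type_objective: float | None = None,
) -> DeletionResult:
    """Knockout objective over wild-type objective (the classical grRatio).

    Ratios below :data:`ZERO_GROWTH_TOLERANCE` are reported as exactly 0;
    a non-growing wild type raises :class:`NonGrowingModelError`.
    """
    genes = set(genes)
    if wild_type_objective is None:
        wt = optimize(model)
        if not wt.optimal:
            raise InfeasibleModelError(f"model {model.model_id!r}: {wt.status}")
        wild_type_objective = wt.objective_value
    if wild_type_objective <= ZERO_GROWTH_TOLERANCE:
        raise NonGrowingModelError(
            f"model {model.model_id!r} has wild-type objective "
            f"{wild_type_objective}; growth ratios undefined"
        )
    ko_model, disabled = delete_genes(model, genes)
    if disabled:
        ko = optimize(ko_model)
        ko_objective = ko.objective_value if ko.optimal else 0.0
    else:
        ko_objective = wild_type_objective
    ratio = ko_objective / wild_type_objective
    if ratio < ZERO_GROWTH_TOLERANCE:
        ratio = 0.0
    return DeletionResult(
        label=label if label is not None else ",".join(sorted(genes)),
        wild_type_objective=wild_type_objective,
        knockout_objective=ko_objective,
        grRatio=ratio,
        disabled_reactions=disabled,
    )


def single_gene_deletion(model: MetabolicModel) -> list[DeletionResult]:
    """Growth ratio for each model gene knocked out individually, in sorted
    gene order."""
    wt = optimize(model)
    if not wt.optimal:
        raise InfeasibleModelError(f"model {model.model_id!r}: {wt.status}")
    return [
        growth_ratio(model, {gene}, label=gene, wild_type_objective=wt.objective_value)
        for gene in sorted(model.genes)
    ]


def combination_deletion(
    model: MetabolicModel,
    target_sets: Sequence[tuple[str, Iterable[str], str, Iterable[str]]],
    synergy_delta: float = SYNERGY_DELTA,
) -> pd.DataFrame:
    """Pairwise combination knockouts.

    For each (labelA, genesA, labelB, genesB), computes grRatio of A alone,
    B alone and the union, and flags synergy when the combined ratio drops
    more than *synergy_delta* below the better single knockout.
    """
    wt = optimize(model)
    if not wt.optimal:
        raise InfeasibleModelError(f"model {model.model_id!r}: {wt.status}")
    wt_obj = wt.objective_value
    cache: dict[frozenset[str], float] = {}

    def ratio(genes: frozenset[str]) -> float:
        if genes not in cache:
            cache[genes] = growth_ratio(
                model, genes, wild_type_objective=wt_obj
            ).grRatio
        return cache[genes]

    rows = []
    for label_a, genes_a, label_b, genes_b in target_sets:
        ga, gb = frozenset(genes_a), frozenset(genes_b)
        ra, rb, rab = ratio(ga), ratio(gb), ratio(ga | gb)
        rows.append(
            {
                "label_a": label_a,
                "label_b": label_b,
                "grRatio_a": ra,
                "grRatio_b": rb,
                "grRatio_ab": rab,
                "synergy": rab < min(ra, rb) - synergy_delta,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label_a", "label_b", "grRatio_a", "grRatio_b", "grRatio_ab", "synergy"],
    )
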