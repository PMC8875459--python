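"""Context-specific model extraction.

A generic reconstruction is specialised to a condition in three moves:

1. constrain uptake to the growth medium;
2. drop reactions that cannot carry flux at steady state (consistency check
   via the classical LP scheme that maximises the number of reactions
   simultaneously carrying at least ``flux_epsilon``);
3. expand a *core* of expression-supported reactions (plus the biomass
   reaction, whose inclusion is always forced) into a flux-consistent
   sub-model by alternating two LPs — one pushing core reactions above
   ``flux_epsilon``, one minimising the L1 weight of non-core flux.

Expression enters through two thresholds: genes scoring at or above the
high threshold are called active (core), at or below the low threshold
inactive, anything between unknown.  Core reactions are those whose GPR is
satisfied by active genes alone; reactions that would only be satisfied if
unknown genes were active are neither core nor penalised during expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, hstack, identity

from .model_core import MediumComposition, MetabolicModel, apply_medium

__all__ = [
    "ActivityCalls",
    "CoreSet",
    "InfeasibleCoreError",
    "fastcc",
    "call_activity",
    "genes_to_core_reactions",
    "extract_context_model",
    "build_context_models",
]

#: minimum flux magnitude a reaction must support to count as consistent
FLUX_EPSILON = 1e-4
# support membership threshold, slightly inside epsilon for solver noise
_SUPPORT_SLACK = 1.0 - 1e-6


class InfeasibleCoreError(RuntimeError):
    """A requested core reaction cannot carry flux in the consistent model."""

    def __init__(self, reaction_ids: Iterable[str]):
        self.reaction_ids = sorted(reaction_ids)
        super().__init__(
            "core reactions cannot carry flux under the current constraints: "
            + ", ".join(self.reaction_ids)
        )


@dataclass(frozen=True)
class ActivityCalls:
    condition_id: str
    core_genes: frozenset[str]
    inactive_genes: frozenset[str]
    unknown_genes: frozenset[str]

    def __post_init__(self) -> None:
        overlap = (
            (self.core_genes & self.inactive_genes)
            | (self.core_genes & self.unknown_genes)
            | (self.inactive_genes & self.unknown_genes)
        )
        if overlap:
            raise ValueError(f"activity calls overlap for genes {sorted(overlap)}")


@dataclass(frozen=True)
class CoreSet:
    """Reactions that must appear in the extracted model."""

    reaction_ids: frozenset[str]
    #: non-core reactions exempt from the L1 penalty during expansion
    penalty_free: frozenset[str] = frozenset()

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.reaction_ids

    def __len__(self) -> int:
        return len(self.reaction_ids)


# ---------------------------------------------------------------------------
# Shared LP pieces
# ---------------------------------------------------------------------------

class _Network:
    """Mutable view of S/bounds supporting direction flips of reversible
    reactions (used only inside the consistency LPs; the caller's model is
    never modified)."""

    def __init__(self, model: MetabolicModel):
        self.rxn_ids = model.reaction_ids
        self.n = len(self.rxn_ids)
        self.index = {r: i for i, r in enumerate(self.rxn_ids)}
        met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoichiometry.items():
                if coef != 0:
                    rows.append(met_index[met])
                    cols.append(j)
                    vals.append(coef)
        self.S = csr_matrix((vals, (rows, cols)), shape=(len(met_index), self.n))
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.irreversible = frozenset(
            j for j in range(self.n) if self.lb[j] >= 0
        )
        self.sign = np.ones(self.n)

    def flip(self, cols: Iterable[int]) -> None:
        cols = list(cols)
        if not cols:
            return
        diag = np.ones(self.n)
        diag[cols] = -1.0
        self.S = self.S.multiply(diag[np.newaxis, :]).tocsr()
        lb, ub = self.lb.copy(), self.ub.copy()
        self.lb[cols] = -ub[cols]
        self.ub[cols] = -lb[cols]
        self.sign[cols] *= -1.0


def _lp7(net: _Network, J: Sequence[int], eps: float) -> np.ndarray | None:
    """Maximise the number of reactions in J carrying flux >= eps.

    Variables (v, z): maximise sum z subject to z_j <= v_j, 0 <= z <= eps.
    Returns the flux vector v or None when infeasible.
    """
    J = list(J)
    k = len(J)
    n = net.n
    sel = csr_matrix(
        (np.ones(k), (range(k), J)), shape=(k, n)
    )
    A_eq = hstack([net.S, csr_matrix((net.S.shape[0], k))]).tocsr()
    A_ub = hstack([-sel, identity(k, format="csr")]).tocsr()
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    bounds = np.column_stack(
        [
            np.concatenate([net.lb, np.zeros(k)]),
            np.concatenate([net.ub, np.full(k, eps)]),
        ]
    )
    res = linprog(
        c=c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(k),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def _lp9(
    net: _Network,
    K: Sequence[int],
    P: Sequence[int],
    weights: np.ndarray,
    eps: float,
) -> np.ndarray | None:
    """Minimise the weighted L1 norm of penalised fluxes while forcing each
    reaction in K to carry at least eps."""
    P = list(P)
    m = len(P)
    n = net.n
    lb = net.lb.copy()
    lb[list(K)] = np.maximum(lb[list(K)], eps)
    if m == 0:
        res = linprog(
            c=np.zeros(n),
            A_eq=net.S,
            b_eq=np.zeros(net.S.shape[0]),
            bounds=np.column_stack([lb, net.ub]),
            method="highs",
        )
        return res.x if res.status == 0 else None
    sel = csr_matrix((np.ones(m), (range(m), P)), shape=(m, n))
    # z_p >= |v_p|  ->  v_p - z_p <= 0 and -v_p - z_p <= 0
    A_ub = hstack(
        [
            csr_matrix(np.vstack([sel.toarray(), -sel.toarray()])),
            csr_matrix(np.vstack([-np.eye(m), -np.eye(m)])),
        ]
    ).tocsr()
    A_eq = hstack([net.S, csr_matrix((net.S.shape[0], m))]).tocsr()
    big = float(np.max(np.abs(np.concatenate([net.lb, net.ub])))) or 1.0
    bounds = np.column_stack(
        [
            np.concatenate([lb, np.zeros(m)]),
            np.concatenate([net.ub, np.full(m, big)]),
        ]
    )
    c = np.concatenate([np.zeros(n), weights[P]])
    res = linprog(
        c=c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=np.zeros(2 * m),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def _support(v: np.ndarray, eps: float) -> set[int]:
    return set(np.flatnonzero(np.abs(v) >= eps * _SUPPORT_SLACK))


# ---------------------------------------------------------------------------
# Consistency check
# ---------------------------------------------------------------------------

def fastcc(model: MetabolicModel, flux_epsilon: float = FLUX_EPSILON) -> set[str]:
    """Reaction ids able to carry |flux| >= flux_epsilon at steady state.

    Follows the block LP scheme: one LP certifies many irreversible
    reactions at once, reversible candidates are retried with flipped
    direction, and stubborn reactions are tested one by one before being
    declared blocked.
    """
    net = _Network(model)
    all_idx = set(range(net.n))
    consistent: set[int] = set()

    J = sorted(all_idx & net.irreversible)
    if J:
        v = _lp7(net, J, flux_epsilon)
        if v is not None:
            consistent |= _support(v, flux_epsilon)
    blocked_irrev = set(J) - consistent
    J = sorted(all_idx - consistent - blocked_irrev)

    flipped = False
    singleton = False
    while J:
        Ji = [J[0]] if singleton else J
        v = _lp7(net, Ji, flux_epsilon)
        if v is not None:
            consistent |= _support(v, flux_epsilon)
        if set(J) & consistent:
            J = sorted(set(J) - consistent)
            flipped = False
        else:
            Ji_rev = [j for j in Ji if j not in net.irreversible]
            if flipped or not Ji_rev:
                flipped = False
                if singleton:
                    J = J[1:]  # blocked
                else:
                    singleton = True
            else:
                net.flip(Ji_rev)
                flipped = True
    return {net.rxn_ids[i] for i in consistent}


# ---------------------------------------------------------------------------
# Expression discretisation and GPR mapping
# ---------------------------------------------------------------------------

def call_activity(
    expression: pd.DataFrame,
    condition_id: str,
    high_threshold: float,
    low_threshold: float,
) -> ActivityCalls:
    """Threshold a condition's expression column into active / inactive /
    unknown gene sets."""
    if high_threshold < low_threshold:
        raise ValueError("high_threshold must be >= low_threshold")
    if condition_id not in expression.columns:
        raise KeyError(f"condition {condition_id!r} not in expression table")
    scores = expression[condition_id]
    if scores.isna().all():
        raise ValueError(f"condition {condition_id!r} has no scores (all NaN)")
    scores = scores.dropna()
    core = frozenset(scores.index[scores >= high_threshold])
    inactive = frozenset(scores.index[scores <= low_threshold]) - core
    unknown = frozenset(scores.index) - core - inactive
    return ActivityCalls(condition_id, core, inactive, unknown)


def genes_to_core_reactions(model: MetabolicModel, calls: ActivityCalls) -> CoreSet:
    """Map gene activity onto reactions through the GPR rules.

    A reaction is core when its rule is satisfied by active genes alone
    (inactive and unknown both false).  A reaction that fails that test but
    would be satisfied if unknown genes were active is placed in
    ``penalty_free``: not forced in, not penalised out.  Reactions without
    gene control are likewise left unpenalised.
    """
    core: set[str] = set()
    penalty_free: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr is None:
            penalty_free.add(rxn.id)
            continue
        strict = rxn.gpr.evaluate_assignment(lambda g: g in calls.core_genes)
        if strict:
            core.add(rxn.id)
            continue
        optimistic = rxn.gpr.evaluate_assignment(
            lambda g: g in calls.core_genes or g in calls.unknown_genes
        )
        if optimistic:
            penalty_free.add(rxn.id)
    return CoreSet(frozenset(core), frozenset(penalty_free))


# ---------------------------------------------------------------------------
# Core expansion
# ---------------------------------------------------------------------------

def _find_sparse_mode(
    net: _Network,
    J: Sequence[int],
    P: Sequence[int],
    weights: np.ndarray,
    singleton: bool,
    eps: float,
) -> set[int]:
    if not J:
        return set()
    Ji = [J[0]] if singleton else list(J)
    v = _lp7(net, Ji, eps)
    if v is None:
        return set()
    K = [j for j in Ji if v[j] >= eps * _SUPPORT_SLACK]
    if not K:
        return set()
    v = _lp9(net, K, P, weights, eps)
    if v is None:
        return set()
    return _support(v, eps)


def extract_context_model(
    model: MetabolicModel,
    core: CoreSet | Iterable[str],
    medium: MediumComposition | None = None,
    flux_epsilon: float = FLUX_EPSILON,
    model_id: str | None = None,
) -> MetabolicModel:
    """Expand *core* into a flux-consistent sub-model of *model*.

    The medium (if given) is applied before extraction.  The input model is
    expected to be flux-consistent already (run :func:`fastcc` first); the
    biomass objective is always added to the core.  Raises
    :class:`InfeasibleCoreError` when a core reaction cannot carry flux
    under the applied constraints.
    """
    if not isinstance(core, CoreSet):
        core = CoreSet(frozenset(core))
    missing = core.reaction_ids - set(model.reaction_ids)
    if missing:
        raise ValueError(f"core reactions not in model: {sorted(missing)}")

    working = apply_medium(model, medium) if medium is not None else model
    net = _Network(working)
    core_ids = set(core.reaction_ids) | {model.objective_reaction_id}
    core_idx = sorted(net.index[r] for r in core_ids)
    penalty_free_idx = {net.index[r] for r in core.penalty_free if r in net.index}
    weights = np.ones(net.n)
    weights[sorted(penalty_free_idx)] = 0.0

    all_idx = set(range(net.n))
    non_core = sorted(all_idx - set(core_idx))

    consistent: set[int] = set()
    J = [j for j in core_idx if j in net.irreversible]
    P = list(non_core)
    supp = _find_sparse_mode(net, J, P, weights, singleton=False, eps=flux_epsilon)
    infeasible = set(J) - supp
    if infeasible:
        raise InfeasibleCoreError(net.rxn_ids[j] for j in infeasible)
    consistent |= supp
    J = sorted(set(core_idx) - consistent)

    flipped = False
    singleton = False
    while J:
        P = sorted(set(non_core) - consistent)
        supp = _find_sparse_mode(net, J, P, weights, singleton, flux_epsilon)
        consistent |= supp
        if set(J) & consistent:
            J = sorted(set(J) - consistent)
            flipped = False
            singleton = False
        else:
            Ji = [J[0]] if singleton else J
            Ji_rev = [j for j in Ji if j not in net.irreversible]
            if flipped or not Ji_rev:
                if singleton:
                    raise InfeasibleCoreError({net.rxn_ids[J[0]]})
                flipped = False
                singleton = True
            else:
                net.flip(Ji_rev)
                flipped = True

    keep = {net.rxn_ids[j] for j in consistent} | {model.objective_reaction_id}
    return working.subset(sorted(keep, key=net.index.__getitem__),
                          model_id=model_id)


# ---------------------------------------------------------------------------
# Per-condition pipeline
# ---------------------------------------------------------------------------

def build_context_models(
    model: MetabolicModel,
    expression: pd.DataFrame,
    medium: MediumComposition | None,
    high_threshold: float,
    low_threshold: float,
    flux_epsilon: float = FLUX_EPSILON,
    conditions: Sequence[str] | None = None,
) -> dict[str, MetabolicModel]:
    """Build one context-specific model per expression condition.

    The medium is applied once, the constrained model reduced to its
    flux-consistent part, and each condition's active genes mapped to core
    reactions (biomass always forced) before expansion.
    """
    constrained = apply_medium(model, medium) if medium is not None else model
    consistent_ids = fastcc(constrained, flux_epsilon)
    if model.objective_reaction_id not in consistent_ids:
        raise InfeasibleCoreError({model.objective_reaction_id})
    consistent = constrained.subset(
        [r for r in constrained.reaction_ids if r in consistent_ids]
    )
    out: dict[str, MetabolicModel] = {}
    for condition in conditions if conditions is not None else expression.columns:
        calls = call_activity(expression, condition, high_threshold, low_threshold)
        mapped = genes_to_core_reactions(consistent, calls)
        core = CoreSet(
            frozenset(mapped.reaction_ids) | {model.objective_reaction_id},
            mapped.penalty_free,
        )
        out[condition] = extract_context_model(
            consistent, core, medium=None, flux_epsilon=flux_epsilon,
            model_id=condition,
        )
    return out
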