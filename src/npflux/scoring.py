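"""Model comparison scores.

Two complementary views of how far a treated model has moved from control:

* **content**: the Jaccard dissimilarity D = 1 − |A∩B|/|A∪B| of the two
  models' reaction sets;
* **flux**: one minus the mean per-reaction overlap of FVA flux ranges,

      si = mean( max(0, min(v1max, v2max) − max(v1min, v2min) + ε)
                 / (max(v1max, v2max) − min(v1min, v2min) + ε) ),

  averaged over the union of reactions in the two tables, a reaction absent
  from one table contributing the degenerate range [0, 0].  ε (default
  1e-4) regularises zero-width ranges: two identical ranges — including two
  absent reactions — always score 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .lp_engine import FluxRangeTable

__all__ = [
    "ContentScore",
    "FluxSimilarityScore",
    "EPSILON",
    "jaccard_dissimilarity",
    "range_overlap",
    "flux_dissimilarity",
    "rank_products",
]

#: default flux-range regularisation constant
EPSILON = 1e-4


@dataclass(frozen=True)
class ContentScore:
    model_id: str
    jaccard: float
    dissimilarity: float


@dataclass(frozen=True)
class FluxSimilarityScore:
    model_id: str
    si: float
    dissimilarity: float
    epsilon: float


def jaccard_dissimilarity(
    reactions_a: Iterable[str],
    reactions_b: Iterable[str],
    model_id: str = "",
) -> ContentScore:
    """Jaccard dissimilarity D = 1 − |A∩B|/|A∪B| of two reaction sets."""
    a, b = set(reactions_a), set(reactions_b)
    union = a | b
    if not union:
        raise ValueError("both reaction sets are empty; Jaccard undefined")
    j = len(a & b) / len(union)
    return ContentScore(model_id=model_id, jaccard=j, dissimilarity=1.0 - j)


def range_overlap(
    r1: tuple[float, float],
    r2: tuple[float, float],
    epsilon: float = EPSILON,
) -> float:
    """Regularised overlap of two flux ranges, in [0, 1]."""
    v1min, v1max = r1
    v2min, v2max = r2
    if v1min > v1max or v2min > v2max:
        raise ValueError("flux range with vmin > vmax")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    numerator = max(0.0, min(v1max, v2max) - max(v1min, v2min) + epsilon)
    denominator = max(v1max, v2max) - min(v1min, v2min) + epsilon
    return min(numerator / denominator, 1.0)


def flux_dissimilarity(
    fva_a: FluxRangeTable,
    fva_b: FluxRangeTable,
    epsilon: float = EPSILON,
    model_id: str = "",
) -> FluxSimilarityScore:
    """Mean flux-range overlap over the union of reactions; absent reactions
    contribute the range [0, 0]."""
    union = sorted(fva_a.reaction_ids | fva_b.reaction_ids)
    if not union:
        raise ValueError("both FVA tables are empty")
    zero = (0.0, 0.0)
    total = 0.0
    for rid in union:
        ra = fva_a[rid] if rid in fva_a else zero
        rb = fva_b[rid] if rid in fva_b else zero
        total += range_overlap(ra, rb, epsilon)
    si = total / len(union)
    return FluxSimilarityScore(
        model_id=model_id, si=si, dissimilarity=1.0 - si, epsilon=epsilon
    )


def rank_products(
    scores: Sequence[tuple[str, float]],
    direction: str = "descending_dissimilarity",
    k: int = 5,
) -> list[str]:
    """Top-k labels by score, descending; ties broken alphabetically.

    ``direction`` names what the score means (dissimilarity or similarity);
    both rank descending on the value supplied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("descending_dissimilarity", "descending_similarity"):
        raise ValueError(f"unknown ranking direction {direction!r}")
    ordered = sorted(scores, key=lambda pair: (-pair[1], pair[0]))
    return [label for label, _ in ordered[:k]]
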