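"""Weight-vector redistribution: the engine's survivor-selection operator.

The merged population (parents + offspring) is split into n sub-populations,
one per weight vector w_i = (w_i1, 1 - w_i1) with evenly spaced w_i1.  Each
individual joins the sub-population whose weight is closest to its
*relative degree*

    R = | f1_bar / (f1_bar + f2_bar) - w_i1 |

computed on normalized objectives, then members are ranked by the
weighted-sum fitness G = w1·f1_bar + w2·f2_bar.  Over-full sub-populations
(size > m/n) repeatedly lose their worst member until exactly m individuals
survive; under-full sets are never touched, which preserves diversity in
sparsely populated search directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .scoring import ObjectiveVector, ReferencePoints, normalize
from .trees import PhyloTree

__all__ = [
    "WeightVector",
    "Individual",
    "SubPopulation",
    "make_weights",
    "relative_degree",
    "weighted_sum",
    "assign_weight",
    "redistribute",
]


@dataclass(frozen=True)
class WeightVector:
    index: int
    w1: float
    w2: float


@dataclass
class Individual:
    """A candidate tree with its scores and selection bookkeeping."""

    tree: PhyloTree
    objectives: Optional[ObjectiveVector] = None
    normalized: Optional[np.ndarray] = None
    subpop: Optional[int] = None
    fitness: Optional[float] = None

    @property
    def evaluated(self) -> bool:
        return self.objectives is not None


@dataclass
class SubPopulation:
    """A weight vector and its members, kept sorted by weighted-sum fitness."""

    weight: WeightVector
    members: List[Individual] = field(default_factory=list)


def make_weights(n: int) -> List[WeightVector]:
    """n weight vectors with w1 evenly spaced on [0, 1] (ascending)."""
    if n < 2:
        raise ValueError(f"need >= 2 weight vectors, got {n}")
    return [WeightVector(i, i / (n - 1), 1.0 - i / (n - 1)) for i in range(n)]


def relative_degree(fbar: Sequence[float], w1: float) -> float:
    """Distance between the solution's objective balance and a weight.

    The balance f1_bar/(f1_bar+f2_bar) is defined as 0.5 when both
    normalized objectives are zero (a solution at the reference point is
    equally good in both directions).
    """
    s = fbar[0] + fbar[1]
    ratio = 0.5 if s == 0 else fbar[0] / s
    return abs(ratio - w1)


def weighted_sum(fbar: Sequence[float], w: WeightVector) -> float:
    """Aggregated fitness G = w1·f1_bar + w2·f2_bar (lower is better)."""
    return w.w1 * fbar[0] + w.w2 * fbar[1]


def assign_weight(fbar: Sequence[float], weights: Sequence[WeightVector]) -> WeightVector:
    """The weight minimizing the relative degree; ties go to the lowest index."""
    best = weights[0]
    best_r = relative_degree(fbar, best.w1)
    for w in weights[1:]:
        r = relative_degree(fbar, w.w1)
        if r < best_r:
            best, best_r = w, r
    return best


def redistribute(
    individuals: Sequence[Individual],
    weights: Sequence[WeightVector],
    ref: ReferencePoints,
    m: int,
) -> List[SubPopulation]:
    """Assign, rank, and trim the merged population down to m survivors.

    Every individual must be evaluated.  Each is normalized against `ref`,
    assigned to its closest weight, and ranked within its sub-population by
    weighted-sum fitness (stable sort; input order breaks exact ties).
    While more than m individuals remain, the globally worst member among
    sub-populations exceeding the capacity m/n is removed.  Requires n | m.
    """
    n = len(weights)
    if m % n != 0:
        raise ValueError(f"population size {m} must be divisible by the {n} weight vectors")
    if len(individuals) < m:
        raise ValueError(f"cannot select {m} survivors from {len(individuals)} individuals")
    subpops = [SubPopulation(w) for w in weights]
    for ind in individuals:
        if not ind.evaluated:
            raise ValueError("redistribute requires evaluated individuals")
        ind.normalized = normalize(ind.objectives, ref)  # type: ignore[arg-type]
        w = assign_weight(ind.normalized, weights)
        ind.subpop = w.index
        ind.fitness = weighted_sum(ind.normalized, w)
        subpops[w.index].members.append(ind)
    for sp in subpops:
        sp.members.sort(key=lambda ind: ind.fitness)  # type: ignore[arg-type, return-value]

    capacity = m // n
    total = len(individuals)
    while total > m:
        # worst tail member among over-capacity sets; ties -> lowest set index
        victim_sp = None
        for sp in subpops:
            if len(sp.members) > capacity:
                if victim_sp is None or sp.members[-1].fitness > victim_sp.members[-1].fitness:  # type: ignore[operator]
                    victim_sp = sp
        assert victim_sp is not None  # sum > m = n*capacity forces an over-full set
        victim_sp.members.pop()
        total -= 1
    return subpops
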