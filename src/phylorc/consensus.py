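"""Majority-rule(+) consensus *branches* from neighbouring sub-populations.

For each search direction (sub-population) the engine gathers the few best
trees from that sub-population and its two neighbours on the weight simplex,
and extracts the splits those elites agree on.  The *core* is every
bipartition occurring in strictly more than half of the elite trees; the
"(+)" extension greedily adds the remaining observed bipartitions in
decreasing frequency order whenever they are compatible with everything
accepted so far.  The result is a pairwise-compatible split set -- always
realizable on a single tree -- that the genetic operators treat as
protected topology.

Deliberately, no consensus *tree* is ever materialized: the engine consumes
only the branch set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Tuple

from .redistribution import SubPopulation
from .trees import Bipartition, PhyloTree, bipartitions

__all__ = [
    "ConsensusBranchSet",
    "EMPTY_CONSENSUS",
    "neighbor_sets",
    "is_compatible",
    "consensus_branches",
    "collect_elites",
]


@dataclass(frozen=True)
class ConsensusBranchSet:
    """Protected bipartitions for one search direction."""

    subpop: int
    branches: FrozenSet[Bipartition]
    elite_count: int

    def __bool__(self) -> bool:
        return bool(self.branches)


#: Protection disabled (ablation mode, or too few sub-populations).
EMPTY_CONSENSUS = ConsensusBranchSet(subpop=-1, branches=frozenset(), elite_count=0)


def neighbor_sets(i: int, n: int) -> Tuple[int, int, int]:
    """The sub-population i together with its two nearest weight neighbours.

    Interior indices take {i-1, i, i+1}; the boundary directions take the
    two closest interior indices instead, so three distinct sets always
    contribute.  Requires n >= 3.
    """
    if n < 3:
        raise ValueError(f"need >= 3 sub-populations for neighbour consensus, got {n}")
    if not 0 <= i < n:
        raise ValueError(f"sub-population index {i} out of range [0, {n})")
    if i == 0:
        return (0, 1, 2)
    if i == n - 1:
        return (n - 3, n - 2, n - 1)
    return (i - 1, i, i + 1)


def is_compatible(a: Bipartition, b: Bipartition, taxa: FrozenSet[str]) -> bool:
    """Whether two splits could coexist in one tree on `taxa`.

    With canonical sides A and B this is the classical condition that one of
    A∩B, A∖B, B∖A, or the complement of A∪B is empty.
    """
    if not (a <= taxa and b <= taxa):
        raise ValueError("bipartition taxa outside the reference taxon set")
    return not (a & b) or a <= b or b <= a or (a | b) == taxa


def consensus_branches(
    elite_trees: Sequence[PhyloTree],
    subpop: int = -1,
    plain_majority: bool = False,
) -> ConsensusBranchSet:
    """Majority-rule(+) consensus splits of k >= 2 trees on one taxon set.

    A split qualifies when it occurs in strictly more trees than the number
    of trees containing a split incompatible with it -- trees that neither
    contain the split nor conflict with it abstain.  This contains the
    plain majority core (occurrence in > k/2 trees), because a conflicting
    tree never contains the split itself, and any two qualifying splits are
    mutually compatible (two incompatible splits cannot both out-vote each
    other's opposition).  With `plain_majority` only the core is returned.
    """
    k = len(elite_trees)
    if k < 2:
        raise ValueError(f"consensus needs >= 2 trees, got {k}")
    taxa = elite_trees[0].taxa
    for t in elite_trees[1:]:
        if t.taxa != taxa:
            raise ValueError("consensus trees must share one taxon set")

    profiles = [bipartitions(t) for t in elite_trees]
    counts: Counter = Counter()
    for prof in profiles:
        counts.update(prof)

    if plain_majority:
        accepted = [b for b, c in counts.items() if c * 2 > k]
    else:
        accepted = []
        for b, c in counts.items():
            opposed = sum(
                1
                for prof in profiles
                if b not in prof
                and any(not is_compatible(b, other, taxa) for other in prof)
            )
            if c > opposed:
                accepted.append(b)
    return ConsensusBranchSet(subpop=subpop, branches=frozenset(accepted), elite_count=k)


def collect_elites(
    subpops: Sequence[SubPopulation], i: int, q: int
) -> List[PhyloTree]:
    """Top-q trees (by each set's own weighted-sum ranking) of the three
    neighbouring sub-populations; sets with fewer members contribute all."""
    if q < 1:
        raise ValueError(f"elites per set must be >= 1, got {q}")
    trees: List[PhyloTree] = []
    for j in neighbor_sets(i, len(subpops)):
        trees.extend(ind.tree for ind in subpops[j].members[:q])
    return trees
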