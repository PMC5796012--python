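"""Genetic operators: Prune-Delete-Graft crossover and NNI mutation,
both honouring consensus-branch protection.

PDG prunes a random subtree from one parent, deletes its taxa from a copy
of the other parent, and grafts the subtree onto a random edge of the
reduced tree.  NNI swaps one pair of subtrees across a random internal
edge.  When a set of protected bipartitions is supplied, PDG resamples
until the offspring retains every protected split the graft-recipient
parent contained (falling back to an unchanged copy of that parent), and
NNI simply never selects a protected edge -- so protected topology is
preserved unconditionally.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np

from .consensus import ConsensusBranchSet
from .redistribution import Individual
from .trees import (
    Bipartition,
    PhyloTree,
    bipartitions,
    canonical_bipartition,
    directed_leafsets,
)

__all__ = [
    "pdg_crossover",
    "nni_mutation",
    "binary_tournament",
    "make_offspring",
    "DEFAULT_MAX_RESAMPLES",
]

#: PDG resampling budget before falling back to an unchanged parent copy.
DEFAULT_MAX_RESAMPLES = 20

Protected = Union[ConsensusBranchSet, FrozenSet[Bipartition], frozenset, None]


def _protected_branches(protected: Protected) -> FrozenSet[Bipartition]:
    if protected is None:
        return frozenset()
    if isinstance(protected, ConsensusBranchSet):
        return protected.branches
    return frozenset(protected)


def _copy_subtree_into(
    src: PhyloTree, root: int, avoid: int, dst: PhyloTree
) -> int:
    """Replicate the subtree of `src` hanging below `root` (seen from
    `avoid`) inside `dst`; returns the new node corresponding to `root`."""
    mapping: Dict[int, int] = {root: dst.new_node(src.label(root))}
    stack: List[Tuple[int, int]] = [(root, avoid)]
    while stack:
        u, pu = stack.pop()
        for w in src.neighbors(u):
            if w == pu:
                continue
            mapping[w] = dst.new_node(src.label(w))
            dst.add_edge(mapping[u], mapping[w], src.branch_length(u, w))
            stack.append((w, u))
    return mapping[root]


def _pdg_once(p1: PhyloTree, p2: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    n = p1.n_leaves
    leafsets = directed_leafsets(p1)
    candidates = [
        (edge, side) for edge, side in leafsets.items() if 1 <= len(side) <= n - 3
    ]
    (parent, child), side = candidates[int(rng.integers(len(candidates)))]
    handle_length = p1.branch_length(parent, child)

    offspring = p2.copy()
    for lab in sorted(side):
        offspring.remove_leaf(lab)
    graft_edges = offspring.edges()
    u, v, length = graft_edges[int(rng.integers(len(graft_edges)))]
    sub_root = _copy_subtree_into(p1, child, parent, offspring)
    mid = offspring.new_node()
    offspring.remove_edge(u, v)
    offspring.add_edge(u, mid, length / 2.0)
    offspring.add_edge(mid, v, length / 2.0)
    offspring.add_edge(mid, sub_root, handle_length)
    return offspring


def pdg_crossover(
    p1: PhyloTree,
    p2: PhyloTree,
    rng: np.random.Generator,
    protected: Protected = None,
    max_resamples: int = DEFAULT_MAX_RESAMPLES,
) -> PhyloTree:
    """Prune a random subtree of `p1` and graft it into a reduced copy of `p2`.

    The pruned subtree has between 1 and n-3 leaves so the reduced recipient
    stays a proper tree; the graft edge's length is split in half and the
    pruned subtree keeps its handle length.  With protection, prune/graft
    choices are resampled until every protected bipartition present in `p2`
    survives in the offspring; after `max_resamples` failures an unchanged
    copy of `p2` is returned.
    """
    if p1.taxa != p2.taxa:
        raise ValueError("crossover parents must share one taxon set")
    if p1.n_leaves < 4:
        raise ValueError(f"crossover needs >= 4 taxa, got {p1.n_leaves}")
    must_keep = _protected_branches(protected) & bipartitions(p2)
    if not must_keep:
        return _pdg_once(p1, p2, rng)
    for _ in range(max_resamples):
        offspring = _pdg_once(p1, p2, rng)
        if must_keep <= bipartitions(offspring):
            return offspring
    return p2.copy()


def nni_mutation(
    tree: PhyloTree,
    rng: np.random.Generator,
    protected: Protected = None,
) -> PhyloTree:
    """Swap one subtree pair across a random unprotected internal edge.

    Each of the two alternative local topologies is produced with
    probability 1/2; branch lengths travel with their subtrees.  If every
    internal edge induces a protected bipartition, an unchanged copy is
    returned.
    """
    if tree.n_leaves < 4:
        raise ValueError(f"NNI needs >= 4 taxa, got {tree.n_leaves}")
    branches = _protected_branches(protected)
    taxa = tree.taxa
    candidates = []
    for (p, c), side in directed_leafsets(tree).items():
        if tree.is_leaf(p) or tree.is_leaf(c):
            continue
        if canonical_bipartition(side, taxa) in branches:
            continue
        candidates.append((p, c))
    if not candidates:
        return tree.copy()
    u, v = candidates[int(rng.integers(len(candidates)))]
    out = tree.copy()
    u_side = [w for w in out.neighbors(u) if w != v]
    v_side = [w for w in out.neighbors(v) if w != u]
    x = u_side[int(rng.integers(2))]
    y = v_side[0]
    len_ux = out.branch_length(u, x)
    len_vy = out.branch_length(v, y)
    out.remove_edge(u, x)
    out.remove_edge(v, y)
    out.add_edge(u, y, len_vy)
    out.add_edge(v, x, len_ux)
    return out


def _dominates(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    return a[0] <= b[0] and a[1] <= b[1] and (a[0] < b[0] or a[1] < b[1])


def binary_tournament(
    population: Sequence[Individual], rng: np.random.Generator
) -> Individual:
    """Two distinct random individuals; Pareto dominance decides, then the
    smaller normalized-objective sum, then a fair coin."""
    i, j = rng.choice(len(population), size=2, replace=False)
    a, b = population[int(i)], population[int(j)]
    if _dominates(a.objectives, b.objectives):  # type: ignore[arg-type]
        return a
    if _dominates(b.objectives, a.objectives):  # type: ignore[arg-type]
        return b
    sa = float(a.normalized.sum()) if a.normalized is not None else 0.0
    sb = float(b.normalized.sum()) if b.normalized is not None else 0.0
    if sa != sb:
        return a if sa < sb else b
    return a if rng.random() < 0.5 else b


def make_offspring(
    population: Sequence[Individual],
    consensus_sets: Optional[Sequence[ConsensusBranchSet]],
    rng: np.random.Generator,
    n_offspring: Optional[int] = None,
    crossover_prob: float = 0.8,
    mutation_prob: float = 0.2,
    max_resamples: int = DEFAULT_MAX_RESAMPLES,
) -> List[Individual]:
    """Produce `n_offspring` children from an evaluated population.

    Parent pairs come from binary tournaments.  With probability
    `crossover_prob` the pair is crossed in both directions (each child is
    protected by the consensus set of the parent it was grafted into);
    otherwise both parents are copied through, keeping their cached scores.
    Each child is then NNI-mutated with probability `mutation_prob` under
    the same protection set.
    """
    if not population:
        raise ValueError("empty population")
    if n_offspring is None:
        n_offspring = len(population)

    def protection_of(ind: Individual) -> Protected:
        if consensus_sets is None or ind.subpop is None:
            return None
        return consensus_sets[ind.subpop]

    offspring: List[Individual] = []
    while len(offspring) < n_offspring:
        pa = binary_tournament(population, rng)
        pb = binary_tournament(population, rng)
        if rng.random() < crossover_prob:
            kids = [
                (pdg_crossover(pa.tree, pb.tree, rng, protection_of(pb), max_resamples),
                 protection_of(pb), None),
                (pdg_crossover(pb.tree, pa.tree, rng, protection_of(pa), max_resamples),
                 protection_of(pa), None),
            ]
        else:
            kids = [
                (pa.tree.copy(), protection_of(pa), pa.objectives),
                (pb.tree.copy(), protection_of(pb), pb.objectives),
            ]
        for tree, prot, cached in kids:
            if rng.random() < mutation_prob:
                tree = nni_mutation(tree, rng, prot)
                cached = None
            offspring.append(Individual(tree=tree, objectives=cached))
    return offspring[:n_offspring]
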