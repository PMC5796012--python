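"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's own algorithms: parsimony and
likelihood by exhaustive enumeration of internal-node states, transition
matrices via scipy's generic matrix exponential, split frequencies via
dendropy's bipartition machinery, hypervolume by grid integration, and
Pareto filtering by the naive O(N^2) scan.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Dict, FrozenSet, List, Sequence, Tuple

import dendropy
import numpy as np
from scipy.linalg import expm

from phylorc.alignment_io import SitePatterns
from phylorc.scoring import GTRModel
from phylorc.trees import PhyloTree


def _fixed_leaf_states(tree: PhyloTree, patterns: SitePatterns, j: int) -> Dict[int, int]:
    """Leaf states for pattern j; requires unambiguous (single-state) masks."""
    row = {lab: i for i, lab in enumerate(patterns.taxa)}
    out = {}
    for u in tree.leaf_ids():
        mask = int(patterns.masks[row[tree.label(u)], j])
        states = [s for s in range(4) if (mask >> s) & 1]
        assert len(states) == 1, "oracle supports unambiguous leaves only"
        out[u] = states[0]
    return out


def brute_force_parsimony(tree: PhyloTree, patterns: SitePatterns) -> int:
    """Minimum substitution count by enumerating all internal-state maps."""
    internals = tree.internal_ids()
    edges = [(u, v) for u, v, _ in tree.edges()]
    assigns = np.array(list(itertools.product(range(4), repeat=len(internals))), dtype=int)
    col = {u: i for i, u in enumerate(internals)}
    total = 0
    for j in range(patterns.n_patterns):
        leaf_state = _fixed_leaf_states(tree, patterns, j)

        def states_of(u: int) -> np.ndarray:
            if u in leaf_state:
                return np.full(len(assigns), leaf_state[u])
            return assigns[:, col[u]]

        cost = np.zeros(len(assigns), dtype=int)
        for u, v in edges:
            cost += states_of(u) != states_of(v)
        total += int(cost.min()) * int(patterns.weights[j])
    return total


def brute_force_log_likelihood(
    tree: PhyloTree, patterns: SitePatterns, model: GTRModel
) -> float:
    """Single-rate-category likelihood by summing over internal states,
    with transition matrices from scipy's expm (not the package's
    eigendecomposition)."""
    assert model.n_categories == 1
    pi = np.asarray(model.freqs)
    Q = model.rate_matrix
    P = {}
    for u, v, t in tree.edges():
        # one matrix per undirected edge; indexed [parent state, child state]
        P[frozenset((u, v))] = expm(Q * t)

    internals = tree.internal_ids()
    root = internals[0] if internals else tree.leaf_ids()[0]
    order, parent = tree.postorder(root)
    edges_down = [(parent[u], u) for u in order if parent[u] is not None]
    assigns = list(itertools.product(range(4), repeat=len(internals)))
    col = {u: i for i, u in enumerate(internals)}
    lnl = 0.0
    for j in range(patterns.n_patterns):
        leaf_state = _fixed_leaf_states(tree, patterns, j)

        def state(u: int, a) -> int:
            return leaf_state[u] if u in leaf_state else a[col[u]]

        lik = 0.0
        for a in assigns:
            p = pi[state(root, a)]
            for pu, u in edges_down:
                p *= P[frozenset((pu, u))][state(pu, a), state(u, a)]
            lik += p
        lnl += float(patterns.weights[j]) * np.log(lik)
    return lnl


def jc_two_taxon_log_likelihood(seq1: str, seq2: str, t: float) -> float:
    """Closed-form Jukes-Cantor likelihood of two aligned sequences at
    divergence t: P(same) = 1/4 + 3/4 e^(-4t/3) per site, each site
    weighted by the stationary 1/4."""
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    p_diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    lnl = 0.0
    for a, b in zip(seq1, seq2):
        lnl += np.log(0.25 * (p_same if a == b else p_diff))
    return float(lnl)


def dendropy_split_frequencies(
    newicks: Sequence[str],
) -> Tuple[Counter, FrozenSet[str]]:
    """Non-trivial split counts via dendropy, canonicalized like the package
    (side excluding the smallest taxon)."""
    tns = dendropy.TaxonNamespace()
    counts: Counter = Counter()
    taxa: FrozenSet[str] = frozenset()
    for nwk in newicks:
        tree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        tree.encode_bipartitions()
        taxa = frozenset(t.label for t in tns)
        ref = min(taxa)
        n = len(taxa)
        for bp in tree.bipartition_encoding:
            side = frozenset(
                t.label for t in tns if bp.leafset_bitmask & tns.taxon_bitmask(t)
            )
            if ref in side:
                side = taxa - side
            if 2 <= len(side) <= n - 2:
                counts[side] += 1
    return counts, taxa


def grid_hypervolume(
    points: Sequence[Tuple[float, float]], ref: Tuple[float, float], resolution: float = 1e-3
) -> float:
    """2-D dominated area by counting midpoint-dominated grid cells."""
    if not points:
        return 0.0
    x0 = min(p[0] for p in points)
    y0 = min(p[1] for p in points)
    xs = np.arange(x0 + resolution / 2, ref[0], resolution)
    ys = np.arange(y0 + resolution / 2, ref[1], resolution)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    dominated = np.zeros(X.shape, dtype=bool)
    for px, py in points:
        dominated |= (X >= px) & (Y >= py)
    return float(dominated.sum()) * resolution * resolution


def pareto_brute(points: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    uniq = sorted(set(points))
    return [
        p
        for p in uniq
        if not any(
            q[0] <= p[0] and q[1] <= p[1] and (q[0] < p[0] or q[1] < p[1]) for q in uniq
        )
    ]


def is_laminar(splits: Sequence[FrozenSet[str]]) -> bool:
    """Canonical sides all exclude one reference taxon, so the split set is
    realizable on a single tree iff the sides form a laminar family."""
    for a, b in itertools.combinations(splits, 2):
        if a & b and not (a <= b or b <= a):
            return False
    return True


def random_patterns(
    taxa: Sequence[str], n_sites: int, rng: np.random.Generator
) -> SitePatterns:
    """Uncompressed random unambiguous site patterns (each weight 1)."""
    masks = np.uint8(1) << rng.integers(0, 4, size=(len(taxa), n_sites)).astype(np.uint8)
    return SitePatterns(
        taxa=tuple(taxa),
        masks=masks,
        weights=np.ones(n_sites, dtype=np.int64),
    )
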