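"""Unrooted binary phylogenetic trees: Newick I/O, random topologies, bipartitions.

Trees are the unit of search for the evolutionary engine.  They are stored
unrooted (internal nodes of degree 3, leaves of degree 1) because both
optimality criteria -- parsimony and likelihood under a reversible model --
and the bipartition machinery used by the consensus operator are invariant
to root placement.  Rooted Newick input is unrooted on read by collapsing
the degree-2 root.

A *bipartition* (split) is the two-way partition of the taxon set induced by
deleting one edge.  It is represented canonically as the frozenset of taxon
labels on the side *not* containing the lexicographically smallest taxon, so
that equality and hashing are deterministic regardless of how the tree was
built or written.
"""

from __future__ import annotations

import re
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "PhyloTree",
    "Bipartition",
    "DEFAULT_BRANCH_LENGTH",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "bipartitions",
    "directed_leafsets",
    "canonical_bipartition",
    "random_tree",
]

#: A canonical split: the side of the taxon set excluding the smallest taxon.
Bipartition = FrozenSet[str]

#: Branch length substituted for edges with no length in the input Newick.
#: Must be positive so the likelihood is finite; configurable per call.
DEFAULT_BRANCH_LENGTH = 0.1


class TreeError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


class PhyloTree:
    """Unrooted, binary, leaf-labelled tree with non-negative branch lengths.

    Nodes are integer handles; leaves carry unique string labels.  For n >= 3
    leaves a valid tree has n - 2 internal nodes and 2n - 3 edges.  The
    degenerate 2-leaf tree (a single edge) is permitted for scoring tests but
    is rejected by :func:`parse_newick` and by the search operators.
    """

    __slots__ = ("_adj", "_label", "_node_of", "_next_id")

    def __init__(self) -> None:
        self._adj: Dict[int, Dict[int, float]] = {}
        self._label: Dict[int, str] = {}
        self._node_of: Dict[str, int] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = {}
        if label is not None:
            if label in self._node_of:
                raise TreeError(f"duplicate leaf label: {label!r}")
            self._label[nid] = label
            self._node_of[label] = nid
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise TreeError(f"negative branch length {length} on edge ({u},{v})")
        if v in self._adj[u]:
            raise TreeError(f"edge ({u},{v}) already present")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    def remove_node(self, u: int) -> None:
        if self._adj[u]:
            raise TreeError(f"cannot remove node {u} with incident edges")
        del self._adj[u]
        lab = self._label.pop(u, None)
        if lab is not None:
            del self._node_of[lab]

    def suppress_node(self, u: int) -> None:
        """Remove a degree-2 node, merging its two edges (lengths summed)."""
        (a, la), (b, lb) = self._adj[u].items()
        self.remove_edge(u, a)
        self.remove_edge(u, b)
        self.remove_node(u)
        self.add_edge(a, b, la + lb)

    def remove_leaf(self, label: str) -> None:
        """Delete a leaf; the neighbour, if left with degree 2, is suppressed."""
        u = self._node_of[label]
        (nb,) = self._adj[u].keys()
        self.remove_edge(u, nb)
        self.remove_node(u)
        if self.degree(nb) == 2 and nb not in self._label:
            self.suppress_node(nb)

    # -- queries ------------------------------------------------------

    def neighbors(self, u: int) -> Tuple[int, ...]:
        return tuple(self._adj[u])

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def is_leaf(self, u: int) -> bool:
        return u in self._label

    def label(self, u: int) -> Optional[str]:
        return self._label.get(u)

    def node_of(self, label: str) -> int:
        return self._node_of[label]

    @property
    def taxa(self) -> FrozenSet[str]:
        return frozenset(self._node_of)

    @property
    def n_leaves(self) -> int:
        return len(self._node_of)

    def leaf_ids(self) -> List[int]:
        return sorted(self._label)

    def internal_ids(self) -> List[int]:
        return sorted(u for u in self._adj if u not in self._label)

    def edges(self) -> List[Tuple[int, int, float]]:
        """All edges as (u, v, length) with u < v, sorted."""
        out = []
        for u, nbrs in self._adj.items():
            for v, l in nbrs.items():
                if u < v:
                    out.append((u, v, l))
        out.sort()
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def branch_length(self, u: int, v: int) -> float:
        return self._adj[u][v]

    def set_branch_length(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        self._adj[u][v] = float(length)
        self._adj[v][u] = float(length)

    def copy(self) -> "PhyloTree":
        t = PhyloTree.__new__(PhyloTree)
        t._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._next_id = self._next_id
        return t

    # -- traversal ----------------------------------------------------

    def postorder(self, root: int) -> Tuple[List[int], Dict[int, Optional[int]]]:
        """Postorder node list and parent map for the tree rooted at `root`."""
        parent: Dict[int, Optional[int]] = {root: None}
        stack = [root]
        order: List[int] = []
        while stack:
            u = stack.pop()
            order.append(u)
            for w in self._adj[u]:
                if w != parent[u]:
                    parent[w] = u
                    stack.append(w)
        order.reverse()
        return order, parent

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        n = self.n_leaves
        nodes = len(self._adj)
        if n == 2:
            if nodes != 2 or self.n_edges != 1:
                raise TreeError("2-leaf tree must be a single edge")
            return
        if n < 3:
            raise TreeError(f"need >= 3 leaves, got {n}")
        if nodes != 2 * n - 2:
            raise TreeError(f"expected {2 * n - 2} nodes for {n} leaves, got {nodes}")
        if self.n_edges != 2 * n - 3:
            raise TreeError(f"expected {2 * n - 3} edges for {n} leaves, got {self.n_edges}")
        for u in self._adj:
            d = self.degree(u)
            if u in self._label and d != 1:
                raise TreeError(f"leaf {self._label[u]!r} has degree {d}")
            if u not in self._label and d != 3:
                raise TreeError(f"internal node {u} has degree {d} (binary trees only)")
        for u, nbrs in self._adj.items():
            for l in nbrs.values():
                if l < 0:
                    raise TreeError("negative branch length")
        # connectivity
        order, _ = self.postorder(next(iter(self._adj)))
        if len(order) != nodes:
            raise TreeError("tree is not connected")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str, default_branch_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """Parse a Newick string into an unrooted binary :class:`PhyloTree`.

    Rooted input (degree-2 root) is unrooted by collapsing the root and
    summing the two root edges.  Edges without a length receive
    `default_branch_length`.  Raises :class:`TreeError` on malformed input,
    duplicate labels, fewer than 3 leaves, or multifurcations.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc

    t = PhyloTree()
    node_map: Dict[object, int] = {}
    for nd in dt.preorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None or lab == "":
                raise TreeError("leaf without a label in Newick input")
            node_map[nd] = t.new_node(str(lab))
        else:
            node_map[nd] = t.new_node()
        if nd.parent_node is not None:
            length = nd.edge.length
            if length is None:
                length = default_branch_length
            if length < 0:
                raise TreeError(f"negative branch length {length!r} in Newick input")
            t.add_edge(node_map[nd.parent_node], node_map[nd], float(length))

    if t.n_leaves < 3:
        raise TreeError(f"need >= 3 leaves, got {t.n_leaves}")

    for u in list(t._adj):
        if not t.is_leaf(u) and t.degree(u) == 2:
            t.suppress_node(u)
    for u in list(t._adj):
        if not t.is_leaf(u) and t.degree(u) != 3:
            raise TreeError(
                f"internal node of degree {t.degree(u)}: only binary trees are supported"
            )
    t.validate()
    return t


def parse_newick_list(
    text: str, default_branch_length: float = DEFAULT_BRANCH_LENGTH
) -> List[PhyloTree]:
    """Parse one Newick tree per non-empty line (or ';'-separated)."""
    out = []
    for chunk in text.replace("\n", " ").split(";"):
        if chunk.strip():
            out.append(parse_newick(chunk + ";", default_branch_length))
    return out


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+|-]+$")


def _fmt_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    """Serialize deterministically: the trifurcation sits at the internal node
    next to the smallest taxon and children are ordered by their smallest
    descendant label, so equal trees always produce identical strings."""
    ref = min(tree.taxa)
    ref_node = tree.node_of(ref)
    if tree.n_leaves == 2:
        a, b = _fmt_label(ref), _fmt_label(tree.label(tree.neighbors(ref_node)[0]))
        l = tree.branch_length(ref_node, tree.neighbors(ref_node)[0])
        if lengths:
            return f"({a}:{_fmt_length(l)},{b}:{_fmt_length(l)});"
        return f"({a},{b});"
    center = tree.neighbors(ref_node)[0]

    order, parent = tree.postorder(center)
    minlab: Dict[int, str] = {}
    for u in order:
        if tree.is_leaf(u):
            minlab[u] = tree.label(u)  # type: ignore[assignment]
        else:
            minlab[u] = min(minlab[w] for w in tree.neighbors(u) if w != parent[u])

    def sub(u: int) -> str:
        if tree.is_leaf(u):
            s = _fmt_label(tree.label(u))  # type: ignore[arg-type]
        else:
            kids = sorted(
                (w for w in tree.neighbors(u) if w != parent[u]), key=minlab.__getitem__
            )
            s = "(" + ",".join(sub(w) for w in kids) + ")"
        if lengths:
            s += ":" + _fmt_length(tree.branch_length(u, parent[u]))  # type: ignore[arg-type]
        return s  # type: ignore[return-value]

    kids = sorted(tree.neighbors(center), key=minlab.__getitem__)
    return "(" + ",".join(sub(w) for w in kids) + ");"


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


def canonical_bipartition(side: Iterable[str], taxa: FrozenSet[str]) -> Bipartition:
    """Canonical form of a split: the side excluding the smallest taxon."""
    side = frozenset(side)
    if min(taxa) in side:
        side = taxa - side
    return side


def directed_leafsets(tree: PhyloTree) -> Dict[Tuple[int, int], FrozenSet[str]]:
    """For the tree rooted at the smallest taxon's leaf: maps each directed
    edge (parent, child) to the leaf labels in the subtree below `child`."""
    root = tree.node_of(min(tree.taxa))
    order, parent = tree.postorder(root)
    below: Dict[int, FrozenSet[str]] = {}
    out: Dict[Tuple[int, int], FrozenSet[str]] = {}
    for u in order:
        if tree.is_leaf(u):
            below[u] = frozenset((tree.label(u),))  # type: ignore[arg-type]
        else:
            acc: set = set()
            for w in tree.neighbors(u):
                if w != parent[u]:
                    acc |= below[w]
            below[u] = frozenset(acc)
        p = parent[u]
        if p is not None:
            out[(p, u)] = below[u]
    return out


def bipartitions(tree: PhyloTree) -> FrozenSet[Bipartition]:
    """The n - 3 non-trivial splits of the tree, canonicalized.

    Trees with fewer than 4 leaves have no non-trivial split and yield the
    empty set.
    """
    taxa = tree.taxa
    n = len(taxa)
    out = set()
    for side in directed_leafsets(tree).values():
        if 2 <= len(side) <= n - 2:
            out.add(canonical_bipartition(side, taxa))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Random topologies
# ---------------------------------------------------------------------------


def random_tree(
    taxa: Sequence[str],
    rng: np.random.Generator,
    branch_dist: Optional[Callable[[np.random.Generator], float]] = None,
) -> PhyloTree:
    """Uniformly random unrooted binary topology by sequential edge attachment.

    Taxa are attached in the given order, each onto an edge chosen uniformly
    from the current tree; since every topology arises from exactly one
    attachment sequence, the (2n-5)!! topologies are equiprobable.  Branch
    lengths are then drawn i.i.d. from `branch_dist` (default:
    exponential with mean 0.1 substitutions/site).
    """
    labels = list(taxa)
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate taxon labels")
    if len(labels) < 3:
        raise TreeError(f"need >= 3 taxa, got {len(labels)}")
    if branch_dist is None:
        branch_dist = lambda r: float(r.exponential(0.1))

    t = PhyloTree()
    center = t.new_node()
    for lab in labels[:3]:
        t.add_edge(center, t.new_node(lab), 1.0)
    for lab in labels[3:]:
        edges = [(u, v) for u, v, _ in t.edges()]
        u, v = edges[int(rng.integers(len(edges)))]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid, 1.0)
        t.add_edge(mid, v, 1.0)
        t.add_edge(mid, t.new_node(lab), 1.0)
    for u, v, _ in t.edges():
        t.set_branch_length(u, v, branch_dist(rng))
    t.validate()
    return t
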