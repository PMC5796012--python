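"""The two optimality criteria and objective normalization.

Objective 1 is the Fitch parsimony score: the minimum number of nucleotide
substitutions the tree requires, summed over weighted site patterns.
Objective 2 is the negated log-likelihood under GTR with discrete-gamma
rate variation (Felsenstein pruning); negation turns both criteria into
minimization problems.

Because the two objectives live on very different scales, each is mapped
into [0, 1] against dynamically tracked reference (componentwise best) and
nadir (componentwise worst) points:

    f_bar_i = (f_i - z*_i) / (znad_i - z*_i)

The reference box is maintained as *running extremes* over the whole run so
the normalization never oscillates between generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .alignment_io import Alignment, CHAR_TO_MASK, SitePatterns
from .trees import PhyloTree

__all__ = [
    "GTRModel",
    "ObjectiveVector",
    "ReferencePoints",
    "empirical_frequencies",
    "gtr_transition_matrix",
    "fitch_parsimony",
    "log_likelihood",
    "normalize",
    "update_reference_points",
    "reference_points_from",
]

#: (parsimony score, negated log-likelihood) -- both minimized.
ObjectiveVector = Tuple[float, float]

#: Default floor applied to branch lengths inside the likelihood so that
#: zero-length edges produced by the operators cannot yield -inf.
BRANCH_LENGTH_FLOOR = 1e-6

_EXCHANGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


@dataclass(frozen=True)
class GTRModel:
    """General time-reversible substitution model with discrete-gamma rates.

    Parameters
    ----------
    freqs
        Stationary base frequencies (pi_A, pi_C, pi_G, pi_T); positive,
        summing to 1 (renormalized exactly on construction).
    exchangeabilities
        The six symmetric rates in the order AC, AG, AT, CG, CT, GT.
        Scale-free: the rate matrix is normalized to one expected
        substitution per unit branch length at stationarity.
    alpha
        Gamma shape for among-site rate variation.
    n_categories
        Number of equal-probability discrete-gamma categories (mean-of-bin
        rates, renormalized to mean exactly 1); 1 disables rate variation.
    """

    freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: Tuple[float, float, float, float, float, float] = (1.0,) * 6
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ValueError(f"base frequencies must be 4 positive values, got {self.freqs}")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"base frequencies must sum to 1, got sum {f.sum():.6f}")
        object.__setattr__(self, "freqs", tuple(f / f.sum()))
        r = np.asarray(self.exchangeabilities, dtype=float)
        if r.shape != (6,) or np.any(r <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC, AG, AT, CG, CT, GT)")
        if self.alpha <= 0:
            raise ValueError(f"gamma shape must be positive, got {self.alpha}")
        if self.n_categories < 1:
            raise ValueError(f"need >= 1 rate category, got {self.n_categories}")

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Q with Q_ij = s_ij * pi_j (i != j), scaled to mean rate 1."""
        pi = np.asarray(self.freqs)
        S = np.zeros((4, 4))
        for (i, j), s in zip(_EXCHANGE_PAIRS, self.exchangeabilities):
            S[i, j] = S[j, i] = s
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    @cached_property
    def _eigen(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        # Reversibility: D Q D^-1 is symmetric for D = diag(sqrt(pi)),
        # so the spectrum is real and exp(Qt) is stable via eigh.
        pi = np.asarray(self.freqs)
        d = np.sqrt(pi)
        B = (d[:, None] * self.rate_matrix) / d[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / d[:, None]
        Uinv = V.T * d[None, :]
        return U, lam, Uinv

    @cached_property
    def category_rates(self) -> np.ndarray:
        """Mean-of-bin rates of the equal-probability gamma discretization."""
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        a = self.alpha
        edges = _gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a, scale=1.0 / a)
        # For X ~ Gamma(a, 1/a) (mean 1): E[X · 1{X <= x}] = P(a+1, a·x).
        partial = gammainc(a + 1.0, a * edges[1:-1])
        cum = np.concatenate(([0.0], partial, [1.0]))
        rates = k * np.diff(cum)
        return rates / rates.mean()


def empirical_frequencies(aln: Alignment, pseudocount: float = 1.0) -> Tuple[float, ...]:
    """Observed base composition over unambiguous characters, smoothed."""
    counts = np.full(4, pseudocount)
    unambiguous = {1: 0, 2: 1, 4: 2, 8: 3}
    for seq in aln.sequences:
        for ch in seq:
            idx = unambiguous.get(CHAR_TO_MASK[ch])
            if idx is not None:
                counts[idx] += 1
    return tuple(counts / counts.sum())


def gtr_transition_matrix(model: GTRModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(r·t) = exp(Q·r·t): row-stochastic substitution probabilities."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if rate <= 0:
        raise ValueError(f"category rate must be > 0, got {rate}")
    U, lam, Uinv = model._eigen
    return (U * np.exp(lam * (t * rate))[None, :]) @ Uinv


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def _check_taxa(tree: PhyloTree, patterns: SitePatterns) -> None:
    if tree.taxa != frozenset(patterns.taxa):
        missing = tree.taxa.symmetric_difference(patterns.taxa)
        raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")


def fitch_parsimony(tree: PhyloTree, patterns: SitePatterns) -> int:
    """Minimum number of substitutions the tree implies (Fitch's algorithm).

    The unrooted tree is rooted on the pendant edge of the smallest taxon;
    the downpass intersects/unions the children's state sets, adding one
    change per empty intersection, and the result is independent of that
    arbitrary rooting.
    """
    _check_taxa(tree, patterns)
    row = {lab: i for i, lab in enumerate(patterns.taxa)}
    root = tree.node_of(min(tree.taxa))
    order, parent = tree.postorder(root)
    npat = patterns.n_patterns
    changes = np.zeros(npat, dtype=np.int64)
    state: Dict[int, np.ndarray] = {}
    for u in order:
        if tree.is_leaf(u):
            state[u] = patterns.masks[row[tree.label(u)]]  # type: ignore[index]
            continue
        acc: Optional[np.ndarray] = None
        for w in tree.neighbors(u):
            if w == parent[u]:
                continue
            if acc is None:
                acc = state[w]
                continue
            inter = acc & state[w]
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | state[w], inter)
        state[u] = acc  # type: ignore[assignment]
    # cost of the pendant edge carrying the root leaf itself
    child = tree.neighbors(root)[0]
    changes += (state[root] & state[child]) == 0
    return int(np.dot(changes, patterns.weights))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

_MASK_TO_IND = np.array(
    [[(m >> b) & 1 for b in range(4)] for m in range(16)], dtype=float
)


def log_likelihood(
    tree: PhyloTree,
    patterns: SitePatterns,
    model: GTRModel,
    branch_length_floor: Optional[float] = BRANCH_LENGTH_FLOOR,
    root: Optional[int] = None,
) -> float:
    """Felsenstein-pruning log-likelihood under GTR + discrete gamma.

    Site likelihoods are averaged over the equal-probability rate
    categories; the returned value is sum over patterns of
    weight * log(site likelihood).  Under the reversible model the result
    is invariant to the (arbitrary) root used for the recursion, which
    defaults to the leaf of the smallest taxon.  Branch lengths below
    `branch_length_floor` are clamped (pass ``None`` to disable).
    """
    _check_taxa(tree, patterns)
    row = {lab: i for i, lab in enumerate(patterns.taxa)}
    if root is None:
        root = tree.node_of(min(tree.taxa))
    order, parent = tree.postorder(root)
    rates = model.category_rates
    ncat = len(rates)
    pi = np.asarray(model.freqs)
    npat = patterns.n_patterns

    def leaf_ind(u: int) -> np.ndarray:
        # (npat, ncat, 4): state-set indicator, identical across categories
        ind = _MASK_TO_IND[patterns.masks[row[tree.label(u)]]]  # type: ignore[index]
        return np.broadcast_to(ind[:, None, :], (npat, ncat, 4))

    partial: Dict[int, np.ndarray] = {}
    for u in order:
        if tree.is_leaf(u):
            partial[u] = leaf_ind(u)
        children = [w for w in tree.neighbors(u) if w != parent[u]]
        if not children:
            continue
        acc = partial[u] if tree.is_leaf(u) else np.ones((npat, ncat, 4))
        for w in children:
            t = tree.branch_length(u, w)
            if branch_length_floor is not None:
                t = max(t, branch_length_floor)
            P = np.stack([gtr_transition_matrix(model, t, r) for r in rates])
            # message to u: sum_s P[c, x, s] * partial[w][p, c, s]
            acc = acc * np.einsum("cxs,pcs->pcx", P, partial[w])
            del partial[w]
        partial[u] = acc

    site_lik = np.mean(partial[root] @ pi, axis=1)  # (npat,)
    if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
        bad = int(np.argmin(site_lik))
        raise ValueError(f"non-finite site likelihood at pattern {bad}")
    return float(np.dot(patterns.weights, np.log(site_lik)))


# ---------------------------------------------------------------------------
# Normalization and reference points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePoints:
    """Running componentwise best (z*) and worst (znad) objective values."""

    z_best: Tuple[float, float]
    z_nadir: Tuple[float, float]

    def __post_init__(self) -> None:
        if any(b > n for b, n in zip(self.z_best, self.z_nadir)):
            raise ValueError(f"reference point exceeds nadir: {self}")


def reference_points_from(observed: Iterable[ObjectiveVector]) -> ReferencePoints:
    pts = np.asarray(list(observed), dtype=float)
    if pts.size == 0:
        raise ValueError("cannot initialize reference points from an empty set")
    return ReferencePoints(
        z_best=tuple(float(x) for x in pts.min(axis=0)),
        z_nadir=tuple(float(x) for x in pts.max(axis=0)),
    )


def update_reference_points(
    ref: ReferencePoints, observed: Iterable[ObjectiveVector]
) -> ReferencePoints:
    """Extend the running extremes with newly observed objective vectors."""
    pts = np.asarray(list(observed), dtype=float)
    if pts.size == 0:
        raise ValueError("cannot update reference points from an empty set")
    return ReferencePoints(
        z_best=tuple(float(x) for x in np.minimum(ref.z_best, pts.min(axis=0))),
        z_nadir=tuple(float(x) for x in np.maximum(ref.z_nadir, pts.max(axis=0))),
    )


def normalize(f: ObjectiveVector, ref: ReferencePoints) -> np.ndarray:
    """Map an objective vector into [0,1]^2 against the reference box.

    A degenerate axis (znad_i == z*_i) maps to 0: every solution is equally
    good there and the axis should not influence selection.
    """
    out = np.empty(2)
    for i in range(2):
        span = ref.z_nadir[i] - ref.z_best[i]
        out[i] = 0.0 if span == 0 else (f[i] - ref.z_best[i]) / span
    return out
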