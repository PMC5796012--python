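"""The multi-objective search engine.

One generation: evaluate new trees under both criteria, fold them into the
running reference box, redistribute parents+offspring over the weight
vectors, recompute each direction's consensus branches from neighbouring
elites, and breed the next batch of offspring under that protection.  The
ablation mode ("R": redistribution only) runs the identical loop with
consensus disabled, which isolates the contribution of branch protection.

Every run is driven by a single seeded NumPy generator, so a (seed, config)
pair reproduces traces and trees bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .alignment_io import Alignment, SitePatterns, compress_patterns
from .consensus import (
    EMPTY_CONSENSUS,
    ConsensusBranchSet,
    collect_elites,
    consensus_branches,
)
from .operators import DEFAULT_MAX_RESAMPLES, make_offspring
from .redistribution import Individual, SubPopulation, make_weights, redistribute
from .scoring import (
    BRANCH_LENGTH_FLOOR,
    GTRModel,
    ObjectiveVector,
    ReferencePoints,
    empirical_frequencies,
    fitch_parsimony,
    log_likelihood,
    normalize,
    reference_points_from,
    update_reference_points,
)
from .trees import PhyloTree, parse_newick_list, random_tree, write_newick

__all__ = [
    "RunConfig",
    "TraceRow",
    "RunResult",
    "Evaluator",
    "initialize_population",
    "pareto_front",
    "hypervolume",
    "evolve",
]


@dataclass(frozen=True)
class RunConfig:
    """Engine parameters.  Defaults follow the common evolutionary settings:
    population 100, 100 generations, crossover 0.8, mutation 0.2, binary
    tournament parent selection."""

    population_size: int = 100
    n_subpopulations: int = 10
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    elites_per_set: int = 5
    consensus: bool = True  # False = ablation mode (redistribution only)
    plain_majority: bool = False  # drop the "(+)" extension, keep the core
    max_resamples: int = DEFAULT_MAX_RESAMPLES
    max_evaluations: Optional[int] = None
    seed: int = 0
    branch_length_floor: Optional[float] = BRANCH_LENGTH_FLOOR
    model: Optional[GTRModel] = None  # None: empirical freqs, unit rates

    def __post_init__(self) -> None:
        if self.population_size % self.n_subpopulations != 0:
            raise ValueError(
                f"population size {self.population_size} must be divisible by "
                f"{self.n_subpopulations} sub-populations"
            )
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model_raw = raw.pop("model", None)
        model = None
        if model_raw is not None:
            model = GTRModel(
                freqs=tuple(model_raw.get("freqs", (0.25,) * 4)),
                exchangeabilities=tuple(model_raw.get("exchangeabilities", (1.0,) * 6)),
                alpha=float(model_raw.get("alpha", 1.0)),
                n_categories=int(model_raw.get("n_categories", 4)),
            )
        return cls(model=model, **raw)


@dataclass(frozen=True)
class TraceRow:
    generation: int
    evaluations: int
    best_parsimony: float  # running minimum of f1
    best_neg_loglik: float  # running minimum of f2
    hypervolume: float  # of the survivor front in normalized space
    z_best: Tuple[float, float]
    z_nadir: Tuple[float, float]
    consensus_branch_count: int
    front_size: int


@dataclass
class RunResult:
    config: RunConfig
    seed: int
    population: List[Individual]
    front: List[Individual]
    trace: List[TraceRow]
    evaluations: int
    reference: ReferencePoints

    def trace_tsv(self) -> str:
        cols = [
            "generation", "evaluations", "best_parsimony", "best_neg_loglik",
            "hypervolume", "z_best_1", "z_best_2", "z_nadir_1", "z_nadir_2",
            "consensus_branch_count", "front_size",
        ]
        lines = ["\t".join(cols)]
        for r in self.trace:
            lines.append(
                "\t".join(
                    f"{v:.10g}" if isinstance(v, float) else str(v)
                    for v in (
                        r.generation, r.evaluations, r.best_parsimony,
                        r.best_neg_loglik, r.hypervolume,
                        r.z_best[0], r.z_best[1], r.z_nadir[0], r.z_nadir[1],
                        r.consensus_branch_count, r.front_size,
                    )
                )
            )
        return "\n".join(lines) + "\n"

    def summary(self) -> Dict:
        return {
            "seed": self.seed,
            "evaluations": self.evaluations,
            "generations": len(self.trace) - 1,
            "best_parsimony": self.reference.z_best[0],
            "best_neg_loglik": self.reference.z_best[1],
            "front_size": len(self.front),
            "front_objectives": [list(ind.objectives) for ind in self.front],
            "mode": "RC" if self.config.consensus else "R",
        }


class Evaluator:
    """Scores trees under both objectives with a per-(topology, lengths)
    cache keyed by the deterministic Newick string, and counts the number
    of genuinely new evaluations."""

    def __init__(
        self,
        patterns: SitePatterns,
        model: GTRModel,
        branch_length_floor: Optional[float] = BRANCH_LENGTH_FLOOR,
    ) -> None:
        self.patterns = patterns
        self.model = model
        self.floor = branch_length_floor
        self.count = 0
        self._memo: Dict[str, ObjectiveVector] = {}

    def score(self, tree: PhyloTree) -> ObjectiveVector:
        key = write_newick(tree)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        f1 = float(fitch_parsimony(tree, self.patterns))
        f2 = -log_likelihood(tree, self.patterns, self.model, self.floor)
        self.count += 1
        self._memo[key] = (f1, f2)
        return (f1, f2)

    def evaluate(self, individuals: Sequence[Individual]) -> None:
        for ind in individuals:
            if ind.objectives is None:
                ind.objectives = self.score(ind.tree)


def initialize_population(
    config: RunConfig,
    taxa: Sequence[str],
    rng: np.random.Generator,
    starting_trees: Optional[Sequence[PhyloTree]] = None,
) -> List[Individual]:
    """Generation 0: either N random topologies with exponential(mean 0.1)
    branch lengths, or user-supplied trees (cycled/truncated to N)."""
    N = config.population_size
    taxa_set = frozenset(taxa)
    if starting_trees is not None:
        for t in starting_trees:
            if t.taxa != taxa_set:
                raise ValueError("starting tree taxa do not match the alignment")
        trees = [starting_trees[i % len(starting_trees)].copy() for i in range(N)]
    else:
        trees = [random_tree(list(taxa), rng) for _ in range(N)]
    return [Individual(tree=t) for t in trees]


def pareto_front(population: Sequence[Individual]) -> List[Individual]:
    """Non-dominated individuals, one representative per objective vector,
    sorted by objectives for deterministic output."""
    seen: Dict[ObjectiveVector, Individual] = {}
    for ind in population:
        if ind.objectives is None:
            raise ValueError("pareto_front requires evaluated individuals")
        seen.setdefault(ind.objectives, ind)
    pts = sorted(seen)
    front = []
    for p in pts:
        dominated = any(
            q[0] <= p[0] and q[1] <= p[1] and (q[0] < p[0] or q[1] < p[1]) for q in pts
        )
        if not dominated:
            front.append(seen[p])
    return front


def hypervolume(points: Sequence[Tuple[float, float]], ref: Tuple[float, float]) -> float:
    """Area dominated by a 2-D minimization front, bounded by `ref`.

    The reference point must be strictly worse than every point in both
    objectives.  Dominated points contribute nothing; the area is the usual
    staircase sum over the front sorted by the first objective.
    """
    if not points:
        return 0.0
    for p in points:
        if not (p[0] < ref[0] and p[1] < ref[1]):
            raise ValueError(f"reference point {ref} not strictly worse than {p}")
    # reduce to the non-dominated staircase
    pts = sorted(set(points))
    stair: List[Tuple[float, float]] = []
    for p in pts:
        while stair and stair[-1][1] >= p[1] and stair[-1][0] >= p[0]:
            stair.pop()
        if not stair or p[1] < stair[-1][1]:
            stair.append(p)
    area = 0.0
    for i, (x, y) in enumerate(stair):
        x_next = stair[i + 1][0] if i + 1 < len(stair) else ref[0]
        area += (x_next - x) * (ref[1] - y)
    return area


#: Reference corner for the per-generation hypervolume of the *normalized*
#: front; slightly outside [0,1]^2 so boundary points still count.
_HV_REF = (1.01, 1.01)


def _trace_row(
    gen: int,
    evaluator: Evaluator,
    survivors: Sequence[Individual],
    ref: ReferencePoints,
    consensus_sets: Sequence[ConsensusBranchSet],
) -> TraceRow:
    front = pareto_front(survivors)
    norm_pts = [tuple(normalize(ind.objectives, ref)) for ind in front]  # type: ignore[arg-type]
    hv = hypervolume(norm_pts, _HV_REF)
    return TraceRow(
        generation=gen,
        evaluations=evaluator.count,
        best_parsimony=ref.z_best[0],
        best_neg_loglik=ref.z_best[1],
        hypervolume=hv,
        z_best=ref.z_best,
        z_nadir=ref.z_nadir,
        consensus_branch_count=sum(len(cs.branches) for cs in consensus_sets),
        front_size=len(front),
    )


def evolve(
    config: RunConfig,
    alignment: Alignment,
    starting_trees: Optional[Sequence[PhyloTree]] = None,
) -> RunResult:
    """Run the full search loop and return population, front and trace.

    In consensus mode each sub-population's offspring are bred under the
    protected branch set computed from its own and its two neighbouring
    sub-populations' elites; in ablation mode protection is empty and the
    consensus step is skipped entirely.
    """
    rng = np.random.default_rng(config.seed)
    patterns = compress_patterns(alignment)
    model = config.model or GTRModel(freqs=empirical_frequencies(alignment))
    evaluator = Evaluator(patterns, model, config.branch_length_floor)
    taxa = sorted(alignment.labels)
    weights = make_weights(config.n_subpopulations)
    N = config.population_size

    population = initialize_population(config, taxa, rng, starting_trees)
    evaluator.evaluate(population)
    ref = reference_points_from([ind.objectives for ind in population])  # type: ignore[misc]
    subpops = redistribute(population, weights, ref, N)
    survivors = [ind for sp in subpops for ind in sp.members]

    use_consensus = config.consensus and config.n_subpopulations >= 3
    consensus_sets: List[ConsensusBranchSet] = [EMPTY_CONSENSUS] * config.n_subpopulations
    trace = [_trace_row(0, evaluator, survivors, ref, consensus_sets)]

    for gen in range(1, config.generations + 1):
        if use_consensus:
            consensus_sets = []
            for i in range(config.n_subpopulations):
                elites = collect_elites(subpops, i, config.elites_per_set)
                if len(elites) >= 2:
                    consensus_sets.append(
                        consensus_branches(elites, subpop=i, plain_majority=config.plain_majority)
                    )
                else:
                    consensus_sets.append(EMPTY_CONSENSUS)
        offspring = make_offspring(
            survivors,
            consensus_sets if use_consensus else None,
            rng,
            n_offspring=N,
            crossover_prob=config.crossover_prob,
            mutation_prob=config.mutation_prob,
            max_resamples=config.max_resamples,
        )
        evaluator.evaluate(offspring)
        ref = update_reference_points(ref, [ind.objectives for ind in offspring])  # type: ignore[misc]
        merged = survivors + offspring
        subpops = redistribute(merged, weights, ref, N)
        survivors = [ind for sp in subpops for ind in sp.members]
        trace.append(_trace_row(gen, evaluator, survivors, ref, consensus_sets))
        if config.max_evaluations is not None and evaluator.count >= config.max_evaluations:
            break

    return RunResult(
        config=config,
        seed=config.seed,
        population=survivors,
        front=pareto_front(survivors),
        trace=trace,
        evaluations=evaluator.count,
        reference=ref,
    )
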