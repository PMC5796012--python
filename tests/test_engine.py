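import numpy as np
import pytest

from phylorc.engine import (
    Evaluator,
    RunConfig,
    evolve,
    hypervolume,
    initialize_population,
    pareto_front,
)
from phylorc.redistribution import Individual
from phylorc.trees import random_tree, write_newick

from .oracles import grid_hypervolume, pareto_brute


def inds(points):
    return [Individual(tree=None, objectives=tuple(map(float, p))) for p in points]


class TestParetoFront:
    def test_singleton(self):
        pop = inds([(3.0, 4.0)])
        assert pareto_front(pop) == pop

    def test_hand_example(self):
        pop = inds([(5, 10), (6, 9), (7, 11)])
        front = {ind.objectives for ind in pareto_front(pop)}
        assert front == {(5.0, 10.0), (6.0, 9.0)}

    def test_duplicates_collapse(self):
        pop = inds([(1, 2), (1, 2), (3, 1)])
        assert len(pareto_front(pop)) == 2

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            pts = [tuple(v) for v in rng.integers(0, 12, size=(40, 2)).astype(float)]
            mine = sorted(ind.objectives for ind in pareto_front(inds(pts)))
            assert mine == pareto_brute(pts)


class TestHypervolume:
    def test_unit_box(self):
        assert hypervolume([(0.0, 0.0)], (1.0, 1.0)) == pytest.approx(1.0)

    def test_empty_front(self):
        assert hypervolume([], (1.0, 1.0)) == 0.0

    def test_two_corner_points(self):
        # each point dominates a degenerate sliver only
        assert hypervolume([(0.0, 1.0), (1.0, 0.0)], (1.0 + 1e-9, 1.0 + 1e-9)) == (
            pytest.approx(2e-9, rel=1e-3)
        )

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError):
            hypervolume([(0.5, 2.0)], (1.0, 1.0))

    def test_matches_grid_integration(self, rng):
        for _ in range(5):
            pts = [tuple(v) for v in rng.uniform(0, 0.9, size=(8, 2))]
            ref = (1.0, 1.0)
            assert hypervolume(pts, ref) == pytest.approx(
                grid_hypervolume(pts, ref, resolution=1e-3), abs=1e-2
            )

    def test_monotone_under_new_nondominated_point(self, rng):
        pts = [(0.5, 0.2), (0.2, 0.6)]
        base = hypervolume(pts, (1.0, 1.0))
        assert hypervolume(pts + [(0.05, 0.9)], (1.0, 1.0)) > base


class TestRunConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            RunConfig(population_size=10, n_subpopulations=4)

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError):
            RunConfig(crossover_prob=1.5)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "population_size: 20\nn_subpopulations: 4\ngenerations: 3\nseed: 9\n"
            "model:\n  freqs: [0.3, 0.2, 0.3, 0.2]\n  alpha: 0.7\n  n_categories: 2\n"
        )
        cfg = RunConfig.from_yaml(str(p))
        assert cfg.population_size == 20
        assert cfg.model.alpha == 0.7
        assert cfg.model.n_categories == 2


class TestInitialization:
    def test_random_mode_size_and_taxa(self, rng):
        cfg = RunConfig(population_size=20, n_subpopulations=4)
        taxa = [f"t{i}" for i in range(6)]
        pop = initialize_population(cfg, taxa, rng)
        assert len(pop) == 20
        assert all(ind.tree.taxa == frozenset(taxa) for ind in pop)
        assert all(ind.objectives is None for ind in pop)

    def test_file_mode_passthrough(self, rng):
        cfg = RunConfig(population_size=4, n_subpopulations=2)
        taxa = [f"t{i}" for i in range(6)]
        given = [random_tree(taxa, rng) for _ in range(4)]
        pop = initialize_population(cfg, taxa, rng, starting_trees=given)
        assert [write_newick(i.tree) for i in pop] == [write_newick(t) for t in given]

    def test_taxon_mismatch_rejected(self, rng):
        cfg = RunConfig(population_size=4, n_subpopulations=2)
        bad = [random_tree(["x", "y", "z", "w"], rng)]
        with pytest.raises(ValueError):
            initialize_population(cfg, ["a", "b", "c", "d"], rng, starting_trees=bad)

    def test_same_seed_identical_population(self):
        cfg = RunConfig(population_size=10, n_subpopulations=2)
        taxa = [f"t{i}" for i in range(8)]
        p1 = initialize_population(cfg, taxa, np.random.default_rng(3))
        p2 = initialize_population(cfg, taxa, np.random.default_rng(3))
        assert [write_newick(i.tree) for i in p1] == [write_newick(i.tree) for i in p2]


def small_config(**kw):
    base = dict(
        population_size=16,
        n_subpopulations=4,
        generations=4,
        seed=11,
        elites_per_set=2,
    )
    base.update(kw)
    return RunConfig(**base)


class TestEvolve:
    def test_zero_generations_returns_evaluated_initial_population(self, benchmark8):
        _, aln, model = benchmark8
        res = evolve(small_config(generations=0, model=model), aln)
        assert len(res.trace) == 1
        assert len(res.population) == 16
        assert all(ind.objectives is not None for ind in res.population)

    def test_population_size_conserved_and_minima_monotone(self, benchmark8):
        _, aln, model = benchmark8
        res = evolve(small_config(model=model), aln)
        assert len(res.population) == 16
        mp = [r.best_parsimony for r in res.trace]
        ll = [r.best_neg_loglik for r in res.trace]
        assert mp == sorted(mp, reverse=True) or all(
            a >= b for a, b in zip(mp, mp[1:])
        )
        assert all(a >= b for a, b in zip(ll, ll[1:]))

    def test_ablation_mode_has_no_consensus(self, benchmark8):
        _, aln, model = benchmark8
        res = evolve(small_config(model=model, consensus=False), aln)
        assert all(r.consensus_branch_count == 0 for r in res.trace)

    def test_front_members_mutually_nondominated(self, benchmark8):
        _, aln, model = benchmark8
        res = evolve(small_config(model=model), aln)
        objs = [ind.objectives for ind in res.front]
        for a in objs:
            for b in objs:
                if a != b:
                    assert not (a[0] <= b[0] and a[1] <= b[1])

    def test_evaluation_budget_stop(self, benchmark8):
        _, aln, model = benchmark8
        res = evolve(small_config(model=model, generations=50, max_evaluations=40), aln)
        assert len(res.trace) < 51


class TestEvaluatorCache:
    def test_identical_trees_scored_once(self, benchmark8, rng):
        from phylorc.alignment_io import compress_patterns

        _, aln, model = benchmark8
        ev = Evaluator(compress_patterns(aln), model)
        t = random_tree(sorted(aln.labels), rng)
        a = ev.score(t)
        b = ev.score(t.copy())
        assert a == b
        assert ev.count == 1
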