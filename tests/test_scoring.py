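import numpy as np
import pytest
from scipy.linalg import expm

from phylorc.alignment_io import Alignment, compress_patterns
from phylorc.scoring import (
    GTRModel,
    ReferencePoints,
    fitch_parsimony,
    gtr_transition_matrix,
    log_likelihood,
    normalize,
    reference_points_from,
    update_reference_points,
)
from phylorc.trees import PhyloTree, parse_newick, random_tree

from .conftest import random_alignment, random_model
from .oracles import (
    brute_force_log_likelihood,
    brute_force_parsimony,
    jc_two_taxon_log_likelihood,
    random_patterns,
)


def patterns_of(labels, seqs):
    return compress_patterns(Alignment(labels=tuple(labels), sequences=tuple(seqs)))


def two_taxon_tree(t):
    tr = PhyloTree()
    a = tr.new_node("A")
    b = tr.new_node("B")
    tr.add_edge(a, b, t)
    return tr


class TestFitch:
    @pytest.mark.parametrize(
        "seqs,score",
        [
            (("A", "A", "G", "G"), 1),
            (("A", "G", "A", "G"), 2),
            (("C", "C", "C", "C"), 0),
        ],
    )
    def test_quartet_single_columns(self, quartet, seqs, score):
        pat = patterns_of("ABCD", seqs)
        assert fitch_parsimony(quartet, pat) == score

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_tree(taxa, rng)
            pat = random_patterns(taxa, int(rng.integers(1, 11)), rng)
            assert fitch_parsimony(tree, pat) == brute_force_parsimony(tree, pat)

    def test_taxon_mismatch(self, quartet):
        with pytest.raises(ValueError, match="mismatch"):
            fitch_parsimony(quartet, patterns_of("ABCE", ("A", "A", "A", "A")))

    def test_constant_column_adds_nothing(self, quartet, rng):
        pat1 = patterns_of("ABCD", ("ACG", "AGG", "GCG", "GAG"))
        pat2 = patterns_of("ABCD", ("ACGT", "AGGT", "GCGT", "GAGT"))
        assert fitch_parsimony(quartet, pat2) == fitch_parsimony(quartet, pat1)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, rng):
        model = random_model(rng)
        assert np.allclose(gtr_transition_matrix(model, 0.0), np.eye(4), atol=1e-14)

    def test_rows_are_stochastic(self, rng):
        model = random_model(rng)
        for t in (0.01, 0.3, 2.5):
            P = gtr_transition_matrix(model, t)
            assert np.all(P >= -1e-15)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_long_time_reaches_stationarity(self, rng):
        model = random_model(rng)
        P = gtr_transition_matrix(model, 100.0)
        assert np.allclose(P, np.tile(model.freqs, (4, 1)), atol=1e-6)

    def test_chapman_kolmogorov_against_expm(self, rng):
        model = random_model(rng)
        for _ in range(5):
            s, t = rng.uniform(0.01, 1.0, 2)
            Pst = gtr_transition_matrix(model, s) @ gtr_transition_matrix(model, t)
            assert np.allclose(Pst, gtr_transition_matrix(model, s + t), atol=1e-10)
            assert np.allclose(
                gtr_transition_matrix(model, s), expm(model.rate_matrix * s), atol=1e-10
            )

    def test_detailed_balance(self, rng):
        model = random_model(rng)
        P = gtr_transition_matrix(model, 0.7)
        pi = np.asarray(model.freqs)
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10)

    def test_category_rates_have_mean_one(self):
        for alpha in (0.3, 1.0, 5.0):
            m = GTRModel(alpha=alpha, n_categories=4)
            assert m.category_rates.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(m.category_rates) > 0)
        # huge alpha: rate variation vanishes
        assert np.allclose(GTRModel(alpha=500.0).category_rates, 1.0, atol=0.1)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            GTRModel(freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            GTRModel(alpha=-1.0)
        with pytest.raises(ValueError):
            GTRModel(exchangeabilities=(1, 1, 1, 1, 1, 0))


class TestLogLikelihood:
    def test_zero_distance_identical_sequences(self, jc_model):
        L = 17
        tree = two_taxon_tree(0.0)
        seq = ("ACGTA" * 4)[:L]
        pat = patterns_of("AB", (seq, seq))
        lnl = log_likelihood(tree, pat, jc_model, branch_length_floor=None)
        assert lnl == pytest.approx(L * np.log(0.25), abs=1e-10)

    def test_jc_closed_form(self, rng, jc_model):
        for t in (0.05, 0.3, 1.2):
            s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            s2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            tree = two_taxon_tree(t)
            pat = patterns_of("AB", (s1, s2))
            assert log_likelihood(tree, pat, jc_model, branch_length_floor=None) == (
                pytest.approx(jc_two_taxon_log_likelihood(s1, s2, t), abs=1e-8)
            )

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 6))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_tree(taxa, rng)
            pat = random_patterns(taxa, 6, rng)
            model = random_model(rng, n_categories=1)
            mine = log_likelihood(tree, pat, model, branch_length_floor=None)
            ref = brute_force_log_likelihood(tree, pat, model)
            assert mine == pytest.approx(ref, rel=1e-8)

    def test_invariant_to_root_choice(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        tree = random_tree(taxa, rng)
        pat = random_patterns(taxa, 12, rng)
        model = random_model(rng, n_categories=4)
        vals = [
            log_likelihood(tree, pat, model, root=r)
            for r in list(tree.internal_ids()) + tree.leaf_ids()
        ]
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_invariant_to_leaf_order(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = random_tree(taxa, rng)
        mat = rng.integers(0, 4, size=(6, 15))
        seqs = ["".join("ACGT"[s] for s in row) for row in mat]
        model = random_model(rng)
        perm = rng.permutation(6)
        pat1 = patterns_of(taxa, seqs)
        pat2 = patterns_of([taxa[i] for i in perm], [seqs[i] for i in perm])
        assert log_likelihood(tree, pat1, model) == pytest.approx(
            log_likelihood(tree, pat2, model), rel=1e-12
        )

    def test_constant_column_adds_its_site_loglik(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        tree = random_tree(taxa, rng)
        model = random_model(rng)
        mat = rng.integers(0, 4, size=(5, 10))
        seqs = ["".join("ACGT"[s] for s in row) for row in mat]
        base = log_likelihood(tree, patterns_of(taxa, seqs), model)
        const = log_likelihood(tree, patterns_of(taxa, ["G"] * 5), model)
        extended = log_likelihood(
            tree, patterns_of(taxa, [s + "G" for s in seqs]), model
        )
        assert extended == pytest.approx(base + const, rel=1e-10)


class TestNormalization:
    def test_box_corners_and_midpoint(self):
        ref = ReferencePoints(z_best=(10.0, -5.0), z_nadir=(20.0, 5.0))
        assert normalize((10.0, -5.0), ref).tolist() == [0.0, 0.0]
        assert normalize((20.0, 5.0), ref).tolist() == [1.0, 1.0]
        assert normalize((15.0, 0.0), ref).tolist() == [0.5, 0.5]

    def test_degenerate_axis_maps_to_zero(self):
        ref = ReferencePoints(z_best=(3.0, 1.0), z_nadir=(3.0, 2.0))
        assert normalize((3.0, 1.5), ref).tolist() == [0.0, 0.5]

    def test_shift_invariance(self, rng):
        for _ in range(10):
            z = rng.normal(size=2)
            span = rng.uniform(0.5, 4.0, size=2)
            f = z + rng.uniform(0, 1, 2) * span
            shift = rng.normal(size=2)
            a = normalize(tuple(f), ReferencePoints(tuple(z), tuple(z + span)))
            b = normalize(
                tuple(f + shift), ReferencePoints(tuple(z + shift), tuple(z + span + shift))
            )
            assert np.allclose(a, b, atol=1e-9)


class TestReferencePoints:
    def test_initialization_from_first_generation(self):
        ref = reference_points_from([(5.0, 2.0), (3.0, 7.0), (4.0, 4.0)])
        assert ref.z_best == (3.0, 2.0)
        assert ref.z_nadir == (5.0, 7.0)

    def test_interior_observations_change_nothing(self):
        ref = ReferencePoints((0.0, 0.0), (10.0, 10.0))
        assert update_reference_points(ref, [(5.0, 5.0), (1.0, 9.0)]) == ref

    def test_order_independence(self, rng):
        obs = [tuple(v) for v in rng.normal(size=(30, 2))]
        ref0 = reference_points_from(obs[:1])
        seq = ref0
        for o in obs[1:]:
            seq = update_reference_points(seq, [o])
        batch = update_reference_points(ref0, obs[1:])
        direct = reference_points_from(obs)
        assert seq == batch == direct

    def test_empty_update_rejected(self):
        with pytest.raises(ValueError):
            update_reference_points(ReferencePoints((0, 0), (1, 1)), [])
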