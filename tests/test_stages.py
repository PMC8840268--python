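"""Juvenile/adult contrasts: D test, K-mult, dK, phylogenetic MANOVA,
phylomorphospace."""

import numpy as np
import pytest

from ontotraj.config import RunConfig
from ontotraj.allometry import TrajectorySet, fit_unique_allometries
from ontotraj.morphometry import ShapeData
from ontotraj.simulate import (
    make_divergence_fixture,
    simulate_bm_tips,
    simulate_markov_habitat,
    simulate_pure_birth_tree,
)
from ontotraj.stages import (
    d_test,
    delta_k_test,
    k_mult,
    phylo_manova,
    phylomorphospace,
)
from ontotraj.trees import read_newick


def _traj(species, juv, adu):
    juv, adu = np.asarray(juv, float), np.asarray(adu, float)
    return TrajectorySet(
        species=list(species),
        lengths=np.linalg.norm(adu - juv, axis=1),
        directions=np.full_like(juv, np.nan),
        juvenile_shape=juv,
        adult_shape=adu,
    )


def _dummy_data(species, n_per=3, q=2, seed=0):
    rng = np.random.default_rng(seed)
    Y, size, lab = [], [], []
    for s in species:
        Y.append(rng.normal(size=(n_per, q)))
        size.append(rng.uniform(0, 1, n_per))
        lab += [s] * n_per
    return ShapeData(Y=np.vstack(Y), size=np.concatenate(size),
                     species=np.array(lab), sex=np.array(["M"] * len(lab)))


class TestDTest:
    def test_hand_computed_toy(self):
        # juveniles coincident, adults at mutual distance 1: D_j=0, D_a=3
        sp = ["a", "b", "c"]
        juv = np.zeros((3, 2))
        adu = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        traj = _traj(sp, juv, adu)
        data = _dummy_data(sp)
        res = d_test(data, None, traj, config=RunConfig(seed=0, n_permutations=99))
        assert res.D_j == 0.0
        assert res.D_a == pytest.approx(3.0)
        assert res.D == pytest.approx(-3.0)
        assert res.D == res.D_j - res.D_a

    def test_identical_stages_give_zero(self):
        sp = ["a", "b", "c"]
        pts = np.array([[0.0, 0], [1, 1], [2, 0]])
        res = d_test(_dummy_data(sp), None, _traj(sp, pts, pts),
                     config=RunConfig(seed=0, n_permutations=49))
        assert res.D == 0.0

    def test_antisymmetric_under_stage_swap(self):
        rng = np.random.default_rng(1)
        sp = [f"s{i}" for i in range(5)]
        J, A = rng.normal(size=(2, 5, 3))
        r1 = d_test(_dummy_data(sp, q=3), None, _traj(sp, J, A),
                    config=RunConfig(seed=0, n_permutations=49))
        r2 = d_test(_dummy_data(sp, q=3), None, _traj(sp, A, J),
                    config=RunConfig(seed=0, n_permutations=49))
        assert r1.D == pytest.approx(-r2.D)

    def test_gated_on_host_rejection(self):
        sp = ["a", "b", "c"]
        traj = _traj(sp, np.zeros((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError, match="HOST"):
            d_test(_dummy_data(sp), None, traj, host_p=0.4,
                   config=RunConfig(seed=0))

    def test_divergence_fixture_detected(self):
        data = make_divergence_fixture(20, 5.0, seed=3)
        fit, traj = fit_unique_allometries(data)
        res = d_test(data, fit, traj, config=RunConfig(seed=3, n_permutations=499))
        assert res.D < 0
        assert res.p < 0.05

    def test_convergence_detected_with_negative_strength(self):
        data = make_divergence_fixture(20, -0.8, seed=4)
        fit, traj = fit_unique_allometries(data)
        res = d_test(data, fit, traj, config=RunConfig(seed=4, n_permutations=499))
        assert res.D > 0


class TestKMult:
    def test_star_tree_k_is_one(self):
        star = read_newick("(" + ",".join(f"t{i}:1" for i in range(9)) + ");")
        rng = np.random.default_rng(0)
        for q in (1, 4):
            K, _ = k_mult(star, rng.normal(size=(9, q)), n_permutations=9, rng=rng)
            assert K == pytest.approx(1.0, abs=1e-9)

    def test_univariate_matches_direct_formula(self):
        tree = simulate_pure_birth_tree(12, np.random.default_rng(2))
        y = simulate_bm_tips(tree, np.random.default_rng(3)).ravel()
        K, _ = k_mult(tree, y, n_permutations=9, rng=np.random.default_rng(0))
        # independent direct-formula oracle
        C = tree.vcv()
        N = len(y)
        Ci = np.linalg.inv(C)
        one = np.ones(N)
        a = (one @ Ci @ y) / (one @ Ci @ one)
        num = (y - a) @ (y - a)
        den = (y - a) @ Ci @ (y - a)
        expected = (num / den) / ((np.trace(C) - N / (one @ Ci @ one)) / (N - 1))
        assert K == pytest.approx(expected, abs=1e-9)

    def test_invariances(self):
        tree = simulate_pure_birth_tree(15, np.random.default_rng(4))
        X = simulate_bm_tips(tree, np.random.default_rng(5), q=3)
        K1, _ = k_mult(tree, X, n_permutations=9, rng=np.random.default_rng(0))
        scaled = tree.copy()
        for nd in scaled.preorder():
            if nd is not scaled.root:
                nd.length *= 3.7
        K2, _ = k_mult(scaled, X, n_permutations=9, rng=np.random.default_rng(0))
        K3, _ = k_mult(tree, X + 11.0, n_permutations=9, rng=np.random.default_rng(0))
        assert K1 == pytest.approx(K2, rel=1e-9)
        assert K1 == pytest.approx(K3, rel=1e-9)

    def test_signal_detected_under_bm(self):
        tree = simulate_pure_birth_tree(40, np.random.default_rng(6))
        X = simulate_bm_tips(tree, np.random.default_rng(7), q=4)
        _, p = k_mult(tree, X, n_permutations=499, rng=np.random.default_rng(0))
        assert p < 0.05


class TestDeltaK:
    def _setup(self, seed, adult_bm=True):
        tree = simulate_pure_birth_tree(30, np.random.default_rng(seed))
        sp = tree.tip_labels
        rngs = np.random.default_rng(seed + 1)
        adu = (simulate_bm_tips(tree, rngs, q=3) if adult_bm
               else rngs.normal(size=(30, 3)))
        juv = rngs.normal(size=(30, 3)) * 0.5
        data = _dummy_data(sp, n_per=20, q=3, seed=seed)
        # make specimen pool echo the stage contrast: half juvenile-like,
        # half adult-like
        for i, s in enumerate(sp):
            m = np.flatnonzero(data.species == s)
            data.Y[m[:10]] = juv[i] + rngs.normal(0, 0.3, (10, 3))
            data.Y[m[10:]] = adu[i] + rngs.normal(0, 0.3, (10, 3))
        return tree, data, _traj(sp, juv, adu)

    def test_identical_matrices_give_zero(self):
        tree = simulate_pure_birth_tree(10, np.random.default_rng(0))
        sp = tree.tip_labels
        pts = np.random.default_rng(1).normal(size=(10, 3))
        dK, Ka, Kj, _ = delta_k_test(
            tree, _dummy_data(sp, q=3), _traj(sp, pts, pts),
            RunConfig(seed=0, n_permutations=49),
        )
        assert dK == pytest.approx(0.0, abs=1e-12)
        assert Ka == pytest.approx(Kj)

    def test_bm_adults_noise_juveniles_positive(self):
        hits = 0
        for s in range(8):
            tree, data, traj = self._setup(100 + s)
            dK, _, _, p = delta_k_test(tree, data, traj,
                                       RunConfig(seed=s, n_permutations=199))
            hits += (dK > 0)
        assert hits >= 7


class TestPhyloManova:
    def test_perfect_size_dependence_hits_min_p(self):
        tree = simulate_pure_birth_tree(25, np.random.default_rng(0))
        size = np.random.default_rng(1).uniform(2, 5, 25)
        hab = np.array(simulate_markov_habitat(tree, np.random.default_rng(2)))
        resp = np.column_stack([size, 2 * size])
        res = phylo_manova(tree, resp, size, hab,
                           config=RunConfig(seed=0, n_permutations=199))
        p_size = res.loc[res["term"] == "size", "p"].iloc[0]
        assert p_size == pytest.approx(1.0 / 200.0)

    def test_constant_response_rejected(self):
        tree = simulate_pure_birth_tree(10, np.random.default_rng(3))
        size = np.random.default_rng(4).uniform(2, 5, 10)
        hab = np.array(["terrestrial"] * 5 + ["trunk"] * 5)
        with pytest.raises(ValueError, match="zero variance"):
            phylo_manova(tree, np.ones((10, 3)), size, hab,
                         config=RunConfig(seed=0, n_permutations=49))


class TestPhylomorphospace:
    def test_two_tip_root_at_midpoint(self):
        t = read_newick("(A:1,B:1);")
        nodes, edges = phylomorphospace(t, np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert nodes.loc["node0"].to_numpy() == pytest.approx([1.0, 0.0])
        assert len(edges) == 2

    def test_root_equals_gls_mean(self):
        tree = simulate_pure_birth_tree(12, np.random.default_rng(5))
        X = simulate_bm_tips(tree, np.random.default_rng(6), q=2)
        nodes, _ = phylomorphospace(tree, X)
        C = tree.vcv()
        Ci = np.linalg.inv(C)
        one = np.ones(12)
        a = (one @ Ci @ X) / (one @ Ci @ one)
        assert nodes.loc["node0"].to_numpy() == pytest.approx(a, abs=1e-9)

    def test_degenerate_all_tips_equal(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        nodes, _ = phylomorphospace(t, np.tile([1.5, -0.5], (3, 1)))
        assert np.allclose(nodes.to_numpy(), [1.5, -0.5])
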