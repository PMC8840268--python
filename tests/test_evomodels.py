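"""Evolutionary model fits: closed-form oracles, limiting cases, AICc."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ontotraj.evomodels import (
    SympatryStructure,
    aicc,
    compare_models,
    fit_gauss_model,
    fit_interaction_model,
)
from ontotraj.simulate import simulate_bm_tips, simulate_pure_birth_tree
from ontotraj.trees import read_newick, read_painted_tree

TREE3 = "((A:1,B:1):1,C:2);"
Y3 = np.array([0.0, 1.0, 4.0])


class TestGaussModels:
    def test_bm_matches_hand_built_gaussian_density(self):
        t = read_newick(TREE3)
        fit = fit_gauss_model(t, Y3, "BM", tip_labels=["A", "B", "C"])
        C = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        s2, z0 = fit.parameters["sigma2"], fit.parameters["z0"]
        oracle = multivariate_normal(mean=np.full(3, z0), cov=s2 * C).logpdf(Y3)
        assert fit.logLik == pytest.approx(oracle, abs=1e-9)

    def test_bm_mle_maximizes_over_grid(self):
        t = read_newick(TREE3)
        fit = fit_gauss_model(t, Y3, "BM", tip_labels=["A", "B", "C"])
        C = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        for s2 in (0.5, 1.0, 2.0, 5.0):
            for z0 in (0.0, 1.0, 2.0):
                ll = multivariate_normal(np.full(3, z0), s2 * C).logpdf(Y3)
                assert ll <= fit.logLik + 1e-9

    def test_ou_alpha_to_zero_recovers_bm(self):
        t = read_newick(TREE3)
        bm = fit_gauss_model(t, Y3, "BM", tip_labels=["A", "B", "C"])
        ou = fit_gauss_model(t, Y3, "OU", tip_labels=["A", "B", "C"],
                             fixed={"alpha": 1e-8})
        assert ou.logLik == pytest.approx(bm.logLik, abs=1e-6)

    def test_eb_r_zero_equals_bm(self):
        t = read_newick(TREE3)
        bm = fit_gauss_model(t, Y3, "BM", tip_labels=["A", "B", "C"])
        eb = fit_gauss_model(t, Y3, "EB", tip_labels=["A", "B", "C"],
                             fixed={"r": 0.0})
        assert eb.logLik == pytest.approx(bm.logLik, abs=1e-12)

    def test_likelihood_invariant_to_tip_order(self):
        tree = simulate_pure_birth_tree(12, np.random.default_rng(0))
        y = simulate_bm_tips(tree, np.random.default_rng(1)).ravel()
        labels = tree.tip_labels
        f1 = fit_gauss_model(tree, y, "BM", tip_labels=labels)
        order = np.random.default_rng(2).permutation(len(labels))
        f2 = fit_gauss_model(tree, y[order], "BM",
                             tip_labels=[labels[i] for i in order])
        assert f1.logLik == pytest.approx(f2.logLik, abs=1e-10)

    def test_bms_single_painting_matches_bm(self):
        pt = read_painted_tree(
            "((A:1[&paint={x:1}],B:1[&paint={x:1}]):1[&paint={x:1}],"
            "C:2[&paint={x:2}]);"
        )
        bm = fit_gauss_model(pt, Y3, "BM", tip_labels=["A", "B", "C"])
        bms = fit_gauss_model(pt, Y3, "BMS", tip_labels=["A", "B", "C"])
        assert bms.logLik == pytest.approx(bm.logLik, abs=1e-6)

    def test_oum_beats_ou_on_two_optima_data(self):
        rng = np.random.default_rng(3)
        tree = simulate_pure_birth_tree(24, rng, support=None)
        # paint half the tips' pendant branches a second regime
        tips = tree.tips()
        for nd in tree.preorder():
            if nd is not tree.root:
                nd.paint = [("r1", nd.length)]
        for t in tips[:12]:
            t.paint = [("r2", t.length)]
        y = np.array([5.0 if t.paint[0][0] == "r2" else -5.0 for t in tips])
        y += rng.normal(0, 0.3, 24)
        ou = fit_gauss_model(tree, y, "OU")
        oum = fit_gauss_model(tree, y, "OUM")
        assert oum.logLik > ou.logLik + 5

    def test_bm_sigma2_recovery(self):
        tree = simulate_pure_birth_tree(100, np.random.default_rng(7))
        errs = []
        for r in range(50):
            y = simulate_bm_tips(tree, np.random.default_rng(500 + r),
                                 sigma2=2.0).ravel()
            f = fit_gauss_model(tree, y, "BM")
            errs.append(abs(f.parameters["sigma2"] - 2.0) / 2.0)
        assert np.median(errs) < 0.15


@pytest.fixture(scope="module")
def tree_and_trait():
    tree = simulate_pure_birth_tree(15, np.random.default_rng(2))
    y = simulate_bm_tips(tree, np.random.default_rng(3), sigma2=2.0).ravel()
    return tree, y


class TestInteractionModels:

    @pytest.mark.parametrize("model,fixed", [
        ("MC", {"S": 0.0}), ("DDl", {"b": 0.0}), ("DD2", {"b": 0.0}),
    ])
    def test_reduces_to_bm(self, tree_and_trait, model, fixed):
        tree, y = tree_and_trait
        bm = fit_gauss_model(tree, y, "BM")
        f = fit_interaction_model(tree, y, model, fixed=fixed)
        assert f.logLik == pytest.approx(bm.logLik, abs=1e-4)

    def test_nonultrametric_rejected(self):
        t = read_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            fit_interaction_model(t, np.array([0.0, 1, 2]), "MC",
                                  tip_labels=["A", "B", "C"])

    def test_mc_attraction_shrinks_tip_variance(self):
        tree = simulate_pure_birth_tree(10, np.random.default_rng(4))
        from ontotraj.evomodels import _mc_V1
        V0 = _mc_V1(tree, 0.0, None)
        V5 = _mc_V1(tree, -5.0, None)
        assert np.all(np.diag(V5) < np.diag(V0) + 1e-12)
        assert np.allclose(V0, tree.vcv(), atol=1e-10)

    def test_sympatry_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            SympatryStructure(["a", "b"], np.array([[1.0, 1], [0, 1]]))
        with pytest.raises(ValueError, match="diagonal"):
            SympatryStructure(["a", "b"], np.array([[0.0, 1], [1, 1]]))

    def test_allopatric_mc_reduces_to_bm(self, tree_and_trait):
        tree, y = tree_and_trait
        n = tree.n_tips
        sym = SympatryStructure(tree.tip_labels, np.eye(n))
        bm = fit_gauss_model(tree, y, "BM")
        f = fit_interaction_model(tree, y, "MC", sympatry=sym, fixed={"S": -3.0})
        assert f.logLik == pytest.approx(bm.logLik, abs=1e-4)


class TestComparison:
    def test_aicc_hand_value(self):
        assert aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-5.0, 2, 3)

    def test_equal_aicc_gives_equal_weights(self):
        from ontotraj.evomodels import ModelFit
        f1 = ModelFit("BM", {}, -5, 2, 10, 20.0, data_fingerprint=1.0)
        f2 = ModelFit("OU", {}, -5, 3, 10, 20.0, data_fingerprint=1.0)
        tab = compare_models([f1, f2])
        assert np.allclose(tab["AICcw"], 0.5)

    def test_two_point_weights(self):
        from ontotraj.evomodels import ModelFit
        f1 = ModelFit("BM", {}, 0, 2, 10, 10.0, data_fingerprint=1.0)
        f2 = ModelFit("OU", {}, 0, 3, 10, 12.0, data_fingerprint=1.0)
        tab = compare_models([f1, f2]).set_index("model")
        assert tab.loc["BM", "AICcw"] == pytest.approx(0.731, abs=1e-3)
        assert tab.loc["OU", "AICcw"] == pytest.approx(0.269, abs=1e-3)

    def test_mixed_data_rejected(self):
        from ontotraj.evomodels import ModelFit
        f1 = ModelFit("BM", {}, 0, 2, 10, 10.0, data_fingerprint=1.0)
        f2 = ModelFit("OU", {}, 0, 3, 10, 12.0, data_fingerprint=2.0)
        with pytest.raises(ValueError, match="different data"):
            compare_models([f1, f2])

    def test_bm_ranked_first_under_bm_data(self):
        wins = 0
        reps = 20
        tree = simulate_pure_birth_tree(60, np.random.default_rng(8))
        for r in range(reps):
            y = simulate_bm_tips(tree, np.random.default_rng(900 + r)).ravel()
            fits = [fit_gauss_model(tree, y, m) for m in ("BM", "OU", "EB")]
            tab = compare_models(fits)
            wins += tab.iloc[0]["model"] == "BM"
        assert wins > reps / 2
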