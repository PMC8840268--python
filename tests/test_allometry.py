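"""Trajectory fitting and comparison: isometry, HOST, pairwise tests,
intercepts, hierarchical partitioning, per-trait ontogenetic shifts."""

import numpy as np
import pandas as pd
import pytest

from ontotraj.config import RunConfig
from ontotraj.allometry import (
    fit_unique_allometries,
    hier_part,
    host_test,
    intercept_test,
    intercept_tests,
    isometry_test,
    ontogenetic_shift_table,
    pairwise_trajectories,
)
from ontotraj.morphometry import ShapeData


def _data(groups, q=2):
    """groups: list of (label, sizes, Y)"""
    Y = np.vstack([g[2] for g in groups])
    size = np.concatenate([g[1] for g in groups])
    species = np.concatenate([[g[0]] * len(g[1]) for g in groups])
    return ShapeData(Y=Y, size=size, species=species, sex=np.array(["M"] * len(size)))


class TestFitUniqueAllometries:
    def test_exact_line_hand_ols(self):
        sizes = np.array([1.0, 2.0, 3.0])
        Y = np.column_stack([np.array([0.0, 1.0, 2.0]), np.zeros(3)])
        data = _data([("a", sizes, Y)])
        fit, traj = fit_unique_allometries(data)
        assert fit.slopes[0] == pytest.approx([1.0, 0.0])
        assert fit.intercepts[0] == pytest.approx([-1.0, 0.0])
        assert traj.lengths[0] == pytest.approx(2.0)  # ||yhat(3) - yhat(1)||

    def test_constant_shape_zero_trajectory(self):
        sizes = np.array([1.0, 2.0, 3.0, 4.0])
        data = _data([("a", sizes, np.ones((4, 3)))], q=3)
        fit, traj = fit_unique_allometries(data)
        assert np.allclose(fit.slopes, 0.0)
        assert traj.lengths[0] == 0.0

    def test_noiseless_recovery(self, noiseless_sim):
        fit, _ = fit_unique_allometries(noiseless_sim.shape)
        truth = noiseless_sim.truth
        idx = [truth.species.index(s) for s in fit.species]
        assert np.max(np.abs(fit.slopes - truth.slopes[idx])) < 1e-10
        assert np.max(np.abs(fit.intercepts - truth.intercepts[idx])) < 1e-10

    def test_predictions_match_ols_fitted_values(self, noisy_sim):
        data = noisy_sim.shape
        fit, _ = fit_unique_allometries(data)
        sp = fit.species[0]
        m = data.species == sp
        X = np.column_stack([np.ones(m.sum()), data.size[m]])
        beta = np.linalg.lstsq(X, data.Y[m], rcond=None)[0]
        for s in (data.size[m].min(), data.size[m].max()):
            assert np.allclose(
                fit.predict(sp, s), beta[0] + beta[1] * s, atol=1e-10
            )

    def test_length_invariant_to_size_shift(self, noisy_sim):
        data = noisy_sim.shape
        _, t1 = fit_unique_allometries(data)
        shifted = ShapeData(
            Y=data.Y, size=data.size + 7.3, species=data.species, sex=data.sex
        )
        _, t2 = fit_unique_allometries(shifted)
        assert np.allclose(t1.lengths, t2.lengths, atol=1e-9)

    def test_constant_size_rejected(self):
        data = _data([("a", np.ones(5), np.random.default_rng(0).normal(size=(5, 2)))])
        with pytest.raises(ValueError, match="singular"):
            fit_unique_allometries(data)


class TestIsometryAndHost:
    def test_constant_shape_is_isometric(self):
        rng = np.random.default_rng(0)
        data = _data([("a", rng.uniform(0, 1, 10), np.ones((10, 2)))])
        p, r2, F = isometry_test(data, "a", RunConfig(seed=0, n_permutations=99))
        assert p == 1.0
        assert r2 == pytest.approx(0.0)

    def test_strong_allometry_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.uniform(0, 1, 30)
            Y = np.outer(x, [1.0, 0.5]) + rng.normal(0, 0.05, (30, 2))
            data = _data([("a", x, Y)])
            p, _, _ = isometry_test(data, "a", RunConfig(seed=s, n_permutations=999))
            hits += p <= 0.001
        assert hits == 20

    def test_host_null_noiseless_identical_slopes(self):
        x1 = np.linspace(0, 1, 10)
        x2 = np.linspace(0.2, 1.2, 10)
        b = np.array([1.0, -0.5])
        data = _data([("a", x1, np.outer(x1, b)), ("b", x2, np.outer(x2, b))])
        res = host_test(data, config=RunConfig(seed=0, n_permutations=199))
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.p > 0.5

    def test_host_detects_orthogonal_slopes(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            x1, x2 = rng.uniform(0, 1, (2, 30))
            d1 = np.outer(x1, [1.0, 0.0]) + rng.normal(0, 0.1, (30, 2))
            d2 = np.outer(x2, [0.0, 1.0]) + rng.normal(0, 0.1, (30, 2))
            data = _data([("a", x1, d1), ("b", x2, d2)])
            res = host_test(data, config=RunConfig(seed=s, n_permutations=499))
            hits += res.p < 0.01
        assert hits >= 9

    def test_single_specimen_species_rejected(self):
        data = _data(
            [("a", np.array([1.0, 2.0]), np.zeros((2, 2))),
             ("b", np.array([1.5]), np.zeros((1, 2)))]
        )
        with pytest.raises(ValueError, match="single specimen"):
            host_test(data)


class TestPairwise:
    def _three_species(self, seed=0, noise=0.02):
        rng = np.random.default_rng(seed)
        b1 = np.array([1.0, 0.0, 0.0])
        b2 = np.array([np.sqrt(2) / 2, np.sqrt(2) / 2, 0.0])
        groups = []
        for name, b in [("a", b1), ("b", b2), ("c", b1)]:
            x = rng.uniform(0, 1, 40)
            groups.append((name, x, np.outer(x, b) + rng.normal(0, noise, (40, 3))))
        return _data(groups, q=3)

    def test_angle_geometry(self):
        data = self._three_species(noise=0.0)
        ang, lng = pairwise_trajectories(data, RunConfig(seed=0, n_permutations=99))
        assert ang.statistic[0, 1] == pytest.approx(45.0, abs=1e-8)
        assert np.allclose(ang.statistic, ang.statistic.T)
        assert np.allclose(np.diag(ang.statistic), 0.0)
        assert np.all((ang.statistic >= 0) & (ang.statistic <= 180))
        assert np.allclose(np.diag(lng.statistic), 0.0)

    def test_same_trajectory_not_significant(self):
        ps_ang, ps_len = [], []
        for s in range(15):
            rng = np.random.default_rng(100 + s)
            b = np.array([1.0, 0.5])
            g = []
            for name in ("a", "b"):
                x = rng.uniform(0, 1, 30)
                g.append((name, x, np.outer(x, b) + rng.normal(0, 0.05, (30, 2))))
            ang, lng = pairwise_trajectories(
                _data(g), RunConfig(seed=s, n_permutations=199)
            )
            ps_ang.append(ang.p[0, 1])
            ps_len.append(lng.p[0, 1])
        assert np.mean(np.asarray(ps_ang) < 0.05) <= 0.25
        assert np.mean(np.asarray(ps_len) < 0.05) <= 0.25

    def test_distinct_slopes_detected(self):
        data = self._three_species(seed=3)
        ang, _ = pairwise_trajectories(data, RunConfig(seed=3, n_permutations=499))
        assert ang.p[0, 1] < 0.05  # 45 degrees apart
        assert ang.p[0, 2] > 0.05  # same direction


class TestIntercept:
    def test_pseudo_species_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 60)
        Y = np.outer(x, [1.0, 0.3]) + rng.normal(0, 0.05, (60, 2))
        data = _data([("a", x[:30], Y[:30]), ("b", x[30:], Y[30:])])
        d, p = intercept_test(data, ("a", "b"), RunConfig(seed=0, n_permutations=199))
        assert d < 0.05
        assert p > 0.2

    def test_parallel_offset_detected(self):
        rng = np.random.default_rng(1)
        b = np.array([1.0, 0.0])
        off = np.array([0.0, 0.5])  # 10 noise SD, orthogonal
        x1, x2 = rng.uniform(0, 1, (2, 30))
        data = _data(
            [("a", x1, np.outer(x1, b) + rng.normal(0, 0.05, (30, 2))),
             ("b", x2, off + np.outer(x2, b) + rng.normal(0, 0.05, (30, 2)))]
        )
        d, p = intercept_test(data, ("a", "b"), RunConfig(seed=1, n_permutations=499))
        assert p < 0.01

    def test_refuses_heterogeneous_pair(self):
        data = _data(
            [
                ("a", np.linspace(0, 1, 30),
                 np.outer(np.linspace(0, 1, 30), [1.0, 0.0])),
                ("b", np.linspace(0, 1, 30),
                 np.outer(np.linspace(0, 1, 30), [0.0, 1.0])),
            ]
        )
        ang, _ = pairwise_trajectories(data, RunConfig(seed=0, n_permutations=199))
        with pytest.raises(ValueError, match="heterogeneous"):
            intercept_tests(data, [("a", "b")], angle_p=ang,
                            config=RunConfig(seed=0, n_permutations=99))


class TestHierPart:
    def test_independent_effects_sum_to_full_r2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["angle", "len", "int"])
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.5, 40)
        table, full = hier_part(y, X)
        assert table["independent"].sum() == pytest.approx(full, abs=1e-10)

    def test_pure_signal_predictor_dominates(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["angle", "len", "int"])
        y = X["angle"].to_numpy()
        table, _ = hier_part(y, X)
        assert table.loc["angle", "independent_pct"] > 90.0

    def test_constant_predictor_warns_and_zeroes(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"angle": rng.normal(size=30), "len": rng.normal(size=30),
             "int": np.ones(30)}
        )
        y = X["angle"].to_numpy() + rng.normal(0, 0.1, 30)
        with pytest.warns(UserWarning, match="constant"):
            table, _ = hier_part(y, X)
        assert table.loc["int", "independent"] == pytest.approx(0.0, abs=1e-10)


class TestShiftTable:
    def test_constructed_tail_shift_proportion(self):
        # 14 species, 11 with negative tail slope: proportion 78.57%
        rng = np.random.default_rng(0)
        groups = []
        signs = [-1.0] * 11 + [1.0] * 3
        for i, sg in enumerate(signs):
            x = rng.uniform(0, 1, 25)
            b = np.array([sg * 0.8, 0.4])
            groups.append(
                (f"s{i:02d}", x, np.outer(x, b) + rng.normal(0, 0.03, (25, 2)))
            )
        data = _data(groups)
        fit, _ = fit_unique_allometries(data)
        tab = ontogenetic_shift_table(
            data, fit, trait_index=0, config=RunConfig(seed=0, n_permutations=199)
        )
        prop = (tab["change"] == "decreases").mean() * 100
        assert prop == pytest.approx(78.57, abs=0.01)

    def test_zero_slope_is_isometric(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 20)
        data = _data([("a", x, rng.normal(0, 0.1, (20, 2)))])
        fit, _ = fit_unique_allometries(data)
        tab = ontogenetic_shift_table(data, fit, config=RunConfig(seed=1, n_permutations=199))
        assert set(tab["change"]) == {"isometric"}

    def test_out_of_range_trait_rejected(self, noisy_sim):
        fit, _ = fit_unique_allometries(noisy_sim.shape)
        with pytest.raises(IndexError):
            ontogenetic_shift_table(noisy_sim.shape, fit, trait_index=99)
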