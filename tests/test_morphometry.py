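"""Shape extraction: log-shape ratios, GPA, sliding, symmetry, dimorphism."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ontotraj.config import RunConfig
from ontotraj.morphometry import (
    LandmarkBlock,
    LinearTable,
    ShapeData,
    centroid_size,
    dimorphism_filter,
    gpa,
    log_shape_ratios,
    opa_align,
    slide_displacements,
    slide_semilandmarks,
    symmetric_component,
)
from ontotraj.simulate import make_landmark_block
from ontotraj.tps import bending_energy, bending_energy_matrix


def _lin(traits, species=None, sex=None):
    n = len(next(iter(traits.values())))
    return LinearTable(
        specimen_id=np.array([f"s{i}" for i in range(n)]),
        species=np.array(species or ["sp"] * n),
        sex=np.array(sex or ["M"] * n),
        traits=pd.DataFrame(traits),
    )


class TestLogShapeRatios:
    def test_two_trait_hand_example(self):
        (sd,) = log_shape_ratios(_lin({"t1": [2.0], "t2": [8.0]}))
        assert sd.size[0] == pytest.approx(np.log(4.0))
        assert sd.Y[0] == pytest.approx([np.log(0.5), np.log(2.0)])

    def test_equal_traits_give_zero_shape(self):
        (sd,) = log_shape_ratios(_lin({"t1": [5.0, 5.0], "t2": [5.0, 5.0]}))
        assert np.allclose(sd.Y, 0.0)
        assert np.allclose(sd.size, np.log(5.0))

    def test_zero_trait_rejected(self):
        with pytest.raises(ValueError):
            _lin({"t1": [0.0], "t2": [1.0]})

    def test_rowwise_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        (sd,) = log_shape_ratios(
            _lin({f"t{j}": rng.uniform(1, 50, 20) for j in range(5)})
        )
        gm = np.exp(sd.Y).prod(axis=1) ** (1 / 5)
        assert np.allclose(gm, 1.0, atol=1e-9)

    def test_combined_size_uses_both_tables(self):
        body = _lin({"t1": [2.0], "t2": [2.0]})
        limbs = _lin({"u1": [8.0], "u2": [8.0]})
        b, l = log_shape_ratios(body, limbs)
        assert b.size[0] == pytest.approx(np.log(4.0))  # GM of (2,2,8,8)
        assert l.size[0] == pytest.approx(np.log(4.0))


def _block(confs, **kw):
    n = confs.shape[0]
    return LandmarkBlock(
        specimen_id=np.array([f"s{i}" for i in range(n)]),
        species=np.array(["sp"] * n),
        sex=np.array(["M"] * n),
        coords=confs,
        **kw,
    )


class TestGpa:
    def test_rigid_motion_removed(self):
        tri = np.array([[0.0, 0], [3, 0], [3, 4]])
        R = np.array([[0.0, -1], [1, 0]])
        blk = _block(np.stack([tri, tri @ R.T + [5.0, 7.0]]))
        al, cs = gpa(blk)
        assert np.max(np.abs(al.coords[0] - al.coords[1])) < 1e-10
        assert cs[0] == pytest.approx(centroid_size(tri))

    def test_centroid_size_by_hand(self):
        tri = np.array([[0.0, 0], [3, 0], [3, 4]])
        c = tri.mean(axis=0)
        assert centroid_size(tri) == pytest.approx(
            np.sqrt(np.sum((tri - c) ** 2))
        )

    def test_two_specimen_matches_svd_superimposition(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(2, 6, 2))
        al, _ = gpa(_block(np.stack([A, B])))
        a0 = (A - A.mean(0)) / centroid_size(A)
        b0 = (B - B.mean(0)) / centroid_size(B)
        d_oracle = np.sum((a0 - opa_align(a0, b0)) ** 2)
        d_gpa = np.sum((al.coords[0] - al.coords[1]) ** 2)
        assert d_gpa == pytest.approx(d_oracle, abs=1e-9)

    def test_invariant_to_input_transforms_and_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 8, 2))
        al1, _ = gpa(_block(X))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        X2 = np.array([3.0 * x @ R.T + [1, -2] for x in X])
        al2, _ = gpa(_block(X2))
        assert np.allclose(al1.coords, al2.coords, atol=1e-8)
        order = [3, 1, 4, 0, 2]
        al3, _ = gpa(_block(X[order]))
        assert np.allclose(al1.coords[order], al3.coords, atol=1e-8)

    def test_degenerate_rejected(self):
        X = np.zeros((2, 4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            gpa(_block(X))


class TestSliding:
    def test_no_sliders_is_identity(self):
        blk = make_landmark_block(5, np.random.default_rng(0))
        blk.slider_triples = []
        out = slide_semilandmarks(blk)
        assert out is blk

    def test_matches_grid_search_single_semilandmark(self):
        mean = np.array([[0.0, 0], [0.5, 0.02], [1, 0], [0.2, 1], [0.8, 1]])
        conf = mean.copy()
        conf[1] = [0.62, 0.018]
        triples = [(0, 1, 2)]
        c = slide_displacements(conf, mean, triples)
        B = bending_energy_matrix(mean)
        t = conf[2] - conf[0]
        t = t / np.linalg.norm(t)

        def energy(cc):
            x = conf.copy()
            x[1] = conf[1] + cc * t
            d = x - mean
            return d[:, 0] @ B @ d[:, 0] + d[:, 1] @ B @ d[:, 1]

        grid = np.linspace(-0.5, 0.5, 2001)
        g0 = grid[int(np.argmin([energy(g) for g in grid]))]
        res = minimize_scalar(energy, bounds=(g0 - 0.01, g0 + 0.01), method="bounded")
        assert c[0] == pytest.approx(res.x, abs=1e-4)

    def test_bending_energy_non_increasing(self):
        blk = make_landmark_block(8, np.random.default_rng(2), warp_sd=0.05)
        al, _ = gpa(blk)
        before = sum(bending_energy(al.coords.mean(0), c) for c in al.coords)
        sl = slide_semilandmarks(al)
        after = sum(bending_energy(sl.coords.mean(0), c) for c in sl.coords)
        assert after <= before + 1e-10

    def test_coincident_neighbors_rejected(self):
        conf = np.array([[0.0, 0], [0.5, 0.1], [0.0, 0], [1, 1]])
        blk = _block(conf[None].repeat(2, axis=0), slider_triples=[(0, 1, 2)])
        with pytest.raises(ValueError, match="slider landmark 1"):
            slide_semilandmarks(blk)


class TestSymmetry:
    def test_symmetric_configuration_is_fixed_point(self):
        conf = np.array(
            [[0.0, 0], [0, 1], [-0.5, 0.5], [0.5, 0.5], [-0.3, 0.9], [0.3, 0.9]]
        )
        blk = _block(
            np.stack([conf, conf]),
            symmetry_pairs=[(2, 3), (4, 5)],
            midline_idx=np.array([0, 1]),
        )
        out = symmetric_component(blk)
        al, _ = gpa(blk)
        assert np.allclose(out.coords, al.coords, atol=1e-10)

    def test_hand_averaged_pair(self):
        # pair at (±1, 0.9/1.1), y-axis midline: pure reflect+relabel+average
        # puts the pair at (±1, 1.0) exactly
        conf = np.array([[0.0, 0], [0, 2], [-1.0, 0.9], [1.0, 1.1]])
        relabel = np.array([0, 1, 3, 2])
        refl = (conf * [-1.0, 1.0])[relabel]
        avg = 0.5 * (conf + refl)
        assert np.allclose(avg[2], [-1.0, 1.0])
        assert np.allclose(avg[3], [1.0, 1.0])

    def test_output_exactly_symmetric(self):
        blk = make_landmark_block(6, np.random.default_rng(3), warp_sd=0.05)
        out = symmetric_component(blk)
        relabel = np.arange(out.coords.shape[1])
        for a, b in out.symmetry_pairs:
            relabel[a], relabel[b] = b, a
        for conf in out.coords:
            refl = opa_align(conf, (conf * [-1.0, 1.0])[relabel])
            assert np.max(np.abs(refl - conf)) < 1e-9

    def test_unpaired_landmark_rejected(self):
        conf = np.random.default_rng(0).normal(size=(2, 5, 2))
        blk = _block(conf, symmetry_pairs=[(2, 3)], midline_idx=np.array([0, 1]))
        with pytest.raises(ValueError, match="unpaired"):
            symmetric_component(blk)


class TestDimorphismFilter:
    def _species(self, rng, n, offset, q=4):
        sex = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2))
        Y = rng.normal(0, 1, (n, q))
        Y[sex == "F"] += offset
        return ShapeData(
            Y=Y, size=rng.uniform(0, 1, n), species=np.array(["sp"] * n), sex=sex
        )

    def test_single_sex_passthrough(self):
        rng = np.random.default_rng(0)
        data = ShapeData(
            Y=rng.normal(size=(10, 3)),
            size=rng.uniform(size=10),
            species=np.array(["sp"] * 10),
            sex=np.array(["M"] * 10),
        )
        out, report = dimorphism_filter(data, RunConfig(seed=0, n_permutations=99))
        assert out.Y.shape == data.Y.shape
        assert not report["females_removed"].any()

    def test_strong_dimorphism_removes_females(self):
        rng = np.random.default_rng(1)
        removed = 0
        for s in range(10):
            data = self._species(np.random.default_rng(s), 30, 3.0)
            out, report = dimorphism_filter(
                data, RunConfig(seed=s, n_permutations=199)
            )
            removed += report["females_removed"].iloc[0]
            if report["females_removed"].iloc[0]:
                assert "F" not in set(np.asarray(out.sex))
        assert removed == 10

    def test_null_removal_rate_near_alpha(self):
        hits = 0
        reps = 120
        for s in range(reps):
            data = self._species(np.random.default_rng(1000 + s), 30, 0.0)
            _, report = dimorphism_filter(data, RunConfig(seed=s, n_permutations=199))
            hits += int(report["females_removed"].iloc[0])
        assert abs(hits / reps - 0.05) < 0.05
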