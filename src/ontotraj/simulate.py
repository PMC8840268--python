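"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates museum ontogenetic series: a pure-birth time tree;
species-level allometric slope and intercept vectors evolving on it under
Brownian motion or an Ornstein-Uhlenbeck process; discrete habitat use
evolving under a symmetric Markov process with an optional juvenile->adult
habitat shift in a fixed fraction of species; per-specimen sizes uniform
over a species-specific log-size range, shapes linear in size plus
isotropic Gaussian noise; and, optionally, 2D landmark configurations
produced by thin-plate-spline warping of a bilaterally symmetric template.

Slope and intercept vectors are projected onto the zero-sum subspace so the
simulated shape variables behave like log-shape ratios (each specimen's
ratios multiply to one up to noise), which makes noiseless series exactly
recoverable by the allometric fitting step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import LandmarkBlock, LinearTable, ShapeData
from .tps import tps_warp
from .trees import Node, Phylogeny

__all__ = [
    "SimSpec",
    "SimTruth",
    "SimOutput",
    "HeterochronyFixture",
    "simulate",
    "simulate_pure_birth_tree",
    "simulate_bm_tips",
    "simulate_markov_habitat",
    "simulate_clade_rate_shift",
    "make_heterochrony_fixtures",
    "make_divergence_fixture",
    "make_landmark_block",
]

HABITATS = ("amphibious", "canopy", "cryptic", "escarpment", "terrestrial", "trunk")


@dataclass
class SimSpec:
    """Study conditions for the generator.

    Defaults reflect the kind of sampling the pipeline targets: a few dozen
    species, ontogenetic series of ~30 specimens, shape described by a
    handful of log-shape-ratio variables, sizes spanning roughly a 3-fold
    (1.1 natural-log units) ontogenetic range, and shape noise small
    relative to ontogenetic change.
    """

    n_species: int = 30
    n_specimens_per_species: tuple = (20, 40)
    q_traits: int = 6
    tree_model: str = "pure-birth"
    trait_model: str = "BM"  # slopes/intercepts: BM or OU
    slope_root_sd: float = 0.15
    slope_bm_rate: float = 0.01  # per unit tree height
    intercept_bm_rate: float = 0.04
    ou_alpha: float = 2.0
    size_base_range: tuple = (2.5, 4.5)  # ln mm, species minimum size
    size_span_range: tuple = (0.8, 1.5)  # ontogenetic ln-size span
    noise_sd: float = 0.05
    habitat_rate: float = 1.0  # total leave rate per unit tree height
    shift_fraction: float = 0.2
    emit_landmarks: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        lo, hi = self.n_specimens_per_species
        if lo < 1 or hi < lo:
            raise ValueError("invalid n_specimens_per_species range")
        if self.q_traits < 2:
            raise ValueError("q_traits must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must lie in [0, 1]")
        if self.tree_model != "pure-birth":
            raise ValueError("only the pure-birth tree model is supported")
        if self.trait_model not in ("BM", "OU"):
            raise ValueError("trait_model must be BM or OU")


@dataclass
class SimTruth:
    tree: Phylogeny
    species: list
    slopes: np.ndarray
    intercepts: np.ndarray
    size_ranges: np.ndarray
    adult_habitat: list
    juvenile_habitat: list
    rate_multipliers: dict = field(default_factory=dict)


@dataclass
class SimOutput:
    shape: ShapeData
    linear: LinearTable
    landmarks: LandmarkBlock | None
    habitat: pd.DataFrame
    tree: Phylogeny
    truth: SimTruth


def simulate_pure_birth_tree(
    n_tips: int,
    rng: np.random.Generator,
    height: float = 1.0,
    support: float | None = None,
) -> Phylogeny:
    """Pure-birth (Yule) tree rescaled to the requested height.

    If ``support`` is given, every internal node receives that posterior
    support value (used by robustness analyses that constrain monophyly of
    well-supported nodes)."""
    root = Node()
    tips = [root.add(Node()), root.add(Node())]
    t = 0.0
    time_of = {root: 0.0}
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        k = rng.integers(len(tips))
        parent = tips[k]
        time_of[parent] = t
        kids = [parent.add(Node()), parent.add(Node())]
        tips[k] = kids[0]
        tips.append(kids[1])
    t_end = t + rng.exponential(1.0 / len(tips))
    scale = height / t_end
    stack = [root]
    label_counter = 0
    while stack:
        nd = stack.pop()
        for c in nd.children:
            tc = time_of.get(c, t_end)
            c.length = (tc - time_of[nd]) * scale
            stack.append(c)
        if not nd.children:
            label_counter += 1
            nd.label = f"sp{label_counter:03d}"
        elif support is not None and nd is not root:
            nd.support = support
    return Phylogeny(root)


def simulate_bm_tips(
    tree: Phylogeny,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    q: int = 1,
    root_state=None,
    alpha: float = 0.0,
    rate_multiplier: dict | None = None,
) -> np.ndarray:
    """Simulate q traits at the tips under BM (alpha = 0) or OU toward the
    root state; optional per-node rate multipliers (inherited by clades)."""
    vals: dict[Node, np.ndarray] = {}
    x0 = np.zeros(q) if root_state is None else np.asarray(root_state, float)
    vals[tree.root] = x0
    mult: dict[Node, float] = {tree.root: 1.0}
    rate_multiplier = rate_multiplier or {}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        mult[nd] = rate_multiplier.get(nd, mult[nd.parent])
        s2 = sigma2 * mult[nd]
        t = nd.length
        prev = vals[nd.parent]
        if alpha > 0:
            ew = np.exp(-alpha * t)
            var = s2 * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)
            vals[nd] = x0 + (prev - x0) * ew + rng.normal(0, np.sqrt(var), q)
        else:
            vals[nd] = prev + rng.normal(0, np.sqrt(s2 * t), q)
    return np.array([vals[t] for t in tree.tips()])


def simulate_markov_habitat(
    tree: Phylogeny,
    rng: np.random.Generator,
    rate: float = 1.0,
    states=HABITATS,
    paint: bool = False,
) -> list:
    """Symmetric-rates Markov character history; returns tip states.

    With ``paint=True`` the realized history is written onto the tree as a
    regime painting (segments per branch, rootward to tipward)."""
    states = list(states)
    vals: dict[Node, str] = {tree.root: states[rng.integers(len(states))]}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        s = vals[nd.parent]
        t = nd.length
        segs = []
        clock = 0.0
        while True:
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if clock + wait >= t:
                segs.append((s, t - clock))
                break
            segs.append((s, wait))
            clock += wait
            s = states[
                (states.index(s) + 1 + rng.integers(len(states) - 1)) % len(states)
            ]
        vals[nd] = s
        if paint:
            nd.paint = segs
    return [vals[t] for t in tree.tips()]


def simulate_clade_rate_shift(
    tree: Phylogeny,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    multiplier: float = 10.0,
    min_clade: int = 6,
):
    """Simulate a univariate BM trait whose rate is multiplied inside one
    randomly chosen clade of at least ``min_clade`` tips. Returns
    (tip_values, clade_tip_labels)."""
    clades = [
        (nd, tips)
        for nd, tips in tree.clades(min_clade).items()
        if len(tips) <= tree.n_tips // 2
    ]
    if not clades:
        raise ValueError("no eligible clade for a rate shift")
    nd, tips = clades[rng.integers(len(clades))]
    y = simulate_bm_tips(
        tree, rng, sigma2=sigma2, q=1, rate_multiplier={nd: multiplier}
    ).ravel()
    return y, tips


def _zero_sum(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=-1, keepdims=True)


def simulate(spec: SimSpec) -> SimOutput:
    """Generate one synthetic study: tree, habitats, species trajectories,
    and individual ontogenetic series. Fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    tree = simulate_pure_birth_tree(spec.n_species, rng)
    species = tree.tip_labels
    S, q = spec.n_species, spec.q_traits

    alpha = spec.ou_alpha if spec.trait_model == "OU" else 0.0
    slope_root = _zero_sum(rng.normal(0.0, spec.slope_root_sd, q))
    slopes = simulate_bm_tips(
        tree, rng, sigma2=spec.slope_bm_rate, q=q, root_state=slope_root, alpha=alpha
    )
    intercepts = simulate_bm_tips(
        tree, rng, sigma2=spec.intercept_bm_rate, q=q, alpha=alpha
    )
    slopes = _zero_sum(slopes)
    intercepts = _zero_sum(intercepts)

    adult_hab = simulate_markov_habitat(tree, rng, spec.habitat_rate, paint=True)
    juv_hab = list(adult_hab)
    n_shift = int(round(spec.shift_fraction * S))
    shifters = rng.choice(S, size=n_shift, replace=False)
    for i in shifters:
        juv_hab[i] = "trunk" if adult_hab[i] != "trunk" else "canopy"

    s_lo = rng.uniform(*spec.size_base_range, S)
    span = rng.uniform(*spec.size_span_range, S)
    size_ranges = np.column_stack([s_lo, s_lo + span])

    rows_Y, rows_size, rows_sp, rows_sex, rows_id = [], [], [], [], []
    counts = rng.integers(
        spec.n_specimens_per_species[0], spec.n_specimens_per_species[1] + 1, S
    )
    for i, sp in enumerate(species):
        n_i = int(counts[i])
        sizes = rng.uniform(size_ranges[i, 0], size_ranges[i, 1], n_i)
        sizes[np.argmin(sizes)] = size_ranges[i, 0]
        sizes[np.argmax(sizes)] = size_ranges[i, 1]
        Y = intercepts[i] + np.outer(sizes, slopes[i])
        if spec.noise_sd > 0:
            Y = Y + rng.normal(0.0, spec.noise_sd, Y.shape)
        rows_Y.append(Y)
        rows_size.append(sizes)
        rows_sp.extend([sp] * n_i)
        rows_sex.extend(rng.choice(["M", "F"], n_i, p=[0.6, 0.4]))
        rows_id.extend([f"{sp}-{j + 1:03d}" for j in range(n_i)])

    Y = np.vstack(rows_Y)
    size = np.concatenate(rows_size)
    shape = ShapeData(
        Y=Y,
        size=size,
        species=np.array(rows_sp),
        sex=np.array(rows_sex),
        dataset_tag="synthetic",
        var_names=[f"trait{j + 1}" for j in range(q)],
    )
    traits = pd.DataFrame(
        np.exp(Y + size[:, None]), columns=shape.var_names
    )
    linear = LinearTable(
        specimen_id=np.array(rows_id),
        species=np.array(rows_sp),
        sex=np.array(rows_sex),
        traits=traits,
    )
    habitat = pd.DataFrame(
        {
            "species": species,
            "juvenile_habitat": juv_hab,
            "adult_habitat": adult_hab,
            "shift": [j != a for j, a in zip(juv_hab, adult_hab)],
        }
    )
    landmarks = None
    if spec.emit_landmarks:
        landmarks = make_landmark_block(
            n_specimens=min(len(size), 60), rng=rng, warp_sd=0.03, noise_sd=0.005
        )
    truth = SimTruth(
        tree=tree,
        species=species,
        slopes=slopes,
        intercepts=intercepts,
        size_ranges=size_ranges,
        adult_habitat=adult_hab,
        juvenile_habitat=juv_hab,
    )
    return SimOutput(shape, linear, landmarks, habitat, tree, truth)


# ---------------------------------------------------------------------
# constructed fixtures


@dataclass
class HeterochronyFixture:
    name: str
    data: ShapeData
    expected_category: str  # trajectory-attribute decision path
    expected_scaling: str  # Tfh family


def _two_species(rng, a1, b1, r1, a2, b2, r2, n=60, noise=0.01, q=None):
    def series(a, b, r, label, k):
        sizes = rng.uniform(r[0], r[1], n)
        sizes[np.argmin(sizes)] = r[0]
        sizes[np.argmax(sizes)] = r[1]
        Y = a + np.outer(sizes, b) + rng.normal(0, noise, (n, len(a)))
        return Y, sizes, [label] * n

    Y1, s1, l1 = series(np.asarray(a1, float), np.asarray(b1, float), r1, "sp1", 0)
    Y2, s2, l2 = series(np.asarray(a2, float), np.asarray(b2, float), r2, "sp2", 1)
    return ShapeData(
        Y=np.vstack([Y1, Y2]),
        size=np.concatenate([s1, s2]),
        species=np.array(l1 + l2),
        sex=np.array(["M"] * (2 * n)),
        dataset_tag="fixture",
    )


def make_heterochrony_fixtures(
    q: int = 4, n: int = 60, noise: float = 0.01, seed: int = 0
) -> list[HeterochronyFixture]:
    """Constructed species pairs realizing each canonical trajectory-shift
    scenario: truncation (ontogenetic scaling), shape-overlap with shifted
    sizes (size-shape dissociation), rotated slope, parallel intercept
    offset, and identical trajectories."""
    rng = np.random.default_rng(seed)
    a = np.zeros(q)
    b = np.zeros(q)
    b[0], b[1] = 1.0, 0.5
    b_rot = np.zeros(q)
    b_rot[0], b_rot[1] = -0.5, 1.0  # orthogonal to b
    ortho = np.zeros(q)
    ortho[2] = 1.0  # orthogonal to both trajectories

    fixtures = [
        HeterochronyFixture(
            "truncation",
            _two_species(rng, a, b, (0.0, 1.0), a, b, (0.0, 0.55), n, noise),
            expected_category="peramorphosis_paedomorphosis",
            expected_scaling="ontogenetic_scaling",
        ),
        HeterochronyFixture(
            "size_shape_dissociation",
            _two_species(rng, a, b, (0.0, 1.0), a - b, b, (1.0, 2.0), n, noise),
            expected_category="parallel_intercept_shift",
            expected_scaling="size_shape_dissociation",
        ),
        HeterochronyFixture(
            "rotated_slope",
            _two_species(rng, a, b, (0.0, 1.0), a, b_rot, (0.0, 1.0), n, noise),
            expected_category="slope_shift",
            expected_scaling="rejected",
        ),
        HeterochronyFixture(
            "parallel_offset",
            _two_species(rng, a, b, (0.0, 1.0), a + 0.5 * ortho, b, (0.0, 1.0), n, noise),
            expected_category="parallel_intercept_shift",
            expected_scaling="rejected",
        ),
        HeterochronyFixture(
            "identical",
            _two_species(rng, a, b, (0.0, 1.0), a, b, (0.0, 1.0), n, noise),
            expected_category="conserved",
            expected_scaling="ontogenetic_scaling",
        ),
    ]
    return fixtures


def make_divergence_fixture(
    n_species: int = 20,
    divergence_strength: float = 5.0,
    n_specimens: int = 20,
    q: int = 4,
    base_radius: float = 0.3,
    noise: float = 0.02,
    seed: int = 0,
) -> ShapeData:
    """Species whose predicted juvenile shapes sit within a ball of radius r
    and adult shapes within radius r*(1+strength); negative strength makes
    adults the tighter stage (ontogenetic convergence)."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = np.random.default_rng(seed)
    r_j = base_radius
    r_a = base_radius * (1.0 + divergence_strength)
    if r_a <= 0:
        raise ValueError("divergence_strength must exceed -1")

    def ball(radius):
        v = rng.normal(size=q)
        v /= np.linalg.norm(v)
        return radius * rng.uniform(0.2, 1.0) * v

    Ys, sizes, labels = [], [], []
    for i in range(n_species):
        juv = ball(r_j)
        adu = ball(r_a)
        a, b = juv, adu - juv
        s = rng.uniform(0.0, 1.0, n_specimens)
        s[np.argmin(s)] = 0.0
        s[np.argmax(s)] = 1.0
        Y = a + np.outer(s, b) + rng.normal(0, noise, (n_specimens, q))
        Ys.append(Y)
        sizes.append(s)
        labels.extend([f"sp{i + 1:03d}"] * n_specimens)
    return ShapeData(
        Y=np.vstack(Ys),
        size=np.concatenate(sizes),
        species=np.array(labels),
        sex=np.array(["M"] * (n_species * n_specimens)),
        dataset_tag="divergence_fixture",
    )


# ---------------------------------------------------------------------
# landmarks


def _symmetric_template():
    """Bilaterally symmetric 2D head-outline-like template: 3 midline
    landmarks, 4 bilateral pairs, and 3 bilateral semilandmark pairs."""
    midline = [(0.0, 0.0), (0.0, 1.2), (0.0, 2.0)]
    pairs = [
        ((-0.5, 0.25), (0.5, 0.25)),
        ((-0.85, 1.0), (0.85, 1.0)),
        ((-0.6, 1.7), (0.6, 1.7)),
        ((-0.25, 1.95), (0.25, 1.95)),
    ]
    semis = [
        ((-0.72, 0.6), (0.72, 0.6)),
        ((-0.82, 1.35), (0.82, 1.35)),
        ((-0.45, 1.85), (0.45, 1.85)),
    ]
    coords = list(midline)
    sym_pairs = []
    for l, r in pairs + semis:
        coords.append(l)
        coords.append(r)
        sym_pairs.append((len(coords) - 2, len(coords) - 1))
    coords = np.array(coords)
    midline_idx = np.array([0, 1, 2])
    # semilandmarks slide between their neighboring fixed landmarks
    slider_triples = [
        (3, 11, 5),  # left cheek between pair0-left and pair1-left
        (4, 12, 6),
        (5, 13, 7),
        (6, 14, 8),
        (7, 15, 9),
        (8, 16, 10),
    ]
    return coords, midline_idx, sym_pairs, slider_triples


def make_landmark_block(
    n_specimens: int = 30,
    rng: np.random.Generator | None = None,
    warp_sd: float = 0.04,
    noise_sd: float = 0.0,
    species=None,
) -> LandmarkBlock:
    """Landmark configurations as smooth TPS deformations of the symmetric
    template, with random rotation, translation and scale (to be removed by
    superimposition)."""
    if rng is None:
        rng = np.random.default_rng(0)
    template, midline_idx, sym_pairs, sliders = _symmetric_template()
    k = template.shape[0]
    ctrl = template[[0, 2, 3, 4, 5, 6, 9, 10]]
    confs = np.empty((n_specimens, k, 2))
    for i in range(n_specimens):
        ctrl_dst = ctrl + rng.normal(0, warp_sd, ctrl.shape)
        conf = tps_warp(ctrl, ctrl_dst, template)
        if noise_sd > 0:
            conf = conf + rng.normal(0, noise_sd, conf.shape)
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        scale = np.exp(rng.normal(0.0, 0.3))
        conf = scale * conf @ R.T + rng.normal(0, 2.0, 2)
        confs[i] = conf
    sp = (
        np.asarray(species)
        if species is not None
        else np.array([f"sp{i % 3 + 1}" for i in range(n_specimens)])
    )
    return LandmarkBlock(
        specimen_id=np.array([f"lm{i + 1:03d}" for i in range(n_specimens)]),
        species=sp,
        sex=np.array(["M"] * n_specimens),
        coords=confs,
        fixed_idx=np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]),
        slider_triples=sliders,
        symmetry_pairs=sym_pairs,
        midline_idx=midline_idx,
    )
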