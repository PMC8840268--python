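"""Juvenile-versus-adult comparative analyses.

Per-species juvenile and adult phenotypes are the shapes predicted by the
unique-allometry regressions at each species' smallest and largest observed
size. On these stage means the module computes: the ontogenetic
convergence/divergence statistic D (summed pairwise disparity of juveniles
minus adults), multivariate Blomberg's K and the adult-juvenile contrast
dK, a simulation-based phylogenetic MANOVA (Garland-style: empirical F
statistics against F distributions from Brownian-motion simulation on the
tree), and phylomorphospace coordinates (ancestral states by GLS under BM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .allometry import AllometricFit, TrajectorySet
from .config import RunConfig
from .morphometry import ShapeData
from .stats import permutation_pvalue
from .trees import Phylogeny

__all__ = [
    "DResult",
    "StageMeans",
    "stage_means",
    "d_test",
    "k_mult",
    "delta_k_test",
    "phylo_manova",
    "phylomorphospace",
    "pca_scores",
]

HABITAT_CATEGORIES = (
    "amphibious",
    "canopy",
    "cryptic",
    "escarpment",
    "terrestrial",
    "trunk",
)


@dataclass
class DResult:
    D: float
    D_j: float
    D_a: float
    p: float
    n_permutations: int


@dataclass
class StageMeans:
    species: list
    juvenile: np.ndarray  # (S, q)
    adult: np.ndarray  # (S, q)
    juvenile_size: np.ndarray
    adult_size: np.ndarray


def stage_means(traj: TrajectorySet, fit: AllometricFit) -> StageMeans:
    return StageMeans(
        species=list(traj.species),
        juvenile=traj.juvenile_shape,
        adult=traj.adult_shape,
        juvenile_size=fit.size_range[:, 0],
        adult_size=fit.size_range[:, 1],
    )


def _sum_pairwise(X: np.ndarray) -> float:
    if X.shape[0] < 2:
        return 0.0
    return float(pdist(X).sum())


def _sum_pairwise_batch(X: np.ndarray) -> np.ndarray:
    # X: (b, S, q) -> (b,) summed pairwise Euclidean distances
    d2 = np.sum((X[:, :, None, :] - X[:, None, :, :]) ** 2, axis=-1)
    return 0.5 * np.sum(np.sqrt(np.maximum(d2, 0.0)), axis=(1, 2))


def _stage_rep_draws(data: ShapeData, groups, rng, n_draws, batch=256):
    """Yield (juv, adu) batches of shape (b, S, q): two random specimens per
    species as juvenile/adult representatives."""
    S = len(groups)
    q = data.Y.shape[1]
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        juv = np.empty((b, S, q))
        adu = np.empty((b, S, q))
        for i, rows in enumerate(groups):
            pick = np.argsort(rng.random((b, rows.size)), axis=1)[:, :2]
            juv[:, i] = data.Y[rows[pick[:, 0]]]
            adu[:, i] = data.Y[rows[pick[:, 1]]]
        yield juv, adu
        done += b


def d_test(
    data: ShapeData,
    fit: AllometricFit,
    traj: TrajectorySet,
    clade_species=None,
    config: RunConfig | None = None,
    host_p: float | None = None,
) -> DResult:
    """Ontogenetic convergence/divergence test.

    D = (summed pairwise distances among predicted juvenile shapes) minus
    (same among adults); positive D means convergence. The null randomizes
    morphology with respect to size: two random specimens per species stand
    in for the juvenile and adult phenotypes. One-sided p per the sign of D.
    """
    cfg = config or RunConfig()
    if host_p is not None and host_p >= cfg.alpha:
        raise ValueError(
            "D test applies to clades whose slope-homogeneity test rejected "
            f"(HOST p = {host_p})"
        )
    sp = list(clade_species) if clade_species is not None else list(traj.species)
    if len(sp) < 2:
        raise ValueError("need at least two species")
    idx = [traj.species.index(s) for s in sp]
    D_j = _sum_pairwise(traj.juvenile_shape[idx])
    D_a = _sum_pairwise(traj.adult_shape[idx])
    D = D_j - D_a

    groups = []
    for s in sp:
        rows = np.flatnonzero(data.species == s)
        if rows.size < 2:
            raise ValueError(f"species {s!r} has < 2 specimens; null undrawable")
        groups.append(rows)
    rng = cfg.rng("d_test:" + "|".join(map(str, sp)))
    chunks = []
    for juv, adu in _stage_rep_draws(data, groups, rng, cfg.n_permutations):
        chunks.append(_sum_pairwise_batch(juv) - _sum_pairwise_batch(adu))
    null = np.concatenate(chunks)
    tail = "greater" if D >= 0 else "less"
    p = permutation_pvalue(D, null, tail)
    return DResult(D=D, D_j=D_j, D_a=D_a, p=p, n_permutations=cfg.n_permutations)


# ---------------------------------------------------------------------
# phylogenetic signal


def _k_stat(X: np.ndarray, Cinv: np.ndarray, ones_Cinv: np.ndarray,
            denom_exp: float) -> float:
    a = (ones_Cinv @ X) / ones_Cinv.sum()
    R = X - a
    num = float(np.sum(R * R))
    den = float(np.sum(R * (Cinv @ R)))
    return (num / den) / denom_exp if den > 0 else np.nan


def k_mult(
    tree: Phylogeny,
    tip_matrix,
    tip_labels=None,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
):
    """Multivariate Blomberg's K with expectation 1 under Brownian motion.

    K = (E/PE) / E_BM, where E is the summed squared distance of tips from
    the phylogenetic mean, PE its phylogenetically corrected counterpart,
    and E_BM = (tr(C) - N / sum(C^-1)) / (N - 1). Univariate data recover
    the classical K. Significance by permuting tips across the tree.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.atleast_2d(np.asarray(tip_matrix, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    order = tree.tip_labels
    if tip_labels is not None:
        lookup = {l: i for i, l in enumerate(tip_labels)}
        if set(order) != set(lookup):
            raise ValueError("tip_labels do not match the tree's tips")
        X = X[[lookup[l] for l in order]]
    C = tree.vcv()
    N = C.shape[0]
    if X.shape[0] != N:
        raise ValueError("tip matrix rows must match the number of tips")
    Cinv = np.linalg.inv(C)
    ones_Cinv = Cinv.sum(axis=0)
    denom_exp = (np.trace(C) - N / ones_Cinv.sum()) / (N - 1)
    K = _k_stat(X, Cinv, ones_Cinv, denom_exp)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = _k_stat(X[rng.permutation(N)], Cinv, ones_Cinv, denom_exp)
    p = permutation_pvalue(K, null, "greater")
    return K, p


def delta_k_test(
    tree: Phylogeny,
    data: ShapeData,
    traj: TrajectorySet,
    config: RunConfig | None = None,
):
    """Contrast of phylogenetic signal between stages: dK = K_adult - K_juv.

    The null randomizes morphology with respect to size (two random
    specimens per species as stage representatives); p is the proportion of
    permuted dK >= observed. Returns (dK, K_a, K_j, p).
    """
    cfg = config or RunConfig()
    order = tree.tip_labels
    if set(order) != set(traj.species):
        raise ValueError("tree tips must match the trajectory species")
    idx = [traj.species.index(s) for s in order]
    C = tree.vcv()
    N = C.shape[0]
    Cinv = np.linalg.inv(C)
    ones_Cinv = Cinv.sum(axis=0)
    denom_exp = (np.trace(C) - N / ones_Cinv.sum()) / (N - 1)
    K_a = _k_stat(traj.adult_shape[idx], Cinv, ones_Cinv, denom_exp)
    K_j = _k_stat(traj.juvenile_shape[idx], Cinv, ones_Cinv, denom_exp)
    dK = K_a - K_j

    groups = []
    for s in order:
        rows = np.flatnonzero(data.species == s)
        if rows.size < 2:
            raise ValueError(f"species {s!r} has < 2 specimens; null undrawable")
        groups.append(rows)
    rng = cfg.rng("delta_k")

    def k_batch(X):
        a = np.einsum("n,bnq->bq", ones_Cinv, X) / ones_Cinv.sum()
        R = X - a[:, None, :]
        num = np.sum(R * R, axis=(1, 2))
        den = np.einsum("bnq,bnq->b", R, Cinv[None] @ R)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (num / den) / denom_exp

    chunks = []
    for juv, adu in _stage_rep_draws(data, groups, rng, cfg.n_permutations):
        chunks.append(k_batch(adu) - k_batch(juv))
    null = np.concatenate(chunks)
    p = permutation_pvalue(dK, null, "greater")
    return dK, K_a, K_j, p


# ---------------------------------------------------------------------
# phylogenetic MANOVA


def pca_scores(X: np.ndarray, min_cumvar: float = 0.95):
    """Covariance-based PCA; returns the scores of the smallest leading set
    of components reaching the cumulative-variance threshold."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    tot = var.sum()
    if tot <= 0:
        raise ValueError("zero variance in response matrix")
    k = int(np.searchsorted(np.cumsum(var) / tot, min_cumvar) + 1)
    k = min(k, len(s))
    return Xc @ Vt[:k].T


def _term_F(Y, bases):
    """Sequential (type I) F per term given nested orthonormal bases.

    bases: list of (Q, rank) from intercept-only to full model. Y may be
    batched (..., n, q).
    """
    tot = np.sum(Y**2, axis=(-2, -1))
    fits = [np.sum((np.swapaxes(Y, -2, -1) @ Q) ** 2, axis=(-2, -1)) for Q, _ in bases]
    n = Y.shape[-2]
    df_res = n - bases[-1][1]
    tol = 1e-12 * np.maximum(tot, 1.0)
    ss_res = np.maximum(tot - fits[-1], 0.0)
    Fs = []
    for t in range(1, len(bases)):
        df_t = bases[t][1] - bases[t - 1][1]
        ss_t = np.maximum(fits[t] - fits[t - 1], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_t / df_t) / (ss_res / df_res)
        # a saturated model: infinite F where the term explains variance
        F = np.where(ss_res > tol, F, np.where(ss_t > tol, np.inf, 0.0))
        Fs.append(F)
    return np.stack(Fs, axis=-1)


def phylo_manova(
    tree: Phylogeny,
    response,
    size,
    habitat,
    species=None,
    config: RunConfig | None = None,
    n_simulations: int | None = None,
    min_cumvar: float = 0.95,
):
    """Simulation-based phylogenetic MANOVA of shape (PC scores) on
    size + habitat + size:habitat.

    Empirical sequential F statistics are compared with F distributions
    from multivariate Brownian-motion simulation on the tree (rate matrix
    estimated from the PC scores; predictors held fixed). Returns a
    DataFrame with one row per term.
    """
    cfg = config or RunConfig()
    nsim = n_simulations if n_simulations is not None else cfg.n_permutations
    X = np.atleast_2d(np.asarray(response, dtype=float))
    order = tree.tip_labels
    if species is not None:
        lookup = {l: i for i, l in enumerate(species)}
        if set(order) != set(lookup):
            raise ValueError("species do not match the tree's tips")
        sel = [lookup[l] for l in order]
        X = X[sel]
        size = np.asarray(size, float)[sel]
        habitat = np.asarray(habitat)[sel]
    else:
        size = np.asarray(size, float)
        habitat = np.asarray(habitat)
    n = X.shape[0]

    scores = pca_scores(X, min_cumvar)

    levels = sorted(set(habitat))
    H = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        H[habitat == lev, j] = 1.0
    counts = {lev: int(np.sum(habitat == lev)) for lev in levels}
    unstable = [lev for lev, c in counts.items() if c < 2]
    if unstable:
        warnings.warn(
            f"habitat levels with a single species (interaction unstable): {unstable}",
            stacklevel=2,
        )

    ones = np.ones((n, 1))
    designs = [
        ones,
        np.column_stack([ones, size]),
        np.column_stack([ones, size, H]),
        np.column_stack([ones, size, H, H * size[:, None]]),
    ]
    bases = []
    for D in designs:
        Q, R = np.linalg.qr(D)
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
        bases.append((Q[:, keep], int(keep.sum())))

    F_obs = _term_F(scores[None], bases)[0]

    # BM rate matrix (ML) on the scores
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    w = Cinv.sum(axis=0)
    a = (w @ scores) / w.sum()
    Rc = scores - a
    Rmat = (Rc.T @ Cinv @ Rc) / n
    Lc = np.linalg.cholesky(C)
    # allow rank-deficient rate matrices
    evals, evecs = np.linalg.eigh(Rmat)
    evals = np.clip(evals, 0.0, None)
    Lr = evecs * np.sqrt(evals)

    rng = cfg.rng("phylo_manova")
    q = scores.shape[1]
    F_null = np.empty((nsim, len(F_obs)))
    batch = max(1, min(512, nsim))
    done = 0
    while done < nsim:
        b = min(batch, nsim - done)
        Z = rng.standard_normal((b, n, q))
        sims = a[None, None, :] + Lc @ Z @ Lr.T
        F_null[done : done + b] = _term_F(sims, bases)
        done += b

    terms = ["size", "habitat", "size:habitat"]
    rows = []
    for t, term in enumerate(terms):
        p = permutation_pvalue(F_obs[t], F_null[:, t], "greater")
        rows.append({
            "term": term,
            "F": F_obs[t],
            "p": p,
            "stable": not (term != "size" and unstable),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# phylomorphospace


def phylomorphospace(tree: Phylogeny, tip_coords, tip_labels=None):
    """Internal-node coordinates by GLS/ML Brownian ancestral estimation.

    Returns (node_coords DataFrame indexed by node id, edges DataFrame with
    parent/child node ids). Tip ids are their labels; internal ids are
    ``node<k>`` in preorder, the root being ``node0``.
    """
    Xt = np.atleast_2d(np.asarray(tip_coords, dtype=float))
    if Xt.shape[0] == 1:
        Xt = Xt.T
    order = tree.tip_labels
    if tip_labels is not None:
        lookup = {l: i for i, l in enumerate(tip_labels)}
        Xt = Xt[[lookup[l] for l in order]]
    tips = tree.tips()
    n = len(tips)
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    w = Cinv.sum(axis=0)
    a = (w @ Xt) / w.sum()

    depths = tree.depths()
    tipsets: dict = {}
    for nd in tree.postorder():
        tipsets[nd] = (
            {nd.label} if nd.is_leaf else set().union(*(tipsets[c] for c in nd.children))
        )
    tip_pos = {l: i for i, l in enumerate(order)}

    internals = [nd for nd in tree.preorder() if not nd.is_leaf]
    ids = {nd: f"node{k}" for k, nd in enumerate(internals)}
    coords = {}
    for nd in internals:
        cov = np.empty(n)
        for l, i in tip_pos.items():
            anc = nd
            while l not in tipsets[anc]:
                anc = anc.parent
            cov[i] = depths[anc]
        coords[ids[nd]] = a + cov @ Cinv @ (Xt - a)
    for l, i in tip_pos.items():
        coords[l] = Xt[i]

    def node_id(nd):
        return nd.label if nd.is_leaf else ids[nd]

    edges = [
        {"parent": node_id(nd), "child": node_id(c)}
        for nd in tree.preorder()
        for c in nd.children
    ]
    node_df = pd.DataFrame.from_dict(coords, orient="index")
    return node_df, pd.DataFrame(edges)
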