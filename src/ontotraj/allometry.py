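"""Ontogenetic allometric trajectories and their comparison.

Each species' trajectory is the OLS regression of multivariate shape on
log size. Trajectory attributes follow the standard vector formulation:
direction = unit slope vector, length = distance between the shapes
predicted at the species' own smallest and largest observed sizes.
Inference is by residual randomization (RRPP): pairwise angle and length
nulls come from permuting the residuals of the common-slope reduced model,
so no multiple-testing correction is applied to those; intercept tests
permute specimen species labels and are Benjamini–Hochberg corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .morphometry import ShapeData
from .stats import bh_adjust, permutation_pvalue, rrpp_f_test

__all__ = [
    "AllometricFit",
    "TrajectorySet",
    "PairwiseMatrix",
    "HostResult",
    "isometry_test",
    "host_test",
    "fit_unique_allometries",
    "pairwise_trajectories",
    "intercept_test",
    "intercept_tests",
    "hier_part",
    "ontogenetic_shift_table",
]


@dataclass
class AllometricFit:
    species: list
    intercepts: np.ndarray  # (S, q)
    slopes: np.ndarray  # (S, q)
    resid_ss: np.ndarray  # (S,)
    size_range: np.ndarray  # (S, 2) observed [min, max] log size

    def index(self, sp) -> int:
        return self.species.index(sp)

    def predict(self, sp, size: float) -> np.ndarray:
        i = self.index(sp)
        return self.intercepts[i] + self.slopes[i] * size


@dataclass
class TrajectorySet:
    species: list
    lengths: np.ndarray  # (S,)
    directions: np.ndarray  # (S, q) unit slope vectors (nan if zero slope)
    juvenile_shape: np.ndarray  # (S, q) predicted at min observed size
    adult_shape: np.ndarray  # (S, q) predicted at max observed size


@dataclass
class PairwiseMatrix:
    species: list
    statistic: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray | None = None

    def to_frame(self, which: str = "statistic") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.species, columns=self.species)


@dataclass
class HostResult:
    F: float
    p: float
    n_permutations: int
    df_effect: int
    df_resid: int


def _species_designs(data: ShapeData, species=None):
    sp_list = list(species) if species is not None else data.species_list()
    mask = np.isin(data.species, sp_list)
    Y = data.Y[mask]
    x = data.size[mask]
    labels = data.species[mask]
    n = Y.shape[0]
    G = np.zeros((n, len(sp_list)))
    for j, sp in enumerate(sp_list):
        G[labels == sp, j] = 1.0
    return sp_list, Y, x, labels, G


def isometry_test(data: ShapeData, species, config: RunConfig | None = None):
    """Test a single species for allometric scaling (shape ~ size).

    Returns (p, R2, F). p >= alpha is read as isometry.
    """
    cfg = config or RunConfig()
    m = data.species == species
    Y = data.Y[m]
    x = data.size[m]
    if Y.shape[0] < 3:
        raise ValueError(f"species {species!r}: too few specimens")
    if np.ptp(x) < 1e-12:
        raise ValueError(f"species {species!r}: zero size variance")
    n = Y.shape[0]
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x])
    res = rrpp_f_test(Y, X0, X1, cfg.n_permutations, cfg.rng(f"isometry:{species}"))
    ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    r2 = res.ss_effect / ss_tot if ss_tot > 0 else 0.0
    return res.p, r2, res.F


def host_test(data: ShapeData, species=None, config: RunConfig | None = None) -> HostResult:
    """Homogeneity-of-slopes test: size x species interaction beyond the
    common-slope model, F compared by residual randomization."""
    cfg = config or RunConfig()
    sp_list, Y, x, labels, G = _species_designs(data, species)
    if len(sp_list) < 2:
        raise ValueError("HOST needs at least two species")
    counts = G.sum(axis=0)
    if np.any(counts < 2):
        bad = [sp for sp, c in zip(sp_list, counts) if c < 2]
        raise ValueError(f"species with a single specimen: {bad}")
    X_red = np.column_stack([G, x])  # size + species (cell-means coding)
    X_full = np.column_stack([G, G * x[:, None]])  # unique slopes
    res = rrpp_f_test(Y, X_red, X_full, cfg.n_permutations, cfg.rng("host"))
    return HostResult(res.F, res.p, cfg.n_permutations, res.df_effect, res.df_resid)


def fit_unique_allometries(data: ShapeData, min_n: int = 2):
    """Per-species OLS of shape on size; trajectory endpoints at each
    species' own observed minimum and maximum size."""
    sp_list = data.species_list()
    q = data.Y.shape[1]
    S = len(sp_list)
    intercepts = np.zeros((S, q))
    slopes = np.zeros((S, q))
    rss = np.zeros(S)
    ranges = np.zeros((S, 2))
    for i, sp in enumerate(sp_list):
        m = data.species == sp
        Y, x = data.Y[m], data.size[m]
        if Y.shape[0] < min_n:
            raise ValueError(f"species {sp!r}: fewer than {min_n} specimens")
        if np.ptp(x) < 1e-12:
            raise ValueError(f"species {sp!r}: singular design (constant size)")
        xc = x - x.mean()
        b = (xc @ Y) / (xc @ xc)
        a = Y.mean(axis=0) - b * x.mean()
        slopes[i], intercepts[i] = b, a
        resid = Y - (a + np.outer(x, b))
        rss[i] = float(np.sum(resid**2))
        ranges[i] = [x.min(), x.max()]
    fit = AllometricFit(sp_list, intercepts, slopes, rss, ranges)
    juv = intercepts + slopes * ranges[:, [0]]
    adu = intercepts + slopes * ranges[:, [1]]
    lengths = np.linalg.norm(adu - juv, axis=1)
    norms = np.linalg.norm(slopes, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(norms[:, None] > 0, slopes / np.where(norms[:, None] > 0, norms[:, None], 1.0), np.nan)
    traj = TrajectorySet(sp_list, lengths, dirs, juv, adu)
    return fit, traj


def _angles_deg(slopes: np.ndarray) -> np.ndarray:
    """Pairwise angles (degrees) between slope vectors; rows of ``slopes``
    may be batched: (..., S, q)."""
    norms = np.linalg.norm(slopes, axis=-1, keepdims=True)
    unit = slopes / np.where(norms > 0, norms, np.nan)
    cos = np.clip(unit @ np.swapaxes(unit, -2, -1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def pairwise_trajectories(
    data: ShapeData, config: RunConfig | None = None, batch: int = 256
):
    """Pairwise angle and length-difference tests between species trajectories.

    Nulls come from residual randomization of the common-slope reduced model
    (shape ~ size + species); every pairwise contrast shares the same
    randomization, so p-values are left unadjusted.
    """
    cfg = config or RunConfig()
    sp_list, Y, x, labels, G = _species_designs(data)
    S = len(sp_list)
    # per-species slope extractor: slopes = W @ Y with W (S, n)
    W = np.zeros((S, Y.shape[0]))
    ranges = np.zeros(S)
    for j, sp in enumerate(sp_list):
        m = labels == sp
        xc = x[m] - x[m].mean()
        W[j, m] = xc / (xc @ xc)
        ranges[j] = np.ptp(x[m])

    slopes = W @ Y
    ang_obs = _angles_deg(slopes)
    L_obs = np.linalg.norm(slopes, axis=1) * ranges
    dL_obs = np.abs(L_obs[:, None] - L_obs[None, :])

    # reduced model: common slope + species intercepts
    X_red = np.column_stack([G, x])
    Q, _ = np.linalg.qr(X_red)
    fit_red = Q @ (Q.T @ Y)
    resid_red = Y - fit_red

    rng = cfg.rng("pairwise")
    nperm = cfg.n_permutations
    ge_ang = np.zeros((S, S))
    ge_dL = np.zeros((S, S))
    done = 0
    n = Y.shape[0]
    while done < nperm:
        b = min(batch, nperm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Yp = fit_red[None] + resid_red[idx]
        sl = np.einsum("sn,bnq->bsq", W, Yp)
        ang = _angles_deg(sl)
        Lp = np.linalg.norm(sl, axis=-1) * ranges[None, :]
        dL = np.abs(Lp[:, :, None] - Lp[:, None, :])
        ge_ang += np.sum(ang >= ang_obs[None], axis=0)
        ge_dL += np.sum(dL >= dL_obs[None], axis=0)
        done += b
    p_ang = (1.0 + ge_ang) / (nperm + 1.0)
    p_dL = (1.0 + ge_dL) / (nperm + 1.0)
    zero = np.linalg.norm(slopes, axis=1) < 1e-12
    if np.any(zero):
        p_ang[zero, :] = np.nan
        p_ang[:, zero] = np.nan
    np.fill_diagonal(p_ang, 1.0)
    np.fill_diagonal(p_dL, 1.0)
    np.fill_diagonal(ang_obs, 0.0)
    angles = PairwiseMatrix(sp_list, ang_obs, p_ang)
    lengths = PairwiseMatrix(sp_list, dL_obs, p_dL)
    return angles, lengths


def intercept_test(data: ShapeData, pair, config: RunConfig | None = None):
    """Euclidean distance between intercept vectors under a common-slope
    model for one species pair; null by permuting specimen species labels."""
    cfg = config or RunConfig()
    sp_list, Y, x, labels, G = _species_designs(data, pair)
    if len(sp_list) != 2:
        raise ValueError("intercept_test takes exactly two species")

    def dist(gmat):
        X = np.column_stack([gmat, x])
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return float(np.linalg.norm(coef[0] - coef[1]))

    d_obs = dist(G)
    rng = cfg.rng(f"intercept:{pair[0]}|{pair[1]}")
    null = np.empty(cfg.n_permutations)
    n = Y.shape[0]
    for i in range(cfg.n_permutations):
        perm = rng.permutation(n)
        null[i] = dist(G[perm])
    p = permutation_pvalue(d_obs, null, "greater")
    return d_obs, p


def intercept_tests(
    data: ShapeData,
    pairs,
    angle_p: PairwiseMatrix | None = None,
    config: RunConfig | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Intercept tests over common-slope pairs, BH-adjusted.

    If ``angle_p`` is given, pairs whose slopes differ significantly
    (unadjusted angle p < alpha) are refused, per the decision path.
    """
    cfg = config or RunConfig()
    a = alpha if alpha is not None else cfg.alpha
    rows = []
    for pair in pairs:
        if angle_p is not None:
            i, j = angle_p.species.index(pair[0]), angle_p.species.index(pair[1])
            if angle_p.p[i, j] < a:
                raise ValueError(
                    f"pair {pair} has heterogeneous slopes; intercept test undefined"
                )
        d, p = intercept_test(data, pair, cfg)
        rows.append({"sp1": pair[0], "sp2": pair[1], "distance": d, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy()).adjusted
    return out


# ---------------------------------------------------------------------
# hierarchical partitioning


def _r2(y: np.ndarray, X: np.ndarray | None) -> float:
    y = np.asarray(y, float)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if X is None or X.shape[1] == 0 or sst == 0:
        return 0.0
    Xd = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    return 1.0 - float(resid @ resid) / sst


def hier_part(y, predictors: pd.DataFrame):
    """Hierarchical partitioning of R^2 over all predictor subsets
    (Chevan & Sutherland). Independent effects sum to the full-model R^2.

    Returns a DataFrame with independent/joint effects and the share of
    summed independent effects per predictor.
    """
    y = np.asarray(y, float)
    names = list(predictors.columns)
    Xall = predictors.to_numpy(dtype=float)
    k = len(names)
    const = [j for j in range(k) if np.ptp(Xall[:, j]) < 1e-12]
    if const:
        warnings.warn(
            f"constant predictors (independent effect 0): {[names[j] for j in const]}",
            stacklevel=2,
        )
    r2 = {}
    for r in range(k + 1):
        for sub in itertools.combinations(range(k), r):
            r2[sub] = _r2(y, Xall[:, list(sub)] if sub else None)
    I = np.zeros(k)
    for j in range(k):
        others = [m for m in range(k) if m != j]
        for r in range(k):
            incs = []
            for sub in itertools.combinations(others, r):
                incs.append(r2[tuple(sorted(sub + (j,)))] - r2[sub])
            I[j] += np.mean(incs)
        I[j] /= k
    full = r2[tuple(range(k))]
    J = np.array([r2[(j,)] - I[j] for j in range(k)])
    tot = I.sum()
    pct = 100.0 * I / tot if tot > 0 else np.zeros(k)
    return pd.DataFrame(
        {"independent": I, "joint": J, "independent_pct": pct}, index=names
    ), full


def ontogenetic_shift_table(
    data: ShapeData,
    fit: AllometricFit,
    trait_index: int | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per species and trait, the direction of ontogenetic change in the
    log-shape ratio: increases / decreases / isometric (by slope sign and a
    univariate residual-randomization test)."""
    cfg = config or RunConfig()
    q = fit.slopes.shape[1]
    if trait_index is not None:
        if not (0 <= trait_index < q):
            raise IndexError(f"trait index {trait_index} out of range [0, {q})")
        traits = [trait_index]
    else:
        traits = list(range(q))
    rows = []
    for sp in fit.species:
        m = data.species == sp
        x = data.size[m]
        n = int(m.sum())
        X0, X1 = np.ones((n, 1)), np.column_stack([np.ones(n), x])
        for j in traits:
            y = data.Y[m][:, [j]]
            res = rrpp_f_test(
                y, X0, X1, min(cfg.n_permutations, 999),
                cfg.rng(f"shift:{sp}:{j}"),
            )
            b = fit.slopes[fit.index(sp), j]
            if res.p >= cfg.alpha or b == 0.0:
                lab = "isometric"
            else:
                lab = "increases" if b > 0 else "decreases"
            rows.append({"species": sp, "trait": j, "slope": b, "p": res.p,
                         "change": lab})
    return pd.DataFrame(rows)
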