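"""Heterochrony detection between species pairs.

Two parallel test families operate on each pair:

* the decision path over trajectory attributes: slope (angle) shift ->
  intercept shift -> adult-shape difference under a shared trajectory
  ("peramorphosis test") -> conserved;
* the trajectory-overlap family: Tfh1 asks whether the pair occupies one
  trajectory in size-shape space (ontogenetic scaling is the null), and,
  where that is rejected, Tfh2 asks whether the pair shares a trajectory
  in shape space alone (size-shape dissociation is the null).

The Tfh statistics are symmetric cross-prediction sums of squares: each
species' specimens are evaluated against the other species' fitted
trajectory (full size-shape line for Tfh1, shape-space line for Tfh2).
Randomizing taxonomic identity of specimens — keeping each specimen's
shape-size pairing intact — gives an exactly calibrated null under
exchangeability. The pooled-regression residual SS is also reported.
Because heterochrony is the null hypothesis, Tfh p-values are not
corrected for multiple testing; the peramorphosis test is BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .morphometry import ShapeData
from .allometry import AllometricFit
from .stats import bh_adjust, permutation_pvalue

__all__ = [
    "PairClassification",
    "peramorphosis_test",
    "peramorphosis_tests",
    "tfh1",
    "tfh2",
    "classify_pair",
]

TFH2_DEFAULT_PERMUTATIONS = 500


def _pair_arrays(data: ShapeData, pair):
    m = np.isin(data.species, list(pair))
    Y = data.Y[m]
    x = data.size[m]
    z = (data.species[m] == pair[0])
    if np.ptp(x) < 1e-12:
        raise ValueError("pooled design singular: no size variation")
    return Y, x, z


def _group_ols(Y, x, z):
    """OLS intercept/slope for the group flagged by boolean z (batched ok).

    z may be (n,) or (B, n); returns intercepts/slopes of shape (q,) or (B, q).
    """
    z = np.asarray(z, float)
    batched = z.ndim == 2
    if not batched:
        z = z[None]
    nz = z.sum(axis=1)
    sx = z @ x
    sxx = z @ (x * x)
    sy = z @ Y
    sxy = (z * x[None]) @ Y
    xbar = sx / nz
    denom = sxx - sx * xbar
    slope = (sxy - xbar[:, None] * sy) / denom[:, None]
    intercept = sy / nz[:, None] - slope * xbar[:, None]
    if not batched:
        return intercept[0], slope[0]
    return intercept, slope


def _perm_labels(rng, n, n1, n_perm):
    """Boolean matrix (n_perm, n): which specimens go to pseudo-species 1."""
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    Z = np.zeros((n_perm, n), dtype=bool)
    rows = np.repeat(np.arange(n_perm), n1)
    Z[rows, order[:, :n1].ravel()] = True
    return Z


def peramorphosis_test(
    data: ShapeData,
    fit: AllometricFit | None,
    pair,
    config: RunConfig | None = None,
):
    """Distance between the phenotypes predicted at each species' maximum
    observed size; null by permuting specimen species labels and refitting.

    Intended for pairs already found to share slope and intercept.
    Returns (adult_distance, p).
    """
    cfg = config or RunConfig()
    Y, x, z = _pair_arrays(data, pair)
    n = len(x)

    def stat(Z):
        iA, bA = _group_ols(Y, x, Z)
        iB, bB = _group_ols(Y, x, ~Z)
        xA = np.max(np.where(Z, x[None] if Z.ndim == 2 else x, -np.inf), axis=-1)
        xB = np.max(np.where(~Z, x[None] if Z.ndim == 2 else x, -np.inf), axis=-1)
        if Z.ndim == 1:
            adA = iA + bA * xA
            adB = iB + bB * xB
            return float(np.linalg.norm(adA - adB))
        adA = iA + bA * xA[:, None]
        adB = iB + bB * xB[:, None]
        return np.linalg.norm(adA - adB, axis=1)

    d_obs = stat(z)
    rng = cfg.rng(f"peram:{pair[0]}|{pair[1]}")
    null = stat(_perm_labels(rng, n, int(z.sum()), cfg.n_permutations))
    return d_obs, permutation_pvalue(d_obs, null, "greater")


def peramorphosis_tests(data, fit, pairs, config: RunConfig | None = None) -> pd.DataFrame:
    cfg = config or RunConfig()
    rows = []
    for pair in pairs:
        d, p = peramorphosis_test(data, fit, pair, cfg)
        rows.append({"sp1": pair[0], "sp2": pair[1], "adult_distance": d, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy()).adjusted
    return out


def tfh1(data: ShapeData, pair, config: RunConfig | None = None):
    """Ontogenetic-scaling test (scaling is the null hypothesis).

    Statistic: symmetric cross-prediction residual SS — each species'
    specimens against the other species' shape~size regression. Null from
    randomizing taxonomic identity over intact (shape, size) tuples.
    Returns (cross_SS, p, pooled_resid_SS); p >= alpha supports scaling.
    """
    cfg = config or RunConfig()
    Y, x, z = _pair_arrays(data, pair)
    n = len(x)

    # pooled single-trajectory residual SS (reported; label-free)
    xc = x - x.mean()
    b_pool = (xc @ Y) / (xc @ xc)
    a_pool = Y.mean(axis=0) - b_pool * x.mean()
    pooled_ss = float(np.sum((Y - a_pool - np.outer(x, b_pool)) ** 2))

    def stat(Z):
        batched = Z.ndim == 2
        iA, bA = _group_ols(Y, x, Z)
        iB, bB = _group_ols(Y, x, ~Z)
        if not batched:
            iA, bA, iB, bB, Zb = iA[None], bA[None], iB[None], bB[None], Z[None]
        else:
            Zb = Z
        predA = iA[:, None, :] + bA[:, None, :] * x[None, :, None]
        predB = iB[:, None, :] + bB[:, None, :] * x[None, :, None]
        rA = np.sum((Y[None] - predA) ** 2, axis=2)  # vs species-1 line
        rB = np.sum((Y[None] - predB) ** 2, axis=2)
        ss = np.sum(np.where(Zb, rB, rA), axis=1)
        return ss if batched else float(ss[0])

    ss_obs = stat(z)
    rng = cfg.rng(f"tfh1:{pair[0]}|{pair[1]}")
    null = stat(_perm_labels(rng, n, int(z.sum()), cfg.n_permutations))
    return ss_obs, permutation_pvalue(ss_obs, null, "greater"), pooled_ss


def tfh2(
    data: ShapeData,
    pair,
    config: RunConfig | None = None,
    n_permutations: int | None = None,
    clamp: bool = False,
):
    """Size-shape-dissociation test (dissociation is the null hypothesis).

    Statistic: symmetric cross sums of squared perpendicular distances from
    each specimen's shape to the other species' regression line in shape
    space (size dimension discarded; the infinite line by default, the
    fitted segment if ``clamp``). Returns (SS_perp, p).
    """
    cfg = config or RunConfig()
    nperm = n_permutations if n_permutations is not None else TFH2_DEFAULT_PERMUTATIONS
    Y, x, z = _pair_arrays(data, pair)
    n = len(x)

    def stat(Z):
        batched = Z.ndim == 2
        Zb = Z if batched else Z[None]
        iA, bA = _group_ols(Y, x, Zb)
        iB, bB = _group_ols(Y, x, ~Zb)
        out = np.zeros(Zb.shape[0])
        for a, b, other in ((iA, bA, ~Zb), (iB, bB, Zb)):
            nrm = np.linalg.norm(b, axis=1)
            if np.any(nrm < 1e-12):
                raise ValueError("degenerate regression line (zero slope)")
            u = b / nrm[:, None]
            diff = Y[None] - a[:, None, :]
            t = np.einsum("bnq,bq->bn", diff, u)
            d2 = np.sum(diff**2, axis=2) - t**2
            out += np.sum(np.where(other, d2, 0.0), axis=1)
        return out if batched else float(out[0])

    if clamp:
        # clamped variant: project onto the fitted segment of the owning group
        def stat(Z):  # noqa: F811
            batched = Z.ndim == 2
            Zb = Z if batched else Z[None]
            out = np.zeros(Zb.shape[0])
            for own, other in ((Zb, ~Zb), (~Zb, Zb)):
                a, b = _group_ols(Y, x, own)
                nrm = np.linalg.norm(b, axis=1)
                if np.any(nrm < 1e-12):
                    raise ValueError("degenerate regression line (zero slope)")
                u = b / nrm[:, None]
                xo = np.where(own, x[None], np.nan)
                lo = np.nanmin(xo, axis=1) * nrm
                hi = np.nanmax(xo, axis=1) * nrm
                diff = Y[None] - a[:, None, :]
                t = np.einsum("bnq,bq->bn", diff, u)
                t = np.clip(t, lo[:, None], hi[:, None])
                d2 = np.sum((diff - t[..., None] * u[:, None, :]) ** 2, axis=2)
                out += np.sum(np.where(other, d2, 0.0), axis=1)
            return out if batched else float(out[0])

    ss_obs = stat(z)
    rng = cfg.rng(f"tfh2:{pair[0]}|{pair[1]}")
    null = stat(_perm_labels(rng, n, int(z.sum()), nperm))
    return ss_obs, permutation_pvalue(ss_obs, null, "greater")


@dataclass
class PairClassification:
    pair: tuple
    category: str  # decision path over trajectory attributes
    scaling_category: str  # Tfh family: ontogenetic_scaling / size_shape_dissociation / rejected / not_tested
    p_values: dict = field(default_factory=dict)
    reason: str = ""


def classify_pair(
    pair,
    angle_p: float | None = None,
    intercept_p: float | None = None,
    peramorphosis_p: float | None = None,
    tfh1_p: float | None = None,
    tfh2_p: float | None = None,
    alpha: float = 0.05,
) -> PairClassification:
    """Assign the pair to its trajectory-shift category along the decision
    path, and independently to its Tfh (heterochrony-as-null) category.

    Intercept and peramorphosis p-values are expected BH-adjusted; angle
    and Tfh p-values unadjusted, mirroring where adjustment applies.
    """
    ps = {
        "angle": angle_p,
        "intercept": intercept_p,
        "peramorphosis": peramorphosis_p,
        "tfh1": tfh1_p,
        "tfh2": tfh2_p,
    }
    reason = ""
    if angle_p is None:
        category, reason = "not_tested", "missing angle test"
    elif angle_p < alpha:
        category = "slope_shift"
    elif intercept_p is None:
        category, reason = "not_tested", "missing intercept test"
    elif intercept_p < alpha:
        category = "parallel_intercept_shift"
    elif peramorphosis_p is None:
        category, reason = "not_tested", "missing peramorphosis test"
    elif peramorphosis_p < alpha:
        category = "peramorphosis_paedomorphosis"
    else:
        category = "conserved"

    if tfh1_p is None:
        scaling = "not_tested"
    elif tfh1_p >= alpha:
        scaling = "ontogenetic_scaling"
    elif tfh2_p is None:
        scaling = "not_tested"
    elif tfh2_p >= alpha:
        scaling = "size_shape_dissociation"
    else:
        scaling = "rejected"
    return PairClassification(tuple(pair), category, scaling, ps, reason)
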