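"""Shared statistical utilities: multiple-testing correction, permutation
p-values, and the residual-randomization (RRPP) linear-model machinery used
by every shape~size test in the pipeline.

The RRPP convention: null distributions for a model contrast are built by
permuting the residuals of the reduced model, adding them back to the
reduced-model fitted values, and recomputing the statistic. Statistics are
distance-based (trace of the residual cross-product), so they apply to
multivariate shape responses directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PValueVector",
    "bh_adjust",
    "permutation_pvalue",
    "resid_ss",
    "rrpp_f_test",
]


@dataclass
class PValueVector:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str = "none"


def bh_adjust(p) -> PValueVector:
    """Benjamini–Hochberg step-up adjustment, capped at 1.

    Raises if any value lies outside [0, 1].
    """
    raw = np.asarray(p, dtype=float)
    if raw.ndim != 1:
        raw = raw.ravel()
    if raw.size == 0:
        return PValueVector(raw=raw, adjusted=raw.copy(), method="benjamini-hochberg")
    if np.any(~np.isfinite(raw)) or np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    adj = np.minimum(np.maximum(adj, raw), 1.0)
    return PValueVector(raw=raw, adjusted=adj, method="benjamini-hochberg")


def permutation_pvalue(observed: float, null_draws, tail: str = "greater") -> float:
    """Permutation p-value with the observed statistic included in the null.

    p = (1 + #draws satisfying the tail condition) / (n_draws + 1), hence
    p in (0, 1].
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("null_draws must be non-empty")
    if tail == "greater":
        count = int(np.sum(draws >= observed))
    elif tail == "less":
        count = int(np.sum(draws <= observed))
    elif tail == "two-sided":
        count = int(np.sum(np.abs(draws) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail: {tail!r}")
    return (1.0 + count) / (draws.size + 1.0)


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def resid_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares (Frobenius) of the OLS fit Y ~ X."""
    Q = _orthobasis(X)
    proj = Q @ (Q.T @ Y)
    return float(np.sum((Y - proj) ** 2))


@dataclass
class RrppResult:
    F: float
    p: float
    df_effect: int
    df_resid: int
    ss_effect: float
    ss_resid_full: float
    null_F: np.ndarray


def rrpp_f_test(
    Y,
    X_reduced,
    X_full,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    batch: int = 512,
) -> RrppResult:
    """Distance-based F test of the terms in ``X_full`` beyond ``X_reduced``,
    with a null distribution from residual randomization of the reduced model.

    Y is (n, q); design matrices include any intercept column explicitly.
    """
    if rng is None:
        rng = np.random.default_rng()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and Y.shape[1] > 1:
        Y = Y.T
    n = Y.shape[0]
    Qr = _orthobasis(X_reduced)
    Qf = _orthobasis(X_full)
    rank_r, rank_f = Qr.shape[1], Qf.shape[1]
    df1 = rank_f - rank_r
    df2 = n - rank_f
    if df1 <= 0:
        raise ValueError("full model does not extend the reduced model")
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")

    fit_r = Qr @ (Qr.T @ Y)
    resid_r = Y - fit_r

    def f_stat_batch(Yb: np.ndarray) -> np.ndarray:
        # Yb: (..., n, q)
        tot = np.sum(Yb**2, axis=(-2, -1))
        ss_r = tot - np.sum((np.swapaxes(Yb, -2, -1) @ Qr) ** 2, axis=(-2, -1))
        ss_f = tot - np.sum((np.swapaxes(Yb, -2, -1) @ Qf) ** 2, axis=(-2, -1))
        ss_eff = ss_r - ss_f
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df1) / np.where(ss_f > 0, ss_f / df2, np.inf)
        return F, ss_eff, ss_f

    F_obs, ss_eff, ss_f = f_stat_batch(Y[None])
    F_obs, ss_eff, ss_f = float(F_obs[0]), float(ss_eff[0]), float(ss_f[0])

    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        Yp = fit_r[None] + resid_r[idx]
        null[done : done + b] = f_stat_batch(Yp)[0]
        done += b
    p = permutation_pvalue(F_obs, null, tail="greater")
    return RrppResult(
        F=F_obs,
        p=p,
        df_effect=df1,
        df_resid=df2,
        ss_effect=ss_eff,
        ss_resid_full=ss_f,
        null_F=null,
    )
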