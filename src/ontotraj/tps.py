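"""Thin-plate splines in 2D: bending-energy matrices (for semilandmark
sliding) and smooth template warps (for synthetic landmark generation)."""

from __future__ import annotations

import numpy as np

__all__ = ["bending_energy_matrix", "bending_energy", "tps_warp"]


def _kernel(d2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d2 * np.log(d2)
    out[~np.isfinite(out)] = 0.0
    return out


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a 2D reference configuration (k, 2).

    The quadratic form ``d.T @ B @ d`` gives the bending energy of a
    per-coordinate displacement field d relative to the reference.
    """
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[0]
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    K = _kernel(d2)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.pinv(L)
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)


def bending_energy(ref: np.ndarray, target: np.ndarray) -> float:
    """Total bending energy of target relative to the reference (x + y)."""
    B = bending_energy_matrix(ref)
    d = np.asarray(target, dtype=float) - np.asarray(ref, dtype=float)
    return float(d[:, 0] @ B @ d[:, 0] + d[:, 1] @ B @ d[:, 1])


def tps_warp(src: np.ndarray, dst: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Warp ``pts`` by the thin-plate spline mapping src -> dst control points."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    pts = np.asarray(pts, float)
    k = src.shape[0]
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    K = _kernel(d2)
    P = np.column_stack([np.ones(k), src])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = dst
    coef = np.linalg.lstsq(L, rhs, rcond=None)[0]
    w, a = coef[:k], coef[k:]
    d2p = np.sum((pts[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    U = _kernel(d2p)
    return U @ w + np.column_stack([np.ones(len(pts)), pts]) @ a
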