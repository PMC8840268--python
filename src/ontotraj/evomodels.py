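"""Trait-evolution model fitting on species attributes of the trajectories
(trajectory length; first PC of the slope vectors).

Eight models: BM, BMS (regime-specific BM rates, non-censored), OU (single
optimum, fixed-root convention so alpha -> 0 recovers BM on an ultrametric
tree), OUM (regime-specific optima), EB (exponentially decaying rate,
r <= 0), MC (matching competition: lineage deviations pulled toward the
mean of co-occurring lineages, S <= 0), and linear / exponential
diversity-dependent rates (DDl, DD2). All likelihoods are multivariate
normal over tips with model-implied mean and covariance; sigma^2 (and GLS
mean parameters) are profiled out, leaving low-dimensional searches.
Models are compared by AICc weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .trees import Node, Phylogeny

__all__ = [
    "ModelFit",
    "SympatryStructure",
    "fit_gauss_model",
    "fit_interaction_model",
    "compare_models",
    "aicc",
]

GAUSS_MODELS = ("BM", "BMS", "OU", "OUM", "EB")
INTERACTION_MODELS = ("MC", "DDl", "DD2")


@dataclass
class ModelFit:
    model: str
    parameters: dict
    logLik: float
    k: int
    n: int
    AICc: float
    AICcw: float | None = None
    converged: bool = True
    data_fingerprint: float = 0.0


@dataclass
class SympatryStructure:
    """Extant species-by-species sympatry (binary, symmetric, unit diagonal),
    held constant along the tree."""

    species: list
    matrix: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T):
            raise ValueError("sympatry matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0):
            raise ValueError("sympatry matrix must have a unit diagonal")
        self.matrix = M

    def sympatric(self, a, b) -> bool:
        i, j = self.species.index(a), self.species.index(b)
        return bool(self.matrix[i, j])


def aicc(logLik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _aicc_or_nan(logLik: float, k: int, n: int) -> float:
    """AICc, or NaN when the sample is too small for the correction term;
    model comparison refuses fits without a finite AICc."""
    try:
        return aicc(logLik, k, n)
    except ValueError:
        return float("nan")


def _align(tree: Phylogeny, y, tip_labels):
    y = np.asarray(y, dtype=float).ravel()
    order = tree.tip_labels
    if tip_labels is not None:
        lookup = {l: i for i, l in enumerate(tip_labels)}
        if set(order) != set(lookup):
            raise ValueError("tip_labels do not match the tree")
        y = y[[lookup[l] for l in order]]
    if y.size != len(order):
        raise ValueError("trait vector length must equal the number of tips")
    return y


def _profile_loglik(y: np.ndarray, V1: np.ndarray, W: np.ndarray | None = None):
    """ML log-likelihood with V = sigma2 * V1 and mean = W @ theta, profiling
    sigma2 and theta. W defaults to a column of ones. Returns
    (loglik, sigma2_hat, theta_hat)."""
    n = y.size
    if W is None:
        W = np.ones((n, 1))
    V1 = 0.5 * (V1 + V1.T)
    L = np.linalg.cholesky(V1)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    yt = np.linalg.solve(L, y)
    Wt = np.linalg.solve(L, W)
    theta, *_ = np.linalg.lstsq(Wt, yt, rcond=None)
    r = yt - Wt @ theta
    s2 = float(r @ r) / n
    if s2 <= 0:
        return -np.inf, 0.0, theta
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
    return float(ll), s2, theta


def _optimize_1d(fun, bounds, n_grid: int = 8):
    """Maximize ``fun`` over a bounded scalar: coarse grid then local polish."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = [fun(g) for g in grid]
    j = int(np.nanargmax(vals))
    a = grid[max(0, j - 1)]
    b = grid[min(n_grid - 1, j + 1)]
    res = minimize_scalar(lambda t: -fun(t), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-8})
    if -res.fun >= vals[j]:
        return float(res.x), float(-res.fun), True
    return float(grid[j]), float(vals[j]), True


def _ou_V1(tree: Phylogeny, alpha: float, stationary_root: bool) -> np.ndarray:
    """OU among-tip covariance divided by sigma^2."""
    C = tree.vcv()
    di = np.diag(C)
    dist = di[:, None] + di[None, :] - 2.0 * C  # patristic tip distances
    if alpha < 1e-12:
        return C.copy()
    if stationary_root:
        return np.exp(-alpha * dist) / (2.0 * alpha)
    return np.exp(-alpha * dist) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)


def _oum_weights(tree: Phylogeny, alpha: float, regimes: list) -> np.ndarray:
    """Regime weight matrix W (tips x regimes): e^{-alpha (T_i - t)} mass per
    regime along each root-to-tip path, root mass assigned to the basal
    regime of the path."""
    segs = tree.tip_path_segments()
    d = tree.depths()
    tipd = [d[t] for t in tree.tips()]
    W = np.zeros((len(segs), len(regimes)))
    ridx = {r: j for j, r in enumerate(regimes)}
    for i, path in enumerate(segs):
        Ti = tipd[i]
        for r, t0, t1 in path:
            W[i, ridx[r]] += np.exp(-alpha * (Ti - t1)) - np.exp(-alpha * (Ti - t0))
        W[i, ridx[path[0][0]]] += np.exp(-alpha * Ti)
    return W


def fit_gauss_model(
    tree: Phylogeny,
    trait,
    model: str,
    tip_labels=None,
    stationary_root: bool = False,
    fixed: dict | None = None,
) -> ModelFit:
    """Fit BM, BMS, OU, OUM or EB by maximum likelihood.

    BMS and OUM require a regime painting on the tree. ``fixed`` pins named
    parameters (e.g. ``{"alpha": 1e-8}``) instead of estimating them (their
    count k is unchanged, for limiting-case comparisons).
    """
    if model not in GAUSS_MODELS:
        raise ValueError(f"unknown Gaussian model {model!r}")
    y = _align(tree, trait, tip_labels)
    n = y.size
    fixed = fixed or {}
    C = tree.vcv()
    T = float(np.max(np.diag(C)))
    fp = float(np.sum(y) + 1e-3 * np.sum(y**2))

    if model == "BM":
        ll, s2, th = _profile_loglik(y, C)
        params = {"sigma2": s2, "z0": float(th[0])}
        k = 2
        return ModelFit("BM", params, ll, k, n, _aicc_or_nan(ll, k, n), data_fingerprint=fp)

    if model == "OU":
        def ll_of(la):
            return _profile_loglik(y, _ou_V1(tree, np.exp(la), stationary_root))[0]

        if "alpha" in fixed:
            alpha = float(fixed["alpha"])
            ok = True
        else:
            la, _, ok = _optimize_1d(ll_of, (np.log(1e-8 / T), np.log(100.0 / T)))
            alpha = float(np.exp(la))
        ll, s2, th = _profile_loglik(y, _ou_V1(tree, alpha, stationary_root))
        params = {"alpha": alpha, "sigma2": s2, "theta": float(th[0])}
        k = 3
        return ModelFit("OU", params, ll, k, n, _aicc_or_nan(ll, k, n), converged=ok,
                        data_fingerprint=fp)

    if model == "EB":
        def V1_of(r):
            if abs(r) < 1e-12:
                return C.copy()
            return (np.exp(r * C) - 1.0) / r

        def ll_of(r):
            return _profile_loglik(y, V1_of(r))[0]

        if "r" in fixed:
            r = float(fixed["r"])
            ok = True
        else:
            r, _, ok = _optimize_1d(ll_of, (-10.0 / T, 0.0))
        ll, s2, th = _profile_loglik(y, V1_of(r))
        params = {"r": float(r), "sigma2": s2, "z0": float(th[0])}
        k = 3
        return ModelFit("EB", params, ll, k, n, _aicc_or_nan(ll, k, n), converged=ok,
                        data_fingerprint=fp)

    if model == "BMS":
        Cs = tree.regime_vcv()
        regs = sorted(Cs)
        if len(regs) < 2:
            # single regime: identical to BM with one rate
            fitbm = fit_gauss_model(tree, y, "BM")
            k = 2
            return ModelFit("BMS", {f"sigma2[{regs[0]}]": fitbm.parameters["sigma2"],
                                    "z0": fitbm.parameters["z0"]},
                            fitbm.logLik, k, n, _aicc_or_nan(fitbm.logLik, k, n),
                            data_fingerprint=fp)
        mats = [Cs[r] for r in regs]

        # optimize relative rates (first regime rate fixed to 1 in V1)
        from scipy.optimize import minimize

        def nll(logrel):
            rel = np.concatenate([[1.0], np.exp(logrel)])
            V1 = sum(w * M for w, M in zip(rel, mats))
            try:
                return -_profile_loglik(y, V1)[0]
            except np.linalg.LinAlgError:
                return np.inf

        best = None
        for start in ([0.0] * (len(regs) - 1), [1.0] * (len(regs) - 1),
                      [-1.0] * (len(regs) - 1)):
            res = minimize(nll, np.asarray(start, float), method="L-BFGS-B",
                           bounds=[(-12, 12)] * (len(regs) - 1))
            if best is None or res.fun < best.fun:
                best = res
        rel = np.concatenate([[1.0], np.exp(best.x)])
        V1 = sum(w * M for w, M in zip(rel, mats))
        ll, s2, th = _profile_loglik(y, V1)
        params = {f"sigma2[{r}]": float(s2 * w) for r, w in zip(regs, rel)}
        params["z0"] = float(th[0])
        k = len(regs) + 1
        return ModelFit("BMS", params, ll, k, n, _aicc_or_nan(ll, k, n),
                        converged=bool(best.success), data_fingerprint=fp)

    # OUM
    regs = tree.regimes()
    if not regs:
        raise ValueError("OUM requires a regime painting")

    def ll_of(la):
        a = np.exp(la)
        V1 = _ou_V1(tree, a, stationary_root)
        W = _oum_weights(tree, a, regs)
        try:
            return _profile_loglik(y, V1, W)[0]
        except np.linalg.LinAlgError:
            return -np.inf

    if "alpha" in fixed:
        alpha = float(fixed["alpha"])
        ok = True
    else:
        la, _, ok = _optimize_1d(ll_of, (np.log(1e-6 / T), np.log(100.0 / T)))
        alpha = float(np.exp(la))
    V1 = _ou_V1(tree, alpha, stationary_root)
    W = _oum_weights(tree, alpha, regs)
    ll, s2, th = _profile_loglik(y, V1, W)
    params = {"alpha": alpha, "sigma2": s2}
    params.update({f"theta[{r}]": float(t) for r, t in zip(regs, th)})
    k = 2 + len(regs)
    return ModelFit("OUM", params, ll, k, n, _aicc_or_nan(ll, k, n), converged=ok,
                    data_fingerprint=fp)


# ---------------------------------------------------------------------
# lineage-interaction models


def _lineage_epochs(tree: Phylogeny, sympatry: SympatryStructure | None):
    """Epoch decomposition with, per epoch, the live branches and the count
    of co-occurring lineages for each (via extant descendants when a
    sympatry structure is given)."""
    times, live = tree.epochs()
    desc = {nd: frozenset(tree.descendant_tips(nd)) for nd in tree.preorder()}
    if sympatry is not None:
        sidx = {s: i for i, s in enumerate(sympatry.species)}
        M = sympatry.matrix

        def co(a: Node, b: Node) -> bool:
            return any(
                M[sidx[x], sidx[yy]] for x in desc[a] for yy in desc[b]
            )
    else:
        def co(a: Node, b: Node) -> bool:
            return True

    counts = []
    comat = []
    for branches in live:
        L = len(branches)
        A = np.eye(L)
        for i in range(L):
            for j in range(i + 1, L):
                A[i, j] = A[j, i] = 1.0 if co(branches[i], branches[j]) else 0.0
        comat.append(A)
        counts.append(A.sum(axis=1))  # includes self
    return times, live, counts, comat


def _dd_V1(tree: Phylogeny, kappa: float, sympatry, form: str) -> np.ndarray:
    """Shared-path integral matrix for diversity-dependent rates, relative
    to sigma0^2: rate(t)/sigma0^2 = 1 + kappa*n(t) (DDl) or e^{kappa n(t)}
    (DD2), with n(t) the lineage's co-occurring count."""
    times, live, counts, _ = _lineage_epochs(tree, sympatry)
    weights: dict[Node, float] = {nd: 0.0 for nd in tree.preorder()}
    for k in range(len(live)):
        dt = times[k + 1] - times[k]
        for b, nct in zip(live[k], counts[k]):
            if form == "DDl":
                rate = 1.0 + kappa * nct
            else:
                rate = float(np.exp(kappa * nct))
            if rate <= 0:
                raise ValueError("non-positive diversity-dependent rate")
            weights[b] += rate * dt
    return _weighted_vcv(tree, weights)


def _weighted_vcv(tree: Phylogeny, weights: dict) -> np.ndarray:
    tips = tree.tips()
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    acc: dict[Node, float] = {tree.root: 0.0}
    for nd in tree.preorder():
        if nd is not tree.root:
            acc[nd] = acc[nd.parent] + weights.get(nd, 0.0)
    V = np.zeros((n, n))
    tipsets: dict[Node, list[int]] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            tipsets[nd] = [idx[nd]]
            V[idx[nd], idx[nd]] = acc[nd]
        else:
            kids = [tipsets[c] for c in nd.children]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            V[i, j] = V[j, i] = acc[nd]
            tipsets[nd] = [i for k in kids for i in k]
    return V


def _mc_V1(tree: Phylogeny, S: float, sympatry) -> np.ndarray:
    """Among-tip covariance (relative to sigma^2) under matching competition:
    deviations decay toward the sympatric mean at rate |S| (S <= 0)."""
    times, live, counts, comat = _lineage_epochs(tree, sympatry)
    V = None
    prev: list[Node] = []
    glq_x, glq_w = np.polynomial.legendre.leggauss(12)
    for k in range(len(live)):
        branches = live[k]
        L = len(branches)
        if V is None:
            V = np.zeros((L, L))
        else:
            # expand V to the new lineage set, inheriting from ancestors
            prev_idx = {b: i for i, b in enumerate(prev)}
            rows = []
            for b in branches:
                anc = b
                while anc not in prev_idx:
                    anc = anc.parent
                rows.append(prev_idx[anc])
            V = V[np.ix_(rows, rows)]
        dt = times[k + 1] - times[k]
        A = comat[k].copy()
        np.fill_diagonal(A, 0.0)
        deg = A.sum(axis=1)
        Mavg = np.divide(A, deg[:, None], out=np.zeros_like(A), where=deg[:, None] > 0)
        Amat = S * (np.eye(L) - Mavg)
        Amat[deg == 0] = 0.0  # allopatric lineages evolve freely
        if abs(S) < 1e-14:
            V = V + dt * np.eye(L)
        else:
            E = expm(Amat * dt)
            # V(dt) = E V E' + int_0^dt e^{A s} e^{A' s} ds (Gauss-Legendre)
            I = np.zeros((L, L))
            for x, w in zip(glq_x, glq_w):
                s = 0.5 * dt * (x + 1.0)
                Es = expm(Amat * s)
                I += w * (Es @ Es.T)
            I *= 0.5 * dt
            V = E @ V @ E.T + I
        prev = branches
    # map final lineages (pendant branches) to tip order
    tips = tree.tips()
    pos = {b: i for i, b in enumerate(prev)}
    order = [pos[t] for t in tips]
    return V[np.ix_(order, order)]


def fit_interaction_model(
    tree: Phylogeny,
    trait,
    model: str,
    sympatry: SympatryStructure | None = None,
    tip_labels=None,
    fixed: dict | None = None,
) -> ModelFit:
    """Fit MC, DDl or DD2 by maximum likelihood on an ultrametric tree.

    Under MC the trait covariance is integrated epoch by epoch through the
    linear SDE for lineage deviations; under DD the rate is a deterministic
    function of the number of co-occurring lineages, so the covariance is a
    shared-path integral. sigma^2 and the root state are profiled.
    """
    if model not in INTERACTION_MODELS:
        raise ValueError(f"unknown interaction model {model!r}")
    if not tree.is_ultrametric(1e-4):
        raise ValueError(f"{model} requires an ultrametric tree")
    y = _align(tree, trait, tip_labels)
    n = y.size
    fixed = fixed or {}
    T = tree.height
    fp = float(np.sum(y) + 1e-3 * np.sum(y**2))

    if model == "MC":
        def ll_of(S):
            try:
                return _profile_loglik(y, _mc_V1(tree, S, sympatry))[0]
            except np.linalg.LinAlgError:
                return -np.inf

        if "S" in fixed:
            S, ok = float(fixed["S"]), True
        else:
            S, _, ok = _optimize_1d(ll_of, (-20.0 / T, 0.0))
        ll, s2, th = _profile_loglik(y, _mc_V1(tree, S, sympatry))
        params = {"S": float(S), "sigma2": s2, "z0": float(th[0])}
        k = 3
        return ModelFit("MC", params, ll, k, n, _aicc_or_nan(ll, k, n), converged=ok,
                        data_fingerprint=fp)

    # DDl / DD2: kappa = b / sigma0^2 (DDl) or b (DD2)
    nmax = tree.n_tips

    def ll_of(kap):
        try:
            return _profile_loglik(y, _dd_V1(tree, kap, sympatry, model))[0]
        except (np.linalg.LinAlgError, ValueError):
            return -np.inf

    if "b" in fixed:
        kap, ok = float(fixed["b"]), True
    else:
        lim = 0.95 / nmax if model == "DDl" else 10.0 / nmax
        kap, _, ok = _optimize_1d(ll_of, (-lim, 10.0 / nmax))
    ll, s2, th = _profile_loglik(y, _dd_V1(tree, kap, sympatry, model))
    if model == "DDl":
        params = {"sigma2_0": s2, "b": float(kap * s2), "z0": float(th[0])}
    else:
        params = {"sigma2_0": s2, "b": float(kap), "z0": float(th[0])}
    k = 3
    return ModelFit(model, params, ll, k, n, _aicc_or_nan(ll, k, n), converged=ok,
                    data_fingerprint=fp)


def compare_models(fits) -> pd.DataFrame:
    """AICc model ranking with Akaike weights; all fits must share the data."""
    fits = list(fits)
    fps = {round(f.data_fingerprint, 8) for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different data")
    a = np.array([f.AICc for f in fits])
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.AICcw = float(wi)
    out = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "logLik": [f.logLik for f in fits],
            "k": [f.k for f in fits],
            "AICc": a,
            "delta_AICc": delta,
            "AICcw": w,
        }
    ).sort_values("AICc", ignore_index=True)
    return out
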