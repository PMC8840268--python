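"""From raw measurements to shape data.

Linear datasets become log-shape ratios (trait / geometric-mean size, then
natural log); landmark datasets go through generalized Procrustes analysis,
bending-energy semilandmark sliding, and extraction of the symmetric
component of shape. A sexual-dimorphism filter drops females of species in
which sex has a significant effect on shape (sampling is male-biased in the
kind of museum series this pipeline targets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .stats import rrpp_f_test
from .tps import bending_energy_matrix

__all__ = [
    "LinearTable",
    "LandmarkBlock",
    "ShapeData",
    "log_shape_ratios",
    "gpa",
    "opa_align",
    "slide_displacements",
    "slide_semilandmarks",
    "symmetric_component",
    "dimorphism_filter",
]


@dataclass
class LinearTable:
    """Specimens x linear traits (mm), with species and sex labels."""

    specimen_id: np.ndarray
    species: np.ndarray
    sex: np.ndarray  # {"M", "F", "unknown"}
    traits: pd.DataFrame  # positive reals, one column per measurement

    def __post_init__(self):
        vals = self.traits.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("all trait values must be finite and > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinearTable":
        meta = ["specimen_id", "species", "sex"]
        return cls(
            specimen_id=df["specimen_id"].to_numpy(),
            species=df["species"].to_numpy(),
            sex=df["sex"].to_numpy(),
            traits=df.drop(columns=meta).astype(float),
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "specimen_id": self.specimen_id,
                "species": self.species,
                "sex": self.sex,
            }
        )
        return pd.concat([out, self.traits.reset_index(drop=True)], axis=1)


@dataclass
class LandmarkBlock:
    """Specimens x landmarks x 2 coordinates with slider/symmetry metadata."""

    specimen_id: np.ndarray
    species: np.ndarray
    sex: np.ndarray
    coords: np.ndarray  # (n, k, 2)
    fixed_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    slider_triples: list = field(default_factory=list)  # [(before, slider, after)]
    symmetry_pairs: list = field(default_factory=list)  # [(left, right)]
    midline_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        k = self.coords.shape[1]
        for trip in self.slider_triples:
            if any(i < 0 or i >= k for i in trip):
                raise ValueError(f"slider triple {trip} references invalid landmark")
        paired = {i for pr in self.symmetry_pairs for i in pr}
        if paired & set(np.asarray(self.midline_idx, dtype=int).tolist()):
            raise ValueError("symmetry pairs must be disjoint from the midline")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


@dataclass
class ShapeData:
    """The common currency of all downstream tests."""

    Y: np.ndarray  # (n, q)
    size: np.ndarray  # (n,) natural-log size
    species: np.ndarray
    sex: np.ndarray
    dataset_tag: str = ""
    var_names: list = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.size = np.asarray(self.size, dtype=float)
        self.species = np.asarray(self.species)
        if self.Y.shape[0] != self.size.shape[0]:
            raise ValueError("Y rows must align with the size vector")

    def subset(self, mask) -> "ShapeData":
        mask = np.asarray(mask)
        return replace(
            self,
            Y=self.Y[mask],
            size=self.size[mask],
            species=self.species[mask],
            sex=np.asarray(self.sex)[mask],
        )

    def species_list(self) -> list:
        seen = []
        for s in self.species:
            if s not in seen:
                seen.append(s)
        return seen


# ---------------------------------------------------------------------
# log-shape ratios


def log_shape_ratios(
    body: LinearTable, limbs: LinearTable | None = None
) -> tuple[ShapeData, ...]:
    """Log-shape ratios with size as the log geometric mean of all traits.

    When a specimen appears in both tables, size is the geometric mean of
    the combined trait set; specimens present in a single table fall back
    to the geometric mean of their available traits (with a warning).
    """
    tables = [t for t in (body, limbs) if t is not None]
    tags = ["body", "limbs"][: len(tables)]

    gm: dict = {}
    counts: dict = {}
    for t in tables:
        vals = np.log(t.traits.to_numpy(dtype=float))
        for sid, row in zip(t.specimen_id, vals):
            gm[sid] = gm.get(sid, 0.0) + row.sum()
            counts[sid] = counts.get(sid, 0) + row.size
    logsize = {sid: gm[sid] / counts[sid] for sid in gm}

    if len(tables) == 2:
        only = set(tables[0].specimen_id) ^ set(tables[1].specimen_id)
        if only:
            warnings.warn(
                f"{len(only)} specimens present in a single table; size uses "
                "the geometric mean of their available traits",
                stacklevel=2,
            )

    out = []
    for t, tag in zip(tables, tags):
        logs = np.log(t.traits.to_numpy(dtype=float))
        size = np.array([logsize[sid] for sid in t.specimen_id])
        Y = logs - size[:, None]
        out.append(
            ShapeData(
                Y=Y,
                size=size,
                species=t.species,
                sex=t.sex,
                dataset_tag=tag,
                var_names=list(t.traits.columns),
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------
# Procrustes superimposition


def centroid_size(conf: np.ndarray) -> float:
    c = conf - conf.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def opa_align(ref: np.ndarray, mob: np.ndarray) -> np.ndarray:
    """Rotate/translate ``mob`` onto ``ref`` (least squares, no reflection,
    no rescaling)."""
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    H = b.T @ a
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    return b @ R + ref.mean(axis=0)


def gpa(block: LandmarkBlock, tol: float = 1e-8, max_iter: int = 100):
    """Generalized Procrustes analysis: center, scale to unit centroid size,
    and iteratively rotate to the updated mean shape.

    Returns (aligned block, centroid sizes before scaling).
    """
    X = block.coords
    n, k, _ = X.shape
    if n < 2 or k < 3:
        raise ValueError("GPA needs >= 2 specimens and >= 3 landmarks")
    cs = np.array([centroid_size(c) for c in X])
    if np.any(cs < 1e-12):
        raise ValueError("degenerate configuration: all landmarks coincident")
    Z = np.array([(c - c.mean(axis=0)) / s for c, s in zip(X, cs)])
    # initial reference: first specimen
    mean = Z[0]
    for _ in range(max_iter):
        Z = np.array([opa_align(mean, z) for z in Z])
        new_mean = Z.mean(axis=0)
        new_mean = (new_mean - new_mean.mean(axis=0)) / centroid_size(new_mean)
        if np.sum((new_mean - mean) ** 2) < tol**2:
            mean = new_mean
            break
        mean = new_mean
    # canonical orientation: mean principal axes, fixed 180-degree convention,
    # so the result does not depend on the input orientation or order
    _, _, Vt = np.linalg.svd(mean - mean.mean(axis=0))
    R = Vt.T
    if np.linalg.det(R) < 0:
        R = R @ np.diag([1.0, -1.0])
    mean_r = mean @ R
    sk = np.sum(mean_r**3, axis=0)
    flip = sk[0] if abs(sk[0]) > abs(sk[1]) else sk[1]
    if flip < 0:
        R = -R  # 180-degree rotation
        mean_r = -mean_r
    Z = np.array([opa_align(mean_r, z @ R) for z in Z])
    aligned = replace(block, coords=Z)
    return aligned, cs


def _tangents(conf: np.ndarray, triples) -> np.ndarray:
    """Unit tangent at each slider from its neighbor triple (central diff)."""
    T = np.zeros((len(triples), 2))
    for j, (a, m, b) in enumerate(triples):
        v = conf[b] - conf[a]
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError(f"slider landmark {m}: coincident neighbors {a},{b}")
        T[j] = v / nrm
    return T


def slide_displacements(
    conf: np.ndarray, mean: np.ndarray, triples, B: np.ndarray | None = None
) -> np.ndarray:
    """Tangent displacement per semilandmark minimizing the thin-plate-spline
    bending energy of (conf + displacement) relative to ``mean``."""
    if B is None:
        B = bending_energy_matrix(mean)
    sliders = [t[1] for t in triples]
    T = _tangents(conf, triples)
    k = conf.shape[0]
    m = len(sliders)
    U = np.zeros((2 * k, m))
    for j, lm in enumerate(sliders):
        U[lm, j] = T[j, 0]
        U[k + lm, j] = T[j, 1]
    B2 = np.kron(np.eye(2), B)
    v = np.concatenate([conf[:, 0] - mean[:, 0], conf[:, 1] - mean[:, 1]])
    A = U.T @ B2 @ U
    rhs = -U.T @ B2 @ v
    return np.linalg.lstsq(A, rhs, rcond=None)[0]


def slide_semilandmarks(
    block: LandmarkBlock, max_outer: int = 5, tol: float = 1e-8
) -> LandmarkBlock:
    """Slide semilandmarks along local tangents to minimize thin-plate-spline
    bending energy relative to the current mean shape, re-running GPA after
    each pass. Bending energy is non-increasing across outer iterations.
    """
    if not block.slider_triples:
        return block
    blk = block
    prev_energy = np.inf
    for _ in range(max_outer):
        blk, _ = gpa(blk)
        Z = blk.coords.copy()
        mean = Z.mean(axis=0)
        B = bending_energy_matrix(mean)
        sliders = [t[1] for t in blk.slider_triples]
        energy = 0.0
        for i in range(Z.shape[0]):
            conf = Z[i]
            T = _tangents(conf, blk.slider_triples)
            c = slide_displacements(conf, mean, blk.slider_triples, B)
            conf[sliders, 0] += c * T[:, 0]
            conf[sliders, 1] += c * T[:, 1]
            d = conf - mean
            energy += float(d[:, 0] @ B @ d[:, 0] + d[:, 1] @ B @ d[:, 1])
            Z[i] = conf
        blk = replace(blk, coords=Z)
        if prev_energy - energy < tol:
            prev_energy = energy
            break
        prev_energy = energy
    blk, _ = gpa(blk)
    return blk


def symmetric_component(block: LandmarkBlock) -> LandmarkBlock:
    """Symmetric component of shape for object symmetry.

    Each configuration is averaged with its reflected, relabeled copy
    (optimally aligned first), then the block is re-superimposed.
    """
    k = block.n_landmarks
    paired = {i for pr in block.symmetry_pairs for i in pr}
    midline = set(np.asarray(block.midline_idx, dtype=int).tolist())
    missing = set(range(k)) - paired - midline
    if missing:
        raise ValueError(f"unpaired non-midline landmarks: {sorted(missing)}")
    relabel = np.arange(k)
    for a, b in block.symmetry_pairs:
        relabel[a], relabel[b] = b, a
    Z = block.coords.copy()
    out = np.empty_like(Z)
    for i, conf in enumerate(Z):
        refl = conf * np.array([-1.0, 1.0])
        refl = refl[relabel]
        refl = opa_align(conf, refl)
        out[i] = 0.5 * (conf + refl)
    blk = replace(block, coords=out)
    blk, _ = gpa(blk)
    return blk


# ---------------------------------------------------------------------
# sexual dimorphism filter


def dimorphism_filter(
    data: ShapeData, config: RunConfig | None = None
) -> tuple[ShapeData, pd.DataFrame]:
    """Residual-randomization ANOVA of shape on sex per species; females of
    significantly dimorphic species are removed (sampling is male-biased).

    Returns the filtered data and a per-species report.
    """
    cfg = config or RunConfig()
    keep = np.ones(data.Y.shape[0], dtype=bool)
    rows = []
    sex = np.asarray(data.sex)
    for sp in data.species_list():
        m = data.species == sp
        sexes = set(sex[m]) - {"unknown"}
        if not {"M", "F"} <= sexes:
            rows.append({"species": sp, "p": np.nan, "females_removed": False,
                         "n_after": int(m.sum())})
            continue
        sub = data.subset(m)
        tested = np.isin(np.asarray(sub.sex), ["M", "F"])
        Y = sub.Y[tested]
        is_f = (np.asarray(sub.sex)[tested] == "F").astype(float)
        n = Y.shape[0]
        X0 = np.ones((n, 1))
        X1 = np.column_stack([np.ones(n), is_f])
        res = rrpp_f_test(
            Y, X0, X1, n_permutations=cfg.n_permutations,
            rng=cfg.rng(f"dimorphism:{sp}"),
        )
        remove = res.p < cfg.alpha
        if remove:
            keep[m & (sex == "F")] = False
        n_after = int((m & keep).sum())
        rows.append({"species": sp, "p": res.p, "females_removed": bool(remove),
                     "n_after": n_after})
        if n_after < 5:
            warnings.warn(
                f"species {sp}: n={n_after} after dimorphism filter (< 5)",
                stacklevel=2,
            )
    report = pd.DataFrame(rows)
    return data.subset(keep), report
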