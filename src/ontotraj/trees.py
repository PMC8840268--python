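"""Rooted time-calibrated phylogenies with optional branch regime paintings.

Newick parsing and serialization go through dendropy; the in-memory
representation is a light mutable node tree tailored to the comparative
methods here: Brownian-motion covariance matrices, per-regime shared path
times (for multi-rate and multi-optimum models), branching epochs (for
interaction models), and clade enumeration (for rate-shift searches).
"""

from __future__ import annotations

import re
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

__all__ = ["Node", "Phylogeny", "read_newick", "read_painted_tree"]


class Node:
    __slots__ = ("label", "length", "support", "children", "parent", "paint")

    def __init__(self, label=None, length=0.0, support=None):
        self.label = label
        self.length = float(length) if length is not None else 0.0
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        # list of (regime, duration) segments ordered rootward->tipward
        self.paint: list[tuple[str, float]] | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with strictly positive branch lengths and unique tips."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for nd in self.preorder():
            if nd is not self.root and not (nd.length > 0):
                raise ValueError(
                    f"non-positive branch length ({nd.length}) above node {nd.label!r}"
                )

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterable[Node]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [nd for nd in self.preorder() if not nd.is_leaf]
        if exclude_root:
            out = [nd for nd in out if nd is not self.root]
        return out

    # -- geometry ------------------------------------------------------

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (root depth 0)."""
        d = {self.root: 0.0}
        for nd in self.preorder():
            if nd is not self.root:
                d[nd] = d[nd.parent] + nd.length
        return d

    @property
    def height(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths()
        hs = np.array([d[t] for t in self.tips()])
        return float(hs.max() - hs.min()) <= rtol * max(hs.max(), 1e-300)

    def mrca_depths(self) -> np.ndarray:
        """Matrix of root-to-MRCA depths between tips = BM covariance / sigma^2."""
        tips = self.tips()
        idx = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        d = self.depths()
        C = np.zeros((n, n))
        tipsets: dict[Node, list[int]] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                tipsets[nd] = [idx[nd]]
                C[idx[nd], idx[nd]] = d[nd]
            else:
                kids = [tipsets[c] for c in nd.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = d[nd]
                tipsets[nd] = [i for k in kids for i in k]
        return C

    def vcv(self) -> np.ndarray:
        return self.mrca_depths()

    # -- regime painting ----------------------------------------------

    @property
    def has_painting(self) -> bool:
        return any(
            nd.paint is not None for nd in self.preorder() if nd is not self.root
        )

    def validate_painting(self, atol: float = 1e-6) -> None:
        for nd in self.preorder():
            if nd is self.root:
                continue
            if nd.paint is None:
                raise ValueError(f"branch above {nd.label!r} lacks regime segments")
            s = sum(dur for _, dur in nd.paint)
            if abs(s - nd.length) > atol:
                raise ValueError(
                    f"painting segments on branch above {nd.label!r} sum to {s}, "
                    f"branch length is {nd.length}"
                )

    def regimes(self) -> list[str]:
        out: set[str] = set()
        for nd in self.preorder():
            if nd.paint:
                out.update(r for r, _ in nd.paint)
        return sorted(out)

    def paint_single_regime(self, regime: str) -> None:
        for nd in self.preorder():
            if nd is not self.root:
                nd.paint = [(regime, nd.length)]

    def regime_vcv(self) -> dict[str, np.ndarray]:
        """Per-regime shared path times: C_r[i,j] = time spent in regime r on
        the root->MRCA(i,j) path. Sum over regimes equals vcv()."""
        self.validate_painting()
        regs = self.regimes()
        tips = self.tips()
        idx = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        occ: dict[Node, dict[str, float]] = {self.root: {r: 0.0 for r in regs}}
        for nd in self.preorder():
            if nd is self.root:
                continue
            o = dict(occ[nd.parent])
            for r, dur in nd.paint:
                o[r] = o.get(r, 0.0) + dur
            occ[nd] = o
        Cs = {r: np.zeros((n, n)) for r in regs}
        tipsets: dict[Node, list[int]] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                tipsets[nd] = [idx[nd]]
                for r in regs:
                    Cs[r][idx[nd], idx[nd]] = occ[nd][r]
            else:
                kids = [tipsets[c] for c in nd.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                for r in regs:
                                    Cs[r][i, j] = Cs[r][j, i] = occ[nd][r]
                tipsets[nd] = [i for k in kids for i in k]
        return Cs

    def tip_path_segments(self) -> list[list[tuple[str, float, float]]]:
        """Per tip, the (regime, t_start, t_end) segments along the root->tip
        path, in time-from-root coordinates. Requires a painting."""
        self.validate_painting()
        d = self.depths()
        out = []
        for tip in self.tips():
            path = []
            nd = tip
            while nd is not self.root:
                path.append(nd)
                nd = nd.parent
            path.reverse()
            segs = []
            for nd in path:
                t0 = d[nd.parent]
                for r, dur in nd.paint:
                    segs.append((r, t0, t0 + dur))
                    t0 += dur
            out.append(segs)
        return out

    # -- epochs (for lineage-interaction models) -----------------------

    def epochs(self):
        """Branching epochs of an ultrametric tree.

        Returns (times, live_sets): times is the sorted array of event times
        (root age 0 .. tree height), live_sets[k] is the list of nodes whose
        branch spans the interval (times[k], times[k+1]).
        """
        if not self.is_ultrametric(1e-4):
            raise ValueError("epoch decomposition requires an ultrametric tree")
        d = self.depths()
        T = self.height
        node_times = sorted({0.0, T} | {round(d[nd], 12) for nd in self.internal_nodes()})
        live = []
        for k in range(len(node_times) - 1):
            t0, t1 = node_times[k], node_times[k + 1]
            mid = 0.5 * (t0 + t1)
            alive = [
                nd
                for nd in self.preorder()
                if nd is not self.root and d[nd.parent] <= mid < d[nd] + 1e-12
            ]
            live.append(alive)
        return np.array(node_times), live

    def descendant_tips(self, nd: Node) -> list[str]:
        if nd.is_leaf:
            return [nd.label]
        out = []
        stack = [nd]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.append(cur.label)
            else:
                stack.extend(cur.children)
        return out

    def clades(self, min_size: int = 2) -> dict[Node, list[str]]:
        """Non-root internal nodes mapped to their tip label sets."""
        return {
            nd: self.descendant_tips(nd)
            for nd in self.internal_nodes(exclude_root=True)
            if len(self.descendant_tips(nd)) >= min_size
        }

    # -- serialization -------------------------------------------------

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                core = nd.label or ""
            else:
                inner = ",".join(fmt(c) for c in nd.children)
                lab = ""
                if include_support and nd.support is not None:
                    lab = _num(nd.support)
                elif nd.label:
                    lab = nd.label
                core = f"({inner}){lab}"
            if nd is self.root:
                return core
            return f"{core}:{_num(nd.length)}"

        return fmt(self.root) + ";"

    def copy(self) -> "Phylogeny":
        def clone(nd: Node) -> Node:
            c = Node(nd.label, nd.length if nd.parent is not None else 0.0, nd.support)
            c.paint = list(nd.paint) if nd.paint is not None else None
            for ch in nd.children:
                c.add(clone(ch))
            return c

        return Phylogeny(clone(self.root))

    def drop_tips(self, labels) -> "Phylogeny":
        """Prune the named tips and suppress the resulting degree-2 nodes."""
        drop = set(labels)
        keep = [l for l in self.tip_labels if l not in drop]
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        t = self.copy()
        true_leaves = set(self.tip_labels) - drop
        changed = True
        while changed:
            changed = False
            for nd in list(t.preorder()):
                # prune dropped tips and internals emptied by pruning
                if (
                    not nd.children
                    and nd.parent is not None
                    and nd.label not in true_leaves
                ):
                    nd.parent.children.remove(nd)
                    changed = True
            # suppress unifurcations
            for nd in list(t.preorder()):
                if nd.is_leaf or nd is t.root:
                    continue
                if len(nd.children) == 1:
                    child = nd.children[0]
                    child.length += nd.length
                    child.parent = nd.parent
                    i = nd.parent.children.index(nd)
                    nd.parent.children[i] = child
                    changed = True
        while len(t.root.children) == 1:
            t.root = t.root.children[0]
            t.root.parent = None
            t.root.length = 0.0
        return Phylogeny(t.root)


def _num(x: float) -> str:
    s = repr(float(x))
    return s


_PAINT_RE = re.compile(r"\[&paint=([^\]]*)\]")
_SEG_RE = re.compile(r"\{([^:{}]+):([0-9.eE+\-]+)\}")


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Internal node labels that parse as numbers in [0, 1] are interpreted as
    node supports (posterior probabilities).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages carry the offset
        raise ValueError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        support = None
        if dnode.child_nodes() and label is not None:
            try:
                val = float(label)
            except ValueError:
                val = None
            if val is not None and 0.0 <= val <= 1.0:
                support = val
                label = None
        nd = Node(label=label, length=dnode.edge.length or 0.0, support=support)
        for ch in dnode.child_nodes():
            nd.add(convert(ch))
        return nd

    root = convert(dtree.seed_node)
    root.length = 0.0
    return Phylogeny(root)


def read_painted_tree(text: str, segments: pd.DataFrame | None = None) -> Phylogeny:
    """Parse a regime-painted tree.

    Two dialects are accepted:

    * newick with ``[&paint={regime:dur}{regime:dur}]`` annotations placed
      after a branch length, segments ordered rootward to tipward;
    * plain newick plus a ``segments`` table with columns
      ``branch`` (child node label), ``regime``, ``duration``.

    Segment durations must sum to the branch length within 1e-6.
    """
    paints: list[list[tuple[str, float]]] = []

    def stash(m: re.Match) -> str:
        segs = [(r, float(dur)) for r, dur in _SEG_RE.findall(m.group(3))]
        if not segs:
            raise ValueError(f"unparseable paint annotation: {m.group(0)}")
        paints.append(segs)
        return f"__PAINT{len(paints) - 1}__"

    # move the annotation into the node label so dendropy keeps it
    tagged = re.sub(
        r"([A-Za-z0-9_.\-]*)(:[0-9.eE+\-]+)" + _PAINT_RE.pattern,
        lambda m: f"{m.group(1)}{stash(m)}{m.group(2)}",
        text,
    )
    tree = read_newick(tagged)
    for nd in tree.preorder():
        for field in ("label",):
            val = getattr(nd, field)
            if val and "__PAINT" in val:
                base, tag = val.split("__PAINT")
                k = int(tag.rstrip("_"))
                nd.paint = paints[k]
                base = base or None
                if base is not None and not nd.is_leaf:
                    try:
                        f = float(base)
                        if 0 <= f <= 1:
                            nd.support, base = f, None
                    except ValueError:
                        pass
                nd.label = base

    if segments is not None:
        by_label = {nd.label: nd for nd in tree.preorder() if nd.label}
        for branch, grp in segments.groupby("branch", sort=False):
            if branch not in by_label:
                raise ValueError(f"segments refer to unknown branch {branch!r}")
            by_label[branch].paint = [
                (str(r.regime), float(r.duration)) for r in grp.itertuples()
            ]

    if tree.has_painting:
        tree.validate_painting()
    return tree
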