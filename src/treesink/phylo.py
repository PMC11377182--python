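"""Phylogenies, Newick I/O, birth-death simulation, and effective-tree transforms.

A :class:`Phylogeny` is a rooted tree with branch lengths proportional to
time.  Tips occupy node ids ``0 .. n_tips-1`` in a canonical left-to-right
order (see :meth:`Phylogeny.from_nested`); internal nodes follow in preorder.
The canonical ordering matters because downstream code treats a community as
a binary vector aligned to tip order, and convolutional features read that
vector positionally.

Effective trees -- branch-length-rescaled versions of the time tree on which
traits appear to evolve under plain Brownian motion -- are produced by
:func:`eb_rescale` (exponential rate change through time, the early/late
burst family) and :func:`delta_rescale` (node depths raised to a power).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phylogeny",
    "TransformParameter",
    "NewickError",
    "read_newick",
    "write_newick",
    "simulate_birth_death",
    "eb_rescale",
    "delta_rescale",
    "tree_depth",
    "cophenetic_distances",
    "shared_path_matrix",
]

#: values of |a| below this are treated as exactly 0 in the EB transform
_EB_ZERO_TOL = 1e-12


class NewickError(ValueError):
    """Raised for malformed Newick input."""


@dataclass(frozen=True)
class TransformParameter:
    """A branch-length transformation: ``model`` is ``"EB"`` or ``"delta"``.

    For EB, ``value`` is the exponent *a* (any real; 0 is the identity /
    Brownian-motion case).  For delta, ``value`` is δ > 0 (1 is identity).
    """

    model: str
    value: float

    def __post_init__(self) -> None:
        if self.model not in ("EB", "delta"):
            raise ValueError(f"unknown transform model {self.model!r}")
        if self.model == "delta" and not self.value > 0:
            raise ValueError("delta transform requires value > 0")

    def apply(self, tree: "Phylogeny") -> "Phylogeny":
        if self.model == "EB":
            return eb_rescale(tree, self.value)
        return delta_rescale(tree, self.value)


class _Nested:
    """Throwaway nested node used while building a Phylogeny."""

    __slots__ = ("label", "length", "children", "_ntips", "_minlab")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []


class Phylogeny:
    """Rooted phylogeny with canonical tip ordering, backed by flat arrays.

    Parameters
    ----------
    tip_labels : sequence of str
        Unique labels for tips ``0 .. n_tips-1`` in canonical order.
    parent : int array, shape (n_nodes,)
        Parent node id per node; the root has parent ``-1``.
    edge_length : float array, shape (n_nodes,)
        Length of the edge above each node (0 for the root).
    """

    def __init__(self, tip_labels: Sequence[str], parent, edge_length):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        n = self.parent.shape[0]
        if self.edge_length.shape != (n,):
            raise ValueError("parent and edge_length must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        if np.any(self.edge_length[np.arange(n) != self.root] < 0):
            raise ValueError("branch lengths must be nonnegative")
        self.n_nodes = n
        self.n_tips = len(self.tip_labels)
        # children lists and a preorder traversal (root first)
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                children[p].append(v)
        self.children = children
        order = np.empty(n, dtype=np.int64)
        stack = [self.root]
        i = 0
        seen = 0
        while stack:
            v = stack.pop()
            order[i] = v
            i += 1
            seen += 1
            stack.extend(reversed(children[v]))
        if seen != n:
            raise ValueError("not all nodes reachable from root")
        self.preorder = order
        self._cache: dict = {}

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_nested(cls, root: _Nested) -> "Phylogeny":
        """Build from a nested node structure, canonicalizing tip order.

        Children are ladderized: sorted by descendant tip count, ties by the
        smallest descendant tip label, so any rotation of the same tree
        yields the same tip order.
        """

        def annotate(nd: _Nested) -> None:
            if not nd.children:
                if nd.label is None:
                    raise NewickError("tip without a label")
                nd._ntips = 1
                nd._minlab = nd.label
                return
            for c in nd.children:
                annotate(c)
            nd.children.sort(key=lambda c: (c._ntips, c._minlab))
            nd._ntips = sum(c._ntips for c in nd.children)
            nd._minlab = min(c._minlab for c in nd.children)

        annotate(root)
        n_tips = root._ntips
        tip_labels: list[str] = []
        parent: list[int] = []
        length: list[float] = []
        next_internal = [n_tips]

        # iterative preorder walk assigning ids: tips 0.., internals n_tips..
        def walk(nd: _Nested, parent_id: int) -> None:
            if nd.children:
                my = next_internal[0]
                next_internal[0] += 1
            else:
                my = len(tip_labels)
                tip_labels.append(nd.label)
            while len(parent) <= my:
                parent.append(-2)
                length.append(0.0)
            parent[my] = parent_id
            length[my] = 0.0 if nd.length is None and parent_id < 0 else float(nd.length if nd.length is not None else 0.0)
            for c in nd.children:
                walk(c, my)

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * n_tips + 1000))
        try:
            walk(root, -1)
        finally:
            sys.setrecursionlimit(old)
        return cls(tip_labels, parent, length)

    def _with_edge_lengths(self, edge_length) -> "Phylogeny":
        """Same topology and labels, new branch lengths (shares path cache)."""
        new = object.__new__(Phylogeny)
        new.tip_labels = self.tip_labels
        new.parent = self.parent
        new.edge_length = np.asarray(edge_length, dtype=float)
        new.root = self.root
        new.n_nodes = self.n_nodes
        new.n_tips = self.n_tips
        new.children = self.children
        new.preorder = self.preorder
        new._cache = {}
        if "paths" in self._cache:
            new._cache["paths"] = self._cache["paths"]
        return new

    def copy(self) -> "Phylogeny":
        return self._with_edge_lengths(self.edge_length.copy())

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def node_depths(self) -> np.ndarray:
        """Time of each node measured from the root (path length)."""
        d = self._cache.get("depths")
        if d is None:
            d = np.zeros(self.n_nodes)
            for v in self.preorder[1:]:
                d[v] = d[self.parent[v]] + self.edge_length[v]
            self._cache["depths"] = d
        return d

    @property
    def path_matrix(self) -> np.ndarray:
        """Boolean (n_tips, n_nodes) matrix: edge v lies on the root->tip path.

        Topology-only, so it is shared between a tree and its rescalings.
        """
        P = self._cache.get("paths")
        if P is None:
            P = np.zeros((self.n_tips, self.n_nodes), dtype=bool)
            for tip in range(self.n_tips):
                v = tip
                while v != self.root:
                    P[tip, v] = True
                    v = self.parent[v]
            self._cache["paths"] = P
        return P

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        td = self.node_depths[: self.n_tips]
        return bool(np.allclose(td, td[0], rtol=rtol, atol=rtol * max(td[0], 1.0)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, depth {tree_depth(self):.4g}>"


# ----------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ----------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny.

    Tip order is canonicalized by ladderization, not by file order, so the
    same tree serialized with rotated clades reads back identically.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises rich positional errors
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> _Nested:
        nd = _Nested()
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickError("tip without a label")
            nd.label = dnode.taxon.label
        nd.length = dnode.edge.length
        if dnode.parent_node is not None and nd.length is None:
            raise NewickError(f"missing branch length above node {nd.label or '(internal)'}")
        nd.children = [convert(c) for c in dnode.child_nodes()]
        return nd

    return Phylogeny.from_nested(convert(dtree.seed_node))


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize to Newick (unquoted labels, decimal branch lengths)."""
    fmt = f"%.{precision}g"

    out = _io.StringIO()
    # iterative post-order emission to avoid recursion limits on big trees
    def emit(v: int) -> str:
        if not tree.children[v]:
            s = tree.tip_labels[v]
        else:
            s = "(" + ",".join(emit(c) for c in tree.children[v]) + ")"
        if v != tree.root:
            s += ":" + (fmt % tree.edge_length[v])
        return s

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * tree.n_nodes + 1000))
    try:
        out.write(emit(tree.root))
    finally:
        sys.setrecursionlimit(old)
    out.write(";")
    return out.getvalue()


# ----------------------------------------------------------------------
# birth-death simulation
# ----------------------------------------------------------------------

def simulate_birth_death(
    n_tips: int,
    birth: float = 0.8,
    death: float = 0.2,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> Phylogeny:
    """Simulate an ultrametric tree with exactly ``n_tips`` extant tips.

    Forward Gillespie simulation from a crown (two lineages at time 0) under
    constant per-lineage birth and death rates; the clock stops at the birth
    event that brings the extant count to ``n_tips``.  Extinct lineages are
    pruned, unifurcations suppressed, and the tree re-rooted at the most
    recent common ancestor of the survivors, so the result is ultrametric.
    Runs that go extinct first are retried up to ``max_attempts`` times.

    Tips are labelled ``t1 .. tN``; ordering is the canonical ladderization.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(max_attempts):
        result = _bd_attempt(rng, n_tips, birth, death)
        if result is not None:
            return result
    raise RuntimeError(
        f"birth-death simulation went extinct in {max_attempts} consecutive attempts"
    )


def _bd_attempt(rng: np.random.Generator, n_tips: int, birth: float, death: float):
    total = birth + death
    p_birth = birth / total
    # lineage records
    parent = [-1, 0, 0]          # lineage 0 is the crown ancestor (zero-length stem)
    start = [0.0, 0.0, 0.0]
    end = [0.0, None, None]      # None while alive
    extant = [1, 2]
    t = 0.0
    while True:
        n = len(extant)
        if n == 0:
            return None
        t += rng.exponential(1.0 / (total * n))
        idx = rng.integers(n)
        lin = extant[idx]
        if rng.random() < p_birth:
            end[lin] = t
            for _ in range(2):
                parent.append(lin)
                start.append(t)
                end.append(None)
            extant[idx] = len(parent) - 2
            extant.append(len(parent) - 1)
            if len(extant) == n_tips:
                break
        else:
            end[lin] = t
            extant[idx] = extant[-1]
            extant.pop()
    # close extant lineages at the stopping time
    alive = set(extant)
    for lin in extant:
        end[lin] = t

    # count surviving descendants per lineage (children lists, reverse order)
    nlin = len(parent)
    kids: list[list[int]] = [[] for _ in range(nlin)]
    for v in range(1, nlin):
        kids[parent[v]].append(v)
    survives = [False] * nlin
    for v in range(nlin - 1, -1, -1):
        if v in alive:
            survives[v] = True
        else:
            survives[v] = any(survives[c] for c in kids[v])

    # build pruned nested tree, suppressing unifurcations
    label_counter = [0]

    def build(v: int, top_start: float) -> _Nested:
        live_kids = [c for c in kids[v] if survives[c]]
        while len(live_kids) == 1 and v not in alive:
            v = live_kids[0]
            live_kids = [c for c in kids[v] if survives[c]]
        nd = _Nested()
        nd.length = end[v] - top_start
        if v in alive and not live_kids:
            label_counter[0] += 1
            nd.label = f"t{label_counter[0]}"
        else:
            nd.children = [build(c, end[v]) for c in live_kids]
        return nd

    # locate the MRCA of survivors: descend from lineage 0 through unifurcations
    v = 0
    while True:
        live = [c for c in kids[v] if survives[c]]
        if len(live) != 1:
            break
        v = live[0]
    root = build(v, start[v])
    root.length = None
    return Phylogeny.from_nested(root)


# ----------------------------------------------------------------------
# effective-tree transforms
# ----------------------------------------------------------------------

def eb_rescale(tree: Phylogeny, a: float) -> Phylogeny:
    """Exponential rate-through-time rescaling (early/late burst family).

    The instantaneous rate at absolute time *t* from the root is e^{a t}, so
    a branch spanning [t1, t2] gets length (e^{a t2} - e^{a t1}) / a.
    Negative *a* concentrates evolution early (stemmy effective tree),
    positive *a* late (tippy), a = 0 is the identity.
    """
    a = float(a)
    if not np.isfinite(a):
        raise ValueError("a must be finite")
    if abs(a) < _EB_ZERO_TOL:
        return tree.copy()
    t2 = tree.node_depths
    t1 = np.where(tree.parent >= 0, tree.node_depths[tree.parent], 0.0)
    # stable form of (e^{a t2} - e^{a t1}) / a: no cancellation as a -> 0
    new = np.exp(a * t1) * np.expm1(a * (t2 - t1)) / a
    new[tree.root] = 0.0
    return tree._with_edge_lengths(new)


def delta_rescale(tree: Phylogeny, delta: float, preserve_depth: bool = True) -> Phylogeny:
    """Raise node depths to the power δ (> 0).

    δ < 1 is stemmy, δ > 1 tippy, δ = 1 identity.  With ``preserve_depth``
    (default) all heights are then scaled by a common factor so the maximum
    root-to-tip depth equals the original depth.
    """
    delta = float(delta)
    if not delta > 0:
        raise ValueError("delta must be > 0")
    h = tree.node_depths
    H = h[: tree.n_tips].max()
    nh = h ** delta
    if preserve_depth and H > 0:
        nh = nh * (H / H ** delta)
    new = nh - np.where(tree.parent >= 0, nh[tree.parent], 0.0)
    new[tree.root] = 0.0
    return tree._with_edge_lengths(new)


def tree_depth(tree: Phylogeny) -> float:
    """Maximum root-to-tip path length."""
    return float(tree.node_depths[: tree.n_tips].max())


def shared_path_matrix(tree: Phylogeny) -> np.ndarray:
    """(n_tips, n_tips) matrix of shared root-to-tip path lengths.

    Equals the Brownian-motion covariance structure of tip values (up to the
    rate sigma^2).
    """
    P = tree.path_matrix
    return (P * tree.edge_length) @ P.T


def cophenetic_distances(tree: Phylogeny) -> np.ndarray:
    """Symmetric matrix of patristic distances between tips, in tip order."""
    C = shared_path_matrix(tree)
    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)
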