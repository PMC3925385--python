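"""Evolutionary distances, neighbor joining, bootstrap supports, Newick output.

The identification engine places each query OTU on an unrooted
neighbor-joining tree built from Kimura two-parameter (K2P) distances over
the query, its top reference hits, and a few outgroups from neighboring
families.  Internal-edge reliability is scored by nonparametric bootstrap:
alignment columns are resampled with replacement, the NJ tree is rebuilt,
and each bipartition of the reference tree is scored by the percentage of
replicate trees that contain it.

Everything here is deterministic: NJ ties are broken by the smallest
``(i, j)`` index pair of the current working matrix, bootstrap resampling is
driven by an explicit seed, and Newick children are emitted in a canonical
order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .seqops import AlignmentParams, DEFAULT_PARAMS, global_align

__all__ = [
    "DistanceMatrix", "PhyloTree", "TreeNode", "BootstrapConfig",
    "p_distance", "k2p_distance", "distance_matrix", "nj_tree",
    "bootstrap_supports", "align_star",
]


class SaturationError(ValueError):
    """K2P correction undefined: substitution saturation between a pair."""


# ---------------------------------------------------------------------------
# distances

_PURINES = {"A", "G"}


def _usable_pairs(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x not in "-N" and y not in "-N"
    ]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among gap/N-free columns."""
    pairs = _usable_pairs(a, b)
    if not pairs:
        raise ValueError("no usable columns")
    return sum(x != y for x, y in pairs) / len(pairs)


def _ts_tv_proportions(a: str, b: str) -> tuple[float, float]:
    pairs = _usable_pairs(a, b)
    if not pairs:
        raise ValueError("no usable columns")
    ts = tv = 0
    for x, y in pairs:
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts / len(pairs), tv / len(pairs)


def k2p_distance(a: str, b: str, labels: tuple[str, str] = ("a", "b")) -> float:
    """Kimura two-parameter distance: d = -ln(1-2P-Q)/2 - ln(1-2Q)/4.

    P and Q are the observed transition and transversion proportions over
    usable columns.  Raises :class:`SaturationError` when either logarithm
    argument is nonpositive.
    """
    P, Q = _ts_tv_proportions(a, b)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair {labels[0]!r} vs {labels[1]!r} (P={P:.3f}, Q={Q:.3f})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.data < 0):
            raise ValueError("distances must be nonnegative")


# site-pair classification codes used by the vectorized bootstrap
_SAME, _TS, _TV, _MASKED = 0, 1, 2, 3


def _encode_sites(seqs: list[str]) -> np.ndarray:
    code = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4, "-": 4}
    return np.array([[code.get(c, 4) for c in s.upper()] for s in seqs], dtype=np.int8)


def _classify_pairs(mat: np.ndarray) -> np.ndarray:
    """(n_pairs, L) array of site classes for each unordered pair i<j."""
    n, _ = mat.shape
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            x, y = mat[i], mat[j]
            cls = np.full(mat.shape[1], _SAME, dtype=np.int8)
            masked = (x == 4) | (y == 4)
            diff = (x != y) & ~masked
            ts = diff & ((x < 2) == (y < 2))  # both purines or both pyrimidines
            cls[diff] = _TV
            cls[ts] = _TS
            cls[masked] = _MASKED
            rows.append(cls)
    return np.array(rows)


def _k2p_from_classes(cls: np.ndarray, labels: list[str]) -> np.ndarray:
    """Distance matrix from a (n_pairs, L) class array (columns may repeat)."""
    n = len(labels)
    usable = (cls != _MASKED).sum(axis=1).astype(float)
    ts = (cls == _TS).sum(axis=1)
    tv = (cls == _TV).sum(axis=1)
    if np.any(usable == 0):
        raise ValueError("pair with no usable columns")
    P, Q = ts / usable, tv / usable
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        k = int(np.argmax((w1 <= 0) | (w2 <= 0)))
        i, j = _pair_of(k, n)
        raise SaturationError(f"saturated pair {labels[i]!r} vs {labels[j]!r}")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    out = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = d[k]
            k += 1
    return out


def _pair_of(k: int, n: int) -> tuple[int, int]:
    for i in range(n):
        for j in range(i + 1, n):
            if k == 0:
                return i, j
            k -= 1
    raise IndexError


def distance_matrix(seqs: Mapping[str, str], model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix over an aligned, equal-length sequence set."""
    labels = list(seqs)
    sl = [seqs[l] for l in labels]
    if len({len(s) for s in sl}) != 1:
        raise ValueError("sequences must be aligned to a common length")
    n = len(labels)
    d = np.zeros((n, n))
    fn = k2p_distance if model == "k2p" else (lambda a, b, labels: p_distance(a, b))
    if model not in ("k2p", "p"):
        raise ValueError(f"unknown distance model {model!r}")
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(sl[i], sl[j], labels=(labels[i], labels[j]))
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = length
        self.support: float | None = None
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode" | None = None

    def add(self, child: "TreeNode", length: float) -> None:
        child.length = length
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) with optional bootstrap supports."""

    root: TreeNode
    labels: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped_deficit: float = 0.0

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.root, self.labels)

    def support_of(self, side: Iterable[str]) -> float:
        """Bootstrap support of the edge splitting ``side`` from the rest.

        Trivial splits (single leaf / all-but-one) are always present and
        score 100.  Unscored internal splits default to 0.
        """
        norm = _normalize_split(frozenset(side), self.labels)
        if norm is None:
            return 100.0
        return self.supports.get(norm, 0.0) if self.supports else 100.0

    def to_newick(self, with_supports: bool = True) -> str:
        return to_newick(self.root, with_supports=with_supports)

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        nodes = {l.name: l for l in self.root.leaves()}
        anc_a = {}
        node, dist = nodes[a], 0.0
        while node is not None:
            anc_a[id(node)] = dist
            dist += node.length
            node = node.parent
        node, dist = nodes[b], 0.0
        while node is not None:
            if id(node) in anc_a:
                return dist + anc_a[id(node)]
            dist += node.length
            node = node.parent
        raise KeyError("leaves not connected")


def _normalize_split(side: frozenset, labels: list[str]) -> frozenset | None:
    """Canonical form of a bipartition; None when trivial."""
    full = frozenset(labels)
    side = frozenset(side) & full
    if len(side) < 2 or len(full - side) < 2:
        return None
    anchor = min(labels)
    return side if anchor not in side else full - side


def tree_bipartitions(root: TreeNode, labels: list[str]) -> set[frozenset]:
    """Nontrivial bipartitions induced by the internal edges of the tree."""
    out = set()
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        norm = _normalize_split(node.leaf_names(), labels)
        if norm is not None:
            out.add(norm)
    return out


def _sort_key(node: TreeNode) -> str:
    return min(l.name for l in node.leaves())


def to_newick(root: TreeNode, with_supports: bool = True) -> str:
    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length + 0.0:.6g}"
        inner = ",".join(
            fmt(c, False) for c in sorted(node.children, key=_sort_key)
        )
        label = ""
        if with_supports and node.support is not None:
            label = str(int(round(node.support)))
        if top:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.length + 0.0:.6g}"

    return fmt(root, True) + ";"


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0
    support_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q-matrix minimization with the standard two-node join and distance
    update; ties are broken by the smallest ``(i, j)`` pair in the current
    working order, so the result is platform-independent.  Negative branch
    lengths are clamped to zero and the clamped total is recorded on the
    returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    D = dm.data.copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        flat = np.full((k, k), np.inf)
        flat[iu] = Q[iu]
        idx = int(np.argmin(flat))  # first occurrence = smallest (i, j)
        i, j = divmod(idx, k)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        parent = TreeNode()
        parent.add(nodes[i], clamp(li))
        parent.add(nodes[j], clamp(lj))
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [m for m in range(k) if m not in (i, j)]
        D2 = np.zeros((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[m] for m in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = TreeNode()
    root.add(a, clamp(0.5 * (dab + dac - dbc)))
    root.add(b, clamp(0.5 * (dab + dbc - dac)))
    root.add(c, clamp(0.5 * (dac + dbc - dab)))
    return PhyloTree(root=root, labels=list(dm.labels), clamped_deficit=deficit)


def bootstrap_supports(seqs: Mapping[str, str], cfg: BootstrapConfig,
                       model: str = "k2p") -> PhyloTree:
    """NJ tree on the full alignment, with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (seeded),
    rebuilds the NJ tree, and every internal bipartition of the reference
    tree is scored by the percentage of replicates containing it.
    """
    labels = list(seqs)
    if len(labels) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    if model not in ("k2p", "p"):
        raise ValueError(f"unknown distance model {model!r}")
    sl = [seqs[l] for l in labels]
    if len({len(s) for s in sl}) != 1:
        raise ValueError("sequences must be aligned to a common length")
    L = len(sl[0])
    cls = _classify_pairs(_encode_sites(sl))

    def dist_from(c: np.ndarray) -> np.ndarray:
        if model == "k2p":
            return _k2p_from_classes(c, labels)
        n = len(labels)
        usable = (c != _MASKED).sum(axis=1).astype(float)
        diff = ((c == _TS) | (c == _TV)).sum(axis=1)
        if np.any(usable == 0):
            raise ValueError("pair with no usable columns")
        p = diff / usable
        out = np.zeros((n, n))
        m = 0
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = p[m]
                m += 1
        return out

    ref = nj_tree(DistanceMatrix(labels, dist_from(cls)))
    ref_bips = ref.bipartitions()
    counts = {bip: 0 for bip in ref_bips}
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(DistanceMatrix(labels, dist_from(cls[:, cols])))
        for bip in rep.bipartitions():
            if bip in counts:
                counts[bip] += 1
    scale = cfg.support_scale / cfg.n_replicates
    ref.supports = {bip: c * scale for bip, c in counts.items()}
    for node in ref.root.walk():
        if node is ref.root or node.is_leaf:
            continue
        norm = _normalize_split(node.leaf_names(), labels)
        if norm is not None:
            node.support = ref.supports[norm]
    return ref


# ---------------------------------------------------------------------------
# star alignment (tree input)


def align_star(seqs: Mapping[str, str],
               params: AlignmentParams = DEFAULT_PARAMS) -> dict[str, str]:
    """Align every sequence pairwise to the first one and pad to common columns.

    A star alignment anchored on the first sequence: gaps opened in the
    anchor by any pairwise alignment are merged (per anchor position, the
    maximum insertion length wins) and all sequences are padded to the merged
    coordinate system.  Appropriate for near-equal-length barcode fragments;
    it is not a general progressive MSA.
    """
    labels = list(seqs)
    if not labels:
        return {}
    anchor = seqs[labels[0]]
    La = len(anchor)
    # per-sequence: insertions[k] = columns inserted in the anchor before
    # anchor position k (k == La means trailing); segments hold the inserted
    # characters plus the character aligned to anchor position k.
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    master_ins = [0] * (La + 1)
    for label in labels[1:]:
        aa, bb, _ = global_align(anchor, seqs[label], params)
        inserts: list[str] = [""] * (La + 1)
        at_pos: list[str] = [""] * La
        k = 0
        for x, y in zip(aa, bb):
            if x == "-":
                inserts[k] += y
            else:
                at_pos[k] = y
                k += 1
        parsed[label] = (inserts, at_pos)
        for k in range(La + 1):
            master_ins[k] = max(master_ins[k], len(inserts[k]))
    out: dict[str, str] = {}
    anchor_row = []
    for k in range(La):
        anchor_row.append("-" * master_ins[k] + anchor[k])
    anchor_row.append("-" * master_ins[La])
    out[labels[0]] = "".join(anchor_row)
    for label in labels[1:]:
        inserts, at_pos = parsed[label]
        row = []
        for k in range(La):
            row.append(inserts[k].ljust(master_ins[k], "-") + at_pos[k])
        row.append(inserts[La].ljust(master_ins[La], "-"))
        out[label] = "".join(row)
    return out
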