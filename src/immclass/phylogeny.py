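"""Family phylogeny: progressive multiple alignment, p-distances,
neighbor joining, and Newick serialization.

The multiple aligner is a classical progressive scheme: a UPGMA guide
tree from pairwise p-distances, then profile-profile merges scored by
the mean pairwise substitution score between columns with affine gap
penalties.  It is a heuristic (no guarantee of optimal sum-of-pairs
score); two sequences reduce exactly to pairwise global alignment.

Trees are built by canonical neighbor joining, which is exact on
additive distance matrices; negative branch-length estimates are
clamped to zero and flagged.  Clade labels have no algorithmic
definition here — monophyly of a named leaf set can be queried
explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
import skbio
from skbio.tree import TreeNode

from .align import DEFAULT_SCHEME, ScoringScheme, global_align, p_distance
from .records import AA20, ProteinRecord

_ALPHABET = AA20 + "X-"
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_NEG_INF = -1e30


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows of unequal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree (stored with an arbitrary trifurcating root)."""

    root: TreeNode
    negative_branches_clamped: bool = False

    def newick(self) -> str:
        return write_newick(self)

    def tip_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def is_monophyletic(self, labels: Sequence[str]) -> bool:
        """True if *labels* form one side of some branch of the unrooted tree."""
        want = frozenset(labels)
        every = frozenset(self.tip_names())
        if not want <= every:
            raise ValueError("labels not all present in tree")
        for node in self.root.traverse(include_self=False):
            side = frozenset(t.name for t in node.tips(include_self=True))
            if side == want or every - side == want:
                return True
        return want == every


# --------------------------------------------------------------------------
# Progressive multiple alignment


def _column_counts(rows: Sequence[str]) -> np.ndarray:
    arr = np.zeros((len(rows[0]), len(_ALPHABET)), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            arr[j, _CHAR_INDEX[c]] += 1
    return arr


def _pair_matrix(scheme: ScoringScheme) -> np.ndarray:
    m = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    mat = scheme.matrix
    for i, a in enumerate(_ALPHABET[:-1]):
        for j, b in enumerate(_ALPHABET[:-1]):
            m[i, j] = mat[a, b]
    return m  # gap row/column stays 0: existing gaps are neutral


def _profile_align(
    rows_a: Sequence[str], rows_b: Sequence[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (Gotoh, vectorized by
    rows).  Returns the gapped rows of each profile, merged order A then B.
    Tie-break: diagonal, then gap in B, then gap in A."""
    go = scheme.gap_open + scheme.gap_extend  # first gapped position
    ge = scheme.gap_extend
    ca = _column_counts(rows_a)
    cb = _column_counts(rows_b)
    S = (ca @ _pair_matrix(scheme) @ cb.T) / (len(rows_a) * len(rows_b))
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG_INF)
    GA = np.full((la + 1, lb + 1), _NEG_INF)  # gap in B (A column vs gap)
    GB = np.full((la + 1, lb + 1), _NEG_INF)  # gap in A
    M[0, 0] = 0.0
    if la:
        GA[1:, 0] = -(go + ge * np.arange(la))
    if lb:
        GB[0, 1:] = -(go + ge * np.arange(lb))
    idx = np.arange(lb + 1)
    for i in range(1, la + 1):
        M[i, 1:] = S[i - 1] + np.maximum.reduce([M[i - 1, :-1], GA[i - 1, :-1], GB[i - 1, :-1]])
        GA[i] = np.maximum.reduce([M[i - 1] - go, GA[i - 1] - ge, GB[i - 1] - go])
        # GB depends only on M/GA of the same row: running-max trick
        W = np.maximum(M[i], GA[i]) + idx * ge
        cw = np.maximum.accumulate(W)
        GB[i, 1:] = cw[:-1] - go - (idx[1:] - 1) * ge
        GB[i, 0] = _NEG_INF

    # traceback by predecessor identity (scores are exact half-integers)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = max(("M", "GA", "GB"), key=lambda s: {"M": M, "GA": GA, "GB": GB}[s][la, lb])
    eps = 1e-9

    def emit(kind: str) -> None:
        nonlocal i, j
        if kind == "diag":
            out_a.append(i - 1)
            out_b.append(j - 1)
            i, j = i - 1, j - 1
        elif kind == "a":
            out_a.append(i - 1)
            out_b.append(None)
            i -= 1
        else:
            out_a.append(None)
            out_b.append(j - 1)
            j -= 1

    while i > 0 or j > 0:
        if state == "M":
            val = M[i, j] - S[i - 1, j - 1]
            emit("diag")
            for prev, arr in (("M", M), ("GA", GA), ("GB", GB)):
                if abs(arr[i, j] - val) < eps:
                    state = prev
                    break
        elif state == "GA":
            val = GA[i, j]
            emit("a")
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            elif abs(GA[i, j] - ge - val) < eps:
                state = "GA"
            else:
                state = "GB"
        else:
            val = GB[i, j]
            emit("b")
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            elif abs(GB[i, j] - ge - val) < eps:
                state = "GB"
            else:
                state = "GA"
        if i == 0 and j > 0:
            state = "GB"
        elif j == 0 and i > 0:
            state = "GA"

    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(r[k] if k is not None else "-" for k in out_a) for r in rows_a]
    new_b = ["".join(r[k] if k is not None else "-" for k in out_b) for r in rows_b]
    return new_a, new_b


def progressive_msa(
    records: Sequence[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    order: str = "guide",
) -> MultipleAlignment:
    """Progressive alignment along a UPGMA guide tree (``order="guide"``)
    or in the given input order (``order="input"``, for comparison)."""
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least two records")
    if len(records) == 2:
        al = global_align(records[0], records[1], scheme)
        return MultipleAlignment(
            ids=(records[0].id, records[1].id), rows=(al.aligned_a, al.aligned_b)
        )
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([r.id], [r.sequence]) for i, r in enumerate(records)
    }
    if order == "input":
        merges = [(0, 1)] + [(len(records) + k, k + 2) for k in range(len(records) - 2)]
    elif order == "guide":
        n = len(records)
        cond = []
        for i in range(n):
            for j in range(i + 1, n):
                cond.append(p_distance(global_align(records[i], records[j], scheme)))
        merges = [(int(a), int(b)) for a, b, *_ in linkage(np.array(cond), method="average")]
    else:
        raise ValueError(f"unknown order {order!r}")
    next_id = len(records)
    for a, b in merges:
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        new_a, new_b = _profile_align(rows_a, rows_b, scheme)
        profiles[next_id] = (ids_a + ids_b, new_a + new_b)
        next_id += 1
    (ids, rows), = profiles.values()
    keep = [j for j in range(len(rows[0])) if any(r[j] != "-" for r in rows)]
    rows = ["".join(r[j] for j in keep) for r in rows]
    original = {rec.id: k for k, rec in enumerate(records)}
    ordered = sorted(range(len(ids)), key=lambda k: original[ids[k]])
    return MultipleAlignment(
        ids=tuple(ids[k] for k in ordered), rows=tuple(rows[k] for k in ordered)
    )


def sum_of_pairs_score(msa: MultipleAlignment, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum over sequence pairs of the affine-gap score of the induced
    pairwise alignment (columns gapped in both rows dropped)."""
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    m = scheme.matrix
    total = 0.0
    for i in range(len(msa.rows)):
        for j in range(i + 1, len(msa.rows)):
            in_gap = None
            for x, y in zip(msa.rows[i], msa.rows[j]):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    side = "a" if x == "-" else "b"
                    total -= ge if in_gap == side else go
                    in_gap = side
                else:
                    total += float(m[x, y])
                    in_gap = None
    return total


# --------------------------------------------------------------------------
# Distances and neighbor joining


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distance over columns gap-free in each pair."""
    n = len(msa.rows)
    if n < 2:
        raise ValueError("need at least two rows")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for x, y in zip(msa.rows[i], msa.rows[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    mismatch += x != y
            if comparable == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no gap-free columns"
                )
            vals[i, j] = vals[j, i] = mismatch / comparable
    return DistanceMatrix(labels=tuple(msa.ids), values=vals)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical NJ; exact on additive matrices.  Negative branch-length
    estimates are clamped to zero and flagged."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
    tree = skbio.tree.nj(sk_dm)
    clamped = False
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return PhyloTree(root=tree, negative_branches_clamped=clamped)


def tree_distance_matrix(tree: PhyloTree, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Patristic (path-length) distances between tips."""
    labels = list(labels) if labels is not None else sorted(tree.tip_names())
    dm = tree.root.tip_tip_distances(endpoints=labels)
    return DistanceMatrix(labels=tuple(labels), values=np.asarray(dm.data, dtype=float))


# --------------------------------------------------------------------------
# Newick


_NEWICK_UNSAFE = set(" \t()[]':;,")


def _quote(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree | TreeNode) -> str:
    """Serialize with branch lengths; labels with metacharacters quoted."""
    root = tree.root if isinstance(tree, PhyloTree) else tree

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _quote(node.name)
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(root) + ";"


def parse_newick(text: str) -> PhyloTree:
    tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    return PhyloTree(root=tree)


# --------------------------------------------------------------------------
# Random additive trees (benchmark utilities)


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator, min_length: float = 0.1, max_length: float = 1.0
) -> PhyloTree:
    """A random unrooted binary tree with U(min,max) branch lengths; its
    tip-tip distance matrix is additive by construction."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")

    def rand_len() -> float:
        return float(rng.uniform(min_length, max_length))

    root = TreeNode()
    for k in range(3):
        root.append(TreeNode(name=f"T{k + 1}", length=rand_len()))
    for k in range(3, n_taxa):
        edges = [n for n in root.traverse(include_self=False)]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        parent.remove(target)
        mid = TreeNode(length=rand_len())
        target.length = rand_len()
        mid.append(target)
        mid.append(TreeNode(name=f"T{k + 1}", length=rand_len()))
        parent.append(mid)
    return PhyloTree(root=root)


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    """Unrooted topology equality via identical bipartition sets."""
    def splits(t: PhyloTree) -> frozenset:
        every = frozenset(t.tip_names())
        out = set()
        for node in t.root.traverse(include_self=False):
            side = frozenset(x.name for x in node.tips(include_self=True))
            if 1 < len(side) < len(every) - 1:
                out.add(min(side, every - side, key=sorted))
        return frozenset(out)

    if set(a.tip_names()) != set(b.tip_names()):
        return False
    return splits(a) == splits(b)
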