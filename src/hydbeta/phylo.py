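"""Distance-based phylogeny of beta-subunit sequences.

A deliberately desk-scale surrogate for a full maximum-likelihood analysis:
sequences are star-aligned through the reference scaffold (each query is
pairwise-aligned to the reference and projected onto its columns; insertions
relative to the reference are dropped), sparsely occupied columns are
trimmed, pairwise distances are computed (p-distance or its Poisson
correction ``-ln(1 - p)``), and a neighbor-joining tree is built. NJ
recovers additive distance matrices exactly, and ties in the Q-criterion
are broken by the lowest index pair so the tree is reproducible.

The scientific claim this supports: beta subunits of non-bifurcating
NADH-dependent enzymes form a clade separate from the bifurcating ones,
checked with :func:`is_monophyletic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import GAP, SubstitutionScheme, map_query
from .records import ProteinRecord


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if np.abs(m - m.T).max(initial=0.0) > 1e-12:
            raise ValueError("matrix must be symmetric within 1e-12")
        if np.abs(np.diag(m)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be zero")
        if m.min(initial=0.0) < 0:
            raise ValueError("distances must be non-negative")


class TreeNode:
    """Node of an (unrooted) tree, stored as rooted at a trifurcation."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf():
                body = node.name
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            return body if top else f"{body}:{node.length:.10g}"
        return fmt(self, True) + ";"


@dataclass
class PhyloTree:
    """Unrooted tree over the distance-matrix taxa.

    ``clamped_branches`` counts negative NJ branch-length estimates that
    were clamped to zero (standard practice; flagged, not hidden).
    """

    root: TreeNode
    ids: tuple
    clamped_branches: int = 0

    def __post_init__(self) -> None:
        if sorted(self.root.leaf_names()) != sorted(self.ids):
            raise ValueError("tree leaves do not match matrix ids")

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set:
        """Leaf bipartitions induced by internal edges (smaller side frozen)."""
        all_leaves = frozenset(self.ids)
        out = set()

        def walk(node: TreeNode):
            below = frozenset(node.leaf_names())
            if 0 < len(below) < len(all_leaves):
                side = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
                out.add(side)
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out


def trim_columns(gapped_sequences, min_occupancy: float):
    """Drop alignment columns whose non-gap fraction is below ``min_occupancy``.

    Returns ``(trimmed_sequences, kept_column_indices)`` with column order
    preserved (indices are 0-based). Raises if no column survives.
    """
    seqs = list(gapped_sequences)
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    ncol = len(seqs[0])
    nseq = len(seqs)
    kept = [
        j for j in range(ncol)
        if sum(s[j] != GAP for s in seqs) / nseq >= min_occupancy
    ]
    if not kept:
        raise ValueError("occupancy trimming removed every column")
    trimmed = ["".join(s[j] for j in kept) for s in seqs]
    return trimmed, kept


def pairwise_distance(a_gapped: str, b_gapped: str, model: str = "poisson") -> float:
    """Evolutionary distance between two rows of a gapped alignment.

    ``p`` is the mismatch fraction over columns where both sequences have a
    residue; ``poisson`` applies the multiple-hit correction ``-ln(1 - p)``.
    """
    if len(a_gapped) != len(b_gapped):
        raise ValueError("gapped sequences must have equal length")
    shared = mismatch = 0
    for ca, cb in zip(a_gapped, b_gapped):
        if ca == GAP or cb == GAP:
            continue
        shared += 1
        mismatch += ca != cb
    if shared == 0:
        raise ValueError("no shared non-gap columns: distance undefined")
    p = mismatch / shared
    if model == "p":
        return p
    if model == "poisson":
        if p >= 1.0:
            raise ValueError("p-distance >= 1: Poisson correction undefined")
        return -np.log1p(-p)
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(gapped: dict, model: str = "poisson") -> DistanceMatrix:
    """All pairwise distances of an aligned block (id -> gapped row)."""
    ids = tuple(gapped)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(gapped[ids[i]], gapped[ids[j]], model)
    return DistanceMatrix(ids=ids, d=d)


def star_alignment(records, reference: ProteinRecord,
                   scheme: SubstitutionScheme | None = None) -> dict:
    """Gapped block over reference columns via pairwise alignment to the reference.

    Each query row has exactly ``len(reference)`` columns: the query residue
    mapped to each reference position, or a gap. Insertions relative to the
    reference are dropped (a documented simplification of a true multiple
    alignment). The reference itself is included as a row.
    """
    rows = {reference.id: reference.residues}
    for rec in records:
        if rec.id == reference.id:
            continue
        _, pmap = map_query(rec, reference, scheme)
        rows[rec.id] = "".join(
            GAP if q is None else rec.residues[q - 1]
            for _, q in pmap.pairs
        )
    return rows


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining with lowest-index-pair tie-breaking.

    Additive matrices are recovered exactly (topology and branch lengths).
    Negative branch-length estimates are clamped to zero and counted in
    ``clamped_branches``.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.asarray(dm.d, dtype=float).copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        # reuse slot i for the new node
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = clamp(lk)
        root.children.append(nodes[k])
    return PhyloTree(root=root, ids=dm.ids, clamped_branches=clamped)


def is_monophyletic(tree: PhyloTree, label_set):
    """Whether some edge bipartitions the leaves into exactly ``label_set`` vs rest.

    Returns ``(flag, splitting_side)``; the side is the frozen label set as
    found among the tree's bipartitions (pendant edges make singletons
    trivially monophyletic).
    """
    labels = frozenset(label_set)
    leaves = frozenset(tree.ids)
    if not labels or not labels < leaves:
        raise ValueError("label_set must be a non-empty proper subset of the leaves")
    if len(labels) == 1:
        return True, labels
    comp = leaves - labels
    side = min(labels, comp, key=lambda s: (len(s), sorted(s)))
    if side in tree.bipartitions():
        return True, side
    return False, None


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances on the tree (for additivity checks)."""
    index = {name: k for k, name in enumerate(tree.ids)}
    n = len(tree.ids)
    d = np.zeros((n, n))

    def walk(node: TreeNode):
        # returns {leaf: distance to node}
        if node.is_leaf():
            return {node.name: 0.0}
        groups = []
        for c in node.children:
            sub = walk(c)
            groups.append({k: v + c.length for k, v in sub.items()})
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
        merged = {}
        for g in groups:
            merged.update(g)
        return merged

    walk(tree.root)
    return DistanceMatrix(ids=tree.ids, d=d)
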