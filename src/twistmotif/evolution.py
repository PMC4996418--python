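"""Sequence-space and phylogenetic analysis of an aligned family.

Gap-heavy columns are trimmed by a gap-fraction threshold (a simple,
reproducible stand-in for slope-based trimming heuristics), pairwise
distances are computed over shared ungapped columns (p-distance or a
normalized similarity-matrix distance, JTT by default), trees come from
neighbor joining with column-bootstrap support, sequence space is
embedded by classical (Torgerson) metric MDS, and per-column
conservation is traced across nested tree partitions.

Neighbor joining is implemented here rather than delegated because the
pipeline's contracts pin down tie-breaking (smallest label pair) and
negative-branch clamping; it reproduces additive distance matrices
exactly and is cross-checked against an independent implementation in
the test suite.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .motif_discovery import find_class_specific_columns
from .seq_io import GAP, Msa

logger = logging.getLogger(__name__)

P_DISTANCE = "p-distance"
MATRIX_NORMALIZED = "matrix-normalized"

#: similarity matrix used for the normalized distance (the JTT matrix)
DEFAULT_SIMILARITY = "JONES"


class TrimmingError(ValueError):
    pass


class DistanceError(ValueError):
    pass


class TreeError(ValueError):
    pass


class EmbeddingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trimming

def trim_alignment(
    msa: Msa,
    max_gap_fraction: float = 0.4,
    drop_ranges: Optional[Sequence[tuple]] = None,
) -> tuple:
    """Remove gap-heavy columns and explicit column ranges.

    Columns whose gap fraction exceeds *max_gap_fraction* are removed;
    1-based inclusive *drop_ranges* are removed regardless.  Returns the
    trimmed Msa and the sorted list of removed 1-based column indices.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    n_rows = len(msa.rows)
    forced = set()
    for lo, hi in drop_ranges or ():
        if not (1 <= lo <= hi <= msa.n_cols):
            raise TrimmingError(f"drop range ({lo}, {hi}) outside 1..{msa.n_cols}")
        forced.update(range(lo, hi + 1))
    removed = []
    kept = []
    for c in range(1, msa.n_cols + 1):
        gap_frac = msa.column(c).count(GAP) / n_rows
        if c in forced or gap_frac > max_gap_fraction:
            removed.append(c)
        else:
            kept.append(c)
    if not kept:
        raise TrimmingError("trimming removed every column")
    return msa.take_columns(kept), removed


# ---------------------------------------------------------------------------
# distances

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    values: np.ndarray  # symmetric, zero diagonal, non-negative
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def msa_distance(
    msa: Msa,
    method: str = P_DISTANCE,
    similarity_matrix=None,
) -> DistanceMatrix:
    """Pairwise distances over columns where neither row is gapped.

    ``p-distance`` is mismatches / compared columns.  ``matrix-normalized``
    is ``1 − s(a,b) / sqrt(s(a,a) · s(b,b))`` with ``s`` the sum of
    similarity-matrix entries over the compared columns (JTT by default),
    clamped below at 0.
    """
    if len(msa.rows) < 2:
        raise DistanceError("need at least 2 rows")
    if method not in (P_DISTANCE, MATRIX_NORMALIZED):
        raise ValueError(f"unknown method {method!r}")
    mat = None
    if method == MATRIX_NORMALIZED:
        mat = (
            similarity_matrix
            if similarity_matrix is not None
            else substitution_matrices.load(DEFAULT_SIMILARITY)
        )
    ids = msa.ids
    rows = [msa.row(i) for i in ids]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            cols = [k for k in range(len(a)) if a[k] != GAP and b[k] != GAP]
            if not cols:
                raise DistanceError(
                    f"no shared ungapped columns for pair ({ids[i]}, {ids[j]})"
                )
            if method == P_DISTANCE:
                mism = sum(1 for k in cols if a[k] != b[k])
                dij = mism / len(cols)
            else:
                sab = sum(float(mat[a[k], b[k]]) for k in cols)
                saa = sum(float(mat[a[k], a[k]]) for k in cols)
                sbb = sum(float(mat[b[k], b[k]]) for k in cols)
                dij = max(0.0, 1.0 - sab / np.sqrt(saa * sbb))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=tuple(ids), values=d, method=method)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; unrooted (trifurcating root).

    The Q-criterion pair with the smallest value is joined each round;
    exact ties are broken by the lexicographically smallest label pair.
    Negative branch-length estimates are clamped to 0 (logged).  On an
    additive matrix the output tree reproduces the input distances
    exactly as path lengths.
    """
    if d.n < 3:
        raise TreeError("neighbor joining needs at least 3 labels")
    labels = list(d.labels)
    nodes = {lab: TreeNode(name=lab) for lab in labels}
    dist = {frozenset((a, b)): d.get(a, b) for a in labels for b in labels if a != b}
    active = list(labels)
    counter = 0

    def clamp(x, where):
        if x < 0:
            logger.info("clamping negative NJ branch length %.6g at %s", x, where)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * dist[frozenset((a, b))] - totals[a] - totals[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = clamp(la, a), clamp(lb, b)
        new_name = f"__nj{counter}"
        counter += 1
        parent = TreeNode(name=None)
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        nodes[new_name] = parent
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab
            )
            dist[frozenset((new_name, c))] = dc
        active = [c for c in active if c not in (a, b)] + [new_name]
    # trifurcating root from the last three clusters
    x, y, z = active
    dxy = dist[frozenset((x, y))]
    dxz = dist[frozenset((x, z))]
    dyz = dist[frozenset((y, z))]
    lx = clamp(0.5 * (dxy + dxz - dyz), x)
    ly = clamp(0.5 * (dxy + dyz - dxz), y)
    lz = clamp(0.5 * (dxz + dyz - dxy), z)
    root = TreeNode(name=None)
    for lab, ln in ((x, lx), (y, ly), (z, lz)):
        child = nodes.pop(lab)
        child.length = ln
        root.append(child)
    return root


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = tree.find(tips[i]).distance(tree.find(tips[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=tuple(tips), values=d, method="tree-path")


def tree_bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions as canonical frozensets of tip names.

    A split is represented by the side *not* containing the
    lexicographically smallest tip, so rooted/unrooted representations
    compare equal.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    anchor = min(all_tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        if anchor in side:
            side = all_tips - side
        if side:
            splits.add(side)
    return splits


def bootstrap_support(
    msa: Msa,
    replicates: int = 1000,
    seed: int = 0,
    method: str = P_DISTANCE,
    similarity_matrix=None,
) -> TreeNode:
    """NJ reference tree with column-bootstrap support percentages.

    Columns are resampled with replacement per replicate; support for
    each internal edge of the reference tree is the percentage of
    replicate NJ trees containing the same bipartition, stored in each
    internal node's ``support`` attribute (and serialized as the node
    label).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ref = nj_tree(msa_distance(msa, method, similarity_matrix))
    rng = np.random.default_rng(seed)
    counts: dict = {}
    n_cols = msa.n_cols
    for _ in range(replicates):
        cols = rng.integers(1, n_cols + 1, size=n_cols)
        rep_msa = msa.take_columns(cols.tolist())
        try:
            rep_tree = nj_tree(msa_distance(rep_msa, method, similarity_matrix))
        except DistanceError:
            continue  # resample produced an all-gap overlap; skip replicate
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_tips = frozenset(t.name for t in ref.tips())
    anchor = min(all_tips)
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        canon = side if anchor not in side else all_tips - side
        pct = 100.0 * counts.get(canon, 0) / replicates
        node.support = pct
        node.name = f"{pct:g}"
    return ref


# ---------------------------------------------------------------------------
# classical MDS

@dataclass(frozen=True)
class MdsEmbedding:
    labels: tuple
    coordinates: np.ndarray  # n x k, columns ordered by eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    explained: np.ndarray  # eigenvalue / sum of positive eigenvalues

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# eigenvalues: "
                + " ".join(f"{e:.10g}" for e in self.eigenvalues)
                + "\n"
            )
            fh.write(
                "label\t" + "\t".join(f"c{i + 1}" for i in range(self.k)) + "\n"
            )
            for lab, row in zip(self.labels, self.coordinates):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def classical_mds(d: DistanceMatrix, k: int = 3) -> MdsEmbedding:
    """Torgerson metric MDS: double-center −½ D², eigendecompose, keep the
    top-*k* positive eigenpairs scaled by √eigenvalue.  Axis signs are
    fixed so the first nonzero loading on each axis is positive."""
    if k < 1:
        raise ValueError("k must be >= 1")
    D = d.values
    n = d.n
    if np.allclose(D, 0):
        return MdsEmbedding(
            labels=d.labels,
            coordinates=np.zeros((n, min(k, 1))),
            eigenvalues=np.zeros(min(k, 1)),
            explained=np.zeros(min(k, 1)),
        )
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * abs(evals[0]))
    pos = evals > tol
    if not pos.any():
        raise EmbeddingError("no positive eigenvalues; degenerate embedding")
    evals_pos = evals[pos]
    vecs_pos = evecs[:, pos]
    keep = min(k, len(evals_pos))
    coords = vecs_pos[:, :keep] * np.sqrt(evals_pos[:keep])
    for axis in range(keep):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return MdsEmbedding(
        labels=d.labels,
        coordinates=coords,
        eigenvalues=evals_pos[:keep],
        explained=evals_pos[:keep] / evals_pos.sum(),
    )


# ---------------------------------------------------------------------------
# evolutionary trace

@dataclass(frozen=True)
class TraceLevel:
    level: int
    groups: tuple  # of (group name, tuple of leaf names)
    column_classes: tuple  # per column: conserved/class-specific/unconserved/gapped


@dataclass(frozen=True)
class TraceResult:
    levels: tuple  # of TraceLevel, level 1..P

    def level(self, p: int) -> TraceLevel:
        return self.levels[p - 1]


def _partition_at_level(tree: TreeNode, p: int) -> list:
    """Leaf groups from cutting at the p−1 internal nodes nearest the root.

    Internal nodes are ranked by root distance (node height), ties by
    traversal (Newick) order; the root counts as the first cut.
    """
    internals = list(tree.non_tips(include_self=True))
    order = {id(n): k for k, n in enumerate(tree.preorder())}

    def height(node):
        h, cur = 0.0, node
        while cur is not tree and cur.parent is not None:
            h += cur.length or 0.0
            cur = cur.parent
        return h

    heights = [height(n) for n in internals]
    ranked = sorted(
        zip(internals, heights), key=lambda t: (t[1], order[id(t[0])])
    )
    selected = {id(n) for n, _ in ranked[: max(0, p - 1)]}
    groups = []

    def emit(node):
        if id(node) in selected and not node.is_tip():
            for child in node.children:
                emit(child)
        else:
            groups.append(tuple(t.name for t in node.tips(include_self=True)))

    emit(tree)
    return groups


def evolutionary_trace(msa: Msa, tree: TreeNode, levels: int = 10) -> TraceResult:
    """Per-column conservation classes across nested tree partitions.

    At level *p* the rooted tree is cut at the p−1 internal nodes
    closest to the root, the alignment rows are grouped by the resulting
    subtrees, and every column is classed conserved / class-specific /
    unconserved / gapped.  Level 1 is the single-group trace, so no
    column can be class-specific there; a column conserved at level 1
    stays conserved at every level.
    """
    tips = sorted(t.name for t in tree.tips())
    if tips != sorted(msa.ids):
        raise ValueError("tree leaves and alignment rows disagree")
    out = []
    for p in range(1, levels + 1):
        parts = _partition_at_level(tree, p)
        if len(parts) == 1:
            # single group: conserved/gapped/unconserved only
            classes = []
            for c in range(1, msa.n_cols + 1):
                col = set(msa.column(c))
                if GAP in col:
                    classes.append("gapped")
                elif len(col) == 1:
                    classes.append("conserved")
                else:
                    classes.append("unconserved")
        else:
            groups = {f"P{k:02d}": list(members) for k, members in enumerate(parts, 1)}
            classes = find_class_specific_columns(msa, groups)
        out.append(
            TraceLevel(
                level=p,
                groups=tuple(
                    (f"P{k:02d}", tuple(members)) for k, members in enumerate(parts, 1)
                ),
                column_classes=tuple(classes),
            )
        )
    return TraceResult(levels=tuple(out))
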