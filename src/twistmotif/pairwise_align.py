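"""Pairwise global/local protein alignment and percent identity.

The scoring default mirrors protein-BLAST defaults: BLOSUM62, gap open 11,
gap extend 1 (a gap of length *k* costs ``open + k * extend``).  Identity
is reported as identical columns over all alignment columns, the way
BLASTP prints "Identities"; values can therefore differ by about one
percentage point from the NCBI server, which applies compositional
adjustments this module deliberately does not.

A small progressive multiple aligner is included so that synthetic
families can be aligned without any external tool.  It is a plain
guide-tree + profile-profile Needleman-Wunsch scheme and makes no claim
to match a production aligner's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import AMINO_ACIDS, GAP, Msa, SequenceRecord


class AlignmentInputError(ValueError):
    pass


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both ≥ 0)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        if Path(self.matrix_name).is_file():
            with open(self.matrix_name) as fh:
                return substitution_matrices.read(fh)
        return _load_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A finished pairwise alignment; empty strings encode an empty local hit."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP and y == GAP:
                raise ValueError("all-gap column in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != GAP
        )

    @property
    def identity_pct(self) -> float:
        if self.n_cols == 0:
            return 0.0
        return 100.0 * self.n_identical / self.n_cols

    @property
    def is_empty(self) -> bool:
        return self.n_cols == 0


def _aligner(s: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = s.matrix
    # BLAST charges open+extend for the first residue of a gap
    al.open_gap_score = -(s.gap_open + s.gap_extend)
    al.extend_gap_score = -s.gap_extend
    al.mode = mode
    return al


def _first_alignment(al, a: str, b: str):
    return al.align(a, b)[0]


def global_align(
    a: SequenceRecord, b: SequenceRecord, s: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal affine-gap global (Needleman-Wunsch) alignment."""
    if not a.residues or not b.residues:
        raise AlignmentInputError("cannot align an empty sequence")
    aln = _first_alignment(_aligner(s, "global"), a.residues, b.residues)
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score), "global")


def local_align(
    a: SequenceRecord, b: SequenceRecord, s: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal affine-gap local (Smith-Waterman) alignment.

    When every attainable score is ≤ 0 the optimal local alignment is
    empty; an explicit empty result is returned rather than an error.
    """
    if not a.residues or not b.residues:
        raise AlignmentInputError("cannot align an empty sequence")
    alns = _aligner(s, "local").align(a.residues, b.residues)
    if alns.score <= 0:
        return PairwiseAlignment("", "", 0.0, "local")
    aln = alns[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score), "local")


@dataclass(frozen=True)
class IdentityReport:
    identity_pct: float
    n_identical: int
    n_cols: int

    @property
    def rounded_pct(self) -> int:
        # round half up, as percentages are quoted in the literature
        import math

        return int(math.floor(self.identity_pct + 0.5))


def percent_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str = "global",
    s: ScoringScheme = DEFAULT_SCORING,
) -> IdentityReport:
    if mode == "global":
        aln = global_align(a, b, s)
    elif mode == "local":
        aln = local_align(a, b, s)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return IdentityReport(aln.identity_pct, aln.n_identical, aln.n_cols)


# ---------------------------------------------------------------------------
# Clustal-style conservation line (presentation only)

_STRONG = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
_WEAK = ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
         "NEQHRK", "FVLIM", "HFY"]


def conservation_line(aligned_a: str, aligned_b: str) -> str:
    """``*``/``:``/``.``/space symbols for a 2-row alignment, Clustal style."""
    out = []
    for x, y in zip(aligned_a, aligned_b):
        if GAP in (x, y):
            out.append(" ")
        elif x == y:
            out.append("*")
        elif any(x in g and y in g for g in _STRONG):
            out.append(":")
        elif any(x in g and y in g for g in _WEAK):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


# ---------------------------------------------------------------------------
# minimal progressive MSA (synthetic self-tests only)

_GAP_COL_PENALTY = 10.0


def _profile_cols(rows):
    """Per-column residue count dicts for a list of gapped strings."""
    n = len(rows[0])
    cols = []
    for j in range(n):
        d = {}
        for r in rows:
            ch = r[j]
            if ch != GAP:
                d[ch] = d.get(ch, 0) + 1
        cols.append(d)
    return cols


def _col_score(ca: dict, cb: dict, mat) -> float:
    na = sum(ca.values())
    nb = sum(cb.values())
    if na == 0 or nb == 0:
        return 0.0
    s = 0.0
    for ra, fa in ca.items():
        for rb, fb in cb.items():
            s += fa * fb * float(mat[ra, rb])
    return s / (na * nb)


def _align_profiles(rows_a, rows_b, mat):
    """Needleman-Wunsch on profile columns with a linear gap-column cost."""
    ca, cb = _profile_cols(rows_a), _profile_cols(rows_b)
    n, m = len(ca), len(cb)
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i, 0] = -_GAP_COL_PENALTY * i
        move[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = -_GAP_COL_PENALTY * j
        move[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + _col_score(ca[i - 1], cb[j - 1], mat)
            up = score[i - 1, j] - _GAP_COL_PENALTY
            left = score[i, j - 1] - _GAP_COL_PENALTY
            best = max(diag, up, left)
            score[i, j] = best
            move[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback (diag preferred, then up, then left — fixed for determinism)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if i > 0 and j > 0 and mv == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and mv == 1:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            i -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            j -= 1
    return (
        ["".join(reversed(r)) for r in out_a],
        ["".join(reversed(r)) for r in out_b],
    )


def progressive_msa(records, s: ScoringScheme = DEFAULT_SCORING) -> Msa:
    """Guide-tree progressive alignment of ≥2 records.

    The guide tree is single-linkage clustering of the global-alignment
    identity distance 1 − identity/100; profiles are merged by global
    profile-profile alignment under *s*'s substitution matrix.
    """
    records = list(records)
    if len(records) < 2:
        raise AlignmentInputError("progressive_msa needs at least 2 records")
    mat = s.matrix
    n = len(records)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(records[i], records[j], "global", s).identity_pct
            dist[(i, j)] = 1.0 - pid / 100.0
    # clusters: list of (member index set, row ids, gapped rows)
    clusters = {i: ([records[i].id], [records[i].residues], {i}) for i in range(n)}

    def cluster_dist(a, b):
        return min(
            dist[(min(x, y), max(x, y))]
            for x in clusters[a][2]
            for y in clusters[b][2]
        )

    keys = sorted(clusters)
    while len(keys) > 1:
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                d = cluster_dist(keys[ai], keys[bi])
                if best is None or d < best[0]:
                    best = (d, keys[ai], keys[bi])
        _, a, b = best
        ids_a, rows_a, mem_a = clusters[a]
        ids_b, rows_b, mem_b = clusters[b]
        new_a, new_b = _align_profiles(rows_a, rows_b, mat)
        clusters[a] = (ids_a + ids_b, new_a + new_b, mem_a | mem_b)
        del clusters[b]
        keys = sorted(clusters)
    ids, rows, _ = clusters[keys[0]]
    # restore the input record order
    order = {rec.id: k for k, rec in enumerate(records)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Msa(tuple(paired))
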