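"""Sequence and alignment IO.

The whole pipeline works on two containers: :class:`SequenceRecord`, an
unaligned protein sequence over the 20 canonical amino acids plus ``X``,
and :class:`Msa`, an equal-length gapped alignment whose rows ungap back
to valid records.  Reading goes through Biopython (FASTA, aligned FASTA,
Clustal); trees go through scikit-bio's ``TreeNode`` (Newick).

Conventions enforced here and relied on everywhere else:

* residues are upper-case; ``*`` stop symbols are stripped with a warning;
* the only gap character is ``-`` (``.`` is converted on read, warned);
* ``X`` is a legal residue; the ambiguity codes B/Z/U/O are rejected so
  that downstream pattern matching never has to guess;
* reported residue positions are 1-based and inclusive.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: canonical residue alphabet (20 amino acids + X)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"

PARALOG_LABELS = ("group-A", "group-B", "unknown")


class SequenceFormatError(ValueError):
    """Illegal residue characters or malformed sequence input."""


class AlignmentFormatError(ValueError):
    """Rows of an alignment disagree in length or are all-gap."""


class NewickFormatError(ValueError):
    """Unparseable or ambiguous Newick text."""


def _clean_residues(raw: str, seq_id: str, allow_gaps: bool) -> str:
    s = raw.upper()
    if s.endswith("*"):
        logger.warning("stripping trailing stop symbol '*' from %s", seq_id)
        s = s.rstrip("*")
    if "*" in s:
        logger.warning("stripping internal stop symbols '*' from %s", seq_id)
        s = s.replace("*", "")
    if "." in s:
        if allow_gaps:
            logger.warning("converting '.' gaps to '-' in %s", seq_id)
            s = s.replace(".", GAP)
        else:
            raise SequenceFormatError(f"gap character '.' in unaligned record {seq_id!r}")
    legal = ALPHABET | ({GAP} if allow_gaps else set())
    for i, ch in enumerate(s, start=1):
        if ch not in legal:
            raise SequenceFormatError(
                f"illegal residue {ch!r} at position {i} of record {seq_id!r}"
            )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One unaligned protein sequence with light metadata."""

    id: str
    residues: str
    description: str = ""
    paralog_label: str = "unknown"

    def __post_init__(self):
        if not self.id:
            raise SequenceFormatError("record id must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        if self.paralog_label not in PARALOG_LABELS:
            raise ValueError(f"bad paralog_label {self.paralog_label!r}")
        cleaned = _clean_residues(self.residues, self.id, allow_gaps=False)
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    def with_label(self, label: str) -> "SequenceRecord":
        return replace(self, paralog_label=label)


@dataclass(frozen=True)
class Msa:
    """Equal-length gapped alignment: an ordered list of (id, row) pairs."""

    rows: tuple  # of (id, gapped_residues)

    def __post_init__(self):
        rows = tuple((str(i), str(r)) for i, r in self.rows)
        if not rows:
            raise AlignmentFormatError("alignment has no rows")
        n = len(rows[0][1])
        ids = [i for i, _ in rows]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate row ids in alignment")
        cleaned = []
        for rid, row in rows:
            row = _clean_residues(row, rid, allow_gaps=True)
            if len(row) != n:
                raise AlignmentFormatError(
                    f"row {rid!r} has {len(row)} columns, expected {n}"
                )
            if set(row) == {GAP}:
                raise AlignmentFormatError(f"row {rid!r} is all gaps")
            cleaned.append((rid, row))
        object.__setattr__(self, "rows", tuple(cleaned))

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list:
        return [i for i, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, r in self.rows:
            if i == rid:
                return r
        raise KeyError(rid)

    def ungapped(self, rid: str) -> SequenceRecord:
        return SequenceRecord(id=rid, residues=self.row(rid).replace(GAP, ""))

    def ungapped_records(self) -> list:
        return [self.ungapped(i) for i, _ in self.rows]

    def column(self, col: int) -> str:
        """1-based column as a string, one character per row."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside 1..{self.n_cols}")
        return "".join(r[col - 1] for _, r in self.rows)

    def take_columns(self, cols: Sequence[int]) -> "Msa":
        """New alignment from the given 1-based columns, in the given order."""
        idx = [c - 1 for c in cols]
        return Msa(tuple((i, "".join(r[j] for j in idx)) for i, r in self.rows))


# ---------------------------------------------------------------------------
# reading / writing


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        head = fh.read(4096)
    if head.lstrip().upper().startswith("CLUSTAL"):
        return "clustal"
    if GAP in "".join(l for l in head.splitlines() if not l.startswith(">")):
        return "aligned_fasta"
    return "fasta"


def read_sequences(path, format: str = "auto"):
    """Read *path*; FASTA yields a list of records, aligned formats an Msa."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "fasta":
        recs = [
            SequenceRecord(id=r.id, residues=str(r.seq), description=r.description)
            for r in SeqIO.parse(str(path), "fasta")
        ]
        seen = set()
        for r in recs:
            if r.id in seen:
                raise SequenceFormatError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        return recs
    if format in ("aligned_fasta", "clustal"):
        bio_fmt = "fasta" if format == "aligned_fasta" else "clustal"
        try:
            aln = AlignIO.read(str(path), bio_fmt)
        except ValueError as e:
            raise AlignmentFormatError(str(e)) from e
        return Msa(tuple((r.id, str(r.seq)) for r in aln))
    raise ValueError(f"unknown format {format!r}")


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_msa(msa: Msa, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees


def read_newick(text: str) -> TreeNode:
    """Parse Newick text into a TreeNode, validating leaf-label uniqueness."""
    try:
        tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as e:  # skbio raises several parse error types
        raise NewickFormatError(f"cannot parse Newick: {e}") from e
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dups = sorted({n for n in tips if tips.count(n) > 1})
        raise NewickFormatError(f"duplicate leaf labels: {', '.join(dups)}")
    if any(n is None for n in tips):
        raise NewickFormatError("unnamed leaf in tree")
    return tree

def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
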