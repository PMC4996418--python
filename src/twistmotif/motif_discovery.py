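"""PROSITE-format motif discovery and scanning.

This is the analytical core of the package: build per-column profiles
from a grouped alignment, express them as PROSITE-syntax patterns,
refine a pattern into a minimal *signature motif* that matches one
paralog group and rejects the other, locate class-specific alignment
columns (the N/T key residue), and scan sequences against
serine/threonine kinase consensus rules.

PROSITE syntax subset
---------------------
``A`` literal residue; ``[TN]`` alternative set; ``{TN}`` excluded set;
``x`` wildcard, optionally repeated ``x(2)`` / ``x(2,4)``; elements may
be separated by ``-``; a trailing ``.`` is allowed.  Matching semantics:
a literal matches only itself, sets match by (non-)membership, and an
``X`` in the *sequence* matches wildcards only — an unknown residue is
never allowed to satisfy a specific element.  When a wildcard range
permits several match lengths at one start position, the shortest match
is reported; each matching start yields exactly one hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seq_io import ALPHABET, AMINO_ACIDS, GAP, Msa, SequenceRecord


class PrositeSyntaxError(ValueError):
    pass


class ProfileError(ValueError):
    pass


class RefinementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pattern elements

@dataclass(frozen=True)
class Literal:
    residue: str

    def matches(self, ch: str) -> bool:
        return ch == self.residue

    def serialize(self) -> str:
        return self.residue


@dataclass(frozen=True)
class AnyOf:
    residues: tuple  # ordered, duplicate-free

    def matches(self, ch: str) -> bool:
        return ch in self.residues and ch != "X"

    def serialize(self) -> str:
        return "[" + "".join(self.residues) + "]"


@dataclass(frozen=True)
class NoneOf:
    residues: tuple

    def matches(self, ch: str) -> bool:
        return ch not in self.residues and ch != "X"

    def serialize(self) -> str:
        return "{" + "".join(self.residues) + "}"


@dataclass(frozen=True)
class Wildcard:
    min_repeat: int = 1
    max_repeat: int = 1

    def serialize(self) -> str:
        if self.min_repeat == self.max_repeat:
            return "x" if self.min_repeat == 1 else f"x({self.min_repeat})"
        return f"x({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple

    def __post_init__(self):
        if not self.elements:
            raise PrositeSyntaxError("pattern must have at least one element")
        for el in self.elements:
            if isinstance(el, (AnyOf, NoneOf)):
                if not el.residues:
                    raise PrositeSyntaxError("empty residue set in pattern")
                if len(set(el.residues)) != len(el.residues):
                    raise PrositeSyntaxError("duplicate residue in set")

    def serialize(self) -> str:
        return "-".join(el.serialize() for el in self.elements)

    @property
    def source_text(self) -> str:
        return self.serialize()

    def __len__(self) -> int:
        return len(self.elements)

    def element_sets(self) -> list:
        """Residue sets per element (frozenset; None for wildcards).

        Used for order-insensitive pattern comparison: the bracket-set
        residue *ordering* is presentational only.
        """
        out = []
        for el in self.elements:
            if isinstance(el, Literal):
                out.append(frozenset(el.residue))
            elif isinstance(el, AnyOf):
                out.append(frozenset(el.residues))
            elif isinstance(el, NoneOf):
                out.append(frozenset(AMINO_ACIDS) - frozenset(el.residues))
            else:
                out.append(None)
        return out


def parse_prosite(text: str) -> PrositePattern:
    """Parse PROSITE-syntax text (see module docstring for the subset)."""
    if not text or not text.strip():
        raise PrositeSyntaxError("empty pattern text")
    s = text.strip()
    if s.endswith("."):
        s = s[:-1]
    elements = []
    i = 0
    n = len(s)

    def fail(msg, pos):
        raise PrositeSyntaxError(f"{msg} at position {pos + 1} in {text!r}")

    while i < n:
        ch = s[i]
        if ch == "-":
            i += 1
            continue
        if ch in ("[", "{"):
            close = "]" if ch == "[" else "}"
            j = s.find(close, i + 1)
            if j == -1:
                fail(f"unterminated {ch!r}", i)
            body = s[i + 1 : j]
            if not body:
                fail("empty residue set", i)
            seen = []
            for k, r in enumerate(body):
                ru = r.upper()
                if ru not in ALPHABET or ru == "X":
                    fail(f"illegal residue {r!r} in set", i + 1 + k)
                if ru in seen:
                    fail(f"duplicate residue {r!r} in set", i + 1 + k)
                seen.append(ru)
            cls = AnyOf if ch == "[" else NoneOf
            elements.append(cls(tuple(seen)))
            i = j + 1
        elif ch in ("x", "X"):
            i += 1
            lo = hi = 1
            if i < n and s[i] == "(":
                j = s.find(")", i + 1)
                if j == -1:
                    fail("unterminated repeat", i)
                body = s[i + 1 : j]
                parts = body.split(",")
                try:
                    if len(parts) == 1:
                        lo = hi = int(parts[0])
                    elif len(parts) == 2:
                        lo, hi = int(parts[0]), int(parts[1])
                    else:
                        raise ValueError
                except ValueError:
                    fail(f"malformed repeat {body!r}", i)
                if lo < 0 or hi < lo:
                    fail(f"malformed repeat range {body!r}", i)
                i = j + 1
            elements.append(Wildcard(lo, hi))
        elif ch.upper() in ALPHABET and ch.upper() != "X":
            elements.append(Literal(ch.upper()))
            i += 1
        else:
            fail(f"unexpected character {ch!r}", i)
    if not elements:
        raise PrositeSyntaxError(f"no elements in pattern {text!r}")
    return PrositePattern(tuple(elements))


# ---------------------------------------------------------------------------
# scanning

@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    matched_text: str

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("bad hit coordinates")


def _match_here(elements, seq: str, pos: int) -> Optional[int]:
    """Length of the shortest match of *elements* at 0-based *pos*, else None."""
    if not elements:
        return 0
    el, rest = elements[0], elements[1:]
    if isinstance(el, Wildcard):
        for take in range(el.min_repeat, el.max_repeat + 1):
            if pos + take > len(seq):
                break
            tail = _match_here(rest, seq, pos + take)
            if tail is not None:
                return take + tail
        return None
    if pos >= len(seq) or not el.matches(seq[pos]):
        return None
    tail = _match_here(rest, seq, pos + 1)
    return None if tail is None else 1 + tail


def scan_prosite(
    pattern: PrositePattern, seq: SequenceRecord, mode: str = "all"
) -> list:
    """All (or the first) pattern hits on *seq*, ordered by start position."""
    if mode not in ("all", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = []
    residues = seq.residues
    for start in range(len(residues)):
        length = _match_here(pattern.elements, residues, start)
        if length is not None and length > 0:
            hits.append(
                MotifHit(
                    seq_id=seq.id,
                    start=start + 1,
                    end=start + length,
                    matched_text=residues[start : start + length],
                )
            )
            if mode == "first":
                break
    return hits


def pattern_matches(pattern: PrositePattern, seq: SequenceRecord) -> bool:
    return bool(scan_prosite(pattern, seq, mode="first"))


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class ColumnProfile:
    """Residue/gap counts per alignment column over a chosen row subset."""

    columns: tuple  # of dicts residue -> count (gap under '-')
    n_rows: int
    source_columns: tuple  # original 1-based column indices
    row_order: tuple  # ids of the profiled rows, top to bottom
    first_rows: tuple  # per column: dict residue -> row rank of first appearance

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    def frequencies(self, col: int) -> dict:
        """Frequencies over residues+gap for 1-based profile column *col*."""
        counts = self.columns[col - 1]
        return {r: c / self.n_rows for r, c in counts.items()}

    def conservation(self, col: int) -> float:
        """Max residue frequency in the column (gaps excluded from the max)."""
        counts = self.columns[col - 1]
        best = max((c for r, c in counts.items() if r != GAP), default=0)
        return best / self.n_rows

    def gap_count(self, col: int) -> int:
        return self.columns[col - 1].get(GAP, 0)


def build_profile(
    msa: Msa,
    row_subset: Optional[Sequence[str]] = None,
    col_range: Optional[tuple] = None,
) -> ColumnProfile:
    """Column profile of *msa*, optionally over a row subset / column interval."""
    if row_subset is not None:
        row_subset = list(row_subset)
        if not row_subset:
            raise ProfileError("empty row subset")
        known = set(msa.ids)
        missing = [r for r in row_subset if r not in known]
        if missing:
            raise ProfileError(f"unknown row ids: {', '.join(missing)}")
        rows = [(i, msa.row(i)) for i in row_subset]
    else:
        rows = list(msa.rows)
    if col_range is None:
        lo, hi = 1, msa.n_cols
    else:
        lo, hi = col_range
        if not (1 <= lo <= hi <= msa.n_cols):
            raise ProfileError(f"column range {col_range} outside 1..{msa.n_cols}")
    columns, first_rows = [], []
    for j in range(lo - 1, hi):
        counts: dict = {}
        first: dict = {}
        for rank, (_, row) in enumerate(rows):
            ch = row[j]
            counts[ch] = counts.get(ch, 0) + 1
            first.setdefault(ch, rank)
        columns.append(counts)
        first_rows.append(first)
    return ColumnProfile(
        columns=tuple(columns),
        n_rows=len(rows),
        source_columns=tuple(range(lo, hi + 1)),
        row_order=tuple(i for i, _ in rows),
        first_rows=tuple(first_rows),
    )


def profile_to_pattern(
    profile: ColumnProfile,
    max_set_size: int = 4,
    min_freq: float = 0.0,
    gap_policy: str = "forbid",
) -> PrositePattern:
    """Express a profile as a PROSITE pattern.

    Per column: one residue above *min_freq* becomes a literal, 2 to
    *max_set_size* an alternative set (ordered by descending frequency,
    ties by first appearance top-to-bottom), more a wildcard.  With
    ``min_freq=0`` the pattern is complete: it matches every ungapped
    row it was built from.
    """
    if gap_policy not in ("forbid", "skip-column"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    elements = []
    for k in range(1, profile.n_cols + 1):
        counts = profile.columns[k - 1]
        if counts.get(GAP, 0):
            if gap_policy == "forbid":
                raise ProfileError(
                    f"gap in alignment column {profile.source_columns[k - 1]}"
                )
            continue
        first = profile.first_rows[k - 1]
        residues = [
            r
            for r, c in counts.items()
            if r != GAP and c / profile.n_rows > min_freq
        ]
        if not residues:  # min_freq filtered everything; keep the modal residue
            residues = [max(counts, key=lambda r: (counts[r], -first[r]))]
        residues.sort(key=lambda r: (-counts[r], first[r]))
        if len(residues) == 1:
            elements.append(Literal(residues[0]))
        elif len(residues) <= max_set_size:
            elements.append(AnyOf(tuple(residues)))
        else:
            elements.append(Wildcard(1, 1))
    if not elements:
        raise ProfileError("no pattern columns left after gap handling")
    return PrositePattern(tuple(elements))


# ---------------------------------------------------------------------------
# discriminative refinement

def _discriminative(pattern, positives, negatives) -> tuple:
    """(is_discriminative, offending ids)."""
    bad = [p.id for p in positives if not pattern_matches(pattern, p)]
    bad += [n.id for n in negatives if pattern_matches(pattern, n)]
    return (not bad, bad)


def refine_discriminative_motif(
    pattern: PrositePattern,
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
) -> PrositePattern:
    """End-trim *pattern* to a minimal motif separating the two sets.

    Elements are removed from either extreme, sequentially and one at a
    time: the leading element is removed repeatedly until a removal
    would break discrimination, then the trailing element likewise, and
    the two phases repeat until neither end can be shortened.  A removal
    stands only if the shortened pattern still matches every positive
    and no negative.  The fixed point is end-trim minimal; trimming the
    front first keeps the core anchored at the left-most element that
    discrimination actually needs (the key-residue column, when the
    discriminating difference is a single class-specific residue).
    """
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise RefinementError("need non-empty positive and negative sets")
    ok, bad = _discriminative(pattern, positives, negatives)
    if not ok:
        raise RefinementError(
            "pattern not discriminative at start; offending sequences: "
            + ", ".join(bad)
        )
    elements = list(pattern.elements)
    changed = True
    while changed and len(elements) > 1:
        changed = False
        for side in ("first", "last"):
            while len(elements) > 1:
                trial = elements[1:] if side == "first" else elements[:-1]
                ok, _ = _discriminative(
                    PrositePattern(tuple(trial)), positives, negatives
                )
                if not ok:
                    break
                elements = trial
                changed = True
    return PrositePattern(tuple(elements))


# ---------------------------------------------------------------------------
# class-specific columns

CONSERVED = "conserved"
CLASS_SPECIFIC = "class-specific"
UNCONSERVED = "unconserved"
GAPPED = "gapped"


def find_class_specific_columns(msa: Msa, groups: dict) -> list:
    """Per-column classification for a partition of rows into ≥2 groups.

    Returns one of ``conserved`` (a single residue across all rows),
    ``class-specific`` (each group internally uniform, ≥2 distinct group
    residues), ``gapped`` (any gap present) or ``unconserved``, per
    column, as a list of length ``msa.n_cols``.
    """
    ids = msa.ids
    assigned = [i for members in groups.values() for i in members]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sorted(assigned) != sorted(ids) or any(not m for m in groups.values()):
        raise ValueError("groups must be a disjoint, covering, non-empty partition")
    rows = {i: msa.row(i) for i in ids}
    out = []
    for j in range(msa.n_cols):
        col_all = {rows[i][j] for i in ids}
        if GAP in col_all:
            out.append(GAPPED)
        elif len(col_all) == 1:
            out.append(CONSERVED)
        else:
            per_group = [{rows[i][j] for i in members} for members in groups.values()]
            if all(len(g) == 1 for g in per_group):
                out.append(CLASS_SPECIFIC)
            else:
                out.append(UNCONSERVED)
    return out


# ---------------------------------------------------------------------------
# kinase consensus scanning

class KinaseRuleError(ValueError):
    pass


@dataclass(frozen=True)
class RuleElement:
    residues: Optional[frozenset]  # None = any residue
    phospho: bool = False

    def matches(self, ch: str) -> bool:
        if self.residues is None:
            return ch != GAP
        # a phospho element in a non-reported position permits its plain residues
        return ch in self.residues


@dataclass(frozen=True)
class KinaseRule:
    kinase_name: str
    elements: tuple
    reported_site_index: int  # 0-based index of the reported phospho element
    consensus_text: str = ""

    def __post_init__(self):
        if not any(e.phospho for e in self.elements):
            raise KinaseRuleError(f"{self.kinase_name}: no phospho element")
        el = self.elements[self.reported_site_index]
        if not el.phospho:
            raise KinaseRuleError(
                f"{self.kinase_name}: reported_site_index is not a phospho element"
            )

    def __len__(self) -> int:
        return len(self.elements)


def parse_kinase_rule(
    kinase_name: str, consensus: str, reported_site_index: int
) -> KinaseRule:
    """Parse a consensus like ``pS-X-X-X-pS-P`` or ``pS/T-X-D/E-D/E/pS-D/E``.

    Tokens are ``-``-separated; each token is ``X`` (any residue) or a
    ``/``-separated residue list whose members may carry a ``p`` prefix
    marking a phosphorylatable position.
    """
    elements = []
    for tok in consensus.strip().split("-"):
        tok = tok.strip()
        if not tok:
            raise KinaseRuleError(f"empty token in consensus {consensus!r}")
        if tok.upper() == "X":
            elements.append(RuleElement(None))
            continue
        residues, phospho = [], False
        for part in tok.split("/"):
            part = part.strip()
            # lowercase 'p' prefix marks a phospho position; bare 'P' is proline
            if part.startswith("p") and len(part) > 1:
                phospho = True
                part = part[1:]
            if len(part) != 1 or part.upper() not in ALPHABET:
                raise KinaseRuleError(f"bad residue {part!r} in {consensus!r}")
            residues.append(part.upper())
        elements.append(RuleElement(frozenset(residues), phospho))
    return KinaseRule(
        kinase_name=kinase_name,
        elements=tuple(elements),
        reported_site_index=reported_site_index,
        consensus_text=consensus,
    )


@dataclass(frozen=True)
class PhosphoSite:
    seq_id: str
    position: int  # 1-based position of the reported phospho residue
    residue: str
    kinase_name: str
    window_start: int
    window_end: int


def scan_kinase_sites(seq: SequenceRecord, rules: Sequence[KinaseRule]) -> list:
    """All consensus matches; the full rule window must fit inside the
    sequence (no overhang).  Sorted by position, then kinase name."""
    sites = []
    residues = seq.residues
    for rule in rules:
        w = len(rule)
        for start in range(len(residues) - w + 1):
            window = residues[start : start + w]
            if all(el.matches(window[k]) for k, el in enumerate(rule.elements)):
                pos = start + rule.reported_site_index
                sites.append(
                    PhosphoSite(
                        seq_id=seq.id,
                        position=pos + 1,
                        residue=residues[pos],
                        kinase_name=rule.kinase_name,
                        window_start=start + 1,
                        window_end=start + w,
                    )
                )
    sites.sort(key=lambda s: (s.position, s.kinase_name))
    return sites


def load_kinase_rules_tsv(path) -> list:
    """Rules from a TSV with columns kinase, consensus, reported-site index."""
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("kinase\t"):
                continue
            name, consensus, idx = line.split("\t")[:3]
            rules.append(parse_kinase_rule(name, consensus, int(idx)))
    return rules
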