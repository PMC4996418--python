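"""Rule-based paralog classification, glycine-rich regions, curation.

The classifier applies the discovered signature motifs in a fixed
decision order; glycine-rich regions are reported as supporting
evidence only — presence or absence of the regions is deliberately
never decisive, since the early Twist1-like lineage lacks them.

Decision order
--------------
1. scan both signature motifs: exactly one match decides the label;
2. otherwise the key residue of the first ``[TN]-S-E-[EG]-E`` sub-motif
   hit decides (N → group-A, T → group-B);
3. otherwise, for sequences of at least ``min_len_for_length_rule``
   residues, overall length decides (≥ high → group-A, ≤ low → group-B;
   Twist1-like proteins run near 200 aa, Twist2-like near 160 aa);
4. otherwise unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import constants
from .motif_discovery import scan_prosite
from .pairwise_align import (
    DEFAULT_SCORING,
    ScoringScheme,
    global_align,
    local_align,
    percent_identity,
)
from .seq_io import SequenceRecord

logger = logging.getLogger(__name__)

GROUP_A = "group-A"
GROUP_B = "group-B"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GlycineRegion:
    start: int  # 1-based inclusive
    end: int
    g_fraction: float
    subtype: str  # "G-A" | "G-S" | "other"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start after end")


def detect_glycine_regions(
    seq: SequenceRecord,
    window: int = 10,
    g_threshold: float = 0.4,
    region_limit: Optional[int] = None,
) -> list:
    """Maximal N-terminal glycine-rich regions, G-A / G-S subtyped.

    Sliding windows of size *window* with glycine fraction ≥
    *g_threshold* are merged into maximal regions; each region is
    re-scored over its full span and subtyped by its most frequent
    non-glycine residue (A-dominant → G-A, S-dominant → G-S, ties or
    other residues → other).  Only the N-terminal search zone up to
    *region_limit* (default ``min(length, 110)``) is examined.
    """
    if window < 3:
        raise ValueError("window must be at least 3")
    residues = seq.residues
    limit = min(len(residues), region_limit if region_limit is not None else 110)
    zone = residues[:limit]
    if len(zone) < window:
        return []
    hits = []  # qualifying window start indices (0-based)
    for i in range(len(zone) - window + 1):
        win = zone[i : i + window]
        if win.count("G") / window >= g_threshold:
            hits.append(i)
    regions = []
    i = 0
    while i < len(hits):
        j = i
        while j + 1 < len(hits) and hits[j + 1] <= hits[j] + window:
            j += 1
        span_start, span_end = hits[i], hits[j] + window - 1
        # trim to glycine boundaries so random flanks inside the merged
        # windows do not dilute the region score or its subtype
        while span_start < span_end and zone[span_start] != "G":
            span_start += 1
        while span_end > span_start and zone[span_end] != "G":
            span_end -= 1
        segment = zone[span_start : span_end + 1]
        g_frac = segment.count("G") / len(segment)
        non_g: dict = {}
        for ch in segment:
            if ch != "G":
                non_g[ch] = non_g.get(ch, 0) + 1
        if non_g:
            best = max(non_g.values())
            dominant = sorted(r for r, c in non_g.items() if c == best)
            subtype = (
                "G-A" if dominant == ["A"] else "G-S" if dominant == ["S"] else "other"
            )
        else:
            subtype = "other"
        if g_frac >= g_threshold:
            regions.append(
                GlycineRegion(span_start + 1, span_end + 1, g_frac, subtype)
            )
        i = j + 1
    return regions


@dataclass(frozen=True)
class ClassificationResult:
    seq_id: str
    label: str
    evidence: tuple  # ordered (rule name, outcome) pairs, always complete

    def evidence_dict(self) -> dict:
        return dict(self.evidence)


def classify_paralog(
    seq: SequenceRecord,
    length_bounds: tuple = (170, 185),
    min_len_for_length_rule: int = 140,
    glycine_kwargs: Optional[dict] = None,
) -> ClassificationResult:
    """Classify one sequence as Twist1-like (group-A) or Twist2-like (group-B)."""
    low, high = length_bounds
    sig_a = scan_prosite(constants.T1_SIGNATURE, seq, mode="first")
    sig_b = scan_prosite(constants.T2_SIGNATURE, seq, mode="first")
    sub2 = scan_prosite(constants.SUBMOTIF2, seq, mode="all")
    if len(sub2) > 1:
        logger.warning(
            "%s: %d [TN]-S-E-[EG]-E hits; key residue taken from the first",
            seq.id,
            len(sub2),
        )
    key_residue = seq.residues[sub2[0].start - 1] if sub2 else ""
    regions = detect_glycine_regions(seq, **(glycine_kwargs or {}))
    region_repr = ";".join(f"{r.start}-{r.end}:{r.subtype}" for r in regions)

    label = UNCLASSIFIED
    if bool(sig_a) != bool(sig_b):
        label = GROUP_A if sig_a else GROUP_B
    elif key_residue in ("N", "T"):
        label = GROUP_A if key_residue == "N" else GROUP_B
    elif len(seq) >= min_len_for_length_rule:
        if len(seq) >= high:
            label = GROUP_A
        elif len(seq) <= low:
            label = GROUP_B

    evidence = (
        ("signature_A", "match" if sig_a else "no-match"),
        ("signature_B", "match" if sig_b else "no-match"),
        ("key_residue", key_residue or "absent"),
        ("length", str(len(seq))),
        ("glycine_regions", region_repr or "none"),
    )
    return ClassificationResult(seq_id=seq.id, label=label, evidence=evidence)


# ---------------------------------------------------------------------------
# curation

@dataclass(frozen=True)
class CurationDecision:
    seq_id: str
    kept: bool
    core_identity: float
    overall_identity: float
    reason: str  # "ok" or the failing criterion with its measured value


def curate_candidates(
    candidates: Sequence[SequenceRecord],
    reference: SequenceRecord,
    core_range: tuple,
    core_min_pct: float = 89.0,
    overall_min_pct: float = 75.0,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list:
    """Keep candidates whose identity to the reference core is ≥
    *core_min_pct* and whose overall identity is > *overall_min_pct*
    (global alignment).  Core identity is measured by local alignment
    but normalized by the core length (identical positions / core
    length), so a short perfect block inside an otherwise diverged core
    does not pass the filter.  Every decision carries the measured
    values and, for rejections, the failing criterion."""
    lo, hi = core_range
    if not (1 <= lo <= hi <= len(reference)):
        raise ValueError(f"core range {core_range} outside reference 1..{len(reference)}")
    core = SequenceRecord(
        id=f"{reference.id}|core", residues=reference.residues[lo - 1 : hi]
    )
    decisions = []
    for cand in candidates:
        aln = local_align(cand, core, scoring)
        core_id = 100.0 * aln.n_identical / len(core)
        overall_id = percent_identity(cand, reference, "global", scoring).identity_pct
        if core_id < core_min_pct:
            kept, reason = False, f"core identity {core_id:.1f} < {core_min_pct}"
        elif overall_id <= overall_min_pct:
            kept, reason = False, f"overall identity {overall_id:.1f} <= {overall_min_pct}"
        else:
            kept, reason = True, "ok"
        decisions.append(
            CurationDecision(
                seq_id=cand.id,
                kept=kept,
                core_identity=core_id,
                overall_identity=overall_id,
                reason=reason,
            )
        )
    return decisions
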