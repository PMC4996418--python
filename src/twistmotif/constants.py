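"""Published Twist1/Twist2 motif and kinase-consensus constants.

The mammalian N-terminal motifs, their PROSITE-format group patterns,
the two sub-motifs (the SSSPVSP-like block and the SEEE block), the
refined signature motifs, and the four Ser/Thr kinase consensus rules
with the printed human N-terminal peptides they were scanned against.

Group A is the Twist1-like paralog (key residue asparagine), group B the
Twist2-like paralog (key residue threonine).  A consistency check —
each group's motif matches its own pattern and signature and fails the
other group's signature, and each peptide yields exactly one site per
applicable kinase rule — runs at import time.
"""

from __future__ import annotations

from .motif_discovery import (
    KinaseRule,
    parse_kinase_rule,
    parse_prosite,
    pattern_matches,
    scan_kinase_sites,
    scan_prosite,
)
from .seq_io import SequenceRecord

# mammalian N-terminal motifs (strictly conserved within mammals)
T1_MAMMAL_MOTIF = "SSSPVSPADDSLSNSEEE"
T2_MAMMAL_MOTIF = "SSSPVSPVDSLGTSEEE"

# group patterns derived from the vertebrate alignment
T1_PATTERN = parse_prosite("[GSA]-[SNR]-S-P-[VEA]-S-P-[AV]-D-D-S-[LVA]-[SG]-N-S-E-[EG]-E")
T2_PATTERN = parse_prosite("S-[SG]-[SC]-P-[VG]-S-P-V-D-S-[LV]-[VG]-T-S-E-E-E")

# conserved sub-motifs shared by both paralogs
SUBMOTIF1 = parse_prosite("[GSA]-[SGNR]-[SC]-P-[VGEA]-S-P-[VA]-D")
SUBMOTIF2 = parse_prosite("[TN]-S-E-[EG]-E")

# combined two-group pattern (with the group-A double aspartate)
COMBINED_PATTERN = parse_prosite(
    "[GSA]-[SGNR]-[SC]-P-[GVEA]-S-P-[VA]-D-D-S-[LVA]-[VGS]-[TN]-S-E-[EG]-E"
)

# minimal end-trimmed signature motifs
T1_SIGNATURE = parse_prosite("P-[VEA]-S-P-[VA]-D-D-S-[LVA]-[SG]-N-S-E")
T2_SIGNATURE = parse_prosite("P-[GV]-S-P-V-D-S-[LV]-[VG]-T-S-E")

# human N-terminal peptides scanned for kinase sites
T1_PEPTIDE = "MMQDVSSSPVSPADDSLSNSEEE"
T2_PEPTIDE = "MEEGSSSPVSPVDSLGTSEEE"

# Ser/Thr kinase consensus rules; the reported site index is the 0-based
# element whose position is quoted (GSK3's primed consensus reports the
# N-terminal phospho-serine)
KINASE_RULES = (
    parse_kinase_rule("GSK3", "pS-X-X-X-pS-P", 0),
    parse_kinase_rule("BARK", "X-E-X-pS-X-X", 3),
    parse_kinase_rule("LKB1", "X-L-X-pT-X-X", 3),
    parse_kinase_rule("CK2", "pS/T-X-D/E-D/E/pS-D/E", 0),
)

KINASE_RULES_BY_NAME = {r.kinase_name: r for r in KINASE_RULES}


def _selfcheck() -> None:
    a = SequenceRecord(id="motifA", residues=T1_MAMMAL_MOTIF)
    b = SequenceRecord(id="motifB", residues=T2_MAMMAL_MOTIF)
    assert pattern_matches(T1_PATTERN, a)
    assert pattern_matches(T2_PATTERN, b)
    assert pattern_matches(T1_SIGNATURE, a)
    assert pattern_matches(T2_SIGNATURE, b)
    assert not pattern_matches(T1_SIGNATURE, b)
    assert not pattern_matches(T2_SIGNATURE, a)
    pep1 = SequenceRecord(id="pepA", residues=T1_PEPTIDE)
    pep2 = SequenceRecord(id="pepB", residues=T2_PEPTIDE)
    gsk3 = KINASE_RULES_BY_NAME["GSK3"]
    assert [s.position for s in scan_kinase_sites(pep1, [gsk3])] == [7]
    assert [s.position for s in scan_kinase_sites(pep2, [gsk3])] == [6]
    for name, pos in (("BARK", 5), ("LKB1", 17), ("CK2", 17)):
        hits = scan_kinase_sites(pep2, [KINASE_RULES_BY_NAME[name]])
        assert [s.position for s in hits] == [pos]


_selfcheck()
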