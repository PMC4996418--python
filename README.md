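# twistmotif

Comparative sequence analysis for the Twist subfamily of bHLH
transcription factors — and, more generally, for any two-paralog protein
family whose members must be told apart by short N-terminal sequence
features rather than by their conserved core domain.

Twist1 and Twist2 arose from a single gene duplication and are routinely
mis-annotated in public databases because their bHLH cores are nearly
identical and the classic discriminator (the Twist1-specific
glycine-rich regions) is absent from early-branching Twist1 lineages.
The N-terminal disordered region, however, carries a short conserved
motif — `SSSPVSPADDSLSNSEEE` in mammalian Twist1, `SSSPVSPVDSLGTSEEE`
in mammalian Twist2 — whose single class-specific key residue
(asparagine in Twist1-like, threonine in Twist2-like sequences) cleanly
separates the two paralogs.  This package implements the full analysis
around that observation:

* **PROSITE-format motif machinery** — a parser/scanner for the pattern
  subset `A`, `[TN]`, `{PG}`, `x`, `x(n)`, `x(n,m)`; alignment column
  profiles; profile → pattern construction; and sequential end-trimming
  of a pattern into a minimal *signature motif* that matches one paralog
  group and rejects the other.  The published group patterns, sub-motifs
  (`[GSA]-[SGNR]-[SC]-P-[VGEA]-S-P-[VA]-D` and `[TN]-S-E-[EG]-E`) and
  signature motifs (`P-[VEA]-S-P-[VA]-D-D-S-[LVA]-[SG]-N-S-E` /
  `P-[GV]-S-P-V-D-S-[LV]-[VG]-T-S-E`) ship as package constants.
* **Rule-based paralog classification** with explicit evidence
  (signature matches → key residue → sequence length), plus detection
  and G-A / G-S subtyping of N-terminal glycine-rich regions and the
  bHLH-core / overall-identity curation filter (≥ 89 % / > 75 %).
* **Ser/Thr kinase consensus scanning** (GSK3 `pS-X-X-X-pS-P`, BARK
  `X-E-X-pS-X-X`, LKB1 `X-L-X-pT-X-X`, CK2 `pS/T-X-D/E-D/E/pS-D/E`)
  over the conserved sub-motifs.
* **Evolutionary analysis** — gap-fraction alignment trimming,
  p-distance and JTT-normalized distance matrices, neighbor-joining
  trees with column-bootstrap support, classical (Torgerson) metric MDS
  of sequence space, and an evolutionary trace classifying every
  alignment column as conserved / class-specific / unconserved / gapped
  across nested tree partitions.
* **A family simulator** that generates Twist-like two-paralog families
  with a planted key column, staged glycine-region insertions and full
  ground truth (records, true alignment, true gene tree), so every
  stage is testable without downloading a single sequence.
* **Pairwise alignment utilities** (BLOSUM62, gap open 11 / extend 1,
  global and local) for the identity comparisons, and a small
  progressive aligner for self-contained tests.

## Worked example

Scan the two published human N-terminal peptides:

```
$ twistmotif classify peptides.fasta
seq_id	label	signature_A	signature_B	key_residue	length	glycine_regions
hTwist1_Nterm	group-A	match	no-match	N	23	none
hTwist2_Nterm	group-B	no-match	match	T	21	none

$ twistmotif kinase peptides.fasta
seq_id	kinase	position	residue	window_start	window_end
hTwist1_Nterm	GSK3	7	S	7	12
hTwist2_Nterm	BARK	5	S	2	7
hTwist2_Nterm	GSK3	6	S	6	11
hTwist2_Nterm	CK2	17	T	17	21
hTwist2_Nterm	LKB1	17	T	14	19
```

The Twist1 peptide `MMQDVSSSPVSPADDSLSNSEEE` matches the Twist1-like
signature motif (and carries the key asparagine); the Twist2 peptide
`MEEGSSSPVSPVDSLGTSEEE` matches the Twist2-like signature, with the key
threonine at position 17.  The kinase scan reproduces the five
published consensus sites: GSK3 at S7 (Twist1) and S6 (Twist2), BARK at
S5, and LKB1 and CK2 both at the T17 key residue — the last two exist
only in Twist2, which is why those kinases are paralog-specific.

A full analysis (curation → motifs → classification → kinase → glycine
→ trim → distances → NJ + bootstrap → MDS → trace) runs with:

```
twistmotif simulate --seed 42 --out sim/
twistmotif run sim/family.fasta --alignment sim/family_true_msa.fasta \
    --labels labels.tsv --seed 1 --out results/
```

and writes one TSV/FASTA/Newick artifact per stage.  Library use mirrors
the CLI: see `twistmotif.classify_paralog`, `twistmotif.scan_prosite`,
`twistmotif.refine_discriminative_motif`, `twistmotif.nj_tree`,
`twistmotif.classical_mds`, `twistmotif.simulate_family`.

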