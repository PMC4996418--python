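# Methods

This note documents the models, conventions and numerical choices
behind `twistmotif`, in the order the pipeline applies them.

## Sequence model and coordinates

Sequences are proteins over the 20 canonical amino acids plus `X`
(unknown).  The ambiguity codes B/Z/U/O are rejected at input rather
than silently accepted, because every downstream stage does exact
residue matching and an ambiguous residue would make pattern-hit
semantics ill-defined; `X` is kept but matches only wildcard pattern
elements.  All reported positions are 1-based and inclusive (so "T17"
means the seventeenth residue).  Alignments use `-` as the only gap
character; `.` is converted on read.

## Pairwise alignment and identity

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment use
affine gaps with the protein-BLAST default scoring: BLOSUM62, gap open
11, gap extend 1, a length-*k* gap costing `11 + k`.  Percent identity
is identical columns divided by all alignment columns, which is how
BLASTP reports "Identities"; no compositional adjustment is applied, so
values can differ from the NCBI server by about one percentage point.
When every attainable local score is ≤ 0 the local alignment is
reported as explicitly empty, not as an error.  Where several optimal
tracebacks exist the first alignment in Biopython's deterministic
enumeration is used, so repeated runs always agree.

The curation filter keeps a candidate when (a) its identity to the
reference core region is ≥ 89 % and (b) its overall global identity to
the reference is > 75 %.  Core identity is measured by local alignment
but normalized by the core length (identical positions / core length):
a short perfect block inside an otherwise shuffled core then scores
low, whereas raw local identity would score it 100 %.

The progressive multiple aligner (single-linkage guide tree on global
identity distance, profile–profile Needleman–Wunsch with a linear
gap-column penalty of 10) exists so that synthetic self-tests need no
external aligner.  It is deliberately minimal; real analyses should
supply a production alignment, which the pipeline loads instead.

## PROSITE patterns, profiles and signature refinement

The pattern language is the PROSITE subset: literal residues,
alternative sets `[TN]`, excluded sets `{PG}`, and wildcards `x`,
`x(n)`, `x(n,m)`, with optional `-` separators and trailing period.
Scanning is element-wise: literals by equality, sets by membership,
wildcards by any residue (including `X`); a sequence `X` satisfies only
wildcards.  Every matching start position yields exactly one hit; when
a wildcard range allows several lengths at one start, the shortest
match is reported.  The scanner is validated against an independent
lazy-regex oracle on 10,000 random pattern/sequence pairs.

A column profile counts residues and gaps per alignment column over a
chosen row subset.  Pattern construction maps each column to a literal
(one residue), an alternative set (2–4 residues, ordered by descending
frequency with ties broken by first appearance top-to-bottom), or a
wildcard (more than 4 residues); `min_freq` (default 0) can drop rare
residues, at the cost of the completeness guarantee that the pattern
matches every training row.  Residue ordering inside brackets is
presentational; pattern comparisons are set-based.

Signature refinement trims a discriminative pattern (matches every
positive, no negative) from its extremes, sequentially and one at a
time: the leading element is removed repeatedly until a removal would
break discrimination, then the trailing element likewise, and the two
phases repeat to a fixed point.  The result is end-trim minimal.
Trimming the front phase first anchors the refined core at the
left-most element discrimination needs; when the discriminating
difference is a single class-specific residue (the N/T key column),
the core therefore retains that column — trimming cannot pass it,
because the conserved `S-E-E-E` tail to its right matches the opposite
group.  A strictly alternating first/last order was considered and
rejected: it converges onto whatever discriminative pair happens to sit
at the geometric center of the pattern (for the packaged motifs, the
D-D pair), which misses the key residue by construction.

Discrimination is defined against caller-supplied labeled sequence
sets.  On tiny corpora the fixed point can be shorter than the
published signature motifs — with only the two printed mammalian motifs
as corpus, `D-D` already separates them — because a binary
match/no-match criterion over a handful of sequences is weaker than the
database-retrieval criterion used to derive the published signatures.

## Kinase consensus scanning

Rules are ordered element lists parsed from text like `pS-X-X-X-pS-P`:
`X` matches any residue, `/`-separated lists are residue sets, and a
lowercase `p` prefix flags a phosphorylatable position.  A window
matches when every element matches; phospho elements in non-reported
positions accept the unmodified residue (a plain S satisfies `pS`).
The whole window must lie inside the sequence — no overhang — which is
why CK2 (four residues required after the site) can report T17 of the
21-residue Twist2 peptide but nothing later.  Each rule names the
element whose position is reported; for GSK3's primed consensus that is
the N-terminal phospho-serine.

## Classification

The decision order is: (1) scan both signature motifs — exactly one
match decides; (2) otherwise the first `[TN]-S-E-[EG]-E` hit decides by
its key residue (N → Twist1-like, T → Twist2-like); (3) otherwise, for
sequences of ≥ 140 residues, length decides (≥ 185 → Twist1-like,
≤ 170 → Twist2-like, interpolating the typical ~200 aa vs ~160 aa
paralog lengths; the 140-residue floor avoids classifying fragments by
length); (4) otherwise unclassified.  Glycine-rich regions are reported
as evidence but are never decisive, since early-branching Twist1-like
sequences lack them.

Glycine regions are detected by sliding 10-residue windows with
glycine fraction ≥ 0.4 inside the N-terminal 110 residues (the
disordered-region search zone), merging qualifying windows, trimming
the merged span to its glycine boundaries, and re-scoring.  Window and
threshold are package choices — no standard numeric definition of
"glycine-rich" exists — set so that both human Twist1 regions are
detected and no mammalian Twist2 N-terminus is.  The subtype is the
dominant non-glycine residue: alanine → G-A, serine → G-S, ties or
other residues → other.

## Distances, trees, MDS, trace

Gap-heavy columns (gap fraction > 0.4 by default) are removed before
distance computation; explicit column ranges (e.g. the glycine-region
columns) can be dropped regardless.  The slope-based "gappyout"
heuristic of dedicated trimming tools is intentionally replaced by this
single-threshold rule: it is reproducible, and at 0.4 it removes
exactly the columns private to one paralog group in a combined
alignment (gapped in the whole other group).

Distances are computed over columns where neither row is gapped:
p-distance (mismatches / compared columns) or a normalized similarity
distance `1 − s(a,b)/√(s(a,a)·s(b,b))` with `s` the summed JTT
similarity-matrix entries, clamped at 0.  A pair with no shared
ungapped columns is an error, not a silent NaN.

Trees come from canonical neighbor joining (Q-criterion; ties broken by
the lexicographically smallest label pair; negative branch estimates
clamped to 0 and logged; unrooted output with a trifurcating root).  NJ
is exact on additive matrices — the suite verifies topology and all
path lengths to 1e-9 on random trees — and the implementation is
cross-checked against an independent NJ implementation.  Maximum
likelihood is deliberately not used: the claims checked here are
topology-level (does the tree contain the paralog split), for which NJ
plus bootstrap is sufficient and fully deterministic.  Bootstrap
support resamples alignment columns with replacement, rebuilds the NJ
tree per replicate, and reports for each internal edge of the reference
tree the percentage of replicates containing the same bipartition
(canonical side: the one excluding the lexicographically smallest
leaf).

Classical (Torgerson) MDS double-centers −½·D², eigendecomposes, and
scales the top-k eigenvectors with positive eigenvalues by
√eigenvalue.  Axis signs are fixed (first nonzero loading positive) so
output is fully deterministic; explained fractions are relative to the
sum of positive eigenvalues.  All retained components are exported —
which components to plot is left to the user.

The evolutionary trace cuts a rooted tree, at level *p*, at the *p − 1*
internal nodes closest to the root (by root distance, ties by traversal
order), groups the alignment rows by the resulting subtrees, and
classifies each column: conserved (one residue everywhere),
class-specific (each group internally uniform, groups differ), gapped
(any gap), else unconserved.  Level 1 has a single group, so nothing is
class-specific there, and a column conserved at level 1 is conserved at
every level.

## The family simulator

The simulator emulates the evolutionary narrative the pipeline is built
to recover: a 160-residue ancestral Twist2-like protein with the
Twist2-like motif at positions 5–21 and a slow core at 61–120; a
duplication (at the root of the default 12-tip pectinate species tree,
fish → amphibian → reptile → bird → mammal) whose Twist1-like copy
receives the Twist1-like motif template (one extra residue, the second
aspartate, plus the T→N key-residue swap); and two atomic insertions on
the Twist1-like lineage only — a G-S region (`GGSGGGSSGG`, at root
position 30) on the branch ancestral to all but the two earliest fish,
and a G-A region (`GGAGGGAGGG`, position 48) later, on the branch
ancestral to the second bird and the mammals — reproducing the
early-G-S / late-G-A ordering.

Substitutions are a per-site-class Poisson process: 0.15 expected
substitutions per site per unit branch length in disordered positions,
0.02 in the core, 0.005 in the motif, 0.02 in inserted regions
(conserved repeats); a substitution draws a different residue
uniformly.  The three class-specific motif columns are immutable, so
the planted key column is exactly recoverable.  Insertions are atomic
whole-region events — no repeat-expansion model — mirroring the
inferred tandem-repeat/duplication origin of the real regions at the
level of presence/absence.  Because indels are restricted to these
planted events, the simulator emits the exact true alignment (root
coordinates plus insertion columns) alongside the records and the true
gene tree, which is what makes trace- and tree-level ground truth
exact.

What the simulator does **not** model: empirical amino-acid exchange
preferences (uniform exchange instead of a JTT-like matrix), rate
variation within a class, background indels, repeat expansion, and
alignment error (pipeline tests run on the true alignment or on the
package's own progressive aligner).  Passing recovery tests therefore
demonstrates that the analysis machinery is correct under the stated
generative model, not that it is robust to real-data alignment noise.

## Problem sizes and determinism

Default test and acceptance problem sizes: 24-sequence families
(~180-column alignments), 200-trial NJ and MDS sweeps, 10,000-pair
scanner/oracle comparisons, and 10–100 bootstrap replicates in tests
(1,000 remains the library default, matching standard practice).  Every
stochastic component (simulator, bootstrap, random sweeps) is driven by
an explicit integer seed through `numpy.random.default_rng`; identical
seeds give byte-identical pipeline artifacts.

## Known limitations

* The published signature motifs were derived against database
  retrieval; the refinement operation here uses binary discrimination
  over supplied sets and reproduces the published signatures only in
  spirit (minimal discriminative core anchored at the key residue), not
  element-for-element on small corpora.
* Identity values may differ from BLASTP server output by ~1 point
  (no compositional adjustment; identity over alignment columns).
* Length-based classification uses fixed thresholds (170/185, floor
  140) interpolated from typical paralog lengths; unusual fusions or
  fragments fall back to `unclassified` rather than being guessed.
* The trace's partition schedule (cut nodes ranked by root distance)
  is one of several reasonable conventions; different rankings can
  produce different intermediate levels on trees with near-equal node
  heights.
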