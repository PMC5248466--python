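# Methods

## The analysis model

A PIT experiment identifies MS/MS peptides against the six-frame
translation of a de novo transcriptome from the same biological sample.
`pitkit` consumes the *outputs* of that identification — transcripts
(FASTA) and a peptide-evidence table mapping each peptide to the ORF ids
it is consistent with — and performs everything downstream. Spectral
search, FDR control and quantification are out of scope by design; the
peptide table is trusted as given.

### ORF extraction

ORFs are extracted from all six reading frames. An ORF runs from an ATG
to the last sense codon before a stop (or to the transcript edge when no
stop follows — de novo transcripts are frequently 3'-truncated, so
open-ended ORFs are retained). The length floor (default 200 nt) is
strict (`> 200`), counts ATG through the last sense codon and excludes
the stop. Within one stop-delimited segment only the ORF from the first
ATG is reported (longest-per-stop); nested starts are suppressed because
they are redundant for peptide matching. Codons containing N translate to
X. Internal coordinates are 0-based half-open on the forward strand of
the transcript; report files print 1-based inclusive coordinates.

### Protein grouping

ORFs whose supporting-peptide sets are identical are indistinguishable by
the evidence and are merged into one protein group. The group count is
the unit of every downstream summary; a `min_peptides` filter (1 or 2) is
applied at summary time, not at grouping time, so both views are always
available from one grouping.

### Local alignment and E-values

Homology search uses optimal Smith–Waterman local alignment (BLOSUM62,
gap open 11, gap extend 1; opening a gap charges open+extend on the first
gap residue). The engine is `Bio.Align.PairwiseAligner` in local mode;
scores are computed for every subject and tracebacks only for reported
hits, so ranking reflects optimal scores over the full database. Among
co-optimal tracebacks the engine's first reported alignment is used — a
deterministic choice for fixed inputs, which is what reproducibility
requires; scores, ranking and the identity of the reported path do not
depend on it.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with the standard
gapped BLOSUM62/11/1 constants λ = 0.267, K = 0.041 (both configurable in
`ScoringScheme`); m is the query length and n the summed residue length
of the database searched, matching the search-space convention the
calling thresholds were calibrated under. Percent identity is identities
over alignment columns (gapped convention); coverage is *query* coverage.

No heuristic seeding is used for protein search: databases at this
pipeline's scale are small and correctness is preferred over speed.
External BLAST results can be imported from 12/13-column tabular files
instead.

### Homology cascade

Tiers are searched in order; the cascade stops at the first tier whose
best hit has identity ≥ 60% *and* E ≤ 1e−5. The E-value condition is
deliberate: a five-residue spurious alignment can reach any identity, and
identity alone must not stop the cascade. Stopping at the first tier
labels the query AEDES; at the second or third, NON_AEDES_INSECT;
anything else (including a fallback-tier stop) NON_INSECT. Percentages
are printed integer-rounded (half-up) and to one decimal.

### TE calling and calibration

Only the top database hit per query (by raw score) is considered. A call
requires E < 1e−5 (strict, as the threshold is conventionally quoted),
identity > 30% and query coverage > 45%, all strict; > 95%/95% earns the
"exact match" tier, counted *within* the standard call set. The
calibration operation recomputes, per coverage (or identity) cutoff, the
fraction of a target set and of a background set whose best TE hit
survives; the knee chooser returns the smallest cutoff where background
has fallen to 20% of its cutoff-0 value while the target retains 80% of
its cutoff-0 value, falling back to the max-difference cutoff. The
published choice was made by inspection; the chooser formalises it, is
advisory only, and both tolerances are parameters.

Single-peptide QC: a call supported by exactly one peptide is removed
when that peptide also matches ORFs outside the call's group that carry a
different element identity (different order/clade), a non-concordant ORF
type within the same clade, or no TE call at all (a host gene).
Concordance between two databases is reported at order level (the
headline "TE identity" agreement) and clade level, over the queries
called in both.

### Enrichment

Counts per order (or clade, or ORF type) are divided by a normaliser —
percent of genome, genomic copy number, or database entries — and
expressed relative to a reference category (LTR retrotransposons), whose
ratio is exactly 1. Categories with an unknown or zero normaliser are
reported as UNDEFINED, never dropped (copy numbers are genuinely unknown
for some cut-and-paste families). SINE and MITE orders are excluded from
protein-enrichment denominators by default because they encode no
proteins of their own; this is configurable. Enrichment uses the post-QC
call list. The ORF-type breakdown counts *distinct elements* per
(clade, ORF type) cell, not calls.

### Annotation evaluation

The built-in transcript-to-genome mapper is a seed-and-extend near-exact
spliced aligner: 21-mer seeds grouped by (supercontig, diagonal), diagonal
clusters chained into exon blocks, greedy x-drop extension (match +1,
mismatch −3, drop 12) at block edges and across unseeded interior gaps.
It is adequate for transcripts within a few percent of the genome
sequence — the regime the generator produces — and is not a general
spliced aligner for diverged transcripts; external spliced alignments can
be imported.

Triage: a transcript with no alignment at ≥ 90% identity and ≥ 50%
coverage is NO_MATCH. If two or more loci score within 95% of the best
locus, AMBIGUOUS (possible duplications; excluded from downstream
counts). Otherwise the best locus is compared with the annotation: ≥ 1 bp
overlap with an annotated gene's exon span *on the same strand* means
ALREADY_ANNOTATED, else NEW_ANNOTATION. The ambiguity margin and the
overlap rule are package choices where the published procedure gives no
rule; both are parameters.

The gap scan counts N characters in the alignment span ± 5 kb, truncated
(and flagged) at supercontig ends; "has a gap" means any N in the window,
with the count also reported. Controls are drawn by greedy
nearest-transcript-length matching without replacement from the
annotated-gene transcripts, deterministic given a seed. The chromosome
ratio divides each chromosome's fraction of new-annotation-bearing
supercontigs (counted once each) by the genome-wide fraction, so 1.0
means no enrichment. Band hotspots rank all bands holding at least one
mapped supercontig by new-annotation count (ties lexicographic, for
determinism) and flag the top 20% (ceiling) if their count exceeds two.
The t-test is the pooled-variance equal-variance two-tailed test
(scipy's `ttest_ind`), with zero-variance inputs handled explicitly:
equal means give (t=0, p=1), unequal means are an error.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the biology of real sequence: a genome of 40 supercontigs (~20–40 kb
of uniform random sequence plus planted features, ~2 Mb total), 70%
mapped to 15 cytological bands on three chromosomes; 50 expressed
annotated host genes; 32 "missing annotation" genes present only in the
Culex tier (20 novel unannotated — concentrated 5/4/3 on the three
planted hotspot bands and ≤ 2 elsewhere — 5 annotated, 3 duplicated at
two loci, 4 absent from the assembly); 5 decoy proteins in no database;
and TE families with the field's ORF architectures: two LTR families
(gag+pol, 25 copies each, every ORF expressed), two non-LTR families
(ORF1+ORF2, 25 copies each, each ORF expressed with probability 0.25 —
the planted 4:1 LTR bias over equal genomic representation), two
cut-and-paste families (transposase; one with unknown copy number to
exercise UNDEFINED enrichment cells), and two database-only families with
no genomic copies (TE databases are not genome-specific; these also donate
the spurious background fragments). Copies diverge 20% from the consensus
at the amino-acid level, except a 12% "recent insertion" fraction at
0.5–2% divergence that produces the exact-match call tier.

Specific modelling choices, and what they do *not* capture:

* **Protein mutation** is per-site substitution with BLOSUM62-weighted
  replacement; expected identity is 100·(1−d)%. No indels, no rate
  heterogeneity, no phylogenetic structure — identity recovery tests are
  exact but alignability is easier than for real diverged TEs.
* **Transcripts** are exact exon concatenations with a 0.05% uniform
  substitution error (assembled transcripts are highly accurate). An
  error can still create a premature stop and destroy a planted CDS
  (~1–2% of transcripts); the ground truth records these as unrecovered,
  and recovery tests condition on that record.
* **Peptides** are uniform random substrings (8–25 aa) of the expressed
  ORF's protein, with a zero-truncated Poisson(3) count per ORF — chosen
  so ~84% of groups carry ≥ 2 peptides, the proportion typical of PIT
  protein groups. No tryptic cleavage model, no detectability or
  abundance model. Peptide-to-ORF match sets are computed by substring
  scan over all extracted ORFs, so shared peptides between near-identical
  TE copies arise naturally. The two planted promiscuous single-peptide
  cases (for QC) are additionally *assigned* a different-order TE ORF in
  the evidence table, modelling search-engine ambiguity at the table
  level rather than the sequence level.
* **Spurious background homology**: three host proteins embed a fragment
  (20/30/42% of their length) of a database-only TE consensus at 30%
  divergence — enough identity to be a real hit, short enough that its
  coverage sits below the 45% knee. This is what makes the background
  calibration curve collapse at the planted knee.
* **N runs** (80–300 nt) are planted 1.5–3.5 kb from 7 of the 20 novel
  genes; features are separated by ≥ 5.5 kb of filler so no other gene's
  ±5 kb window reaches a foreign gap.
* The genome has no TSDs, no nested insertions, no repeat landscape
  beyond the planted copies; triage ambiguity comes only from the
  deliberately duplicated genes.

Because the generator's regime is benign (low divergence, crisp planted
structure), passing recovery tests demonstrates that the *bookkeeping and
statistics* of the pipeline are correct — not that the thresholds would
perform identically on real, messier data.

All randomness flows from one integer seed through a single
`numpy.random.default_rng` stream; no global random state is touched, and
the same seed reproduces byte-identical files.

## Problem sizes and determinism

The default scenario runs the complete pipeline in ~30 s on one core:
~220 transcripts, ~430 ORFs, ~220 protein groups, ~35k pairwise protein
alignments across the cascade, TE calling and calibration (score-only
passes with tracebacks computed just for reported hits). These sizes were
chosen as the smallest at which the planted effects (4:1 bias with
n ≈ 125 TE proteins, 5% spurious background, 3 hotspot bands) are
resolvable against sampling noise. Reports contain no timestamps or
absolute paths, so identical inputs and seed give byte-identical output
files.

## Known limitations

* The alignment engine is exact but O(mn) per pair; it is not meant for
  proteome-scale all-vs-all search. Import externally computed tabular
  results for large databases.
* The built-in genome mapper assumes near-identity and substitution-only
  divergence; introns are recovered by diagonal chaining, not by splice
  signal modelling.
* E-value constants are the standard gapped BLOSUM62/11/1 values and are
  not re-estimated per database composition.
* The viral screen requires a user-supplied viral protein database and
  applies only the score>50 floor plus TE/host exclusion; it performs no
  taxonomic post-processing.
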