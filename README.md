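# pitkit

Downstream analysis of **PIT** (proteomics informed by transcriptomics)
datasets. In a PIT experiment, MS/MS peptides are identified against a
six-frame translation of a de novo transcriptome assembled from the same
sample, instead of against a reference proteome. That makes the analysis
independent of the quality of the organism's genome annotation — and
therefore able to interrogate it. `pitkit` implements the downstream steps
for a non-model insect (written around the *Aedes aegypti* case, but
generic):

* **ORF extraction and grouping** — six-frame translation of every
  transcript, keeping ORFs with a start codon and length strictly > 200 nt;
  ORFs indistinguishable by their supporting peptides are merged into
  protein groups.
* **Tiered homology cascade** — each protein group is searched against an
  ordered list of reference proteomes (*Ae. aegypti* → *Culex
  quinquefasciatus* → *Drosophila melanogaster*); the cascade stops at the
  first tier whose best hit reaches 60% identity at E ≤ 1e−5, partitioning
  the proteome into *Aedes* / non-*Aedes* insect / non-insect categories.
* **TE protein calling** — non-insect proteins are searched against
  transposable-element protein databases (a TEfam-like and a RepBase-like
  input); the top hit by alignment score is called a TE protein when
  E < 1e−5, identity > 30% and query coverage > 45%, with an "exact match"
  tier at > 95%/95%. The 30/45 thresholds are supported by a calibration
  procedure that traces target and background retention curves across
  cutoffs and picks the knee where background collapses. Single-peptide
  calls whose peptide also matches discordant ORFs are removed (QC), and
  calls from the two databases are compared at order and clade level.
* **Enrichment normalisation** — per-order/clade protein counts are
  normalised by genome percentage, genomic copy number or database entry
  count and expressed relative to LTR retrotransposons (ratio 1), turning
  raw counts into relative protein-level activity.
* **Genome-annotation evaluation** — transcripts encoding non-*Aedes*
  insect proteins are aligned to the genome and triaged (no match /
  already annotated / ambiguous / new annotation); sequencing-gap N runs
  are counted in a ±5 kb window around each new annotation versus a
  transcript-length-matched control set (equal-variance two-tailed
  t-test); hotspots of missing annotation are detected per chromosome
  (normalised supercontig ratios) and per cytological band (top 20% of
  bands with more than two new annotations).
* **Synthetic data** — a deterministic generator plants a toy genome,
  annotation, TE families with gag/pol, ORF1/ORF2 and transposase
  architectures, sequencing gaps, transcripts and peptide evidence, with a
  full ground-truth record, so every stage can be tested by parameter
  recovery.

The core statistics are standard: Smith–Waterman local alignment under
BLOSUM62 with affine gaps (open 11, extend 1), Karlin–Altschul E-values
E = K·m·n·e^(−λS) with λ = 0.267, K = 0.041 (bit score (λS − ln K)/ln 2),
and the pooled-variance two-sample t statistic.

## Worked example

Generate the default synthetic study and run every stage:

```sh
pitkit simulate --seed 1 --out-dir demo
pitkit run-all --config demo/run_config.yaml
```

`demo/report/` then contains 19 TSV/JSON tables. The cascade partition
(`cascade_partition_min1pep.tsv`):

```
category          count  pct_int  pct_1dp
AEDES             50     23       22.8
NON_AEDES_INSECT  32     15       14.6
NON_INSECT        137    63       62.6
```

50 groups matched the host proteome, 32 matched only the other dipteran
tiers (planted missing annotation), and 137 matched nothing — the TE-rich
subset. From `summary.json`: 130 TE calls (16 in the exact-match tier),
the calibration knee selected at 45% coverage, and the triage of the 32
non-*Aedes* transcripts into 4 no-match / 5 already annotated / 3
ambiguous / 20 new annotations, exactly as planted. 35% of new
annotations have a sequencing gap within 5 kb (t = 3.01, p = 0.0046
against matched controls). The genome-normalised enrichment table
(`enrichment_order_genome_pct.tsv`):

```
category  count  ratio      defined
DNA_TIR   11     0.444614   True
LTR       97     1          True
NON_LTR   22     0.227672   True
```

recovers the planted 4:1 LTR:non-LTR expression bias (1/0.228 ≈ 4.4-fold
LTR enrichment over equal genomic representation), and `band_hotspots.tsv`
flags exactly the three planted bands (1p3, 1q4, 2p4).

## Layout

```
src/pitkit/
  orfs.py        six-frame translation, ORF extraction, peptide grouping
  align.py       Smith-Waterman, E-values, ranked search, BLAST tabular IO
  cascade.py     tiered homology classification, partition summaries, viral screen
  tecalls.py     TE calling, calibration curves, QC, database concordance
  enrichment.py  per-category counts and normalised enrichment ratios
  annotate.py    transcript-genome mapping, triage, gap scan, hotspots, t-test
  simulate.py    deterministic synthetic-data generator with ground truth
  pipeline.py    orchestration and report writing
  cli.py         `pitkit` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
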