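"""Genome-annotation evaluation: transcript triage, gap scanning, hotspots.

Transcripts encoding proteins that match other insects but not the host's
own annotation are candidates for missing annotation.  Each is aligned to
the genome assembly and triaged:

* NO_MATCH          - no alignment passes the identity/coverage floor
* AMBIGUOUS         - two or more loci score within a margin of the best
                      (possible duplications or assembly errors; excluded)
* ALREADY_ANNOTATED - the best locus overlaps an annotated gene's exon
                      span on the same strand
* NEW_ANNOTATION    - a well-localised, unannotated locus: new annotation

The surrounding assembly quality is assessed by counting N characters
(sequencing gaps) in a window extending a flank (default 5 kb) on each side
of the alignment span, compared against an equal-sized, transcript-length
matched control sample of transcripts mapping to annotated genes.  Hotspots
of missing annotation are detected per chromosome (normalised ratio of
new-annotation-bearing supercontigs to mapped supercontigs) and per
cytological band (top 20% of bands by new-annotation count, requiring more
than two).

The built-in transcript-to-genome aligner is a seed-and-extend near-exact
spliced mapper (k-mer seeds on matching diagonals, greedy x-drop extension,
multi-exon chaining) adequate for low-divergence transcripts; externally
produced spliced alignments can be imported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

from Bio.Seq import Seq
from intervaltree import IntervalTree

CAT_NO_MATCH = "NO_MATCH"
CAT_ALREADY_ANNOTATED = "ALREADY_ANNOTATED"
CAT_AMBIGUOUS = "AMBIGUOUS"
CAT_NEW_ANNOTATION = "NEW_ANNOTATION"
TRIAGE_CATEGORIES = (CAT_NO_MATCH, CAT_ALREADY_ANNOTATED, CAT_AMBIGUOUS, CAT_NEW_ANNOTATION)

UNPLACED = "UNPLACED"

__all__ = [
    "GenomeAlignmentHit",
    "TriageParams",
    "TriageRecord",
    "GapScanRecord",
    "AnnotatedGene",
    "GenomeIndex",
    "align_transcripts",
    "triage",
    "gap_scan",
    "matched_control_sample",
    "chromosome_enrichment",
    "band_hotspots",
    "ttest_equal_var",
    "read_chromosome_map",
    "load_gff3_genes",
    "TRIAGE_CATEGORIES",
]


@dataclass(frozen=True)
class GenomeAlignmentHit:
    """A spliced alignment of one transcript to one supercontig."""

    transcript_id: str
    supercontig: str
    strand: str  # "+" or "-"
    blocks: tuple[tuple[int, int], ...]  # genomic intervals, 0-based half-open
    pct_identity: float
    transcript_coverage_pct: float
    score: float

    def __post_init__(self) -> None:
        blocks = tuple((int(a), int(b)) for a, b in self.blocks)
        if not blocks:
            raise ValueError("alignment with no blocks")
        for (a, b) in blocks:
            if b <= a:
                raise ValueError("empty alignment block")
        for (a, b), (c, d) in zip(blocks, blocks[1:]):
            if c < b:
                raise ValueError("alignment blocks overlap or are unordered")
        object.__setattr__(self, "blocks", blocks)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class TriageParams:
    min_identity_pct: float = 90.0
    min_coverage_pct: float = 50.0
    ambiguity_margin: float = 0.95  # fraction of best score

    def __post_init__(self) -> None:
        if not (0 < self.ambiguity_margin <= 1):
            raise ValueError("ambiguity_margin must be in (0,1]")


@dataclass(frozen=True)
class TriageRecord:
    transcript_id: str
    category: str
    best_hit: GenomeAlignmentHit | None
    n_loci: int

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.category!r}")
        if self.category == CAT_NO_MATCH and self.best_hit is not None:
            raise ValueError("NO_MATCH record with a best hit")
        if self.category == CAT_AMBIGUOUS and self.n_loci < 2:
            raise ValueError("AMBIGUOUS record with fewer than two loci")


@dataclass(frozen=True)
class GapScanRecord:
    transcript_id: str
    flank_nt: int
    n_count_in_window: int
    has_gap: bool
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def __post_init__(self) -> None:
        if self.has_gap != (self.n_count_in_window > 0):
            raise ValueError("has_gap inconsistent with N count")


@dataclass(frozen=True)
class AnnotatedGene:
    """A gene's exon span on the genome, for overlap triage."""

    gene_id: str
    supercontig: str
    strand: str
    start: int  # exon-span start, 0-based
    end: int  # exon-span end, half-open

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"malformed annotation interval for {self.gene_id}")


# ---------------------------------------------------------------------------
# Built-in near-exact spliced mapper


class GenomeIndex:
    """k-mer index of a genome, reusable across transcript alignments."""

    def __init__(self, genome: Mapping[str, str], k: int = 21):
        self.k = k
        self.genome = {cid: seq.upper() for cid, seq in genome.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((cid, i))


def _extend(q: str, g: str, qpos: int, gpos: int, direction: int, xdrop: int = 12):
    """Greedy x-drop extension; returns number of positions advanced."""
    best = 0
    score = 0
    best_len = 0
    length = 0
    while True:
        nq = qpos + direction * (length + 1)
        ng = gpos + direction * (length + 1)
        if direction > 0:
            if nq >= len(q) or ng >= len(g):
                break
            match = q[nq] == g[ng]
        else:
            if nq < 0 or ng < 0:
                break
            match = q[nq] == g[ng]
        score += 1 if match else -3
        length += 1
        if score > best:
            best, best_len = score, length
        if best - score > xdrop:
            break
    return best_len


def _align_orientation(
    q: str, index: GenomeIndex, seed_step: int
) -> list[tuple[str, list[tuple[int, int, int, int]]]]:
    """Collect diagonal seed clusters per contig.

    Returns per-contig chains of (t_start, t_end, g_start, g_end) blocks.
    """
    k = index.k
    hits: dict[tuple[str, int], list[int]] = {}
    positions = list(range(0, max(1, len(q) - k + 1), seed_step))
    if positions and positions[-1] != len(q) - k:
        positions.append(len(q) - k)
    for i in positions:
        for cid, gpos in index.index.get(q[i : i + k], ()):
            hits.setdefault((cid, gpos - i), []).append(i)
    # one cluster per (contig, diagonal)
    clusters: dict[str, list[tuple[int, int, int]]] = {}
    for (cid, diag), tpos in hits.items():
        t0, t1 = min(tpos), max(tpos) + k
        clusters.setdefault(cid, []).append((t0, t1, diag))
    chains = []
    for cid, cl in clusters.items():
        cl.sort()
        # merge clusters on near-identical diagonals (tiny indel tolerance)
        merged: list[list[int]] = []
        for t0, t1, diag in cl:
            if merged and abs(merged[-1][2] - diag) <= 3 and t0 <= merged[-1][1] + index.k:
                merged[-1][1] = max(merged[-1][1], t1)
            else:
                merged.append([t0, t1, diag])
        blocks = [(t0, t1, t0 + diag, t1 + diag) for t0, t1, diag in merged]
        chains.append((cid, blocks))
    return chains


def align_transcripts(
    transcripts: Sequence[tuple[str, str]],
    genome: Mapping[str, str] | GenomeIndex,
    k: int = 21,
    seed_step: int = 4,
    min_score: int = 40,
) -> dict[str, list[GenomeAlignmentHit]]:
    """Map transcripts to the genome with the built-in spliced mapper.

    Transcripts with no seed hits are reported with an empty hit list, not
    as an error.  Per transcript, each (contig, orientation) chain yields at
    most one hit; hits are sorted by score descending.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    results: dict[str, list[GenomeAlignmentHit]] = {}
    for tid, seq in transcripts:
        seq = seq.upper()
        hits: list[GenomeAlignmentHit] = []
        for strand, q in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
            for cid, blocks in _align_orientation(q, index, seed_step):
                g = index.genome[cid]
                # extend outer edges of the chain
                t0, t1, g0, g1 = blocks[0]
                left = _extend(q, g, t0, g0, -1)
                blocks[0] = (t0 - left, t1, g0 - left, g1)
                t0, t1, g0, g1 = blocks[-1]
                right = _extend(q, g, t1 - 1, g1 - 1, +1)
                blocks[-1] = (t0, t1 + right, g0, g1 + right)
                # close interior gaps between consecutive blocks
                closed = [blocks[0]]
                for nxt in blocks[1:]:
                    pt0, pt1, pg0, pg1 = closed[-1]
                    nt0, nt1, ng0, ng1 = nxt
                    if nt0 > pt1:  # unseeded transcript gap: extend toward each other
                        fwd = _extend(q, g, pt1 - 1, pg1 - 1, +1)
                        fwd = min(fwd, nt0 - pt1)
                        pt1 += fwd
                        pg1 += fwd
                        back = _extend(q, g, nt0, ng0, -1)
                        back = min(back, nt0 - pt1)
                        nt0 -= back
                        ng0 -= back
                        closed[-1] = (pt0, pt1, pg0, pg1)
                    closed.append((nt0, nt1, ng0, ng1))
                matches = 0
                aligned = 0
                gblocks = []
                for bt0, bt1, bg0, bg1 in closed:
                    bt0 = max(bt0, 0)
                    bg0 = max(bg0, 0)
                    n = min(bt1 - bt0, len(g) - bg0)
                    if n <= 0:
                        continue
                    seg_q = q[bt0 : bt0 + n]
                    seg_g = g[bg0 : bg0 + n]
                    matches += sum(1 for a, b in zip(seg_q, seg_g) if a == b)
                    aligned += n
                    gblocks.append((bg0, bg0 + n))
                if aligned == 0:
                    continue
                score = matches - 3 * (aligned - matches)
                if score < min_score:
                    continue
                gblocks.sort()
                # drop malformed overlapping chains (repeat-induced)
                ok = all(b[0] >= a[1] for a, b in zip(gblocks, gblocks[1:]))
                if not ok:
                    continue
                hits.append(
                    GenomeAlignmentHit(
                        transcript_id=tid,
                        supercontig=cid,
                        strand=strand,
                        blocks=tuple(gblocks),
                        pct_identity=100.0 * matches / aligned,
                        transcript_coverage_pct=100.0 * aligned / len(seq),
                        score=float(score),
                    )
                )
        hits.sort(key=lambda h: (-h.score, h.supercontig, h.span))
        results[tid] = hits
    return results


# ---------------------------------------------------------------------------
# Triage


def triage(
    hits_by_transcript: Mapping[str, Sequence[GenomeAlignmentHit]],
    annotations: Sequence[AnnotatedGene],
    params: TriageParams = TriageParams(),
) -> list[TriageRecord]:
    """Assign each transcript to exactly one annotation-status category."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in annotations:
        trees.setdefault((gene.supercontig, gene.strand), IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )
    records = []
    for tid in sorted(hits_by_transcript):
        hits = [
            h
            for h in hits_by_transcript[tid]
            if h.pct_identity >= params.min_identity_pct
            and h.transcript_coverage_pct >= params.min_coverage_pct
        ]
        if not hits:
            records.append(TriageRecord(tid, CAT_NO_MATCH, None, 0))
            continue
        best = max(hits, key=lambda h: h.score)
        n_loci = sum(1 for h in hits if h.score >= params.ambiguity_margin * best.score)
        if n_loci >= 2:
            records.append(TriageRecord(tid, CAT_AMBIGUOUS, best, n_loci))
            continue
        tree = trees.get((best.supercontig, best.strand))
        s, e = best.span
        if tree is not None and tree.overlap(s, e):
            records.append(TriageRecord(tid, CAT_ALREADY_ANNOTATED, best, 1))
        else:
            records.append(TriageRecord(tid, CAT_NEW_ANNOTATION, best, 1))
    return records


def gap_scan(
    genome: Mapping[str, str], hit: GenomeAlignmentHit, flank_nt: int = 5000
) -> GapScanRecord:
    """Count sequencing-gap Ns in the alignment span +/- a flank."""
    if hit.supercontig not in genome:
        raise KeyError(f"supercontig {hit.supercontig!r} absent from genome")
    seq = genome[hit.supercontig]
    s, e = hit.span
    lo = s - flank_nt
    hi = e + flank_nt
    truncated_up = lo < 0
    truncated_down = hi > len(seq)
    lo = max(lo, 0)
    hi = min(hi, len(seq))
    n_count = seq[lo:hi].upper().count("N")
    return GapScanRecord(
        transcript_id=hit.transcript_id,
        flank_nt=flank_nt,
        n_count_in_window=n_count,
        has_gap=n_count > 0,
        truncated_upstream=truncated_up,
        truncated_downstream=truncated_down,
    )


def matched_control_sample(
    new_set: Sequence[tuple[str, int]],
    pool: Sequence[tuple[str, int]],
    seed: int,
) -> list[str]:
    """Greedy nearest-transcript-length matching without replacement.

    ``new_set`` and ``pool`` are (id, transcript length) pairs; returns
    ``len(new_set)`` control ids from the pool.  Deterministic given the
    seed; ties in length distance are broken by a seeded shuffle.
    """
    if len(pool) < len(new_set):
        raise ValueError("control pool smaller than target set")
    rng = np.random.default_rng(seed)
    pool_items = list(pool)
    rng.shuffle(pool_items)
    available = list(pool_items)
    controls = []
    order = list(new_set)
    rng.shuffle(order)
    for _, length in order:
        best_i = min(range(len(available)), key=lambda i: abs(available[i][1] - length))
        controls.append(available.pop(best_i)[0])
    return sorted(controls)


def read_chromosome_map(path) -> dict[str, tuple[str, str]]:
    """TSV (supercontig, chromosome, band); unmapped contigs may be listed
    with chromosome UNPLACED or simply omitted."""
    import csv

    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sc = row["supercontig"]
            if sc in out:
                raise ValueError(f"supercontig {sc!r} listed twice in chromosome map")
            out[sc] = (row["chromosome"], row.get("band", ""))
    return out


def chromosome_enrichment(
    triage_records: Sequence[TriageRecord],
    chr_map: Mapping[str, tuple[str, str]],
):
    """Normalised ratio of new-annotation-bearing supercontigs per chromosome.

    raw_chr = (supercontigs on chr with >=1 NEW_ANNOTATION) / (mapped
    supercontigs on chr); the normalised ratio divides by the genome-wide
    raw ratio, so 1.0 means no enrichment.  A supercontig carrying several
    new annotations counts once.
    """
    import pandas as pd

    mapped_by_chr: dict[str, set[str]] = {}
    for sc, (chrom, _band) in chr_map.items():
        if chrom == UNPLACED:
            continue
        mapped_by_chr.setdefault(chrom, set()).add(sc)
    if not mapped_by_chr:
        raise ValueError("no mapped supercontigs in chromosome map")
    pit_contigs = {
        r.best_hit.supercontig
        for r in triage_records
        if r.category == CAT_NEW_ANNOTATION and r.best_hit is not None
    }
    total_mapped = sum(len(v) for v in mapped_by_chr.values())
    total_pit = sum(len(pit_contigs & v) for v in mapped_by_chr.values())
    global_ratio = total_pit / total_mapped
    rows = []
    for chrom in sorted(mapped_by_chr):
        mapped = mapped_by_chr[chrom]
        if not mapped:
            raise ValueError(f"chromosome {chrom} has zero mapped supercontigs")
        raw = len(pit_contigs & mapped) / len(mapped)
        rows.append(
            {
                "chromosome": chrom,
                "pit_supercontigs": len(pit_contigs & mapped),
                "mapped_supercontigs": len(mapped),
                "raw_ratio": raw,
                "normalized_ratio": raw / global_ratio if global_ratio > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def band_hotspots(
    triage_records: Sequence[TriageRecord],
    chr_map: Mapping[str, tuple[str, str]],
    top_fraction: float = 0.2,
    min_count: int = 2,
):
    """Flag cytological bands enriched for new annotation.

    Bands are ranked by new-annotation count (descending, ties by band
    name); the top ``ceil(top_fraction * n_bands)`` bands are flagged
    enriched iff their count is strictly greater than ``min_count``.  The
    ranking universe is every band holding at least one mapped supercontig.
    """
    import pandas as pd

    bands = sorted(
        {band for chrom, band in chr_map.values() if chrom != UNPLACED and band}
    )
    counts = {b: 0 for b in bands}
    for r in triage_records:
        if r.category != CAT_NEW_ANNOTATION or r.best_hit is None:
            continue
        entry = chr_map.get(r.best_hit.supercontig)
        if entry is None or entry[0] == UNPLACED:
            continue
        band = entry[1]
        if band in counts:
            counts[band] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_top = math.ceil(top_fraction * len(ranked)) if ranked else 0
    rows = []
    for rank, (band, count) in enumerate(ranked):
        rows.append(
            {
                "band": band,
                "new_annotation_count": count,
                "enriched": rank < n_top and count > min_count,
            }
        )
    return pd.DataFrame(rows)


def ttest_equal_var(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance (equal variance) two-tailed Student t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least two observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = _sstats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def load_gff3_genes(path) -> list[AnnotatedGene]:
    """Read gene exon spans from a GFF3 file (gene/mRNA/exon features).

    The exon span of a gene is the interval from its first to last exon;
    genes without exon children fall back to the gene interval itself.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = list(db.children(gene, featuretype="exon"))
        if exons:
            start = min(e.start for e in exons) - 1
            end = max(e.end for e in exons)
        else:
            start, end = gene.start - 1, gene.end
        genes.append(
            AnnotatedGene(
                gene_id=gene.id,
                supercontig=gene.seqid,
                strand=gene.strand,
                start=start,
                end=end,
            )
        )
    return genes
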