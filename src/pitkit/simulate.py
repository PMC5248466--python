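"""Deterministic synthetic fixtures for the PIT downstream pipeline.

The generator emits a complete toy study in the exact formats the analysis
modules consume: a genome of supercontigs partially mapped to chromosomes
and cytological bands, an annotation with a deliberate fraction of genes
omitted (the "new annotation" targets), transposable-element families
planted as diverged genomic copies with characteristic ORF architectures
(gag/pol for LTR retrotransposons, ORF1/ORF2 for non-LTR elements,
transposase for cut-and-paste DNA transposons), planted sequencing-gap
N runs, transcripts derived from the expressed loci with a small
substitution error rate, a peptide-evidence table (distinct peptides per
expressed ORF drawn from a zero-truncated Poisson), tiered reference
proteomes, two TE protein databases (a mosquito-curated one and a larger
"relabelled" one to exercise concordance analysis), and per-category genome
TE statistics.  A ground-truth object records every planted fact so that
parameter-recovery tests can compare the pipeline's output against what was
actually simulated.

Everything is driven by one integer seed through a single
``numpy.random.default_rng`` stream; the same seed reproduces byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .orfs import NaSeq, PeptideEvidence, six_frame_orfs, write_fasta, write_peptide_evidence
from .tecalls import TEEntry, write_te_fasta
from .enrichment import TEGenomeStats

AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = ["TEFamilySpec", "SynthConfig", "GroundTruth", "generate", "mutate_protein"]


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class TEFamilySpec:
    family_id: str
    te_class: str
    order: str
    clade: str
    orfs: tuple[tuple[str, int], ...]  # (orf_type, protein length)
    copies: int
    divergence: float  # per-site amino-acid divergence of each genomic copy
    expr_prob: float  # per-copy, per-ORF probability of protein expression
    copy_number_known: bool = True


def _default_families() -> tuple[TEFamilySpec, ...]:
    # Equal genomic representation for LTR vs non-LTR (same copy counts and
    # ORF lengths) with a 4:1 planted expression bias toward LTR elements.
    return (
        TEFamilySpec("Ele7", "I", "LTR", "Ty3/gypsy", (("GAG", 150), ("POL", 250)), 25, 0.2, 1.0),
        TEFamilySpec("Ele150", "I", "LTR", "Ty1/copia", (("GAG", 150), ("POL", 250)), 25, 0.2, 1.0),
        TEFamilySpec("Jock1", "I", "NON_LTR", "Jockey", (("ORF1", 150), ("ORF2", 250)), 25, 0.2, 0.25),
        TEFamilySpec("R4e", "I", "NON_LTR", "R4", (("ORF1", 150), ("ORF2", 250)), 25, 0.2, 0.25),
        TEFamilySpec("Mar5", "II", "DNA_TIR", "IS630-Tc1-mariner", (("TRANSPOSASE", 200),), 20, 0.2, 0.5),
        TEFamilySpec("Mut2", "II", "DNA_TIR", "Mutator", (("TRANSPOSASE", 180),), 5, 0.2, 0.4, False),
        # database-only families: known from other mosquito species, with no
        # copies in this genome (curated TE databases are not genome-specific)
        TEFamilySpec("EleQ", "I", "LTR", "Ty3/gypsy", (("GAG", 170),), 0, 0.2, 0.0),
        TEFamilySpec("JockQ", "I", "NON_LTR", "Jockey", (("ORF1", 170),), 0, 0.2, 0.0),
    )


_BANDS = {
    "1": ("1p1", "1p2", "1p3", "1q1", "1q4"),
    "2": ("2p1", "2p2", "2p4", "2q1", "2q2"),
    "3": ("3p1", "3p2", "3q1", "3q2", "3q3"),
}


@dataclass(frozen=True)
class SynthConfig:
    """Default values define the package's reference study scenario."""

    seed: int
    n_supercontigs: int = 40
    mapped_fraction: float = 0.7
    n_host_genes: int = 50
    n_culex_only: int = 5  # annotated genes present only in the Culex tier
    n_novel: int = 20  # unannotated genes -> planted new annotation
    n_duplicated: int = 3  # unannotated genes planted at two loci
    n_unplaced: int = 4  # genes whose locus is missing from the assembly
    n_decoys: int = 5  # expressed proteins absent from every database
    hotspot_plan: tuple[tuple[str, int], ...] = (
        ("1p3", 5),
        ("1q4", 4),
        ("2p4", 3),
        ("1p1", 2),
        ("2q1", 2),
        ("3q2", 2),
    )
    te_families: tuple[TEFamilySpec, ...] = field(default_factory=_default_families)
    n_gap_genes: int = 7  # novel genes flanked by a planted N run
    gap_run_range: tuple[int, int] = (80, 300)
    transcript_error_rate: float = 0.0005
    peptide_lambda: float = 3.0
    peptide_len_range: tuple[int, int] = (8, 25)
    spurious_fragment_fractions: tuple[float, ...] = (0.20, 0.30, 0.42)
    spurious_fragment_divergence: float = 0.30
    recent_copy_fraction: float = 0.12  # copies nearly identical to consensus
    culex_divergence: float = 0.25
    drosophila_divergence: float = 0.40
    repbase_relabel_fraction: float = 0.4
    n_qc_ambiguous: int = 2  # planted promiscuous single-peptide TE calls


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    genes: pd.DataFrame  # one row per planted gene locus/transcript
    te_expressed: pd.DataFrame  # one row per expressed TE ORF transcript
    transcripts: pd.DataFrame  # transcript -> expected cascade category etc.
    planted_hotspots: tuple[str, ...]
    band_counts: dict[str, int]
    chr_map: dict[str, tuple[str, str]]
    files: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "te_expressed": self.te_expressed.to_dict(orient="records"),
            "transcripts": self.transcripts.to_dict(orient="records"),
            "planted_hotspots": list(self.planted_hotspots),
            "band_counts": self.band_counts,
            "chr_map": {k: list(v) for k, v in self.chr_map.items()},
            "files": {k: Path(v).name for k, v in self.files.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence-level helpers

_BLOSUM = substitution_matrices.load("BLOSUM62")
_NEIGHBOR_P = {}
for _a in AA20:
    _w = np.array([2.0 ** _BLOSUM[_a, _b] if _b != _a else 0.0 for _b in AA20])
    _NEIGHBOR_P[_a] = _w / _w.sum()

_CODONS = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


def mutate_protein(protein: str, divergence: float, seed_or_rng) -> str:
    """Per-site substitution with probability ``divergence``; replacement
    residues follow a BLOSUM62-weighted neighbour distribution, so the
    expected identity to the input is 100*(1 - divergence)."""
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0,1)")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = []
    for a in protein:
        if a in _NEIGHBOR_P and rng.random() < divergence:
            out.append(rng.choice(list(AA20), p=_NEIGHBOR_P[a]))
        else:
            out.append(a)
    return "".join(out)


def _random_protein(rng, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def _reverse_translate(rng, protein: str) -> str:
    return "".join(rng.choice(_CODONS[a]) for a in protein)


def _random_nt(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _with_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != c])
    return "".join(chars)


def _ztp(rng, lam: float) -> int:
    """Zero-truncated Poisson draw."""
    while True:
        k = rng.poisson(lam)
        if k > 0:
            return int(k)


# ---------------------------------------------------------------------------
# Generator internals


@dataclass
class _GeneSpec:
    gene_id: str
    role: str  # host | spurious_host | culex_only | novel | duplicated | unplaced | decoy
    protein: str
    transcript: str  # error-free transcript (exon concatenation)
    cds_start: int  # CDS start within the transcript
    cds_end: int
    exon_split: int | None  # transcript offset where exon2 begins, or None
    intron_len: int
    strand: str
    annotated: bool
    band: str | None = None
    with_gap: bool = False


def _make_gene(rng, gene_id, role, *, annotated, strand=None, band=None, protein=None):
    plen = int(rng.integers(150, 401))
    if protein is None:
        protein = _random_protein(rng, plen)
    cds = _reverse_translate(rng, protein) + rng.choice(["TAA", "TAG", "TGA"])
    utr5 = _random_nt(rng, int(rng.integers(30, 81)))
    utr3 = _random_nt(rng, int(rng.integers(30, 81)))
    transcript = utr5 + cds + utr3
    two_exon = rng.random() < 0.35
    exon_split = int(rng.integers(200, len(transcript) - 200)) if two_exon else None
    intron_len = int(rng.integers(300, 801)) if two_exon else 0
    if strand is None:
        strand = "-" if rng.random() < 0.3 else "+"
    return _GeneSpec(
        gene_id=gene_id,
        role=role,
        protein=protein,
        transcript=transcript,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds) - 3,
        exon_split=exon_split,
        intron_len=intron_len,
        strand=strand,
        annotated=annotated,
        band=band,
    )


def _gene_genomic_block(rng, gene: _GeneSpec):
    """Genomic sequence of a gene plus exon intervals relative to the block."""
    t = gene.transcript
    if gene.exon_split is None:
        plus_seq = t
        exons_plus = [(0, len(t))]
    else:
        intron = _random_nt(rng, gene.intron_len)
        # avoid accidental canonical-looking 21-mer reuse: intron is random
        plus_seq = t[: gene.exon_split] + intron + t[gene.exon_split :]
        exons_plus = [
            (0, gene.exon_split),
            (gene.exon_split + gene.intron_len, len(plus_seq)),
        ]
    if gene.strand == "+":
        return plus_seq, exons_plus
    rc = str(Seq(plus_seq).reverse_complement())
    L = len(plus_seq)
    exons = sorted((L - e, L - s) for s, e in exons_plus)
    return rc, exons


def generate(config: SynthConfig, out_dir) -> GroundTruth:
    """Emit the full fixture bundle into ``out_dir`` and return ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- supercontigs and chromosome map ------------------------------------
    contig_ids = [f"supercont{i + 1:03d}" for i in range(config.n_supercontigs)]
    n_mapped = int(round(config.mapped_fraction * config.n_supercontigs))
    band_cycle = [b for bands in _BANDS.values() for b in bands]
    chr_map: dict[str, tuple[str, str]] = {}
    band_contigs: dict[str, list[str]] = {b: [] for b in band_cycle}
    for i, cid in enumerate(contig_ids):
        if i < n_mapped:
            band = band_cycle[i % len(band_cycle)]
            chrom = band[0]
            chr_map[cid] = (chrom, band)
            band_contigs[band].append(cid)
        else:
            chr_map[cid] = ("UNPLACED", "")
    unmapped = [c for c in contig_ids if chr_map[c][0] == "UNPLACED"]

    # --- gene roster ---------------------------------------------------------
    genes: list[_GeneSpec] = []
    n_spurious = len(config.spurious_fragment_fractions)

    # TE consensus proteins (needed early for the spurious host fragments)
    consensus: dict[tuple[str, str], str] = {}
    for fam in config.te_families:
        for orf_type, plen in fam.orfs:
            consensus[(fam.family_id, orf_type)] = _random_protein(rng, plen)

    for i in range(config.n_host_genes):
        gid = f"AAEL{i + 1:06d}"
        if i < n_spurious:
            frac = config.spurious_fragment_fractions[i]
            plen = int(rng.integers(280, 320))
            base = _random_protein(rng, plen)
            # fragments come from database-only (never-expressed) families
            # where available, so the planted background homology cannot
            # cross-talk with expressed TE queries in the cascade
            donor_pool = [f for f in config.te_families if f.expr_prob == 0 and f.orfs] or list(
                config.te_families
            )
            donor_fam = donor_pool[i % len(donor_pool)]
            donor = consensus[(donor_fam.family_id, donor_fam.orfs[0][0])]
            frag_len = min(int(round(frac * plen)), len(donor))
            frag_src = int(rng.integers(0, len(donor) - frag_len + 1))
            # moderately diverged: well above the 30% identity floor so the
            # spurious hit is real, crisp enough that the local alignment
            # stays confined to the planted span
            frag = mutate_protein(
                donor[frag_src : frag_src + frag_len], config.spurious_fragment_divergence, rng
            )
            ins = int(rng.integers(20, plen - frag_len - 10))
            protein = base[:ins] + frag + base[ins + frag_len :]
            genes.append(_make_gene(rng, gid, "spurious_host", annotated=True, protein=protein))
        else:
            genes.append(_make_gene(rng, gid, "host", annotated=True))
    for i in range(config.n_culex_only):
        genes.append(_make_gene(rng, f"CULONLY{i + 1:04d}", "culex_only", annotated=True))
    novel_slots = [(band, k) for band, count in config.hotspot_plan for k in range(count)]
    band_counts = {band: count for band, count in config.hotspot_plan}
    for i in range(config.n_novel):
        band = novel_slots[i][0] if i < len(novel_slots) else None
        g = _make_gene(rng, f"NOVEL{i + 1:04d}", "novel", annotated=False, band=band)
        if i < config.n_gap_genes:
            g.with_gap = True
        genes.append(g)
    for i in range(config.n_duplicated):
        genes.append(_make_gene(rng, f"DUP{i + 1:04d}", "duplicated", annotated=False))
    for i in range(config.n_unplaced):
        genes.append(_make_gene(rng, f"LOST{i + 1:04d}", "unplaced", annotated=False))
    for i in range(config.n_decoys):
        genes.append(_make_gene(rng, f"DECOY{i + 1:04d}", "decoy", annotated=False))

    # --- TE copies -----------------------------------------------------------
    te_copy_rows = []
    te_transcripts = []  # (transcript_id, seq-without-errors, meta)
    te_blocks = []  # (copy_id, family, nt block to place)
    for fam in config.te_families:
        for c in range(fam.copies):
            copy_id = f"{fam.family_id}_c{c + 1:02d}"
            # a fraction of copies are recent insertions, near-identical to
            # the consensus (but not byte-identical, so their proteins stay
            # distinguishable by peptides): these yield the "exact match" tier
            copy_div = (
                float(rng.uniform(0.005, 0.02))
                if rng.random() < config.recent_copy_fraction
                else fam.divergence
            )
            parts = []
            orf_cds = {}
            for orf_type, _plen in fam.orfs:
                copy_protein = mutate_protein(consensus[(fam.family_id, orf_type)], copy_div, rng)
                cds = _reverse_translate(rng, copy_protein) + "TAA"
                orf_cds[orf_type] = (copy_protein, cds)
                parts.append(cds)
                parts.append(_random_nt(rng, int(rng.integers(40, 121))))
            block = _random_nt(rng, 60) + "".join(parts)
            te_blocks.append((copy_id, fam, block))
            for orf_type, _plen in fam.orfs:
                if rng.random() < fam.expr_prob:
                    copy_protein, cds = orf_cds[orf_type]
                    utr5 = _random_nt(rng, int(rng.integers(30, 81)))
                    utr3 = _random_nt(rng, int(rng.integers(30, 81)))
                    tid = f"TRINITY_TE_{copy_id}_{orf_type}"
                    te_transcripts.append(
                        (
                            tid,
                            utr5 + cds + utr3,
                            {
                                "family": fam.family_id,
                                "order": fam.order,
                                "clade": fam.clade,
                                "orf_type": orf_type,
                                "copy_id": copy_id,
                                "divergence": copy_div,
                                "cds_start": len(utr5),
                            },
                        )
                    )
            te_copy_rows.append(
                {"copy_id": copy_id, "family": fam.family_id, "order": fam.order, "len": len(block)}
            )

    # --- assign features to contigs and assemble the genome -----------------
    placements: dict[str, list] = {cid: [] for cid in contig_ids}

    def _pick_contig(candidates):
        return candidates[int(rng.integers(0, len(candidates)))]

    gene_loci: dict[str, list[tuple[str, int, int, list[tuple[int, int]]]]] = {}
    for g in genes:
        if g.role in ("unplaced", "decoy"):
            continue
        if g.role == "novel" and g.band is not None:
            cands = band_contigs[g.band]
        elif g.role == "novel":
            cands = unmapped
        else:
            cands = contig_ids
        n_loci = 2 if g.role == "duplicated" else 1
        if n_loci == 2:
            c1 = _pick_contig(contig_ids)
            c2 = _pick_contig([c for c in contig_ids if c != c1])
            chosen = [c1, c2]
        else:
            chosen = [_pick_contig(cands)]
        for cid in chosen:
            placements[cid].append(("gene", g))
    for copy_id, fam, block in te_blocks:
        placements[_pick_contig(contig_ids)].append(("te", (copy_id, fam, block)))

    genome: dict[str, str] = {}
    gff_rows: list[str] = []
    for cid in contig_ids:
        parts: list[str] = []
        pos = 0

        def _filler():
            nonlocal pos
            f = _random_nt(rng, int(rng.integers(5500, 8001)))
            parts.append(f)
            pos += len(f)

        for kind, payload in placements[cid]:
            _filler()
            if kind == "gene":
                g = payload
                block, exons = _gene_genomic_block(rng, g)
                start = pos
                parts.append(block)
                pos += len(block)
                gene_loci.setdefault(g.gene_id, []).append(
                    (cid, start, start + len(block), [(start + s, start + e) for s, e in exons])
                )
                if g.annotated:
                    gexons = [(start + s, start + e) for s, e in exons]
                    gff_rows.append(
                        f"{cid}\tpitkit_sim\tgene\t{start + 1}\t{start + len(block)}\t.\t{g.strand}\t.\tID={g.gene_id}"
                    )
                    gff_rows.append(
                        f"{cid}\tpitkit_sim\tmRNA\t{start + 1}\t{start + len(block)}\t.\t{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}"
                    )
                    for k, (es, ee) in enumerate(gexons, 1):
                        gff_rows.append(
                            f"{cid}\tpitkit_sim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\tID={g.gene_id}.e{k};Parent={g.gene_id}.t1"
                        )
                if kind == "gene" and g.role == "novel" and g.with_gap:
                    spacer = _random_nt(rng, int(rng.integers(1500, 3501)))
                    run = "N" * int(rng.integers(*config.gap_run_range))
                    parts.append(spacer + run)
                    pos += len(spacer) + len(run)
            else:
                copy_id, fam, block = payload
                parts.append(block)
                pos += len(block)
        _filler()
        genome[cid] = "".join(parts)

    # --- transcripts with errors --------------------------------------------
    transcripts: list[tuple[str, str]] = []
    tx_meta: dict[str, dict] = {}
    for g in genes:
        tid = f"TRINITY_{g.gene_id}"
        seq = _with_errors(rng, g.transcript, config.transcript_error_rate)
        transcripts.append((tid, seq))
        tx_meta[tid] = {"kind": "gene", "gene": g}
    for tid, seq, meta in te_transcripts:
        seq = _with_errors(rng, seq, config.transcript_error_rate)
        transcripts.append((tid, seq))
        tx_meta[tid] = {"kind": "te", "meta": meta}

    # --- ORF extraction and recovered main ORFs -----------------------------
    orf_records = []
    main_orf: dict[str, object] = {}
    for tid, seq in transcripts:
        recs = six_frame_orfs(NaSeq(tid, seq))
        orf_records.extend(recs)
        info = tx_meta[tid]
        cds_start = (
            info["gene"].cds_start if info["kind"] == "gene" else info["meta"]["cds_start"]
        )
        cds_len = (
            3 * len(info["gene"].protein)
            if info["kind"] == "gene"
            else 3 * len(_find_te_protein(info["meta"], consensus))
        )
        best, best_ov = None, 0
        for r in recs:
            if r.frame <= 0:
                continue
            ov = max(0, min(r.end, cds_start + cds_len) - max(r.start, cds_start))
            if ov > best_ov:
                best, best_ov = r, ov
        if best is not None and best_ov >= 0.5 * cds_len:
            main_orf[tid] = best

    # --- peptide evidence ----------------------------------------------------
    protein_of = {r.orf_id: r.protein for r in orf_records}
    all_orf_items = sorted(protein_of.items())
    evidence: dict[str, set[str]] = {}
    qc_planted: list[str] = []
    expressed = [(tid, main_orf[tid]) for tid, _ in transcripts if tid in main_orf]

    def _matching_orfs(peptide: str) -> set[str]:
        return {oid for oid, prot in all_orf_items if peptide in prot}

    ltr_candidates = [
        tid
        for tid, _ in expressed
        if tx_meta[tid]["kind"] == "te" and tx_meta[tid]["meta"]["order"] == "LTR"
    ]
    tir_candidates = [
        tid
        for tid, _ in expressed
        if tx_meta[tid]["kind"] == "te" and tx_meta[tid]["meta"]["order"] == "DNA_TIR"
    ]

    lo, hi = config.peptide_len_range

    def _draw_peptide(prot: str) -> str:
        plen = min(int(rng.integers(lo, hi + 1)), len(prot))
        start = int(rng.integers(0, len(prot) - plen + 1))
        return prot[start : start + plen]

    own_peptides: dict[str, list[str]] = {}
    for tid, orf in expressed:
        peps = []
        for _ in range(_ztp(rng, config.peptide_lambda)):
            pep = _draw_peptide(orf.protein)
            if len(pep) >= 6:
                peps.append(pep)
                evidence.setdefault(pep, set()).update(_matching_orfs(pep) | {orf.orf_id})
        own_peptides[tid] = peps

    # Plant promiscuous single-peptide TE identifications: replace a target
    # ORF's peptides with a single peptide whose match set also covers a
    # different-order TE ORF (modelling peptide-to-protein ambiguity as the
    # upstream search engine reports it).  Candidates whose protein is still
    # matched by someone else's peptide are skipped so the planted group is
    # genuinely single-peptide.
    if tir_candidates:
        drawn_by: dict[str, int] = {}
        for peps in own_peptides.values():
            for pep in peps:
                drawn_by[pep] = drawn_by.get(pep, 0) + 1
        for tid in ltr_candidates:
            if len(qc_planted) >= config.n_qc_ambiguous:
                break
            orf = main_orf[tid]
            own = set(own_peptides[tid])
            colliders = [
                pep
                for pep in evidence
                if pep in orf.protein
                and (pep not in own or drawn_by.get(pep, 0) > own_peptides[tid].count(pep))
            ]
            if colliders:
                continue  # another ORF's peptide matches this protein: not plantable
            for pep in own_peptides[tid]:
                ids = evidence.get(pep)
                if ids is None:
                    continue
                ids.discard(orf.orf_id)
                if not ids:
                    del evidence[pep]
            pep = _draw_peptide(orf.protein)
            partner = main_orf[tir_candidates[int(rng.integers(0, len(tir_candidates)))]]
            evidence.setdefault(pep, set()).update(
                _matching_orfs(pep) | {orf.orf_id, partner.orf_id}
            )
            qc_planted.append(tid)

    evidence_records = [
        PeptideEvidence(p, frozenset(ids)) for p, ids in sorted(evidence.items())
    ]

    # --- tier databases -------------------------------------------------------
    aedes_db = [(g.gene_id, g.protein) for g in genes if g.role in ("host", "spurious_host")]
    culex_db = [
        (f"CPIJ_{g.gene_id}", mutate_protein(g.protein, config.culex_divergence, rng))
        for g in genes
        if g.role in ("host", "spurious_host", "culex_only", "novel", "duplicated", "unplaced")
    ]
    dros_db = [
        (f"FB_{g.gene_id}", mutate_protein(g.protein, config.drosophila_divergence, rng))
        for g in genes
        if g.role == "host"
    ][: max(5, config.n_host_genes // 2)]

    # --- TE databases ---------------------------------------------------------
    tefam_entries = []
    for fam in config.te_families:
        for j, (orf_type, _plen) in enumerate(fam.orfs):
            tefam_entries.append(
                TEEntry(
                    te_id=f"TF{len(tefam_entries) + 1:06d}_{fam.family_id}_{orf_type.lower()}",
                    source_db="TEFAM",
                    te_class=fam.te_class,
                    order=fam.order,
                    clade=fam.clade,
                    orf_type=orf_type,
                    protein=consensus[(fam.family_id, orf_type)],
                )
            )
    repbase_entries = []
    n_relabel = int(round(config.repbase_relabel_fraction * len(tefam_entries)))
    relabel_idx = set(
        rng.choice(len(tefam_entries), size=n_relabel, replace=False).tolist()
    )
    for i, e in enumerate(tefam_entries):
        order, clade, orf_type, te_class = e.order, e.clade, e.orf_type, e.te_class
        if i in relabel_idx:
            clade = f"RB-{clade}"
            if i % 2 == 0:  # half of the relabelled entries also change order
                if order != "DNA_TIR":
                    order, orf_type, te_class = "DNA_TIR", "TRANSPOSASE", "II"
                else:
                    order, orf_type, te_class = "LTR", "POL", "I"
        repbase_entries.append(
            TEEntry(
                te_id=f"RB{i + 1:06d}",
                source_db="REPBASE",
                te_class=te_class,
                order=order,
                clade=clade,
                orf_type=orf_type,
                protein=mutate_protein(e.protein, 0.05, rng),
            )
        )

    # --- genome TE stats -------------------------------------------------------
    genome_bp = sum(len(s) for s in genome.values())
    stats_rows: dict[str, dict] = {}
    for fam in config.te_families:
        fam_bp = sum(r["len"] for r in te_copy_rows if r["family"] == fam.family_id)
        for cat in (fam.order, fam.clade):
            row = stats_rows.setdefault(
                cat, {"genome_pct": 0.0, "copy_number": 0, "db_entries": 0, "known": True}
            )
            row["genome_pct"] += 100.0 * fam_bp / genome_bp
            row["copy_number"] += fam.copies
            row["db_entries"] += len(fam.orfs)
            if not fam.copy_number_known and cat == fam.clade:
                row["known"] = False
    stats = TEGenomeStats(
        per_category={
            cat: {
                "genome_pct": r["genome_pct"],
                "copy_number": r["copy_number"] if r["known"] else None,
                "db_entries": r["db_entries"],
            }
            for cat, r in stats_rows.items()
        }
    )

    # --- write files -----------------------------------------------------------
    files = {}

    def _path(name):
        files[name.split(".")[0]] = str(out / name)
        return out / name

    write_fasta(sorted(genome.items()), _path("genome.fasta"))
    with open(_path("annotation.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(gff_rows) + "\n")
    with open(_path("chromosome_map.tsv"), "w") as fh:
        fh.write("supercontig\tchromosome\tband\n")
        for cid in contig_ids:
            chrom, band = chr_map[cid]
            fh.write(f"{cid}\t{chrom}\t{band}\n")
    write_fasta(transcripts, _path("transcripts.fasta"))
    write_peptide_evidence(evidence_records, _path("peptides.tsv"))
    write_fasta(aedes_db, _path("tier_aedes.fasta"))
    write_fasta(culex_db, _path("tier_culex.fasta"))
    write_fasta(dros_db, _path("tier_drosophila.fasta"))
    write_te_fasta(tefam_entries, _path("te_tefam.fasta"))
    write_te_fasta(repbase_entries, _path("te_repbase.fasta"))
    stats.to_tsv(_path("te_genome_stats.tsv"))

    # --- ground truth -----------------------------------------------------------
    gene_rows = []
    expected_triage = {
        "novel": "NEW_ANNOTATION",
        "duplicated": "AMBIGUOUS",
        "unplaced": "NO_MATCH",
        "culex_only": "ALREADY_ANNOTATED",
    }
    for g in genes:
        loci = gene_loci.get(g.gene_id, [])
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "role": g.role,
                "transcript_id": f"TRINITY_{g.gene_id}",
                "annotated": g.annotated,
                "band": g.band or "",
                "with_gap": g.with_gap,
                "strand": g.strand,
                "n_loci": len(loci),
                "contig": loci[0][0] if loci else "",
                "recovered": f"TRINITY_{g.gene_id}" in main_orf,
                "expected_triage": expected_triage.get(g.role, ""),
            }
        )
    te_rows = []
    for tid, _seq, meta in te_transcripts:
        te_rows.append(
            {
                "transcript_id": tid,
                "family": meta["family"],
                "order": meta["order"],
                "clade": meta["clade"],
                "orf_type": meta["orf_type"],
                "divergence": meta["divergence"],
                "recovered": tid in main_orf,
                "qc_planted": tid in qc_planted,
            }
        )
    tx_rows = []
    for tid, _seq in transcripts:
        info = tx_meta[tid]
        if info["kind"] == "gene":
            role = info["gene"].role
            cat = (
                "AEDES"
                if role in ("host", "spurious_host")
                else "NON_AEDES_INSECT"
                if role in ("culex_only", "novel", "duplicated", "unplaced")
                else "NON_INSECT"
            )
        else:
            cat = "NON_INSECT"
        tx_rows.append(
            {
                "transcript_id": tid,
                "expected_category": cat,
                "recovered": tid in main_orf,
                "main_orf_id": main_orf[tid].orf_id if tid in main_orf else "",
            }
        )
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        te_expressed=pd.DataFrame(te_rows),
        transcripts=pd.DataFrame(tx_rows),
        planted_hotspots=tuple(
            band for band, count in config.hotspot_plan if count > 2
        ),
        band_counts=band_counts,
        chr_map=chr_map,
        files=files,
    )
    truth.to_json(out / "ground_truth.json")
    files["ground_truth"] = str(out / "ground_truth.json")
    return truth


def _find_te_protein(meta: Mapping, consensus: Mapping) -> str:
    return consensus[(meta["family"], meta["orf_type"])]


def make_calibration_fixture(
    seed: int,
    n_target: int = 50,
    te_fraction: float = 0.8,
    n_background: int = 60,
    spurious_fractions: tuple[float, ...] = (0.20, 0.30, 0.42),
    te_divergence: float = 0.2,
    fragment_divergence: float = 0.30,
):
    """A compact target/background/database trio for threshold calibration.

    The target set holds ``te_fraction`` full-length diverged TE proteins
    (the rest are unrelated); the background set holds host-like proteins of
    which the first few carry short embedded TE fragments whose coverage
    fractions are given by ``spurious_fractions`` - deeply diverged but
    still well above the identity floor, producing the short-span spurious
    matches whose collapse defines the coverage knee.

    Returns ``(target_queries, background_queries, te_db)``.
    """
    rng = np.random.default_rng(seed)
    fams = [
        ("CalEle1", "LTR", "Ty3/gypsy", "GAG", 160),
        ("CalEle1", "LTR", "Ty3/gypsy", "POL", 260),
        ("CalEle2", "NON_LTR", "Jockey", "ORF1", 160),
        ("CalEle2", "NON_LTR", "Jockey", "ORF2", 260),
    ]
    te_db = []
    consensus = []
    for i, (fam, order, clade, orf, plen) in enumerate(fams):
        prot = _random_protein(rng, plen)
        consensus.append(prot)
        te_db.append(
            TEEntry(
                te_id=f"CAL{i + 1:03d}",
                source_db="TEFAM",
                te_class="I",
                order=order,
                clade=clade,
                orf_type=orf,
                protein=prot,
            )
        )
    n_te = int(round(te_fraction * n_target))
    target = []
    for i in range(n_target):
        if i < n_te:
            base = consensus[i % len(consensus)]
            target.append((f"tgt{i + 1:03d}", mutate_protein(base, te_divergence, rng)))
        else:
            target.append((f"tgt{i + 1:03d}", _random_protein(rng, int(rng.integers(150, 301)))))
    background = []
    for i in range(n_background):
        plen = int(rng.integers(280, 320))
        prot = _random_protein(rng, plen)
        if i < len(spurious_fractions):
            frac = spurious_fractions[i]
            donor = consensus[i % len(consensus)]
            frag_len = min(int(round(frac * plen)), len(donor))
            src = int(rng.integers(0, len(donor) - frag_len + 1))
            frag = mutate_protein(donor[src : src + frag_len], fragment_divergence, rng)
            ins = int(rng.integers(10, plen - frag_len - 5))
            prot = prot[:ins] + frag + prot[ins + frag_len :]
        background.append((f"bg{i + 1:03d}", prot))
    return target, background, te_db
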