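"""End-to-end orchestration of the PIT downstream analysis.

Stages: six-frame ORF extraction -> peptide grouping -> tiered homology
cascade -> TE calling against one or two databases (with calibration curves
and single-peptide QC) -> enrichment normalisation -> genome-annotation
evaluation (triage, gap scan with matched controls, chromosome/band
hotspots).  All stage outputs are written as TSV/JSON tables plus a run
manifest echoing every parameter actually applied; reruns with identical
inputs and seed produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, cascade as _cascade, enrichment as _enrich, orfs as _orfs, tecalls as _te
from .align import DEFAULT_SCHEME, ScoringScheme
from .annotate import (
    GenomeIndex,
    TriageParams,
    align_transcripts,
    band_hotspots,
    chromosome_enrichment,
    gap_scan,
    load_gff3_genes,
    matched_control_sample,
    read_chromosome_map,
    triage,
    ttest_equal_var,
)
from .cascade import (
    CascadeParams,
    ReferenceTier,
    classify_all,
    partition_summary,
    TIER_AEDES,
    TIER_CULEX,
    TIER_DROSOPHILA,
)
from .enrichment import TEGenomeStats, count_calls, orf_breakdown, relative_enrichment
from .orfs import group_peptides, read_fasta, read_peptide_evidence, six_frame_orfs
from .tecalls import (
    TECallParams,
    call_tes,
    coverage_calibration,
    db_concordance,
    identity_calibration,
    qc_single_peptide,
    read_te_fasta,
    select_coverage_threshold,
    _top_hits,
)

log = logging.getLogger("pitkit.pipeline")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Paths to every input plus the thresholds of each stage."""

    transcripts: str
    peptides: str
    tier_aedes: str
    tier_culex: str
    tier_drosophila: str
    te_primary: str  # TEfam-like database
    genome: str
    annotation: str
    chromosome_map: str
    te_genome_stats: str
    output_dir: str
    te_secondary: str | None = None  # RepBase-like database
    seed: int = 0
    min_orf_nt: int = 200
    min_peptides: int = 1
    cascade: CascadeParams = field(default_factory=CascadeParams)
    te_params: TECallParams = field(default_factory=TECallParams)
    triage_params: TriageParams = field(default_factory=TriageParams)
    flank_nt: int = 5000
    enrichment_reference: str = "LTR"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (
            ("cascade", CascadeParams),
            ("te_params", TECallParams),
            ("triage_params", TriageParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "transcripts",
            "peptides",
            "tier_aedes",
            "tier_culex",
            "tier_drosophila",
            "te_primary",
            "genome",
            "annotation",
            "chromosome_map",
            "te_genome_stats",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.te_secondary and not Path(self.te_secondary).exists():
            raise FileNotFoundError(f"te_secondary: {self.te_secondary}")


@dataclass
class ReportBundle:
    partition: dict[int, pd.DataFrame]  # min_peptides -> table
    cascade_results: list
    groups: list
    orf_count: int
    te_calls: list
    te_calls_secondary: list
    te_calls_combined: list
    background_calls_primary: list
    background_calls_combined: list
    calibration: dict[str, object]
    selected_coverage: float
    concordance: dict
    enrichment_tables: list
    orf_matrix: pd.DataFrame
    triage_records: list
    triage_counts: dict[str, int]
    gap_new: pd.DataFrame
    gap_control: pd.DataFrame
    gap_ttest: tuple[float, float] | None
    chromosome_table: pd.DataFrame
    band_table: pd.DataFrame
    manifest: dict


def _stage(name: str, **counts) -> None:
    log.info("stage %s: %s", name, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: RunConfig, scheme: ScoringScheme = DEFAULT_SCHEME) -> ReportBundle:
    config.validate()

    # -- ORF extraction ------------------------------------------------------
    transcripts = read_fasta(config.transcripts)
    orf_records = []
    for t in transcripts:
        orf_records.extend(six_frame_orfs(t, min_nt=config.min_orf_nt))
    protein_of = {r.orf_id: r.protein for r in orf_records}
    _stage("orfs", transcripts=len(transcripts), orfs=len(orf_records))

    # -- grouping ------------------------------------------------------------
    evidence = read_peptide_evidence(config.peptides)
    groups = group_peptides(evidence, orf_records)
    # one representative query per group: its longest member ORF
    representatives = []
    for g in groups:
        rep = max(g.orf_ids, key=lambda oid: (len(protein_of[oid]), oid))
        representatives.append((g.group_id, protein_of[rep]))
    _stage("groups", peptides=len(evidence), groups=len(groups))

    # -- cascade -------------------------------------------------------------
    tiers = [
        ReferenceTier(TIER_AEDES, [(s.id, s.sequence) for s in _read_protein_fasta(config.tier_aedes)]),
        ReferenceTier(TIER_CULEX, [(s.id, s.sequence) for s in _read_protein_fasta(config.tier_culex)]),
        ReferenceTier(
            TIER_DROSOPHILA, [(s.id, s.sequence) for s in _read_protein_fasta(config.tier_drosophila)]
        ),
    ]
    results = classify_all(representatives, tiers, config.cascade, scheme)
    partition = {1: partition_summary(results, 1)}
    partition[2] = partition_summary(results, 2, groups)
    by_cat: dict[str, list[tuple[str, str]]] = {c: [] for c in _cascade.CATEGORIES}
    rep_seq = dict(representatives)
    for r in results:
        by_cat[r.category].append((r.query_id, rep_seq[r.query_id]))
    _stage("cascade", **{c: len(v) for c, v in by_cat.items()})

    # -- TE calling ------------------------------------------------------------
    te_primary = read_te_fasta(config.te_primary)
    target = by_cat[_cascade.CAT_NON_INSECT]
    background = by_cat[_cascade.CAT_AEDES]
    hits_t_primary = _top_hits(target, te_primary, scheme)
    hits_b_primary = _top_hits(background, te_primary, scheme)
    calls_primary = call_tes(target, te_primary, config.te_params, scheme, top_hits=hits_t_primary)
    calls_primary = qc_single_peptide(calls_primary, groups, evidence)
    bg_calls_primary = call_tes(
        background, te_primary, config.te_params, scheme, top_hits=hits_b_primary
    )

    calls_secondary: list = []
    calls_combined: list = []
    bg_calls_combined: list = []
    if config.te_secondary:
        te_secondary = read_te_fasta(config.te_secondary)
        hits_t_sec = _top_hits(target, te_secondary, scheme)
        calls_secondary = call_tes(
            target, te_secondary, config.te_params, scheme, top_hits=hits_t_sec
        )
        combined = list(te_primary) + list(te_secondary)
        hits_t_comb = {
            q: max(
                (h for h in (hits_t_primary[q], hits_t_sec[q]) if h is not None),
                key=lambda eh: eh[1].raw_score,
                default=None,
            )
            for q, _ in target
        }
        calls_combined = call_tes(target, combined, config.te_params, scheme, top_hits=hits_t_comb)
        hits_b_sec = _top_hits(background, te_secondary, scheme)
        hits_b_comb = {
            q: max(
                (h for h in (hits_b_primary[q], hits_b_sec[q]) if h is not None),
                key=lambda eh: eh[1].raw_score,
                default=None,
            )
            for q, _ in background
        }
        bg_calls_combined = call_tes(
            background, combined, config.te_params, scheme, top_hits=hits_b_comb
        )
    concordance = db_concordance(calls_primary, calls_secondary) if calls_secondary else {}
    _stage(
        "te_calls",
        primary=len(calls_primary),
        secondary=len(calls_secondary),
        background=len(bg_calls_primary),
    )

    # -- calibration -----------------------------------------------------------
    cov_t, cov_b = coverage_calibration(
        target,
        background,
        te_primary,
        identity_min_pct=config.te_params.identity_min_pct,
        evalue_max=config.te_params.evalue_max,
        scheme=scheme,
        target_hits=hits_t_primary,
        background_hits=hits_b_primary,
    )
    id_t, id_b = identity_calibration(
        target,
        background,
        te_primary,
        coverage_min_pct=config.te_params.coverage_min_pct,
        evalue_max=config.te_params.evalue_max,
        scheme=scheme,
        target_hits=hits_t_primary,
        background_hits=hits_b_primary,
    )
    selected = select_coverage_threshold(cov_t, cov_b)
    _stage("calibration", selected_coverage=selected)

    # -- enrichment ---------------------------------------------------------------
    stats = TEGenomeStats.from_tsv(config.te_genome_stats)
    enrichment_tables = []
    order_counts = count_calls(calls_primary, _enrich.LEVEL_ORDER)
    for norm in _enrich.NORMALIZERS:
        enrichment_tables.append(
            relative_enrichment(
                order_counts, stats, norm, config.enrichment_reference, _enrich.LEVEL_ORDER
            )
        )
    clade_counts = count_calls(calls_primary, _enrich.LEVEL_CLADE)
    ref_clade = max(clade_counts, key=lambda c: (clade_counts[c], c))
    for norm in _enrich.NORMALIZERS:
        enrichment_tables.append(
            relative_enrichment(clade_counts, stats, norm, ref_clade, _enrich.LEVEL_CLADE)
        )
    orf_matrix = orf_breakdown(calls_primary)
    _stage("enrichment", orders=len(order_counts), clades=len(clade_counts))

    # -- annotation evaluation ------------------------------------------------------
    genome = {s.id: s.sequence for s in read_fasta(config.genome)}
    index = GenomeIndex(genome)
    tx_seq = {t.id: t.sequence for t in transcripts}
    tx_of_orf = {r.orf_id: r.transcript_id for r in orf_records}
    group_tx = {}
    for g in groups:
        rep = max(g.orf_ids, key=lambda oid: (len(protein_of[oid]), oid))
        group_tx[g.group_id] = tx_of_orf[rep]
    na_tx = sorted({group_tx[q] for q, _ in by_cat[_cascade.CAT_NON_AEDES_INSECT]})
    hits = align_transcripts([(tid, tx_seq[tid]) for tid in na_tx], index)
    annotations = load_gff3_genes(config.annotation)
    records = triage(hits, annotations, config.triage_params)
    triage_counts = {c: sum(1 for r in records if r.category == c) for c in annotate.TRIAGE_CATEGORIES}

    new_records = [r for r in records if r.category == annotate.CAT_NEW_ANNOTATION]
    gap_new = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "n_count": g.n_count_in_window,
                "has_gap": g.has_gap,
                "truncated": g.truncated_upstream or g.truncated_downstream,
            }
            for r in new_records
            for g in [gap_scan(genome, r.best_hit, config.flank_nt)]
        ]
    )

    # matched control: transcripts of AEDES-category groups with a unique locus
    aedes_tx = sorted({group_tx[q] for q, _ in by_cat[_cascade.CAT_AEDES]})
    pool_hits = align_transcripts([(tid, tx_seq[tid]) for tid in aedes_tx], index)
    pool_best = {
        tid: hs[0]
        for tid, hs in pool_hits.items()
        if hs
        and hs[0].pct_identity >= config.triage_params.min_identity_pct
        and hs[0].transcript_coverage_pct >= config.triage_params.min_coverage_pct
    }
    gap_control = pd.DataFrame(columns=["transcript_id", "n_count", "has_gap", "truncated"])
    gap_ttest = None
    if new_records and len(pool_best) >= len(new_records):
        targets = [(r.transcript_id, len(tx_seq[r.transcript_id])) for r in new_records]
        pool = [(tid, len(tx_seq[tid])) for tid in sorted(pool_best)]
        controls = matched_control_sample(targets, pool, config.seed)
        gap_control = pd.DataFrame(
            [
                {
                    "transcript_id": tid,
                    "n_count": g.n_count_in_window,
                    "has_gap": g.has_gap,
                    "truncated": g.truncated_upstream or g.truncated_downstream,
                }
                for tid in controls
                for g in [gap_scan(genome, pool_best[tid], config.flank_nt)]
            ]
        )
        if len(gap_new) >= 2 and len(gap_control) >= 2:
            try:
                gap_ttest = ttest_equal_var(gap_new["n_count"], gap_control["n_count"])
            except ValueError:
                gap_ttest = None

    chr_map = read_chromosome_map(config.chromosome_map)
    chrom_table = chromosome_enrichment(records, chr_map)
    band_table = band_hotspots(records, chr_map)
    _stage("annotation_eval", **triage_counts)

    manifest = {
        "seed": config.seed,
        "min_orf_nt": config.min_orf_nt,
        "min_peptides": config.min_peptides,
        "cascade": asdict(config.cascade),
        "te_params": asdict(config.te_params),
        "triage_params": asdict(config.triage_params),
        "flank_nt": config.flank_nt,
        "enrichment_reference": config.enrichment_reference,
        "scoring": {
            "matrix": scheme.matrix_name,
            "gap_open": scheme.gap_open,
            "gap_extend": scheme.gap_extend,
            "lambda": scheme.lam,
            "K": scheme.K,
        },
        "counts": {
            "transcripts": len(transcripts),
            "orfs": len(orf_records),
            "groups": len(groups),
            "te_calls": len(calls_primary),
            **{f"cascade_{k}": len(v) for k, v in by_cat.items()},
            **{f"triage_{k}": v for k, v in triage_counts.items()},
        },
    }

    return ReportBundle(
        partition=partition,
        cascade_results=results,
        groups=groups,
        orf_count=len(orf_records),
        te_calls=calls_primary,
        te_calls_secondary=calls_secondary,
        te_calls_combined=calls_combined,
        background_calls_primary=bg_calls_primary,
        background_calls_combined=bg_calls_combined,
        calibration={"coverage": (cov_t, cov_b), "identity": (id_t, id_b)},
        selected_coverage=selected,
        concordance=concordance,
        enrichment_tables=enrichment_tables,
        orf_matrix=orf_matrix,
        triage_records=records,
        triage_counts=triage_counts,
        gap_new=gap_new,
        gap_control=gap_control,
        gap_ttest=gap_ttest,
        chromosome_table=chrom_table,
        band_table=band_table,
        manifest=manifest,
    )


def _read_protein_fasta(path):
    from Bio import SeqIO

    class _P:
        __slots__ = ("id", "sequence")

        def __init__(self, i, s):
            self.id, self.sequence = i, s

    return [_P(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_report(bundle: ReportBundle, out_dir) -> dict[str, str]:
    """Write all bundle tables; returns a name -> path mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def _tsv(name, df: pd.DataFrame, **kw):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=kw.pop("index", False), float_format="%.6g")
        written[name] = str(p)

    for mp, table in bundle.partition.items():
        _tsv(f"cascade_partition_min{mp}pep", table)
    _tsv(
        "cascade_results",
        pd.DataFrame(
            [
                {
                    "query_id": r.query_id,
                    "category": r.category,
                    "stopping_tier": r.stopping_tier or "",
                    **{
                        f"{tag}_subject": (m.subject_id if m else "")
                        for tag, m in sorted(r.best_match_per_tier.items())
                    },
                }
                for r in bundle.cascade_results
            ]
        ),
    )
    _tsv(
        "te_calls",
        pd.DataFrame(
            [
                {
                    "query_id": c.query_id,
                    "te_id": c.te_entry.te_id,
                    "order": c.te_entry.order,
                    "clade": c.te_entry.clade,
                    "orf_type": c.te_entry.orf_type,
                    "tier": c.tier,
                    "pct_identity": c.match.pct_identity,
                    "query_coverage_pct": c.match.query_coverage_pct,
                    "evalue": c.match.evalue,
                    "raw_score": c.match.raw_score,
                }
                for c in sorted(bundle.te_calls, key=lambda c: c.query_id)
            ]
        ),
    )
    for axis, (ct, cb) in bundle.calibration.items():
        _tsv(
            f"calibration_{axis}",
            pd.DataFrame(
                {
                    "cutoff": ct.grid,
                    "target_prop": ct.proportion_at_cutoff,
                    "background_prop": cb.proportion_at_cutoff,
                }
            ),
        )
    for t in bundle.enrichment_tables:
        _tsv(f"enrichment_{t.level.lower()}_{t.normalizer.lower()}", t.table)
    if not bundle.orf_matrix.empty:
        _tsv("orf_breakdown", bundle.orf_matrix, index=True)
    _tsv(
        "triage",
        pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "category": r.category,
                    "supercontig": r.best_hit.supercontig if r.best_hit else "",
                    "start": r.best_hit.span[0] + 1 if r.best_hit else "",
                    "end": r.best_hit.span[1] if r.best_hit else "",
                    "strand": r.best_hit.strand if r.best_hit else "",
                    "n_loci": r.n_loci,
                }
                for r in bundle.triage_records
            ]
        ),
    )
    _tsv("gap_scan_new", bundle.gap_new)
    _tsv("gap_scan_control", bundle.gap_control)
    _tsv("chromosome_enrichment", bundle.chromosome_table)
    _tsv("band_hotspots", bundle.band_table)

    summary = {
        "manifest": bundle.manifest,
        "partition": {
            str(mp): t.to_dict(orient="records") for mp, t in bundle.partition.items()
        },
        "triage_counts": bundle.triage_counts,
        "n_te_calls": len(bundle.te_calls),
        "n_te_calls_exact": sum(1 for c in bundle.te_calls if c.tier == "EXACT"),
        "selected_coverage_threshold": bundle.selected_coverage,
        "concordance": bundle.concordance,
        "gap_ttest": list(bundle.gap_ttest) if bundle.gap_ttest else None,
        "new_annotation_gap_fraction": (
            float(bundle.gap_new["has_gap"].mean()) if len(bundle.gap_new) else None
        ),
    }
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    written["summary"] = str(p)
    return written
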