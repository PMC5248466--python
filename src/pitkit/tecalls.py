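"""Transposable-element protein calling, threshold calibration and QC.

A query protein is called a TE protein when the top hit (by raw alignment
score) against a TE protein database passes E-value < 1e-5, amino-acid
identity > 30% and query coverage > 45% (all strict).  Calls whose top hit
exceeds 95% identity over 95% coverage are additionally flagged as the
"exact match" tier - the operational same-element criterion for highly
divergent mobile elements.

The 30/45 thresholds come from a calibration procedure: the proportion of a
target set (non-insect PIT hits, expected to contain real TE proteins) and
a background set (PIT hits matching annotated host genes, expected to
contain none because repeats are masked in the reference) retaining a TE
match is traced as the coverage (or identity) cutoff rises.  The background
curve collapses quickly while the target curve resists, and the knee where
background has collapsed but the target is still largely retained is the
working threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from Bio import SeqIO

from .align import DEFAULT_SCHEME, HomologyMatch, ScoringScheme, search
from .orfs import PeptideEvidence, ProteinGroup

TE_ORDERS = ("LTR", "NON_LTR", "PLE", "DNA_TIR", "HELITRON", "MITE", "SINE")
ORF_TYPES = ("GAG", "POL", "ENV", "ORF1", "ORF2", "TRANSPOSASE", "REP_HELICASE", "OTHER")
SOURCE_DBS = ("TEFAM", "REPBASE", "OTHER")

# Protein-coding constraints per order: which ORF types an order may carry.
_ORDER_ORFS = {
    "LTR": {"GAG", "POL", "ENV", "OTHER"},
    "NON_LTR": {"ORF1", "ORF2", "OTHER"},
    "DNA_TIR": {"TRANSPOSASE", "OTHER"},
}

__all__ = [
    "TEEntry",
    "TECallParams",
    "TECall",
    "CalibrationCurve",
    "call_tes",
    "coverage_calibration",
    "identity_calibration",
    "select_coverage_threshold",
    "qc_single_peptide",
    "db_concordance",
    "read_te_fasta",
    "write_te_fasta",
]


@dataclass(frozen=True)
class TEEntry:
    """One TE database protein with its classification metadata."""

    te_id: str
    source_db: str
    te_class: str  # "I" (retrotransposons) or "II" (DNA transposons)
    order: str
    clade: str
    orf_type: str
    protein: str

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.te_class not in ("I", "II"):
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.order not in TE_ORDERS:
            raise ValueError(f"unknown TE order {self.order!r}")
        if self.orf_type not in ORF_TYPES:
            raise ValueError(f"unknown ORF type {self.orf_type!r}")
        allowed = _ORDER_ORFS.get(self.order)
        if allowed is not None and self.orf_type not in allowed:
            raise ValueError(f"order {self.order} cannot carry ORF type {self.orf_type}")


@dataclass(frozen=True)
class TECallParams:
    evalue_max: float = 1e-5
    identity_min_pct: float = 30.0
    coverage_min_pct: float = 45.0
    exact_identity_pct: float = 95.0
    exact_coverage_pct: float = 95.0

    def __post_init__(self) -> None:
        if self.exact_identity_pct < self.identity_min_pct:
            raise ValueError("exact identity threshold below standard threshold")
        if self.exact_coverage_pct < self.coverage_min_pct:
            raise ValueError("exact coverage threshold below standard threshold")


TIER_EXACT = "EXACT"
TIER_STANDARD = "STANDARD"


@dataclass(frozen=True)
class TECall:
    query_id: str
    te_entry: TEEntry
    match: HomologyMatch
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in (TIER_EXACT, TIER_STANDARD):
            raise ValueError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    dataset_tag: str  # TARGET or BACKGROUND
    axis: str  # COVERAGE or IDENTITY
    grid: tuple[float, ...]
    proportion_at_cutoff: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.proportion_at_cutoff):
            raise ValueError("grid and proportions length mismatch")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be ascending")
        props = self.proportion_at_cutoff
        if any(b > a + 1e-12 for a, b in zip(props, props[1:])):
            raise ValueError("proportions must be monotone non-increasing")


def _top_hits(
    queries: Sequence[tuple[str, str]],
    te_db: Sequence[TEEntry],
    scheme: ScoringScheme,
) -> dict[str, tuple[TEEntry, HomologyMatch] | None]:
    """Best hit per query (by raw score) against the TE database."""
    if not te_db:
        raise ValueError("empty TE database")
    by_id = {e.te_id: e for e in te_db}
    if len(by_id) != len(te_db):
        raise ValueError("duplicate te_id in database")
    seqs = [(e.te_id, e.protein) for e in te_db]
    out: dict[str, tuple[TEEntry, HomologyMatch] | None] = {}
    for qid, seq in queries:
        hits = search(seq, seqs, scheme, query_id=qid, db_tag="TE", top_n=1)
        out[qid] = (by_id[hits[0].subject_id], hits[0]) if hits else None
    return out


def _passes(m: HomologyMatch, params: TECallParams) -> bool:
    return (
        m.evalue < params.evalue_max
        and m.pct_identity > params.identity_min_pct
        and m.query_coverage_pct > params.coverage_min_pct
    )


def call_tes(
    queries: Sequence[tuple[str, str]],
    te_db: Sequence[TEEntry],
    params: TECallParams = TECallParams(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
    *,
    top_hits: Mapping[str, tuple[TEEntry, HomologyMatch] | None] | None = None,
) -> list[TECall]:
    """At most one TE call per query, from its top-scoring database hit.

    ``top_hits`` may carry precomputed best hits (e.g. shared with the
    calibration step) to avoid re-aligning.
    """
    hits = top_hits if top_hits is not None else _top_hits(queries, te_db, scheme)
    calls = []
    for qid, _ in queries:
        best = hits.get(qid)
        if best is None:
            continue
        entry, m = best
        if not _passes(m, params):
            continue
        tier = (
            TIER_EXACT
            if m.pct_identity > params.exact_identity_pct
            and m.query_coverage_pct > params.exact_coverage_pct
            else TIER_STANDARD
        )
        calls.append(TECall(query_id=qid, te_entry=entry, match=m, tier=tier))
    return calls


def _calibration(
    target_hits,
    background_hits,
    grid: Sequence[float],
    axis: str,
    fixed_check,
) -> tuple[CalibrationCurve, CalibrationCurve]:
    if len(grid) == 0:
        raise ValueError("empty calibration grid")
    grid = tuple(float(g) for g in grid)
    curves = []
    for tag, hits in (("TARGET", target_hits), ("BACKGROUND", background_hits)):
        n = len(hits)
        if n == 0:
            raise ValueError(f"{tag} query set is empty")
        values = []
        for h in hits.values():
            if h is None:
                continue
            _, m = h
            if fixed_check(m):
                values.append(m.query_coverage_pct if axis == "COVERAGE" else m.pct_identity)
        props = tuple(sum(1 for v in values if v > c) / n for c in grid)
        curves.append(
            CalibrationCurve(dataset_tag=tag, axis=axis, grid=grid, proportion_at_cutoff=props)
        )
    return curves[0], curves[1]


def coverage_calibration(
    target_queries: Sequence[tuple[str, str]],
    background_queries: Sequence[tuple[str, str]],
    te_db: Sequence[TEEntry],
    grid: Sequence[float] = tuple(range(0, 101, 5)),
    identity_min_pct: float = 30.0,
    evalue_max: float = 1e-5,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    *,
    target_hits=None,
    background_hits=None,
) -> tuple[CalibrationCurve, CalibrationCurve]:
    """Proportion of each set retaining a TE best hit as the coverage cutoff
    rises (identity and E-value held at the fixed thresholds)."""
    th = target_hits if target_hits is not None else _top_hits(target_queries, te_db, scheme)
    bh = (
        background_hits
        if background_hits is not None
        else _top_hits(background_queries, te_db, scheme)
    )
    return _calibration(
        th, bh, grid, "COVERAGE", lambda m: m.evalue < evalue_max and m.pct_identity > identity_min_pct
    )


def identity_calibration(
    target_queries: Sequence[tuple[str, str]],
    background_queries: Sequence[tuple[str, str]],
    te_db: Sequence[TEEntry],
    grid: Sequence[float] = tuple(range(0, 101, 5)),
    coverage_min_pct: float = 45.0,
    evalue_max: float = 1e-5,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    *,
    target_hits=None,
    background_hits=None,
) -> tuple[CalibrationCurve, CalibrationCurve]:
    """As ``coverage_calibration`` with the axes swapped: coverage fixed,
    identity cutoff varied."""
    th = target_hits if target_hits is not None else _top_hits(target_queries, te_db, scheme)
    bh = (
        background_hits
        if background_hits is not None
        else _top_hits(background_queries, te_db, scheme)
    )
    return _calibration(
        th,
        bh,
        grid,
        "IDENTITY",
        lambda m: m.evalue < evalue_max and m.query_coverage_pct > coverage_min_pct,
    )


def select_coverage_threshold(
    curve_target: CalibrationCurve,
    curve_background: CalibrationCurve,
    background_tolerance: float = 0.2,
    target_retention: float = 0.8,
) -> float:
    """Advisory threshold choice from a pair of calibration curves.

    Returns the smallest cutoff where the background proportion has fallen
    to ``background_tolerance`` of its value at cutoff 0 while the target
    still retains ``target_retention`` of its value at cutoff 0; if no
    cutoff qualifies, falls back to the cutoff maximising the
    target-background difference (earliest such cutoff).
    """
    if curve_target.grid != curve_background.grid:
        raise ValueError("calibration curves computed on different grids")
    t0 = curve_target.proportion_at_cutoff[0]
    b0 = curve_background.proportion_at_cutoff[0]
    for c, tp, bp in zip(
        curve_target.grid, curve_target.proportion_at_cutoff, curve_background.proportion_at_cutoff
    ):
        if bp <= background_tolerance * b0 and tp >= target_retention * t0:
            return c
    diffs = [
        tp - bp
        for tp, bp in zip(curve_target.proportion_at_cutoff, curve_background.proportion_at_cutoff)
    ]
    return curve_target.grid[int(np.argmax(diffs))]


def _concordant(a: TEEntry, b: TEEntry) -> bool:
    """Same element identity for QC purposes: same order and clade, and the
    same ORF type when the elements are related (same clade)."""
    return a.order == b.order and a.clade == b.clade and a.orf_type == b.orf_type


def qc_single_peptide(
    calls: Sequence[TECall],
    groups: Sequence[ProteinGroup],
    evidence: Sequence[PeptideEvidence],
) -> list[TECall]:
    """Remove single-peptide TE calls whose peptide is promiscuous.

    A call supported by exactly one peptide is dropped when that peptide
    also matches ORFs outside the call's protein group that carry a
    different TE identity (different element, or a non-concordant ORF type
    within related elements) or belong to a non-TE protein.  Uniquely
    mapping single peptides and all multi-peptide calls are retained.
    """
    by_group: dict[str, ProteinGroup] = {}
    for g in groups:
        by_group[g.group_id] = g
        for oid in g.orf_ids:
            by_group[oid] = g
    pep_orfs: dict[str, frozenset[str]] = {e.peptide: e.matched_orf_ids for e in evidence}
    orf_call: dict[str, TECall] = {}
    for c in calls:
        g = by_group.get(c.query_id)
        members = g.orf_ids if g else frozenset({c.query_id})
        for oid in members:
            orf_call[oid] = c
        orf_call[c.query_id] = c
    kept = []
    for c in calls:
        g = by_group.get(c.query_id)
        if g is None:
            raise KeyError(f"TE call query {c.query_id!r} not found in any protein group")
        if g.n_peptides > 1:
            kept.append(c)
            continue
        (pep,) = tuple(g.peptides) if g.peptides else (None,)
        others = (pep_orfs.get(pep, frozenset()) - g.orf_ids) if pep else frozenset()
        suspicious = False
        for oid in others:
            other_call = orf_call.get(oid)
            if other_call is None or not _concordant(other_call.te_entry, c.te_entry):
                suspicious = True
                break
        if not suspicious:
            kept.append(c)
    return kept


def db_concordance(
    calls_primary: Sequence[TECall], calls_secondary: Sequence[TECall]
) -> dict:
    """Agreement between two databases' calls on the shared queries.

    Order-level agreement is the headline TE-identity concordance (an LTR
    retrotransposon versus a cut-and-paste DNA transposon is an identity
    disagreement); clade/superfamily agreement is the finer measure.
    """
    p = {c.query_id: c for c in calls_primary}
    s = {c.query_id: c for c in calls_secondary}
    shared = sorted(set(p) & set(s))
    out = {
        "n_shared": len(shared),
        "n_only_primary": len(set(p) - set(s)),
        "n_only_secondary": len(set(s) - set(p)),
        "order_agreement": None,
        "clade_agreement": None,
    }
    if shared:
        order_agree = sum(1 for q in shared if p[q].te_entry.order == s[q].te_entry.order)
        clade_agree = sum(
            1
            for q in shared
            if p[q].te_entry.order == s[q].te_entry.order
            and p[q].te_entry.clade == s[q].te_entry.clade
        )
        out["order_agreement"] = order_agree / len(shared)
        out["clade_agreement"] = clade_agree / len(shared)
    return out


# ---------------------------------------------------------------------------
# TE FASTA with key=value header metadata

_HEADER_RE = re.compile(r"^(?P<te_id>[^|]+)(?P<meta>(\|[A-Za-z_]+=[^|]*)*)$")


def read_te_fasta(path, default_source: str = "OTHER") -> list[TEEntry]:
    """Read a TE database FASTA whose headers encode metadata as
    ``te_id|source=TEFAM|class=I|order=LTR|clade=Ty3/gypsy|orf=gag``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0]
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(f"unparseable TE header {header!r}")
        meta = dict(kv.split("=", 1) for kv in m.group("meta").split("|") if "=" in kv)
        entries.append(
            TEEntry(
                te_id=m.group("te_id"),
                source_db=meta.get("source", default_source).upper(),
                te_class=meta.get("class", "I"),
                order=meta.get("order", "LTR").upper(),
                clade=meta.get("clade", ""),
                orf_type=meta.get("orf", "OTHER").upper(),
                protein=str(rec.seq),
            )
        )
    return entries


def write_te_fasta(entries: Iterable[TEEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = (
                f"{e.te_id}|source={e.source_db}|class={e.te_class}"
                f"|order={e.order}|clade={e.clade}|orf={e.orf_type.lower()}"
            )
            fh.write(f">{header}\n{e.protein}\n")
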