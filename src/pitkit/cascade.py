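"""Tiered homology classification of PIT proteins, plus the viral screen.

Each query protein is searched against an ordered list of reference
proteomes (Aedes aegypti, then Culex quinquefasciatus, then Drosophila
melanogaster, optionally a final fallback database).  The cascade stops at
the first tier whose best hit reaches the identity stop threshold (default
60% of aligned columns) at a significant E-value; the stopping tier decides
the category:

* AEDES            - stopped at the Aedes tier (known A. aegypti gene)
* NON_AEDES_INSECT - stopped at Culex or Drosophila (an insect protein
                     missing from the A. aegypti annotation)
* NON_INSECT       - everything else, including fallback-tier stops and
                     proteins with no qualifying hit anywhere

The NON_INSECT subset is the substrate for transposable-element and virus
screens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

from .align import DEFAULT_SCHEME, HomologyMatch, ScoringScheme, search
from .orfs import ProteinGroup

TIER_AEDES = "AEDES"
TIER_CULEX = "CULEX"
TIER_DROSOPHILA = "DROSOPHILA"
TIER_FALLBACK = "FALLBACK"

CAT_AEDES = "AEDES"
CAT_NON_AEDES_INSECT = "NON_AEDES_INSECT"
CAT_NON_INSECT = "NON_INSECT"
CATEGORIES = (CAT_AEDES, CAT_NON_AEDES_INSECT, CAT_NON_INSECT)

__all__ = [
    "ReferenceTier",
    "CascadeParams",
    "CascadeResult",
    "classify_protein",
    "classify_all",
    "partition_summary",
    "screen_viral",
    "round_half_up",
    "CATEGORIES",
]


@dataclass(frozen=True)
class ReferenceTier:
    tag: str
    db: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "db", tuple(self.db))


@dataclass(frozen=True)
class CascadeParams:
    identity_stop_pct: float = 60.0
    evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.identity_stop_pct <= 100):
            raise ValueError("identity_stop_pct must be in (0,100]")


@dataclass(frozen=True)
class CascadeResult:
    query_id: str
    category: str
    stopping_tier: str | None
    best_match_per_tier: Mapping[str, HomologyMatch | None] = field(default_factory=dict)


def _category_for(stopping_tier: str | None) -> str:
    if stopping_tier == TIER_AEDES:
        return CAT_AEDES
    if stopping_tier in (TIER_CULEX, TIER_DROSOPHILA):
        return CAT_NON_AEDES_INSECT
    return CAT_NON_INSECT


def classify_protein(
    protein: str,
    tiers: Sequence[ReferenceTier],
    params: CascadeParams = CascadeParams(),
    *,
    query_id: str = "query",
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> CascadeResult:
    """Search the tiers in order; stop at the first qualifying best hit."""
    if not tiers:
        raise ValueError("at least one reference tier required")
    seen = set()
    for tier in tiers:
        if tier.tag in seen:
            raise ValueError(f"duplicate tier tag {tier.tag!r}")
        seen.add(tier.tag)
        if not tier.db:
            raise ValueError(f"tier {tier.tag!r} has an empty database")
    best: dict[str, HomologyMatch | None] = {}
    stopping = None
    for tier in tiers:
        hits = search(protein, tier.db, scheme, query_id=query_id, db_tag=tier.tag, top_n=1)
        top = hits[0] if hits else None
        best[tier.tag] = top
        if (
            top is not None
            and top.pct_identity >= params.identity_stop_pct
            and top.evalue <= params.evalue_max
        ):
            stopping = tier.tag
            break
    return CascadeResult(
        query_id=query_id,
        category=_category_for(stopping),
        stopping_tier=stopping,
        best_match_per_tier=best,
    )


def classify_all(
    queries: Sequence[tuple[str, str]],
    tiers: Sequence[ReferenceTier],
    params: CascadeParams = CascadeParams(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[CascadeResult]:
    return [
        classify_protein(seq, tiers, params, query_id=qid, scheme=scheme) for qid, seq in queries
    ]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (3.5 -> 4), as used for all reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def partition_summary(
    results: Sequence[CascadeResult],
    min_peptides: int = 1,
    groups: Sequence[ProteinGroup] | None = None,
) -> pd.DataFrame:
    """Per-category counts and percentages of the cascade partition.

    With ``min_peptides=2`` the summary is restricted to queries whose
    protein group is supported by at least two distinct peptides (queries
    are matched to groups by group id or by ORF membership).  Percentages
    are reported both integer-rounded (half-up) and to one decimal.
    """
    if not results:
        raise ValueError("no cascade results to summarise")
    if min_peptides not in (1, 2):
        raise ValueError("min_peptides must be 1 or 2")
    kept = list(results)
    if min_peptides > 1:
        if groups is None:
            raise ValueError("groups required when min_peptides > 1")
        lookup: dict[str, ProteinGroup] = {}
        for g in groups:
            lookup[g.group_id] = g
            for oid in g.orf_ids:
                lookup[oid] = g
        kept = [
            r
            for r in results
            if r.query_id in lookup and lookup[r.query_id].n_peptides >= min_peptides
        ]
    n = len(kept)
    rows = []
    for cat in CATEGORIES:
        count = sum(1 for r in kept if r.category == cat)
        pct = 100.0 * count / n if n else 0.0
        rows.append(
            {
                "category": cat,
                "count": count,
                "pct_int": int(round_half_up(pct, 0)),
                "pct_1dp": round_half_up(pct, 1),
            }
        )
    return pd.DataFrame(rows)


def screen_viral(
    nonmatched: Sequence[tuple[str, str]],
    viral_db: Sequence[tuple[str, str]],
    min_raw_score: int = 50,
    te_db: Sequence[tuple[str, str]] | None = None,
    host_db: Sequence[tuple[str, str]] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[HomologyMatch]:
    """Screen non-insect proteins against a viral protein database.

    A query is reported when its best viral hit scores strictly above
    ``min_raw_score`` and neither its best transposable-element hit nor its
    best host-protein hit exceeds that viral score (excluding viral entries
    that are really TE or cellular homologues).
    """
    if not viral_db:
        raise ValueError("empty viral database")
    aligner = scheme.aligner

    def best_score(q: str, db) -> int:
        if not db:
            return 0
        return max(int(round(aligner.score(q, s.upper()))) for _, s in db)

    out = []
    for qid, seq in nonmatched:
        hits = search(seq, viral_db, scheme, query_id=qid, db_tag="VIRAL", top_n=1)
        if not hits or hits[0].raw_score <= min_raw_score:
            continue
        viral_score = hits[0].raw_score
        if best_score(seq, te_db or ()) > viral_score:
            continue
        if best_score(seq, host_db or ()) > viral_score:
            continue
        out.append(hits[0])
    return out
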