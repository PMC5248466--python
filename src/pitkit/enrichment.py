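"""Per-category TE-call counting and relative-enrichment normalisation.

Raw protein counts per TE order (or clade, or ORF type) confound expression
with genomic and database representation: an order may yield more proteins
simply because the genome carries more copies of it.  The enrichment ratio
therefore normalises each category's protein count by one of three
normalisers - percent of the genome derived from that category, genomic
copy number, or the number of database entries - and expresses the result
relative to a reference category (LTR retrotransposons by convention, whose
ratio is exactly 1):

    ratio_c = (count_c / norm_c) / (count_ref / norm_ref)

Categories with an unknown or zero normaliser are surfaced as UNDEFINED
(NaN with a flag), never silently dropped.  Non-protein-coding orders
(SINE, MITE - non-autonomous elements that borrow other TEs' proteins) are
excluded from protein-enrichment tables by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tecalls import TECall

LEVEL_ORDER = "ORDER"
LEVEL_CLADE = "CLADE"
LEVEL_ORF_TYPE = "ORF_TYPE"
LEVELS = (LEVEL_ORDER, LEVEL_CLADE, LEVEL_ORF_TYPE)

NORM_GENOME_PCT = "GENOME_PCT"
NORM_COPY_NUMBER = "COPY_NUMBER"
NORM_DB_ENTRIES = "DB_ENTRIES"
NORMALIZERS = (NORM_GENOME_PCT, NORM_COPY_NUMBER, NORM_DB_ENTRIES)

NON_CODING_ORDERS = ("SINE", "MITE")

_NORM_COLUMN = {
    NORM_GENOME_PCT: "genome_pct",
    NORM_COPY_NUMBER: "copy_number",
    NORM_DB_ENTRIES: "db_entries",
}

__all__ = [
    "TEGenomeStats",
    "EnrichmentTable",
    "count_calls",
    "relative_enrichment",
    "orf_breakdown",
    "LEVELS",
    "NORMALIZERS",
]


@dataclass(frozen=True)
class TEGenomeStats:
    """Genomic and database representation per TE category.

    ``copy_number`` may be None (unknown, e.g. for some cut-and-paste
    families); ``genome_pct`` and ``db_entries`` are required non-negative.
    """

    per_category: Mapping[str, dict]

    def value(self, category: str, normalizer: str) -> float | None:
        row = self.per_category.get(category)
        if row is None:
            return None
        v = row.get(_NORM_COLUMN[normalizer])
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    @classmethod
    def from_tsv(cls, path) -> "TEGenomeStats":
        df = pd.read_csv(path, sep="\t", na_values=["NA", "UNKNOWN"])
        per = {}
        for _, r in df.iterrows():
            per[str(r["category"])] = {
                "genome_pct": float(r["genome_pct"]),
                "copy_number": None if pd.isna(r["copy_number"]) else int(r["copy_number"]),
                "db_entries": int(r["db_entries"]),
            }
        return cls(per_category=per)

    def to_tsv(self, path) -> None:
        rows = []
        for cat in sorted(self.per_category):
            r = self.per_category[cat]
            rows.append(
                {
                    "category": cat,
                    "genome_pct": r["genome_pct"],
                    "copy_number": "NA" if r["copy_number"] is None else r["copy_number"],
                    "db_entries": r["db_entries"],
                }
            )
        pd.DataFrame(rows, columns=["category", "genome_pct", "copy_number", "db_entries"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class EnrichmentTable:
    level: str
    reference_category: str
    normalizer: str
    table: pd.DataFrame  # columns: category, count, ratio, defined

    def ratio(self, category: str) -> float:
        row = self.table[self.table["category"] == category]
        if row.empty:
            raise KeyError(category)
        return float(row["ratio"].iloc[0])


def _category_of(call: TECall, level: str) -> str:
    if level == LEVEL_ORDER:
        return call.te_entry.order
    if level == LEVEL_CLADE:
        if not call.te_entry.clade:
            raise ValueError(f"call {call.query_id} lacks clade metadata")
        return call.te_entry.clade
    if level == LEVEL_ORF_TYPE:
        return call.te_entry.orf_type
    raise ValueError(f"unknown level {level!r}")


def count_calls(
    calls: Sequence[TECall], level: str, categories: Sequence[str] | None = None
) -> dict[str, int]:
    """Tally calls per category at the requested level.

    ``categories`` fixes the category universe so that zero-call categories
    are reported as 0; by default the universe is the categories observed.
    """
    counts: dict[str, int] = {c: 0 for c in categories} if categories else {}
    for call in calls:
        cat = _category_of(call, level)
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def relative_enrichment(
    counts: Mapping[str, int],
    stats: TEGenomeStats,
    normalizer: str,
    reference: str,
    level: str = LEVEL_ORDER,
    exclude_non_coding: bool = True,
) -> EnrichmentTable:
    """Normalised protein-count ratios relative to a reference category."""
    if normalizer not in NORMALIZERS:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    counts = dict(counts)
    if exclude_non_coding and level == LEVEL_ORDER:
        for nc in NON_CODING_ORDERS:
            counts.pop(nc, None)
    if reference not in counts or counts[reference] <= 0:
        raise ValueError(f"reference category {reference!r} has no calls")
    ref_norm = stats.value(reference, normalizer)
    if ref_norm is None or ref_norm <= 0:
        raise ValueError(f"reference category {reference!r} has unknown/zero normalizer")
    ref_rate = counts[reference] / ref_norm
    rows = []
    for cat in sorted(counts):
        norm = stats.value(cat, normalizer)
        if norm is None or norm <= 0:
            rows.append({"category": cat, "count": counts[cat], "ratio": np.nan, "defined": False})
        else:
            rows.append(
                {
                    "category": cat,
                    "count": counts[cat],
                    "ratio": (counts[cat] / norm) / ref_rate,
                    "defined": True,
                }
            )
    return EnrichmentTable(
        level=level,
        reference_category=reference,
        normalizer=normalizer,
        table=pd.DataFrame(rows),
    )


def orf_breakdown(calls: Sequence[TECall]) -> pd.DataFrame:
    """Distinct-element counts per (clade, ORF type).

    Each cell counts the number of different elements (te_ids) for which
    that ORF's protein was detected, not the number of calls - repeated
    detections of one element's gag count once.
    """
    if not calls:
        return pd.DataFrame()
    seen: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        key = (c.te_entry.clade, c.te_entry.orf_type)
        seen.setdefault(key, set()).add(c.te_entry.te_id)
    clades = sorted({k[0] for k in seen})
    orf_types = sorted({k[1] for k in seen})
    mat = pd.DataFrame(0, index=clades, columns=orf_types)
    for (clade, orf), ids in seen.items():
        mat.loc[clade, orf] = len(ids)
    mat.index.name = "clade"
    return mat
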