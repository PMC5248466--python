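"""Protein local alignment, Karlin-Altschul E-values and ranked database search.

The alignment engine stands in for the web BLASTp searches a PIT analysis
normally delegates: optimal Smith-Waterman local alignment under BLOSUM62
with affine gap costs (opening a gap of length L costs ``gap_open +
L * gap_extend``, i.e. the first gap residue is charged open + extend).
Raw scores are converted to bit scores and E-values with the ungapped-form
Karlin-Altschul statistics E = K * m * n * exp(-lambda * S), using the
standard gapped BLOSUM62/11/1 parameterisation (lambda = 0.267, K = 0.041)
by default; m is the query length and n the summed residue length of the
database searched.

External searches can be imported from the 12/13-column BLAST tabular
dialect (``qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore [qcovs]``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "HomologyMatch",
    "smith_waterman",
    "evalue",
    "bit_score",
    "search",
    "read_tabular_matches",
    "write_tabular_matches",
]


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._matrix = substitution_matrices.load(self.matrix_name)
        self._aligner = None

    @property
    def matrix(self):
        return self._matrix

    @property
    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            a = Align.PairwiseAligner()
            a.mode = "local"
            a.substitution_matrix = self._matrix
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            self._aligner = a
        return self._aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment; spans are 0-based half-open on each sequence."""

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    raw_score: int
    identities: int
    aln_length: int  # alignment columns, including gap columns
    query_aln: str | None = None
    subject_aln: str | None = None

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.aln_length


@dataclass(frozen=True)
class HomologyMatch:
    """One query-subject search result with BLAST-style summary statistics."""

    query_id: str
    subject_id: str
    db_tag: str
    raw_score: int
    bit_score: float
    evalue: float
    pct_identity: float
    query_coverage_pct: float
    query_span: tuple[int, int] | None = None
    subject_span: tuple[int, int] | None = None
    aln_length: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= 100):
            raise ValueError("pct_identity outside [0,100]")
        if not (0 <= self.query_coverage_pct <= 100):
            raise ValueError("query_coverage_pct outside [0,100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


def _check_protein(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty {label} sequence")
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label} contains non-amino-acid residues {sorted(bad)}")
    return seq


def smith_waterman(
    query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult | None:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when no cell of the dynamic-programming matrix is
    positive (no local alignment scores above zero).  Among co-optimal
    alignments the engine's first reported traceback is used, which is
    deterministic for fixed inputs.
    """
    query = _check_protein(query, "query")
    subject = _check_protein(subject, "subject")
    score = scheme.aligner.score(query, subject)
    if score <= 0:
        return None
    aln = next(iter(scheme.aligner.align(query, subject)))
    q_blocks, s_blocks = aln.aligned
    identities = 0
    columns = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            columns += (qs - prev_q_end) + (ss - prev_s_end)  # gap columns
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                identities += 1
        columns += qe - qs
        prev_q_end, prev_s_end = qe, se
    qa, sa = str(aln[0]), str(aln[1])
    return AlignmentResult(
        query_span=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        subject_span=(int(s_blocks[0][0]), int(s_blocks[-1][1])),
        raw_score=int(round(score)),
        identities=identities,
        aln_length=columns,
        query_aln=qa,
        subject_aln=sa,
    )


def bit_score(raw_score: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalised score S' = (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2)


def evalue(
    raw_score: int,
    query_len: int,
    db_len: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Expected chance alignments at score >= S in an m x n search space."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return scheme.K * query_len * db_len * math.exp(-scheme.lam * raw_score)


def _match_from_alignment(
    query_id: str,
    subject_id: str,
    db_tag: str,
    aln: AlignmentResult,
    query_len: int,
    db_len: int,
    scheme: ScoringScheme,
) -> HomologyMatch:
    qs, qe = aln.query_span
    return HomologyMatch(
        query_id=query_id,
        subject_id=subject_id,
        db_tag=db_tag,
        raw_score=aln.raw_score,
        bit_score=bit_score(aln.raw_score, scheme),
        evalue=evalue(aln.raw_score, query_len, db_len, scheme),
        pct_identity=aln.pct_identity,
        query_coverage_pct=100.0 * (qe - qs) / query_len,
        query_span=aln.query_span,
        subject_span=aln.subject_span,
        aln_length=aln.aln_length,
    )


def search(
    query: str,
    db: Sequence[tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    *,
    query_id: str = "query",
    db_tag: str = "",
    min_raw_score: int = 1,
    top_n: int | None = None,
) -> list[HomologyMatch]:
    """Rank all database subjects against one query.

    Sorted by raw score descending, then E-value ascending, then subject id
    lexicographic; subjects scoring below ``min_raw_score`` are omitted.
    Tracebacks are computed only for the returned (top ``top_n``) matches,
    so the ranking is by optimal score over the full database.
    """
    if not db:
        raise ValueError("empty database")
    query = _check_protein(query, "query")
    db_len = sum(len(s) for _, s in db)
    aligner = scheme.aligner
    scored = []
    for sid, sseq in db:
        if not sseq:
            raise ValueError(f"empty subject sequence {sid!r}")
        s = int(round(aligner.score(query, sseq.upper())))
        if s >= min_raw_score:
            scored.append((-s, sid, sseq))
    scored.sort(key=lambda t: (t[0], t[1]))
    if top_n is not None:
        scored = scored[:top_n]
    out = []
    for _, sid, sseq in scored:
        aln = smith_waterman(query, sseq, scheme)
        if aln is None:  # pragma: no cover - min_raw_score >= 1 excludes this
            continue
        out.append(_match_from_alignment(query_id, sid, db_tag, aln, len(query), db_len, scheme))
    return out


# ---------------------------------------------------------------------------
# BLAST tabular interoperability

_N_COLS = 12


def read_tabular_matches(
    stream: TextIO | Iterable[str],
    query_lengths: dict[str, int] | None = None,
    db_tag: str = "",
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[HomologyMatch]:
    """Parse 12- or 13-column BLAST tabular rows (1-based inclusive coords).

    The optional 13th column is query coverage (percent); when absent the
    coverage is computed from qstart/qend and ``query_lengths``.
    """
    out = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (_N_COLS, _N_COLS + 1):
            raise ValueError(f"line {lineno}: expected 12 or 13 columns, got {len(parts)}")
        try:
            qid, sid = parts[0], parts[1]
            pident = float(parts[2])
            length = int(parts[3])
            qstart, qend = int(parts[6]), int(parts[7])
            sstart, send = int(parts[8]), int(parts[9])
            ev = float(parts[10])
            bits = float(parts[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
        if len(parts) == _N_COLS + 1:
            qcov = float(parts[12])
        else:
            if query_lengths is None or qid not in (query_lengths or {}):
                raise KeyError(
                    f"line {lineno}: query length for {qid!r} required to compute coverage"
                )
            qcov = 100.0 * (qend - qstart + 1) / query_lengths[qid]
        raw = int(round((bits * math.log(2) + math.log(scheme.K)) / scheme.lam))
        out.append(
            HomologyMatch(
                query_id=qid,
                subject_id=sid,
                db_tag=db_tag,
                raw_score=raw,
                bit_score=bits,
                evalue=ev,
                pct_identity=pident,
                query_coverage_pct=qcov,
                query_span=(qstart - 1, qend),
                subject_span=(min(sstart, send) - 1, max(sstart, send)),
                aln_length=length,
            )
        )
    return out


def write_tabular_matches(matches: Iterable[HomologyMatch], stream: TextIO) -> None:
    """Write 13-column BLAST tabular (coverage in the 13th column)."""
    for m in matches:
        qs, qe = m.query_span if m.query_span else (0, 0)
        ss, se = m.subject_span if m.subject_span else (0, 0)
        length = m.aln_length if m.aln_length is not None else qe - qs
        stream.write(
            "\t".join(
                [
                    m.query_id,
                    m.subject_id,
                    f"{m.pct_identity:.3f}",
                    str(length),
                    "0",
                    "0",
                    str(qs + 1),
                    str(qe),
                    str(ss + 1),
                    str(se),
                    f"{m.evalue:.3g}",
                    f"{m.bit_score:.1f}",
                    f"{m.query_coverage_pct:.3f}",
                ]
            )
            + "\n"
        )
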