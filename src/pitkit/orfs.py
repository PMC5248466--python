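"""Nucleotide/protein sequence handling, six-frame ORF extraction and peptide grouping.

A PIT (proteomics-informed-by-transcriptomics) search database is built by
translating every de novo assembled transcript in all six reading frames and
retaining open reading frames longer than a length floor (default 200 nt,
strictly greater, counted from the ATG through the last sense codon and
excluding the stop).  Peptide-spectrum matches arriving from the upstream
search engine are consumed as a table mapping peptide sequences to the ORFs
they are consistent with; ORFs indistinguishable by their supporting peptide
sets are merged into protein groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")

__all__ = [
    "NaSeq",
    "OrfRecord",
    "PeptideEvidence",
    "ProteinGroup",
    "translate",
    "six_frame_orfs",
    "group_peptides",
    "read_fasta",
    "write_fasta",
    "read_peptide_evidence",
    "write_peptide_evidence",
    "write_orf_records",
    "read_orf_records",
]


def _normalize_nt(sequence: str) -> str:
    """Uppercase, RNA U -> T; reject residues outside {A,C,G,T,N}."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class NaSeq:
    """A nucleotide sequence (transcript or genome scaffold)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        object.__setattr__(self, "sequence", _normalize_nt(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A translated ORF from one reading frame of a transcript.

    ``start``/``end`` are 0-based half-open coordinates on the *forward*
    strand of the transcript regardless of frame sign.  ``nt_length`` runs
    from the ATG through the last sense codon, excluding any stop codon.
    """

    orf_id: str
    transcript_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int
    end: int
    nt_length: int
    protein: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.nt_length != self.end - self.start:
            raise ValueError("nt_length inconsistent with coordinates")
        if self.nt_length % 3 != 0:
            raise ValueError("nt_length not divisible by 3")
        if len(self.protein) != self.nt_length // 3:
            raise ValueError("protein length inconsistent with nt_length")
        if not self.protein.startswith("M"):
            raise ValueError("ORF protein must begin with M")


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide and the set of ORF ids it is consistent with."""

    peptide: str
    matched_orf_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.peptide) < 6:
            raise ValueError("peptides shorter than 6 residues are not accepted")
        if not self.matched_orf_ids:
            raise ValueError("peptide with empty ORF match set")
        object.__setattr__(self, "matched_orf_ids", frozenset(self.matched_orf_ids))


@dataclass(frozen=True)
class ProteinGroup:
    """ORFs indistinguishable by their supporting peptides."""

    group_id: str
    orf_ids: frozenset[str]
    n_peptides: int
    peptides: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("protein group without peptide support")


_STOPS = {"TAA", "TAG", "TGA"}


def translate(nt: str) -> str:
    """Translate a coding nucleotide string with the standard genetic code.

    Codons containing N translate to X; a single trailing stop codon is
    trimmed; an internal stop raises ``ValueError``.
    """
    seq = _normalize_nt(nt)
    if len(seq) % 3 != 0:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon")
    return aa


def _frame_orfs(working: str, offset: int, min_nt: int):
    """Yield (start_on_working, nt_length) for ORFs in one frame.

    Longest-per-stop rule: within each stop-delimited segment only the ORF
    from the first ATG is reported.  Segments reaching the sequence edge
    without a stop are retained (open 3' end).
    """
    n_codons = (len(working) - offset) // 3
    codons = [working[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)]
    seg_start = 0  # codon index of current stop-delimited segment
    for idx in range(n_codons + 1):
        at_edge = idx == n_codons
        if at_edge or codons[idx] in _STOPS:
            # segment is codons[seg_start:idx]
            for j in range(seg_start, idx):
                if codons[j] == "ATG":
                    nt_length = 3 * (idx - j)
                    if nt_length > min_nt:
                        yield offset + 3 * j, nt_length
                    break
            seg_start = idx + 1


def six_frame_orfs(seq: NaSeq, min_nt: int = 200) -> list[OrfRecord]:
    """Extract ORFs with a start codon and nt length strictly > ``min_nt``
    from all six reading frames of a transcript.

    Coordinates are reported on the forward strand of the transcript
    (0-based, half-open); for negative frames the protein is the translation
    of the reverse complement of that span.
    """
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    if not seq.sequence:
        raise ValueError("empty sequence")
    fwd = seq.sequence
    rev = str(Seq(fwd).reverse_complement())
    n = len(fwd)
    records: list[OrfRecord] = []
    counter = 0
    for strand, working in ((1, fwd), (-1, rev)):
        for offset in range(3):
            for w_start, nt_length in _frame_orfs(working, offset, min_nt):
                counter += 1
                if strand == 1:
                    start, end = w_start, w_start + nt_length
                else:
                    start, end = n - (w_start + nt_length), n - w_start
                protein = translate(working[w_start : w_start + nt_length])
                records.append(
                    OrfRecord(
                        orf_id=f"{seq.id}.orf{counter}",
                        transcript_id=seq.id,
                        frame=strand * (offset + 1),
                        start=start,
                        end=end,
                        nt_length=nt_length,
                        protein=protein,
                    )
                )
    return records


def group_peptides(
    evidence: Iterable[PeptideEvidence], orfs: Sequence[OrfRecord]
) -> list[ProteinGroup]:
    """Merge ORFs that share an identical supporting-peptide set.

    Only ORFs supported by at least one peptide appear in the output; the
    minimum-peptide filter (1 vs 2 peptides) is applied downstream, not here.
    """
    known = {o.orf_id for o in orfs}
    support: dict[str, set[str]] = {}
    for ev in evidence:
        dangling = ev.matched_orf_ids - known
        if dangling:
            raise KeyError(f"peptide {ev.peptide!r} references unknown ORFs {sorted(dangling)}")
        for oid in ev.matched_orf_ids:
            support.setdefault(oid, set()).add(ev.peptide)
    by_set: dict[frozenset[str], list[str]] = {}
    for oid, peps in support.items():
        by_set.setdefault(frozenset(peps), []).append(oid)
    groups = []
    for peps, oids in sorted(by_set.items(), key=lambda kv: min(kv[1])):
        groups.append(
            ProteinGroup(
                group_id=f"G{len(groups) + 1:05d}",
                orf_ids=frozenset(oids),
                n_peptides=len(peps),
                peptides=peps,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> list[NaSeq]:
    return [NaSeq(r.id, str(r.seq), r.description) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in entries]
    SeqIO.write(records, str(path), "fasta")


def read_peptide_evidence(path) -> list[PeptideEvidence]:
    """TSV with columns ``peptide`` and ``orf_ids`` (comma-separated)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                PeptideEvidence(
                    peptide=row["peptide"],
                    matched_orf_ids=frozenset(x for x in row["orf_ids"].split(",") if x),
                )
            )
    return out


def write_peptide_evidence(evidence: Iterable[PeptideEvidence], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["peptide", "orf_ids"])
        for ev in sorted(evidence, key=lambda e: e.peptide):
            w.writerow([ev.peptide, ",".join(sorted(ev.matched_orf_ids))])


def write_orf_records(orfs: Sequence[OrfRecord], fasta_path, tsv_path) -> None:
    """Protein FASTA plus a TSV sidecar with 1-based inclusive coordinates."""
    write_fasta(((o.orf_id, o.protein) for o in orfs), fasta_path)
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["orf_id", "transcript_id", "frame", "start", "end", "nt_length"])
        for o in orfs:
            w.writerow([o.orf_id, o.transcript_id, f"{o.frame:+d}", o.start + 1, o.end, o.nt_length])


def read_orf_records(fasta_path, tsv_path) -> list[OrfRecord]:
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    with open(tsv_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                OrfRecord(
                    orf_id=row["orf_id"],
                    transcript_id=row["transcript_id"],
                    frame=int(row["frame"]),
                    start=int(row["start"]) - 1,
                    end=int(row["end"]),
                    nt_length=int(row["nt_length"]),
                    protein=proteins[row["orf_id"]],
                )
            )
    return out
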