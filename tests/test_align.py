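"""Local alignment, E-values and ranked search."""

import io

import numpy as np
import pytest

from pitkit.align import (
    DEFAULT_SCHEME,
    HomologyMatch,
    ScoringScheme,
    bit_score,
    evalue,
    read_tabular_matches,
    search,
    smith_waterman,
    write_tabular_matches,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# smith_waterman vs an exhaustive-enumeration oracle (<= 2 gap columns)


def sw_oracle(q: str, s: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Best local-alignment score by explicit path enumeration.

    Paths start and end on a substitution column and may contain at most two
    gap columns in total; a gap column costs open+extend when it opens a run
    and extend when it continues one.  For short peptides under BLOSUM62
    with 11/1 gap costs this space contains the optimum.
    """
    m = scheme.matrix
    open_cost = scheme.gap_open + scheme.gap_extend
    ext_cost = scheme.gap_extend
    best = 0

    def dfs(i, j, score, gapcols, last):
        nonlocal best
        if last == "D":
            best = max(best, score)
        if i < len(q) and j < len(s):
            dfs(i + 1, j + 1, score + m[q[i], s[j]], gapcols, "D")
        if gapcols < 2 and last is not None:
            if i < len(q):
                cost = ext_cost if last == "I" else open_cost
                dfs(i + 1, j, score - cost, gapcols + 1, "I")
            if j < len(s):
                cost = ext_cost if last == "J" else open_cost
                dfs(i, j + 1, score - cost, gapcols + 1, "J")

    for i in range(len(q)):
        for j in range(len(s)):
            dfs(i, j, 0, 0, None)
    return int(best)


def test_identical_sequences_align_perfectly():
    a = smith_waterman("MKWVTFISLLF", "MKWVTFISLLF")
    assert a.identities == 11
    assert a.aln_length == 11
    assert a.pct_identity == 100.0
    assert a.query_span == (0, 11) and a.subject_span == (0, 11)


def test_no_positive_cell_returns_none():
    assert smith_waterman("AAAA", "GGGG") is None


def test_empty_or_invalid_sequences_raise():
    with pytest.raises(ValueError):
        smith_waterman("", "MK")
    with pytest.raises(ValueError):
        smith_waterman("MK", "M*K")


def test_score_matches_enumeration_oracle_on_random_peptides():
    rng = np.random.default_rng(11)
    for _ in range(100):
        q = "".join(rng.choice(list(AA), size=6))
        s = "".join(rng.choice(list(AA), size=6))
        a = smith_waterman(q, s)
        got = a.raw_score if a else 0
        assert got == sw_oracle(q, s), (q, s)


def test_score_symmetry():
    rng = np.random.default_rng(5)
    for _ in range(200):
        q = "".join(rng.choice(list(AA), size=rng.integers(5, 30)))
        s = "".join(rng.choice(list(AA), size=rng.integers(5, 30)))
        a, b = smith_waterman(q, s), smith_waterman(s, q)
        assert (a.raw_score if a else 0) == (b.raw_score if b else 0)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def test_evalue_closed_form_regression():
    # E = K*m*n*exp(-lambda*S) at S=100, m=n=1000, lambda=0.267, K=0.041
    assert evalue(100, 1000, 1000) == pytest.approx(1.0402103961102521e-07, rel=1e-12)


def test_evalue_linear_in_db_length():
    assert evalue(80, 500, 2000) == pytest.approx(2 * evalue(80, 500, 1000))


def test_evalue_monotone_decreasing_in_score():
    for s in range(10, 200, 7):
        assert evalue(s + 1, 300, 1e6) < evalue(s, 300, 1e6)


def test_bitscore_evalue_equivalence():
    # E == m*n*2^(-bit score)
    s, m, n = 120, 400, 50_000
    assert evalue(s, m, n) == pytest.approx(m * n * 2 ** (-bit_score(s)), rel=1e-9)


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=1, gap_extend=2)
    with pytest.raises(ValueError):
        ScoringScheme(lam=-1)


# ---------------------------------------------------------------------------
# ranked search


def test_search_finds_identical_entry_first():
    rng = np.random.default_rng(2)
    query = "".join(rng.choice(list(AA), size=40))
    db = [("decoy%d" % i, "".join(rng.choice(list(AA), size=40))) for i in range(5)]
    db.append(("self", query))
    hits = search(query, db, query_id="q")
    assert hits[0].subject_id == "self"
    assert hits[0].pct_identity == 100.0


def test_search_tie_break_is_lexicographic():
    query = "MKWVTFISLLF"
    hits = search(query, [("zzz", query), ("aaa", query)])
    assert [h.subject_id for h in hits[:2]] == ["aaa", "zzz"]


def test_search_matches_all_pairs_oracle():
    rng = np.random.default_rng(3)
    queries = ["".join(rng.choice(list(AA), size=30)) for _ in range(15)]
    db = [(f"s{i:02d}", "".join(rng.choice(list(AA), size=30))) for i in range(15)]
    db_len = sum(len(s) for _, s in db)
    for q in queries:
        got = [(h.subject_id, h.raw_score) for h in search(q, db)]
        pairs = []
        for sid, sseq in db:
            a = smith_waterman(q, sseq)
            sc = a.raw_score if a else 0
            if sc >= 1:
                pairs.append((sid, sc, evalue(sc, len(q), db_len)))
        pairs.sort(key=lambda t: (-t[1], t[2], t[0]))
        assert got == [(sid, sc) for sid, sc, _ in pairs]


def test_search_invariant_to_db_order():
    rng = np.random.default_rng(9)
    query = "".join(rng.choice(list(AA), size=50))
    db = [(f"s{i}", "".join(rng.choice(list(AA), size=50))) for i in range(10)]
    a = search(query, db)
    b = search(query, list(reversed(db)))
    assert [(h.subject_id, h.raw_score) for h in a] == [(h.subject_id, h.raw_score) for h in b]


def test_metrics_bounded():
    rng = np.random.default_rng(13)
    for _ in range(50):
        q = "".join(rng.choice(list(AA), size=rng.integers(10, 60)))
        s = "".join(rng.choice(list(AA), size=rng.integers(10, 60)))
        for h in search(q, [("x", s)], query_id="q") or []:
            assert 0 <= h.pct_identity <= 100
            assert 0 <= h.query_coverage_pct <= 100


# ---------------------------------------------------------------------------
# tabular interoperability


ROW12 = "q1\ts1\t95.000\t100\t5\t0\t1\t100\t1\t100\t1e-30\t200.0"
ROW13 = ROW12 + "\t50.000"


def test_coverage_from_query_length():
    (m,) = read_tabular_matches(io.StringIO(ROW12 + "\n"), query_lengths={"q1": 200})
    assert m.query_coverage_pct == pytest.approx(50.0)
    assert m.query_span == (0, 100)


def test_mixed_12_and_13_column_rows():
    rows = ROW13 + "\n" + ROW12 + "\n"
    ms = read_tabular_matches(io.StringIO(rows), query_lengths={"q1": 200})
    assert len(ms) == 2
    assert ms[0].query_coverage_pct == pytest.approx(50.0)  # from column 13
    assert ms[1].query_coverage_pct == pytest.approx(50.0)  # computed


def test_malformed_rows_raise():
    with pytest.raises(ValueError):
        read_tabular_matches(io.StringIO("a\tb\tc\n"))
    with pytest.raises(ValueError):
        read_tabular_matches(io.StringIO(ROW12.replace("95.000", "many") + "\n"))
    with pytest.raises(KeyError):
        read_tabular_matches(io.StringIO(ROW12 + "\n"))  # no length table


def test_tabular_roundtrip():
    ms = read_tabular_matches(io.StringIO(ROW13 + "\n"))
    buf = io.StringIO()
    write_tabular_matches(ms, buf)
    back = read_tabular_matches(io.StringIO(buf.getvalue()))
    for a, b in zip(ms, back):
        assert a.subject_id == b.subject_id
        assert a.pct_identity == pytest.approx(b.pct_identity, abs=1e-3)
        assert a.query_coverage_pct == pytest.approx(b.query_coverage_pct, abs=1e-3)
        assert a.evalue == pytest.approx(b.evalue, rel=1e-2)
        assert a.query_span == b.query_span and a.subject_span == b.subject_span
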