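"""TE protein calling, calibration curves, QC and database concordance."""

import numpy as np
import pytest

from pitkit.align import smith_waterman
from pitkit.orfs import PeptideEvidence, ProteinGroup
from pitkit.simulate import make_calibration_fixture, mutate_protein
from pitkit.tecalls import (
    CalibrationCurve,
    TECall,
    TECallParams,
    TEEntry,
    call_tes,
    coverage_calibration,
    db_concordance,
    identity_calibration,
    qc_single_peptide,
    read_te_fasta,
    select_coverage_threshold,
    write_te_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _prot(rng, n=150):
    return "M" + "".join(rng.choice(list(AA), size=n - 1))


def _entry(te_id, protein, order="LTR", clade="Ty3/gypsy", orf="GAG", src="TEFAM"):
    klass = "II" if order in ("DNA_TIR", "HELITRON", "MITE") else "I"
    return TEEntry(te_id, src, klass, order, clade, orf, protein)


@pytest.fixture(scope="module")
def te_db():
    rng = np.random.default_rng(17)
    return [
        _entry("TF000001", _prot(rng, 150), "LTR", "Ty3/gypsy", "GAG"),
        _entry("TF000002", _prot(rng, 250), "LTR", "Ty3/gypsy", "POL"),
        _entry("TF000003", _prot(rng, 150), "NON_LTR", "Jockey", "ORF1"),
        _entry("TF000004", _prot(rng, 200), "DNA_TIR", "IS630-Tc1-mariner", "TRANSPOSASE"),
    ]


def test_identical_query_is_exact_tier(te_db):
    (call,) = call_tes([("q1", te_db[0].protein)], te_db)
    assert call.tier == "EXACT" and call.te_entry.te_id == "TF000001"


def test_thresholds_are_strict(te_db):
    # a match at exactly the identity floor must not be called
    params = TECallParams(identity_min_pct=100.0, exact_identity_pct=100.0)
    calls = call_tes([("q1", te_db[0].protein)], te_db, params)
    assert calls == []  # identity == 100 is not > 100


def test_diverged_copy_called_standard_then_lost_at_higher_floor(te_db):
    rng = np.random.default_rng(17)
    query = mutate_protein(te_db[1].protein, 0.55, rng)
    aln = smith_waterman(query, te_db[1].protein)
    assert 30 < aln.pct_identity < 60  # constructed divergence verified
    calls = call_tes([("q1", query)], te_db)
    assert len(calls) == 1 and calls[0].tier == "STANDARD"
    assert call_tes([("q1", query)], te_db, TECallParams(identity_min_pct=60)) == []


def test_raising_thresholds_never_adds_calls(te_db):
    rng = np.random.default_rng(23)
    queries = [("q%d" % i, mutate_protein(te_db[i % 4].protein, 0.1 * (i % 6), rng)) for i in range(12)]
    base = len(call_tes(queries, te_db))
    for params in (
        TECallParams(identity_min_pct=50),
        TECallParams(coverage_min_pct=70),
        TECallParams(evalue_max=1e-30),
    ):
        assert len(call_tes(queries, te_db, params)) <= base


# ---------------------------------------------------------------------------
# calibration


def test_background_without_te_homology_is_flat_zero(te_db):
    rng = np.random.default_rng(41)
    target = [("t1", te_db[0].protein)]
    background = [("b%d" % i, _prot(rng, 200)) for i in range(5)]
    ct, cb = coverage_calibration(target, background, te_db)
    assert all(p == 0 for p in cb.proportion_at_cutoff)
    assert select_coverage_threshold(ct, cb) == ct.grid[0]


def test_perfect_target_curve_shape(te_db):
    target = [("t%d" % i, e.protein) for i, e in enumerate(te_db)]
    ct, _ = coverage_calibration(target, [("b1", te_db[0].protein)], te_db)
    # full-coverage matches survive every cutoff below 100
    assert all(p == 1.0 for c, p in zip(ct.grid, ct.proportion_at_cutoff) if c < 100)
    assert ct.proportion_at_cutoff[-1] == 0.0  # coverage > 100 is impossible


def test_identity_grid_at_100_keeps_only_perfect_matches(te_db):
    rng = np.random.default_rng(19)
    target = [("t1", te_db[0].protein), ("t2", mutate_protein(te_db[1].protein, 0.2, rng))]
    ct, _ = identity_calibration(target, [("b1", _prot(rng))], te_db, grid=(0, 50, 100))
    assert ct.proportion_at_cutoff[-1] == 0.0
    assert ct.proportion_at_cutoff[0] == 1.0


def test_curves_monotone_on_random_fixtures(te_db):
    rng = np.random.default_rng(19)
    target = [("t%d" % i, mutate_protein(te_db[i % 4].protein, rng.uniform(0, 0.5), rng)) for i in range(10)]
    background = [("b%d" % i, _prot(rng, 180)) for i in range(10)]
    for curve in coverage_calibration(target, background, te_db) + identity_calibration(
        target, background, te_db
    ):
        p = curve.proportion_at_cutoff
        assert all(a >= b for a, b in zip(p, p[1:]))


def test_calibration_matches_bruteforce_filter(te_db):
    from pitkit.tecalls import _top_hits

    rng = np.random.default_rng(29)
    target = [("t%d" % i, mutate_protein(te_db[i % 4].protein, 0.3, rng)) for i in range(8)]
    background = [("b%d" % i, _prot(rng, 180)) for i in range(8)]
    hits = _top_hits(target, te_db, __import__("pitkit.align", fromlist=["DEFAULT_SCHEME"]).DEFAULT_SCHEME)
    ct, _ = identity_calibration(target, background, te_db, grid=(30, 40, 50))
    for c, p in zip(ct.grid, ct.proportion_at_cutoff):
        manual = sum(
            1
            for h in hits.values()
            if h is not None
            and h[1].evalue < 1e-5
            and h[1].query_coverage_pct > 45
            and h[1].pct_identity > c
        ) / len(target)
        assert p == pytest.approx(manual)


def test_knee_selection_on_constructed_curves():
    """Curves mimicking the published shapes: background drops fast, target
    resists to ~75% coverage; the knee sits at 45."""
    grid = tuple(range(0, 101, 5))
    target = tuple(0.16 if c <= 75 else 0.02 for c in grid)
    background = tuple(0.007 if c == 0 else (0.004 if c < 45 else 0.0) for c in grid)
    assert select_coverage_threshold(
        CalibrationCurve("TARGET", "COVERAGE", grid, target),
        CalibrationCurve("BACKGROUND", "COVERAGE", grid, background),
    ) == 45


def test_identical_curves_fall_back_to_max_difference():
    grid = (0.0, 50.0, 100.0)
    flat = (0.5, 0.5, 0.5)
    c = CalibrationCurve("TARGET", "COVERAGE", grid, flat)
    b = CalibrationCurve("BACKGROUND", "COVERAGE", grid, flat)
    assert select_coverage_threshold(c, b) == 0.0


def test_synthetic_fixture_knee_recovered():
    target, background, db = make_calibration_fixture(seed=11)
    ct, cb = coverage_calibration(target, background, db)
    assert cb.proportion_at_cutoff[ct.grid.index(45)] == 0.0  # background collapsed
    assert select_coverage_threshold(ct, cb) == 45


def test_mismatched_grids_rejected():
    a = CalibrationCurve("TARGET", "COVERAGE", (0.0, 50.0), (1.0, 1.0))
    b = CalibrationCurve("BACKGROUND", "COVERAGE", (0.0, 45.0), (1.0, 1.0))
    with pytest.raises(ValueError):
        select_coverage_threshold(a, b)


# ---------------------------------------------------------------------------
# single-peptide QC


def _call(query_id, entry, identity=80.0, coverage=90.0):
    from pitkit.align import HomologyMatch

    m = HomologyMatch(query_id, entry.te_id, "TE", 500, 100.0, 1e-40, identity, coverage)
    return TECall(query_id, entry, m, "STANDARD")


def test_multi_peptide_calls_always_retained(te_db):
    groups = [ProteinGroup("G1", frozenset({"o1"}), 3, frozenset({"AAAAAAAA", "CCCCCCCC", "DDDDDDDD"}))]
    ev = [PeptideEvidence("AAAAAAAA", frozenset({"o1", "o9"}))]
    calls = [_call("G1", te_db[0])]
    assert qc_single_peptide(calls, groups, ev) == calls


def test_unique_single_peptide_retained(te_db):
    groups = [ProteinGroup("G1", frozenset({"o1"}), 1, frozenset({"AAAAAAAA"}))]
    ev = [PeptideEvidence("AAAAAAAA", frozenset({"o1"}))]
    calls = [_call("G1", te_db[0])]
    assert qc_single_peptide(calls, groups, ev) == calls


def test_promiscuous_single_peptide_removed(te_db):
    """A single peptide shared with an ORF called to a different order."""
    groups = [
        ProteinGroup("G1", frozenset({"o1"}), 1, frozenset({"AAAAAAAA"})),
        ProteinGroup("G2", frozenset({"o2"}), 2, frozenset({"AAAAAAAA", "EEEEEEEE"})),
    ]
    ev = [
        PeptideEvidence("AAAAAAAA", frozenset({"o1", "o2"})),
        PeptideEvidence("EEEEEEEE", frozenset({"o2"})),
    ]
    calls = [_call("G1", te_db[0]), _call("G2", te_db[3])]  # LTR vs DNA_TIR
    kept = qc_single_peptide(calls, groups, ev)
    assert [c.query_id for c in kept] == ["G2"]


def test_single_peptide_shared_with_non_te_orf_removed(te_db):
    groups = [ProteinGroup("G1", frozenset({"o1"}), 1, frozenset({"AAAAAAAA"}))]
    ev = [PeptideEvidence("AAAAAAAA", frozenset({"o1", "host_orf"}))]
    calls = [_call("G1", te_db[0])]
    assert qc_single_peptide(calls, groups, ev) == []


# ---------------------------------------------------------------------------
# database concordance


def test_identical_call_sets_fully_agree(te_db):
    calls = [_call("q%d" % i, te_db[i % 4]) for i in range(6)]
    c = db_concordance(calls, calls)
    assert c["order_agreement"] == 1.0 and c["clade_agreement"] == 1.0
    assert c["n_shared"] == 6


def test_disjoint_call_sets_have_no_shared_queries(te_db):
    a = [_call("qa", te_db[0])]
    b = [_call("qb", te_db[1])]
    c = db_concordance(a, b)
    assert c["n_shared"] == 0 and c["order_agreement"] is None


def test_constructed_overlap_agreement_fractions(te_db):
    """8 shared queries, 2 order-level and 4 clade-level disagreements."""
    ltr_g, ltr_p, nonltr, tir = te_db
    other_clade = _entry("RB1", ltr_g.protein, "LTR", "BEL", "GAG", "REPBASE")
    primary = [_call("q%d" % i, ltr_g) for i in range(8)]
    secondary = (
        [_call("q%d" % i, ltr_g) for i in range(4)]  # full agreement
        + [_call("q%d" % i, other_clade) for i in range(4, 6)]  # clade mismatch only
        + [_call("q%d" % i, tir) for i in range(6, 8)]  # order mismatch
    )
    c = db_concordance(primary, secondary)
    assert c["n_shared"] == 8
    assert c["order_agreement"] == pytest.approx(0.75)
    assert c["clade_agreement"] == pytest.approx(0.50)


# ---------------------------------------------------------------------------
# metadata formats


def test_te_fasta_roundtrip(tmp_path, te_db):
    p = tmp_path / "te.fasta"
    write_te_fasta(te_db, p)
    back = read_te_fasta(p)
    assert back == list(te_db)


def test_te_entry_invariants():
    with pytest.raises(ValueError):
        _entry("x", "MKL", order="LTR", orf="TRANSPOSASE")  # LTR cannot carry a transposase
    with pytest.raises(ValueError):
        _entry("x", "MKL", order="NON_LTR", orf="GAG")
    with pytest.raises(ValueError):
        TECallParams(exact_identity_pct=20)
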