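"""Transcript-to-genome mapping, triage, gap scanning and hotspot detection."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats as sstats

from pitkit.annotate import (
    AnnotatedGene,
    CAT_ALREADY_ANNOTATED,
    CAT_AMBIGUOUS,
    CAT_NEW_ANNOTATION,
    CAT_NO_MATCH,
    GenomeAlignmentHit,
    TriageParams,
    align_transcripts,
    band_hotspots,
    chromosome_enrichment,
    gap_scan,
    matched_control_sample,
    triage,
    ttest_equal_var,
)


def _rand_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(101)
    return {"sc1": _rand_nt(rng, 12000), "sc2": _rand_nt(rng, 12000)}, rng


# ---------------------------------------------------------------------------
# built-in mapper


def test_exact_substring_single_block(toy_genome):
    genome, _ = toy_genome
    tx = genome["sc1"][2000:3000]
    hits = align_transcripts([("t1", tx)], genome)["t1"]
    assert hits, "exact substring must map"
    h = hits[0]
    assert h.supercontig == "sc1" and h.strand == "+"
    assert h.pct_identity == 100.0
    assert h.blocks[0][0] == 2000 and h.blocks[-1][1] == 3000
    assert len(h.blocks) == 1


def test_two_exon_transcript_reconstructed(toy_genome):
    genome, _ = toy_genome
    exon1 = genome["sc2"][1000:1600]
    exon2 = genome["sc2"][2100:2700]  # 500 bp intron
    hits = align_transcripts([("t1", exon1 + exon2)], genome)["t1"]
    h = hits[0]
    assert len(h.blocks) == 2
    assert h.blocks[0] == (1000, 1600) and h.blocks[1] == (2100, 2700)
    assert h.transcript_coverage_pct == pytest.approx(100.0)


def test_reverse_complement_maps_minus_strand(toy_genome):
    genome, _ = toy_genome
    tx = str(Seq(genome["sc1"][4000:5000]).reverse_complement())
    h = align_transcripts([("t1", tx)], genome)["t1"][0]
    assert h.strand == "-"
    assert h.blocks[0][0] == 4000 and h.blocks[-1][1] == 5000


def test_unmappable_transcript_reports_empty(toy_genome):
    genome, _ = toy_genome
    rng = np.random.default_rng(555)
    assert align_transcripts([("t1", _rand_nt(rng, 800))], genome)["t1"] == []


# ---------------------------------------------------------------------------
# triage


def _hit(tid, sc, start, end, strand="+", identity=99.0, coverage=98.0, score=900.0):
    return GenomeAlignmentHit(tid, sc, strand, ((start, end),), identity, coverage, score)


def test_triage_categories_partition():
    hits = {
        "t_none": [],
        "t_low": [_hit("t_low", "sc1", 0, 500, identity=50.0)],
        "t_amb": [_hit("t_amb", "sc1", 0, 500), _hit("t_amb", "sc2", 0, 500, score=880.0)],
        "t_ann": [_hit("t_ann", "sc1", 1000, 1500)],
        "t_new": [_hit("t_new", "sc2", 1000, 1500)],
    }
    ann = [AnnotatedGene("g1", "sc1", "+", 1200, 2000)]
    records = triage(hits, ann)
    by = {r.transcript_id: r.category for r in records}
    assert by == {
        "t_none": CAT_NO_MATCH,
        "t_low": CAT_NO_MATCH,
        "t_amb": CAT_AMBIGUOUS,
        "t_ann": CAT_ALREADY_ANNOTATED,
        "t_new": CAT_NEW_ANNOTATION,
    }
    assert len(records) == len(hits)


def test_opposite_strand_overlap_is_new_annotation():
    hits = {"t1": [_hit("t1", "sc1", 1000, 1500, strand="-")]}
    ann = [AnnotatedGene("g1", "sc1", "+", 1200, 2000)]
    (r,) = triage(hits, ann)
    assert r.category == CAT_NEW_ANNOTATION


def test_empty_annotation_yields_no_already_annotated():
    hits = {"t1": [_hit("t1", "sc1", 0, 500)]}
    records = triage(hits, [])
    assert records[0].category == CAT_NEW_ANNOTATION


def test_ambiguity_respects_margin():
    close = {"t": [_hit("t", "sc1", 0, 500, score=1000.0), _hit("t", "sc2", 0, 500, score=960.0)]}
    far = {"t": [_hit("t", "sc1", 0, 500, score=1000.0), _hit("t", "sc2", 0, 500, score=700.0)]}
    assert triage(close, [])[0].category == CAT_AMBIGUOUS
    assert triage(far, [])[0].category == CAT_NEW_ANNOTATION


# ---------------------------------------------------------------------------
# gap scan


def test_gap_scan_clean_window(toy_genome):
    genome, _ = toy_genome
    rec = gap_scan(genome, _hit("t1", "sc1", 6000, 6500), flank_nt=2000)
    assert not rec.has_gap and rec.n_count_in_window == 0


def test_gap_scan_detects_planted_run():
    rng = np.random.default_rng(7)
    seq = _rand_nt(rng, 20000)
    seq = seq[:9000] + "N" * 100 + seq[9100:]  # run 3 kb downstream of the span
    genome = {"sc": seq}
    rec = gap_scan(genome, _hit("t1", "sc", 5000, 6000), flank_nt=5000)
    assert rec.has_gap and rec.n_count_in_window >= 100


def test_gap_scan_truncation_flagged(toy_genome):
    genome, _ = toy_genome
    rec = gap_scan(genome, _hit("t1", "sc1", 1000, 1500), flank_nt=5000)
    assert rec.truncated_upstream and not rec.truncated_downstream
    with pytest.raises(KeyError):
        gap_scan(genome, _hit("t1", "nope", 0, 10))


# ---------------------------------------------------------------------------
# matched controls


def test_matched_control_exact_pool():
    targets = [("t%d" % i, 500 + 10 * i) for i in range(20)]
    pool = [("p%d" % i, 500 + 10 * i) for i in range(20)]
    controls = matched_control_sample(targets, pool, seed=23)
    lengths = {pid: l for pid, l in pool}
    assert len(controls) == 20
    assert np.mean([lengths[c] for c in controls]) == pytest.approx(
        np.mean([l for _, l in targets])
    )


def test_matched_control_deterministic():
    rng = np.random.default_rng(23)
    targets = [("t%d" % i, int(rng.integers(300, 3000))) for i in range(40)]
    pool = [("p%d" % i, int(rng.integers(300, 3000))) for i in range(400)]
    a = matched_control_sample(targets, pool, seed=23)
    b = matched_control_sample(targets, pool, seed=23)
    assert a == b
    lengths = dict(pool)
    tmean = np.mean([l for _, l in targets])
    assert abs(np.mean([lengths[c] for c in a]) - tmean) <= 0.05 * tmean


def test_pool_too_small_rejected():
    with pytest.raises(ValueError):
        matched_control_sample([("a", 1), ("b", 2)], [("p", 1)], seed=0)


# ---------------------------------------------------------------------------
# chromosome / band enrichment


def _map3():
    # three chromosomes, two contigs each
    out = {}
    for i, chrom in enumerate(["1", "1", "2", "2", "3", "3"]):
        out[f"sc{i}"] = (chrom, f"{chrom}p1")
    return out


def _new(tid, sc):
    from pitkit.annotate import TriageRecord

    return TriageRecord(tid, CAT_NEW_ANNOTATION, _hit(tid, sc, 0, 500), 1)


def test_uniform_distribution_gives_unit_ratios():
    records = [_new("t0", "sc0"), _new("t2", "sc2"), _new("t4", "sc4")]
    df = chromosome_enrichment(records, _map3()).set_index("chromosome")
    assert df["normalized_ratio"].tolist() == pytest.approx([1.0, 1.0, 1.0])


def test_all_hits_on_one_chromosome():
    records = [_new("t0", "sc0"), _new("t1", "sc1")]
    df = chromosome_enrichment(records, _map3()).set_index("chromosome")
    assert df.loc["1", "normalized_ratio"] == pytest.approx(3.0)
    assert df.loc["2", "normalized_ratio"] == 0.0


def test_supercontig_counted_once():
    records = [_new("ta", "sc0"), _new("tb", "sc0")]
    df = chromosome_enrichment(records, _map3()).set_index("chromosome")
    assert df.loc["1", "pit_supercontigs"] == 1


def test_band_hotspots_hand_computed():
    """10 bands with counts 6,5,4,1,... -> top-2 flagged (ceil(0.2*10)=2)."""
    chr_map = {f"c{i}": ("1", f"1b{i}") for i in range(10)}
    records = []
    k = 0
    for band_i, n in [(0, 6), (1, 5), (2, 4), (3, 1)]:
        for _ in range(n):
            records.append(_new(f"t{k}", f"c{band_i}"))
            k += 1
    df = band_hotspots(records, chr_map)
    flagged = set(df[df["enriched"]]["band"])
    assert flagged == {"1b0", "1b1"}  # count 4 ranks 3rd, outside the top 20%


def test_band_hotspots_require_more_than_two():
    chr_map = {f"c{i}": ("1", f"1b{i}") for i in range(5)}
    records = [_new("t0", "c0"), _new("t1", "c0")]  # top band has only 2
    df = band_hotspots(records, chr_map)
    assert not df["enriched"].any()


def test_single_band_holding_all_annotations():
    chr_map = {"c0": ("1", "1p1")}
    records = [_new(f"t{i}", "c0") for i in range(4)]
    df = band_hotspots(records, chr_map)
    assert df[df["band"] == "1p1"]["enriched"].iloc[0]


# ---------------------------------------------------------------------------
# equal-variance t-test


def test_ttest_identical_samples():
    assert ttest_equal_var([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)


def test_ttest_antisymmetric():
    t1, p1 = ttest_equal_var([1, 2, 3, 7], [2, 3, 4])
    t2, p2 = ttest_equal_var([2, 3, 4], [1, 2, 3, 7])
    assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


def test_ttest_matches_closed_form_oracle():
    """x=[1,2,3], y=[2,3,4]: pooled s^2=1, t=-1/sqrt(2/3), df=4."""
    x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    t, p = ttest_equal_var(x, y)
    t_oracle = (2.0 - 3.0) / math.sqrt(1.0 * (1 / 3 + 1 / 3))
    p_oracle = 2 * sstats.t.sf(abs(t_oracle), df=4)
    assert t == pytest.approx(t_oracle, rel=1e-12)
    assert t == pytest.approx(-1.224744871391589, rel=1e-9)
    assert p == pytest.approx(p_oracle, rel=1e-12)
    assert p == pytest.approx(0.2878641347266908, rel=1e-6)


def test_ttest_degenerate_cases():
    with pytest.raises(ValueError):
        ttest_equal_var([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        ttest_equal_var([1.0, 1.0], [2.0, 2.0])  # zero variance, unequal means
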