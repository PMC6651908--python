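"""Read QC: pair filters, clean-pair logic, dedup, subsampling, reports."""

import numpy as np
import pandas as pd
import pytest

from asmeval import qc, synth
from asmeval.core import ReadRecord

ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


def make_pair(seq1="ACGT" * 25, seq2="TGCA" * 25, q1=30, q2=30):
    return (ReadRecord("p", 1, seq1, [q1] * len(seq1)),
            ReadRecord("p", 2, seq2, [q2] * len(seq2)))


def thresholds(**kw):
    return qc.QcThresholds(adapters=(ADAPTER,), **kw)


# ------------------------------------------------------------- pair filter


def test_clean_pair_kept():
    assert qc.filter_read_pair(make_pair(), thresholds()) == "keep"


def test_low_quality_rule_is_strict():
    t = thresholds()
    seq = "A" * 100
    # exactly 10% low-quality bases: not dropped (strictly more required)
    q = [9] * 10 + [30] * 90
    pair = (ReadRecord("p", 1, seq, q), ReadRecord("p", 2, seq, [30] * 100))
    assert qc.filter_read_pair(pair, t) == "keep"
    q = [9] * 11 + [30] * 89
    pair = (ReadRecord("p", 1, seq, q), ReadRecord("p", 2, seq, [30] * 100))
    assert qc.filter_read_pair(pair, t) == "drop:low_quality"
    # phred exactly at the threshold does not count as low-quality
    q = [10] * 100
    pair = (ReadRecord("p", 1, seq, q), ReadRecord("p", 2, seq, [30] * 100))
    assert qc.filter_read_pair(pair, t) == "keep"


def test_ambiguous_rule_is_strict():
    t = thresholds()
    base = "A" * 99
    pair = make_pair(seq1=base + "N", seq2="A" * 100)
    assert qc.filter_read_pair(pair, t) == "keep"  # exactly 1%
    pair = make_pair(seq1="NN" + "A" * 98, seq2="A" * 100)
    assert qc.filter_read_pair(pair, t) == "drop:ambiguous"


def test_adapter_anchored_geometry():
    t = thresholds()
    half = len(ADAPTER) - len(ADAPTER) // 2  # ceil(len/2)
    prefix = ADAPTER[:half]
    # adapter prefix at the read's 3' end: dropped
    read = "C" * (100 - half) + prefix
    assert qc.filter_read_pair(make_pair(seq1=read), t) == "drop:adapter"
    # same bases in the middle of the read: not anchored, kept
    read = "C" * 40 + prefix + "C" * (60 - half)
    assert qc.filter_read_pair(make_pair(seq1=read), t) == "keep"
    # one mismatch tolerated, two are not
    one_mm = "T" + prefix[1:]
    read = "C" * (100 - half) + one_mm
    assert qc.filter_read_pair(make_pair(seq1=read), t) == "drop:adapter"
    two_mm = "TT" + prefix[2:]
    read = "C" * (100 - half) + two_mm
    assert qc.filter_read_pair(make_pair(seq1=read), t) == "keep"


def test_full_adapter_readthrough_detected():
    t = thresholds()
    read = "C" * (100 - len(ADAPTER)) + ADAPTER
    assert qc.filter_read_pair(make_pair(seq2=read), t) == "drop:adapter"


def test_category_priority_order():
    # a pair failing both adapter and quality is recorded as adapter
    t = thresholds()
    read = "C" * (100 - len(ADAPTER)) + ADAPTER
    pair = (ReadRecord("p", 1, read, [5] * 100),
            ReadRecord("p", 2, "A" * 100, [30] * 100))
    assert qc.filter_read_pair(pair, t) == "drop:adapter"


def test_filter_pairs_recovers_synthetic_labels():
    labelled = synth.simulate_qc_reads(400, 100, [ADAPTER], seed=5)
    t = thresholds()
    for pair, label in labelled:
        verdict = qc.filter_read_pair(pair, t)
        expected = "keep" if label == "keep" else f"drop:{label}"
        assert verdict == expected
    kept, counts = qc.filter_pairs([p for p, _ in labelled], t)
    truth = pd.Series([lb for _, lb in labelled]).value_counts()
    assert len(kept) == truth.get("keep", 0)
    for cat in ("adapter", "low_quality", "ambiguous"):
        assert counts[cat] == truth.get(cat, 0)


# -------------------------------------------------------- clean-pair filter


def placement_frame(rows):
    return pd.DataFrame(rows, columns=qc.PLACEMENT_COLUMNS)


def test_clean_pair_filter_orientation_and_span():
    rows = [
        ("ok", "chr1", 100, "+", 300, "-", True),
        ("ok_swapped", "chr1", 300, "-", 100, "+", True),  # mate order free
        ("same_strand", "chr1", 100, "+", 300, "+", True),
        ("divergent", "chr1", 300, "+", 100, "-", True),
        ("too_far", "chr1", 100, "+", 20_000, "-", True),
        ("improper", "chr1", 100, "+", 300, "-", False),
    ]
    kept = qc.clean_pair_filter(placement_frame(rows), max_span=10_000)
    assert set(kept) == {"ok", "ok_swapped"}


def test_clean_pair_filter_span_boundary():
    # outer span exactly max_span is kept (at most max_span)
    rows = [("edge", "chr1", 0, "+", 900, "-", True)]
    kept = qc.clean_pair_filter(placement_frame(rows), max_span=1000)
    assert set(kept) == {"edge"}
    kept = qc.clean_pair_filter(placement_frame(rows), max_span=800)
    assert set(kept) == set()


# ------------------------------------------------------------------- dedup


def test_deduplicate_both_mate_convention():
    rows = [
        ("a", "chr1", 100, "+", 300, "-", True),
        ("b", "chr1", 100, "+", 300, "-", True),   # duplicate of a
        ("c", "chr1", 100, "+", 301, "-", True),   # differs in mate-2 pos
        ("d", "chr1", 100, "-", 300, "+", True),   # differs in strands
        ("e", "chr2", 100, "+", 300, "-", True),   # different sequence
    ]
    kept = qc.deduplicate(placement_frame(rows))
    assert set(kept) == {"a", "c", "d", "e"}


def test_deduplicate_keeps_first_by_pair_id():
    rows = [
        ("z_late", "chr1", 100, "+", 300, "-", True),
        ("a_early", "chr1", 100, "+", 300, "-", True),
    ]
    kept = qc.deduplicate(placement_frame(rows))
    assert set(kept) == {"a_early"}


def test_duplicate_injection_rate_recovered():
    import dataclasses

    cfg = dataclasses.replace(synth.preset_completeness(seed=3),
                              duplicate_rate=0.3)
    genome, ann, truth = synth.simulate_genome_annotation(cfg)
    reads, placements = synth.simulate_reads(genome, truth, cfg, 20_000)
    kept = qc.deduplicate(placements)
    removed = 1 - len(kept) / len(placements)
    # every injected duplicate is removed; chance coordinate collisions
    # between independent pairs can remove slightly more
    assert removed >= reads["duplicate"].mean() - 1e-9
    assert removed == pytest.approx(0.3, abs=0.02)


# -------------------------------------------------------------- subsampling


def test_subsample_nesting_and_size():
    rng = np.random.default_rng(0)
    pairs = pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(500)],
        "bases": 200,
    })
    prev = None
    for target in (1000, 5000, 20_000, 60_000):
        sub = qc.subsample_to_bases(pairs, target, seed=7)
        got = sub["bases"].sum()
        assert got >= target and got - target < 200  # first pair crossing
        if prev is not None:
            assert set(prev["pair_id"]).issubset(set(sub["pair_id"]))
        prev = sub
    # deterministic given the seed
    again = qc.subsample_to_bases(pairs, 20_000, seed=7)
    assert list(again["pair_id"]) == list(
        qc.subsample_to_bases(pairs, 20_000, seed=7)["pair_id"])
    del rng


def test_subsample_whole_library_when_small():
    pairs = pd.DataFrame({"pair_id": ["a", "b"], "bases": [200, 200]})
    sub = qc.subsample_to_bases(pairs, 10_000, seed=0)
    assert len(sub) == 2


def test_subsample_rejects_nonpositive_target():
    pairs = pd.DataFrame({"pair_id": ["a"], "bases": [200]})
    with pytest.raises(ValueError):
        qc.subsample_to_bases(pairs, 0, seed=0)


# ----------------------------------------------------------------- pooling


def test_pool_libraries_prefixes_pair_ids():
    a = pd.DataFrame({"pair_id": ["x", "y"], "bases": [200, 200]})
    b = pd.DataFrame({"pair_id": ["x"], "bases": [200]})
    pooled = qc.pool_libraries({"libA": a, "libB": b})
    assert sorted(pooled["pair_id"]) == ["libA:x", "libA:y", "libB:x"]
    assert len(pooled) == 3  # same raw ids no longer collide


# ------------------------------------------------------------- step report


def test_step_report_percent_convention():
    steps = pd.DataFrame([
        {"platform": "P", "library": "l1",
         "raw": 1000, "filtered": 900, "deduplicated": 450},
        {"platform": "P", "library": "l2",
         "raw": 3000, "filtered": 2100, "deduplicated": 1050},
    ])
    rep = qc.build_step_report(steps)
    # aggregates sum libraries before dividing: (4000-3000)/4000
    assert rep.pct_removed("P", "filtered") == pytest.approx(25.0)
    assert rep.pct_removed("P", "deduplicated") == pytest.approx(50.0)
    assert rep.total("P", "deduplicated") == 1500
    lib = rep.per_library.set_index("library")
    assert lib.loc["l1", "pct_removed_filtered"] == pytest.approx(10.0)
    assert lib.loc["l2", "pct_removed_filtered"] == pytest.approx(30.0)


def test_step_report_rejects_increasing_counts():
    steps = pd.DataFrame([{"platform": "P", "library": "l",
                           "raw": 100, "filtered": 150}])
    with pytest.raises(ValueError):
        qc.build_step_report(steps)


def test_step_report_category_pct():
    steps = pd.DataFrame([{"platform": "P", "library": "l",
                           "raw": 1000, "filtered": 900}])
    cats = pd.DataFrame([{"platform": "P", "library": "l",
                          "adapter": 40, "low_quality": 50, "ambiguous": 10}])
    rep = qc.build_step_report(steps, cats)
    assert rep.category_pct("P", "adapter") == pytest.approx(4.0)
    assert rep.category_pct("P", "low_quality") == pytest.approx(5.0)


def test_report_tsv_round_trip(tmp_path):
    steps = pd.DataFrame([{"platform": "P", "library": "l",
                           "raw": 100, "filtered": 90}])
    rep = qc.build_step_report(steps)
    path = tmp_path / "report.tsv"
    qc.write_report_tsv(rep, path)
    text = path.read_text()
    assert "pct_removed_filtered" in text and "aggregate" in text
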