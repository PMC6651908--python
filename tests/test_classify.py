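"""Scaffold classification: fractions, exon structure, ORFs, sweeps."""

import numpy as np
import pandas as pd
import pytest

from asmeval import classify as cl
from asmeval.core import AnnotationSet, Block, BlockAlignment, Transcript


def aln(blocks, qsize=None, tname="chr1", qname="s"):
    if qsize is None:
        qsize = sum(b.size for b in blocks)
    m = sum(b.size for b in blocks)
    return BlockAlignment(qname, qsize, tname, 10_000, "+", blocks, m)


# ---------------------------------------------------- annotation fraction


def test_annotation_fraction_both_denominators():
    t = Transcript("t", "g", "chr1", "+", [(100, 200)])
    # scaffold of 50 bases fully inside the exon: overlap 50,
    # 50/50 = 1.0 beats 50/100
    a = aln([Block(0, 120, 50)])
    assert cl.annotation_fraction(a, t) == pytest.approx(1.0)
    # scaffold of 400 bases covering the whole exon: overlap 100,
    # max(100/400, 100/100) = 1.0 via the transcript denominator
    a = aln([Block(0, 50, 400)], qsize=400)
    assert cl.annotation_fraction(a, t) == pytest.approx(1.0)
    # half overlap both ways
    a = aln([Block(0, 150, 100)], qsize=100)
    assert cl.annotation_fraction(a, t) == pytest.approx(
        max(50 / 100, 50 / 100))


def test_annotation_fraction_other_sequence_is_zero():
    t = Transcript("t", "g", "chr2", "+", [(100, 200)])
    assert cl.annotation_fraction(aln([Block(0, 120, 50)]), t) == 0.0


def test_best_annotation_fraction_picks_maximum():
    ann = AnnotationSet([
        Transcript("near", "g1", "chr1", "+", [(0, 50)]),
        Transcript("far", "g2", "chr1", "+", [(95, 200)]),
    ])
    a = aln([Block(0, 90, 100)], qsize=100)
    frac, tid = cl.best_annotation_fraction(a, ann)
    assert tid == "far"
    assert frac == pytest.approx(95 / 100)


def test_annotation_fraction_oracle_randomized():
    rng = np.random.default_rng(7)
    for _ in range(300):
        exons = sorted(rng.choice(200, size=4, replace=False))
        t = Transcript("t", "g", "chr1", "+",
                       [(exons[0], exons[1]), (exons[2], exons[3])]
                       if exons[1] < exons[2] else [(exons[0], exons[1])])
        bs = int(rng.integers(0, 150))
        blen = int(rng.integers(1, 60))
        a = aln([Block(0, bs, blen)], qsize=blen + int(rng.integers(0, 20)))
        emask = np.zeros(400, dtype=bool)
        for s, e in t.exons:
            emask[s:e] = True
        amask = np.zeros(400, dtype=bool)
        amask[bs:bs + blen] = True
        ov = int((emask & amask).sum())
        expected = max(ov / a.qsize, ov / t.length)
        assert cl.annotation_fraction(a, t) == pytest.approx(expected)


# --------------------------------------------------------- exon structure


def test_exon_structure_intron_and_query_gap_rules():
    # target gap >= 30 with small query gap: an intron boundary
    a = aln([Block(0, 0, 50), Block(50, 80, 50)])
    assert cl.exon_structure(a) == (2, False)
    # target gap below the floor: one exon
    a = aln([Block(0, 0, 50), Block(50, 70, 50)])
    assert cl.exon_structure(a) == (1, True)
    # large query gap alongside the target gap: unaligned insertion,
    # not an intron
    a = aln([Block(0, 0, 50), Block(80, 100, 50)], qsize=130)
    assert cl.exon_structure(a) == (1, True)


def test_intronic_fraction():
    ann = AnnotationSet([
        Transcript("t", "g", "chr1", "+", [(0, 100), (200, 300)]),
    ])
    a = aln([Block(0, 150, 100)], qsize=100)  # [150,250): 50 intronic bases
    assert cl.intronic_fraction(a, ann) == pytest.approx(0.5)


# ------------------------------------------------------------------ ORFs


def orf_oracle(seq, min_aa):
    comp = str.maketrans("ACGT", "TGCA")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for s in (seq, seq.translate(comp)[::-1]):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            for i, c in enumerate(codons):
                if c != "ATG":
                    continue
                for j in range(i + 1, len(codons)):
                    if codons[j] in stops:
                        best = max(best, j - i)
                        break
    return best >= min_aa, best


def test_find_orfs_exact_cases():
    assert cl.find_orfs("ATG" + "GCT" * 5 + "TAA", min_aa=6) == (True, 6)
    # no stop codon: no ORF
    assert cl.find_orfs("ATG" + "GCT" * 50, min_aa=1) == (False, 0)
    # ORF on the reverse strand
    fwd = "ATG" + "GAA" * 4 + "TGA"
    comp = str.maketrans("ACGT", "TGCA")
    rc = fwd.translate(comp)[::-1]
    assert cl.find_orfs(rc, min_aa=5) == (True, 5)


def test_find_orfs_oracle_randomized():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for _ in range(300):
        seq = "".join(rng.choice(bases, size=int(rng.integers(30, 120))))
        assert cl.find_orfs(seq, 5) == orf_oracle(seq, 5)


# ------------------------------------------------------------ thresholds


def records_frame(fractions, single_exon=None, intronic=None):
    n = len(fractions)
    return pd.DataFrame({
        "scaffold_id": [f"s{i}" for i in range(n)],
        "length": [400] * n,
        "fraction": fractions,
        "best_transcript": ["t"] * n,
        "exon_count": [1] * n,
        "single_exon": single_exon if single_exon is not None else [True] * n,
        "intronic_fraction": [0.0] * n,
        "intronic": intronic if intronic is not None else [False] * n,
    })


def test_classify_annotated_strict_threshold():
    rec = records_frame([0.80, 0.801, 1.0])
    table = cl.classify_annotated(rec).set_index("threshold")
    # at t=80 a fraction of exactly 0.80 is NOT annotated
    assert table.loc[80, "n_annotated"] == 2
    assert table.loc[80, "n_unannotated"] == 1
    assert table.loc[0, "n_annotated"] == 3
    assert table.loc[100, "n_annotated"] == 0  # 1.0 > 1.0 is false


def test_classify_annotated_monotone_and_conserves_total():
    rng = np.random.default_rng(3)
    rec = records_frame(list(rng.random(200)))
    table = cl.classify_annotated(rec)
    counts = table["n_annotated"].to_numpy()
    assert (np.diff(counts) <= 0).all()
    assert (table["n_annotated"] + table["n_unannotated"] == 200).all()


def test_classify_intronic_sei():
    rec = records_frame(
        [0.1, 0.2, 0.3, 0.9],
        single_exon=[True, True, False, True],
        intronic=[True, False, True, True],
    )
    flags, sei = cl.classify_intronic(rec, threshold=80)
    # unannotated single-exon: s0, s1 -> one intronic
    assert sei == pytest.approx(0.5)
    assert len(flags) == 2
    _, sei_empty = cl.classify_intronic(records_frame([0.99]), threshold=80)
    assert np.isnan(sei_empty)


def test_sweep_summary_columns(toy_annotation):
    a1 = aln([Block(0, 10, 50), Block(50, 100, 60), Block(110, 200, 40)],
             qname="sA")
    rec = cl.classify_scaffolds([a1], toy_annotation,
                                {"sA": "ATG" + "A" * 300 + "TAA"})
    summary = cl.sweep_summary(rec)
    assert len(summary) == 101
    for col in ("threshold", "n_annotated", "n_unannotated", "se_annotated",
                "se_unannotated", "sei", "orf_annotated", "orf_unannotated"):
        assert col in summary.columns


def test_intron_length_summary(toy_annotation):
    hist = cl.intron_length_summary(toy_annotation)
    assert hist.attrs["n_introns"] == 3  # tA has 2 introns, tB has 1
    assert hist["count"].sum() == 3


def test_params_validation():
    with pytest.raises(ValueError):
        cl.ClassificationParams(threshold_grid=(0, 101))
    with pytest.raises(ValueError):
        cl.ClassificationParams(orf_min_aa=0)
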