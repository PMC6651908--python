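"""Synthetic data generator: determinism, truth consistency, injections."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asmeval import gcbias as gb
from asmeval import synth

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@pytest.fixture(scope="module")
def small_study():
    cfg = synth.preset_completeness(seed=11)
    genome, annotation, truth = synth.simulate_genome_annotation(cfg)
    return cfg, genome, annotation, truth


def test_simulation_is_deterministic():
    cfg = synth.preset_completeness(seed=4)
    g1, a1, t1 = synth.simulate_genome_annotation(cfg)
    g2, a2, t2 = synth.simulate_genome_annotation(cfg)
    assert g1.sequences == g2.sequences
    pd.testing.assert_frame_equal(t1.transcripts, t2.transcripts)
    r1, p1 = synth.simulate_reads(g1, t1, cfg, 2000)
    r2, p2 = synth.simulate_reads(g2, t2, cfg, 2000)
    pd.testing.assert_frame_equal(r1, r2)
    pd.testing.assert_frame_equal(p1, p2)


def test_different_seeds_differ():
    c1 = synth.preset_completeness(seed=1)
    c2 = synth.preset_completeness(seed=2)
    g1, _, _ = synth.simulate_genome_annotation(c1)
    g2, _, _ = synth.simulate_genome_annotation(c2)
    assert g1.sequences != g2.sequences


def test_truth_table_consistency(small_study):
    cfg, genome, annotation, truth = small_study
    tr = truth.transcripts
    objs = synth.all_transcript_objects(truth)
    assert set(tr["transcript_id"]) == set(objs)
    ann_ids = set(annotation.transcripts)
    # annotated flag matches membership in the annotation
    for row in tr.itertuples():
        assert (row.transcript_id in ann_ids) == row.annotated
        t = objs[row.transcript_id]
        assert t.length == row.length
        assert len(t.exons) == row.exon_count
        seq = t.spliced_sequence(genome)
        assert gb.gc_content(seq) == pytest.approx(row.gc, abs=1e-9)
    # TPM normalization
    assert tr["tpm"].sum() == pytest.approx(1e6)


def test_unannotated_templates_sit_in_introns():
    cfg = synth.preset_depth_study(seed=11)
    genome, annotation, truth = synth.simulate_genome_annotation(cfg)
    objs = synth.all_transcript_objects(truth)
    unann = truth.transcripts[~truth.transcripts["annotated"]]
    assert len(unann) > 0
    for row in unann.itertuples():
        t = objs[row.transcript_id]
        assert row.exon_count == 1
        if row.intronic:
            from asmeval import intervals as iv
            intron_union = annotation.intron_union[t.seqname]
            inside = iv.total_length(iv.intersect(t.exons, intron_union))
            assert inside == t.length


def test_reads_match_placed_fragments(small_study):
    cfg, genome, annotation, truth = small_study
    reads, placements = synth.simulate_reads(genome, truth, cfg, 300)
    pairs = synth.render_read_pairs(genome, truth, reads, cfg)
    objs = synth.all_transcript_objects(truth)
    L = cfg.read_length
    for (m1, m2), row in zip(pairs, reads.itertuples()):
        spliced = objs[row.transcript_id].spliced_sequence(genome)
        assert m1.sequence == spliced[row.frag_start:row.frag_start + L]
        tail = spliced[row.frag_end - L:row.frag_end]
        assert m2.sequence == tail.translate(_COMPLEMENT)[::-1]


def test_abundance_law_recovered():
    # transcript abundances are exponential; the MLE of the mean from
    # the truth table must recover the configured scale
    cfg = synth.preset_completeness(seed=9)
    cfg = dataclasses.replace(cfg, n_genes=600)
    _, _, truth = synth.simulate_genome_annotation(cfg)
    ann = truth.transcripts[truth.transcripts["annotated"]]
    a = ann["abundance"].to_numpy()
    mean = a.mean()
    # exponential mean estimate: relative SE = 1/sqrt(n)
    assert abs(mean - 1.0 / cfg.abundance_rate) < 4 * mean / np.sqrt(len(a))
    # a Kolmogorov-Smirnov test against the fitted exponential
    assert stats.kstest(a, "expon", args=(0, mean)).pvalue > 0.01


def test_fragment_level_gc_bias_shifts_sampling():
    cfg0 = synth.preset_gc_bias(seed=2)
    genome, annotation, truth = synth.simulate_genome_annotation(cfg0)
    cfg_b = dataclasses.replace(cfg0, gc_bias=synth.log_linear_bias(2.0))
    objs = synth.all_transcript_objects(truth)
    seqs = {tid: t.spliced_sequence(genome) for tid, t in objs.items()}

    def mean_fragment_gc(reads):
        vals = []
        for row in reads.sample(2000, random_state=0).itertuples():
            frag = seqs[row.transcript_id][row.frag_start:row.frag_end]
            vals.append(gb.gc_content(frag))
        return float(np.mean(vals))

    r0, _ = synth.simulate_reads(genome, truth, cfg0, 20_000,
                                 with_placements=False)
    rb, _ = synth.simulate_reads(genome, truth, cfg_b, 20_000,
                                 with_placements=False)
    assert mean_fragment_gc(rb) < mean_fragment_gc(r0) - 0.02


def test_transcript_read_depth_totals(small_study):
    cfg, genome, annotation, truth = small_study
    reads, _ = synth.simulate_reads(genome, truth, cfg, 5000,
                                    with_placements=False)
    lengths = {t: o.length for t, o in
               synth.all_transcript_objects(truth).items()}
    depth = synth.transcript_read_depth(reads, lengths, cfg.read_length)
    for tid, d in depth.items():
        assert len(d) == lengths[tid]
    total = sum(float(d.sum()) for d in depth.values())
    assert total == pytest.approx(len(reads) * 2 * cfg.read_length)


def test_scaffold_truth_alignments(small_study):
    cfg, genome, annotation, truth = small_study
    scaffolds, alignments, sdf = synth.simulate_scaffolds(
        genome, truth, cfg, n_chimeras=4)
    objs = synth.all_transcript_objects(truth)
    by_name = {a.qname: a for a in alignments}
    for row in sdf.itertuples():
        a = by_name[row.scaffold_id]
        seq = scaffolds.sequences[row.scaffold_id]
        assert a.qsize == len(seq)
        if not row.chimeric:
            # aligned target blocks reproduce the source exon pieces
            t = objs[row.sources]
            assert a.tname == t.seqname
            covered = sum(b.size for b in a.blocks)
            assert covered == len(seq)
            # scaffold sequence matches the genome through the blocks
            for b in a.blocks:
                g = genome.sequences[a.tname][b.tstart:b.tend]
                assert seq[b.qstart:b.qend] == g
        else:
            assert "+" in row.sources
    n_chim = int(sdf["chimeric"].sum())
    assert n_chim == 4


def test_chimeras_join_two_transcripts(small_study):
    cfg, genome, annotation, truth = small_study
    _, alignments, sdf = synth.simulate_scaffolds(genome, truth, cfg,
                                                  n_chimeras=3)
    chim = sdf[sdf["chimeric"]]
    for row in chim.itertuples():
        left, right = row.sources.split("+")
        assert left != right
        alns = [a for a in alignments if a.qname == row.scaffold_id]
        assert len(alns) == 2
        # neither half alone covers 98% of the scaffold
        assert all(a.aligned_query_fraction < 0.98 for a in alns)


def test_partial_scaffolds_cover_requested_fraction(small_study):
    cfg, genome, annotation, truth = small_study
    _, alignments, sdf = synth.simulate_scaffolds(
        genome, truth, cfg, completeness=0.6)
    objs = synth.all_transcript_objects(truth)
    for a, row in zip(alignments, sdf.itertuples()):
        if row.chimeric:
            continue
        t = objs[row.sources]
        frac = sum(b.size for b in a.blocks) / t.length
        assert frac == pytest.approx(0.6, abs=2.0 / t.length)


def test_gc_preset_spans_gc_range():
    cfg = synth.preset_gc_bias(seed=6)
    genome, annotation, truth = synth.simulate_genome_annotation(cfg)
    objs = synth.all_transcript_objects(truth)
    lo, hi = cfg.gc_range
    for tid, t in list(objs.items())[:10]:
        seq = t.spliced_sequence(genome)
        window_gc = [gb.gc_content(seq[i:i + 100])
                     for i in range(0, len(seq) - 99, 100)]
        # stratified segment targets: windows reach both ends of the range
        assert min(window_gc) < lo + 0.08
        assert max(window_gc) > hi - 0.08
        # per-transcript mean GC is close to the range midpoint
        assert np.mean(window_gc) == pytest.approx((lo + hi) / 2, abs=0.03)


def test_seed_derivation_fits_in_31_bits():
    cfg = synth.preset_completeness(seed=2**31 - 1)
    rng = cfg.rng("reads")
    assert isinstance(rng, np.random.Generator)
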