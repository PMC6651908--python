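"""Synthetic genomes, annotations, reads and scaffolds with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: multi-exon gene models with heterogeneous intron lengths,
exponentially distributed transcript abundances, unannotated single-exon
templates placed in introns or intergenic space, paired error-free reads
with optional fragment-level GC-dependent sampling bias and PCR
duplicates, and scaffolds with controlled completeness, UTR-like flanks
and chimerism.

Everything is driven by one 64-bit seed; per-stage generators are
derived deterministically from it.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval.core import (
    AnnotationSet,
    Block,
    BlockAlignment,
    GenomeModel,
    ReadRecord,
    Transcript,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int, gc: float,
                exact: bool = False) -> np.ndarray:
    """Random uint8 base array with GC content ``gc``.

    With ``exact`` the sequence carries exactly round(gc*n) G/C bases
    (composition control for GC-bias analyses, where the realized GC of
    a window must equal the target the bias acted on); otherwise bases
    are drawn independently with that expectation.
    """
    if not exact:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return _BASES[rng.choice(4, size=n, p=p)]
    k = round(gc * n)
    strong = _BASES[rng.integers(1, 3, size=k)]          # G/C
    weak = _BASES[rng.choice([0, 3], size=n - k)]         # A/T
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return seq


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Lengths are in bases; ``abundance_rate`` is the rate (1/scale) of
    the exponential abundance law in arbitrary molecule units.
    ``gc_range`` gives the per-transcript GC-target sampler (uniform);
    if ``gc_segment_length`` is set, GC targets are drawn independently
    per segment of that length *within* each transcript, which makes the
    per-transcript mean bias weight roughly constant across transcripts
    and lets windowed depth-ratio analyses identify the bias function.
    ``gc_bias`` is a vectorized weight function w(GC) on [0, 1]
    (None or constant 1 means unbiased sampling).
    """

    n_genes: int = 100
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (200, 2000)
    intergenic_length_range: tuple[int, int] = (300, 1500)
    n_chromosomes: int = 2
    gc_range: tuple[float, float] = (0.35, 0.65)
    gc_segment_length: int | None = None
    background_gc: float = 0.40
    abundance_rate: float = 1.0
    unannotated_fraction: float = 0.0
    unannotated_placement: str = "intronic"  # or "intergenic"
    unannotated_length_range: tuple[int, int] = (300, 800)
    unannotated_abundance_scale: float = 1.0
    read_length: int = 100
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    duplicate_rate: float = 0.0
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.exon_length_range, self.intron_length_range,
                       self.intergenic_length_range,
                       self.unannotated_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if not 0.0 <= self.unannotated_fraction < 1.0:
            raise ValueError("unannotated_fraction must lie in [0, 1)")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.abundance_rate <= 0:
            raise ValueError("abundance_rate must be positive")
        if self.unannotated_placement not in ("intronic", "intergenic"):
            raise ValueError("placement must be 'intronic' or 'intergenic'")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the seed."""
        stage_key = zlib.crc32(stage.encode())  # stable across processes
        ss = np.random.SeedSequence([int(self.seed), stage_key])
        return np.random.default_rng(ss)


# Bias-function builders -----------------------------------------------------


def exp_gc_penalty(strength: float = 4.0, knee: float = 0.6
                   ) -> Callable[[np.ndarray], np.ndarray]:
    """w(GC) = exp(-strength * max(0, GC - knee)): penalty above a knee."""
    def w(gc: np.ndarray) -> np.ndarray:
        return np.exp(-strength * np.maximum(0.0, np.asarray(gc) - knee))
    return w


def log_linear_bias(coeff: float) -> Callable[[np.ndarray], np.ndarray]:
    """w(GC) = 10**(-coeff * GC): log10-linear depletion with GC."""
    def w(gc: np.ndarray) -> np.ndarray:
        return np.power(10.0, -coeff * np.asarray(gc))
    return w


@dataclass
class TruthTable:
    """Ground truth linking transcripts, scaffolds and read pairs.

    ``transcripts``: transcript_id, seqname, annotated, exon_count,
    intronic, length, gc, abundance, tpm.
    ``scaffolds`` (once scaffolds are simulated): scaffold_id, sources,
    completeness, chimeric.
    ``reads`` (once reads are simulated): pair_id, transcript_id,
    frag_start, frag_end (spliced coordinates), duplicate.
    """

    transcripts: pd.DataFrame
    scaffolds: pd.DataFrame | None = None
    reads: pd.DataFrame | None = None
    # full Transcript objects incl. unannotated templates, for read and
    # scaffold simulation and for oracle checks
    transcript_objects: dict[str, Transcript] = field(default_factory=dict)

    def tpm(self) -> pd.Series:
        return self.transcripts.set_index("transcript_id")["tpm"]


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


def _transcript_sequence(rng: np.random.Generator, length: int,
                         cfg: SimConfig) -> tuple[np.ndarray, float]:
    """Spliced transcript sequence honouring the configured GC structure."""
    lo, hi = cfg.gc_range
    if cfg.gc_segment_length is None:
        gc = rng.uniform(lo, hi)
        seq = _random_seq(rng, length, gc)
    else:
        # segmented mode: segment GC targets are a stratified, permuted
        # sample of gc_range (one stratum midpoint per segment, small
        # jitter), so every transcript carries the same GC mixture and
        # the per-transcript mean of any GC-dependent weight is constant
        # across transcripts. Composition is exact in every 100 b block
        # so the measured GC of analysis windows inside a segment equals
        # the target a fragment-level bias acted on.
        block = 100
        n_seg = -(-length // cfg.gc_segment_length)
        width = (hi - lo) / n_seg
        targets = lo + width * (np.arange(n_seg) + 0.5)
        targets = targets + rng.uniform(-width / 2, width / 2, size=n_seg)
        rng.shuffle(targets)
        pieces = []
        pos = 0
        for gc in targets:
            n = min(cfg.gc_segment_length, length - pos)
            for b0 in range(0, n, block):
                pieces.append(_random_seq(rng, min(block, n - b0), float(gc),
                                          exact=True))
            pos += n
        seq = np.concatenate(pieces)
    gc_actual = float(np.isin(seq, _BASES[1:3]).mean())
    return seq, gc_actual


def simulate_genome_annotation(cfg: SimConfig
                               ) -> tuple[GenomeModel, AnnotationSet,
                                          TruthTable]:
    """Build a toy genome, its annotation, and the transcript truth table.

    Annotated genes are multi-exon (one transcript per gene); unannotated
    single-exon templates are embedded inside introns or intergenic
    spacers according to the configured placement, and appear in the
    truth table but not in the annotation.
    """
    rng = cfg.rng("genome")
    n_unann = round(cfg.n_genes * cfg.unannotated_fraction
                    / (1.0 - cfg.unannotated_fraction))

    chrom_parts: dict[str, list[np.ndarray]] = {}
    chrom_pos: dict[str, int] = {}
    transcripts: list[Transcript] = []
    truth_rows = []
    # candidate slots for unannotated templates: (seqname, start, end)
    intron_slots: list[tuple[str, int, int]] = []
    intergenic_slots: list[tuple[str, int, int]] = []

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    for name in chrom_names:
        chrom_parts[name] = []
        chrom_pos[name] = 0

    def _append(name: str, seq: np.ndarray) -> tuple[int, int]:
        start = chrom_pos[name]
        chrom_parts[name].append(seq)
        chrom_pos[name] = start + len(seq)
        return start, chrom_pos[name]

    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chromosomes]
        s, e = _append(chrom, _random_seq(
            rng, rng.integers(*cfg.intergenic_length_range, endpoint=True),
            cfg.background_gc))
        intergenic_slots.append((chrom, s, e))

        k = int(rng.integers(*cfg.exon_count_range, endpoint=True))
        exon_lens = rng.integers(*cfg.exon_length_range, endpoint=True,
                                 size=k)
        tseq, gc = _transcript_sequence(rng, int(exon_lens.sum()), cfg)
        exons = []
        off = 0
        for i, elen in enumerate(exon_lens):
            es, ee = _append(chrom, tseq[off:off + elen])
            exons.append((es, ee))
            off += elen
            if i < k - 1:
                ilen = int(rng.integers(*cfg.intron_length_range,
                                        endpoint=True))
                istart, iend = _append(
                    chrom, _random_seq(rng, ilen, cfg.background_gc))
                intron_slots.append((chrom, istart, iend))
        tid = f"t{g:05d}"
        transcripts.append(Transcript(tid, f"g{g:05d}", chrom, "+", exons))
        truth_rows.append(dict(
            transcript_id=tid, seqname=chrom, annotated=True, exon_count=k,
            intronic=False, length=int(exon_lens.sum()), gc=gc,
        ))

    # trailing spacer per chromosome
    for name in chrom_names:
        s, e = _append(name, _random_seq(
            rng, rng.integers(*cfg.intergenic_length_range, endpoint=True),
            cfg.background_gc))
        intergenic_slots.append((name, s, e))

    sequences = {
        name: np.concatenate(parts) if parts else np.array([], dtype=np.uint8)
        for name, parts in chrom_parts.items()
    }

    # place unannotated single-exon templates
    slots = (intron_slots if cfg.unannotated_placement == "intronic"
             else intergenic_slots)
    margin = 10
    usable = [s for s in slots]
    rng.shuffle(usable)
    placed = 0
    for chrom, s, e in usable:
        if placed >= n_unann:
            break
        ulen = int(rng.integers(*cfg.unannotated_length_range, endpoint=True))
        if e - s < ulen + 2 * margin:
            continue
        start = int(rng.integers(s + margin, e - margin - ulen, endpoint=True))
        useq, gc = _transcript_sequence(rng, ulen, cfg)
        sequences[chrom][start:start + ulen] = useq
        tid = f"u{placed:05d}"
        transcripts.append(  # not part of the annotation
            Transcript(tid, tid, chrom, "+", [(start, start + ulen)])
        )
        truth_rows.append(dict(
            transcript_id=tid, seqname=chrom, annotated=False, exon_count=1,
            intronic=cfg.unannotated_placement == "intronic", length=ulen,
            gc=gc,
        ))
        placed += 1
    if placed < n_unann:
        raise ValueError(
            f"only {placed}/{n_unann} unannotated templates fit the genome; "
            "enlarge introns/intergenic spacers or reduce the fraction"
        )

    genome = GenomeModel({
        name: seq.tobytes().decode("ascii")
        for name, seq in sequences.items()
    })
    annotation = AnnotationSet(
        [t for t in transcripts if t.transcript_id.startswith("t")],
        genome=genome,
    )

    truth = pd.DataFrame(truth_rows)
    ab_rng = cfg.rng("abundance")
    scale = 1.0 / cfg.abundance_rate
    ab = ab_rng.exponential(scale, size=len(truth))
    ab[~truth["annotated"].to_numpy()] *= cfg.unannotated_abundance_scale
    truth["abundance"] = ab
    truth["tpm"] = 1e6 * ab / ab.sum()

    table = TruthTable(
        transcripts=truth,
        transcript_objects={t.transcript_id: t for t in transcripts},
    )
    return genome, annotation, table


def all_transcript_objects(truth: TruthTable) -> dict[str, Transcript]:
    return truth.transcript_objects


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(genome: GenomeModel, truth: TruthTable, cfg: SimConfig,
                   n_pairs: int, with_placements: bool = True,
                   ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Draw ``n_pairs`` error-free read pairs; return truth + placements.

    Fragments are sampled per transcript with probability proportional
    to abundance times w(GC of the fragment) via rejection sampling;
    duplicates are injected at the configured rate as exact coordinate
    copies of earlier pairs. Returns ``(reads, placements)``: the reads
    truth table (spliced fragment coordinates) and the genome-space
    placement table used by the QC filters (None when
    ``with_placements`` is off — depth and GC analyses work in
    transcript space and do not need it).
    """
    rng = cfg.rng("reads")
    tr_objs = all_transcript_objects(truth)
    df = truth.transcripts
    tids = df["transcript_id"].to_numpy()
    len_arr = df["length"].to_numpy()
    feasible = len_arr >= cfg.read_length
    if not feasible.any():
        raise ValueError("no transcript can hold even one read")
    ab = df["abundance"].to_numpy() * feasible
    p = ab / ab.sum()

    # concatenated G/C prefix sums for O(1) vectorized fragment GC
    offsets = np.concatenate([[0], np.cumsum(len_arr)])
    is_gc = np.empty(int(offsets[-1]), dtype=np.uint8)
    for i, tid in enumerate(tids):
        arr = np.frombuffer(
            tr_objs[tid].spliced_sequence(genome).encode(), dtype=np.uint8)
        is_gc[offsets[i]:offsets[i + 1]] = (arr == ord("G")) | (arr == ord("C"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])

    bias = cfg.gc_bias
    if bias is not None:
        wmax = float(np.max(bias(np.linspace(0.0, 1.0, 201))))

    acc: list[np.ndarray] = []
    n_acc = 0
    batch = int(np.clip(2 * n_pairs, 1024, 500_000))
    while n_acc < n_pairs:
        tr = rng.choice(len(tids), size=batch, p=p)
        flen = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd,
                                  size=batch)).astype(np.int64)
        flen = np.clip(flen, cfg.read_length, len_arr[tr])
        start = (rng.random(batch) * (len_arr[tr] - flen + 1)).astype(np.int64)
        if bias is not None:
            base = offsets[tr] + start
            gc = (gc_cum[base + flen] - gc_cum[base]) / flen
            keep = rng.random(batch) < bias(gc) / wmax
            tr, start, flen = tr[keep], start[keep], flen[keep]
        acc.append(np.stack([tr, start, flen], axis=1))
        n_acc += len(tr)
    pool = np.concatenate(acc)[:n_pairs]

    # duplicate injection: each emitted pair is, with prob duplicate_rate,
    # an exact coordinate copy of a uniformly chosen earlier unique pair
    dup = np.zeros(n_pairs, dtype=bool)
    if cfg.duplicate_rate > 0:
        rows = np.empty((n_pairs, 3), dtype=np.int64)
        uniques: list[int] = []
        next_unique = 0
        for k in range(n_pairs):
            if uniques and rng.random() < cfg.duplicate_rate:
                rows[k] = rows[uniques[int(rng.integers(len(uniques)))]]
                dup[k] = True
            else:
                rows[k] = pool[next_unique]
                uniques.append(k)
                next_unique += 1
    else:
        rows = pool

    tr_i, start, flen = rows[:, 0], rows[:, 1], rows[:, 2]
    pair_ids = np.array([f"p{k:08d}" for k in range(n_pairs)])
    reads = pd.DataFrame({
        "pair_id": pair_ids,
        "transcript_id": tids[tr_i],
        "frag_start": start,
        "frag_end": start + flen,
        "duplicate": dup,
    })
    if not with_placements:
        return reads, None

    pos1 = np.empty(n_pairs, dtype=np.int64)
    pos2 = np.empty(n_pairs, dtype=np.int64)
    seqname = np.empty(n_pairs, dtype=object)
    for k in range(n_pairs):
        t = tr_objs[tids[tr_i[k]]]
        pos1[k] = t.spliced_to_genome(int(start[k]))
        pos2[k] = t.spliced_to_genome(int(start[k] + flen[k]) - cfg.read_length)
        seqname[k] = t.seqname
    placements = pd.DataFrame({
        "pair_id": pair_ids,
        "seq": seqname,
        "pos1": pos1,
        "strand1": "+",
        "pos2": pos2,
        "strand2": "-",
        "proper": True,
    })
    return reads, placements


def render_read_pairs(genome: GenomeModel, truth: TruthTable,
                      reads: pd.DataFrame, cfg: SimConfig
                      ) -> list[tuple[ReadRecord, ReadRecord]]:
    """Materialize read sequences (error-free) from the reads truth table."""
    tr_objs = all_transcript_objects(truth)
    seqs = {tid: tr_objs[tid].spliced_sequence(genome)
            for tid in reads["transcript_id"].unique()}
    rl = cfg.read_length
    q = [cfg.base_quality] * rl
    out = []
    for row in reads.itertuples(index=False):
        frag = seqs[row.transcript_id][row.frag_start:row.frag_end]
        r1 = ReadRecord(row.pair_id, 1, frag[:rl], list(q))
        r2 = ReadRecord(row.pair_id, 2, _revcomp(frag[-rl:]), list(q))
        out.append((r1, r2))
    return out


def transcript_read_depth(reads: pd.DataFrame,
                          lengths: Mapping[str, int],
                          read_length: int) -> dict[str, np.ndarray]:
    """Per-position read depth in spliced coordinates, per transcript.

    Each mate contributes ``read_length`` covered positions (mates of
    short fragments overlap and count twice, as in a real pileup).
    """
    depth = {tid: np.zeros(n + 1, dtype=np.int64)
             for tid, n in lengths.items()}
    for tid, grp in reads.groupby("transcript_id", sort=False):
        d = depth[tid]
        s = grp["frag_start"].to_numpy()
        e = grp["frag_end"].to_numpy()
        np.add.at(d, s, 1)
        np.add.at(d, np.minimum(s + read_length, len(d) - 1), -1)
        np.add.at(d, np.maximum(e - read_length, 0), 1)
        np.add.at(d, e, -1)
    return {tid: np.cumsum(d[:-1]) for tid, d in depth.items()}


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------


def simulate_scaffolds(genome: GenomeModel, truth: TruthTable,
                       cfg: SimConfig,
                       completeness: float | Mapping[str, float] = 1.0,
                       flank: int = 0,
                       n_chimeras: int = 0,
                       transcript_ids: Sequence[str] | None = None,
                       ) -> tuple[GenomeModel, list[BlockAlignment],
                                  pd.DataFrame]:
    """Emit one scaffold per transcript plus optional chimeras.

    Each scaffold covers a contiguous spliced window of ``completeness``
    times the transcript length (scalar or per-transcript mapping in
    (0, 1]), optionally extended by ``flank`` random bases on each side
    (UTR-like sequence absent from the annotation). Chimeras concatenate
    halves of two transcripts, preferentially from different
    chromosomes, so no single alignment can cover 98% of them. PSL-style
    alignments reflect the true placements.
    """
    rng = cfg.rng("scaffolds")
    tr_objs = all_transcript_objects(truth)
    if transcript_ids is None:
        transcript_ids = list(truth.transcripts["transcript_id"])

    def frac_of(tid: str) -> float:
        f = (completeness if isinstance(completeness, (int, float))
             else completeness.get(tid, 1.0))
        if not 0.0 < f <= 1.0:
            raise ValueError(f"completeness fraction {f} outside (0, 1]")
        return float(f)

    scaffolds: dict[str, str] = {}
    alignments: list[BlockAlignment] = []
    rows = []

    for tid in transcript_ids:
        t = tr_objs[tid]
        f = frac_of(tid)
        spliced = t.spliced_sequence(genome)
        L = len(spliced)
        core = max(1, round(f * L))
        start = int(rng.integers(0, L - core, endpoint=True))
        left = _random_seq(rng, flank, cfg.background_gc).tobytes().decode()
        right = _random_seq(rng, flank, cfg.background_gc).tobytes().decode()
        seq = left + spliced[start:start + core] + right
        sid = f"sc_{tid}"
        scaffolds[sid] = seq
        blocks = []
        qpos = flank  # query starts walk the spliced window past the flank
        for gs, ge in t.spliced_window_to_genome(start, start + core):
            blocks.append(Block(qpos, gs, ge - gs))
            qpos += ge - gs
        alignments.append(BlockAlignment(
            sid, len(seq), t.seqname, genome.lengths[t.seqname], "+",
            blocks, core))
        rows.append(dict(scaffold_id=sid, sources=tid, completeness=f,
                         chimeric=False))

    # chimeras
    ann_ids = [tid for tid in transcript_ids
               if len(tr_objs[tid].spliced_sequence(genome)) >= 200]
    for c in range(n_chimeras):
        a, b = _pick_chimera_pair(rng, ann_ids, tr_objs)
        ta, tb = tr_objs[a], tr_objs[b]
        sa = ta.spliced_sequence(genome)
        sb = tb.spliced_sequence(genome)
        ka, kb = len(sa) // 2, len(sb) // 2
        seq = sa[:ka] + sb[len(sb) - kb:]
        sid = f"chim{c:04d}"
        scaffolds[sid] = seq
        qsize = len(seq)
        blocks_a = []
        qpos = 0
        for gs, ge in ta.spliced_window_to_genome(0, ka):
            blocks_a.append(Block(qpos, gs, ge - gs))
            qpos += ge - gs
        alignments.append(BlockAlignment(
            sid, qsize, ta.seqname, genome.lengths[ta.seqname], "+",
            blocks_a, ka))
        blocks_b = []
        qpos = ka
        for gs, ge in tb.spliced_window_to_genome(len(sb) - kb, len(sb)):
            blocks_b.append(Block(qpos, gs, ge - gs))
            qpos += ge - gs
        alignments.append(BlockAlignment(
            sid, qsize, tb.seqname, genome.lengths[tb.seqname], "+",
            blocks_b, kb))
        rows.append(dict(scaffold_id=sid, sources=f"{a}+{b}",
                         completeness=1.0, chimeric=True))

    scaffold_df = pd.DataFrame(rows)
    truth.scaffolds = scaffold_df
    return GenomeModel(scaffolds), alignments, scaffold_df


def _pick_chimera_pair(rng: np.random.Generator, ids: Sequence[str],
                       tr_objs: Mapping[str, Transcript]) -> tuple[str, str]:
    a = b = 0
    for _ in range(100):
        a, b = rng.choice(len(ids), size=2, replace=False)
        if tr_objs[ids[a]].seqname != tr_objs[ids[b]].seqname:
            break
    return ids[int(a)], ids[int(b)]


# ---------------------------------------------------------------------------
# Corrupted reads for QC testing
# ---------------------------------------------------------------------------


def simulate_qc_reads(n: int, read_length: int, adapters: Sequence[str],
                      seed: int,
                      label_fractions: Mapping[str, float] | None = None,
                      ) -> list[tuple[tuple[ReadRecord, ReadRecord], str]]:
    """Read pairs with known defect labels for exercising the pair filter.

    Labels: ``keep`` (clean), ``adapter`` (read-through adapter at the
    3' end), ``low_quality`` (>10% of bases below PHRED 10),
    ``ambiguous`` (>1% N's). Returns ``((mate1, mate2), label)`` tuples.
    """
    if label_fractions is None:
        label_fractions = {"keep": 0.7, "adapter": 0.1,
                           "low_quality": 0.1, "ambiguous": 0.1}
    rng = np.random.default_rng(seed)
    labels = list(label_fractions)
    probs = np.array([label_fractions[k] for k in labels], dtype=float)
    probs /= probs.sum()
    out = []
    for i in range(n):
        label = labels[int(rng.choice(len(labels), p=probs))]
        mates = []
        corrupt_mate = int(rng.integers(2))
        for m in range(2):
            seq = _random_seq(rng, read_length, 0.5).tobytes().decode()
            qual = [30] * read_length
            if m == corrupt_mate:
                if label == "adapter":
                    ad = adapters[int(rng.integers(len(adapters)))]
                    k = int(rng.integers((len(ad) + 1) // 2, len(ad),
                                         endpoint=True))
                    seq = seq[:read_length - k] + ad[:k]
                elif label == "low_quality":
                    n_low = int(read_length * 0.10) + 1 + int(
                        rng.integers(0, read_length // 5))
                    n_low = min(n_low, read_length)
                    pos = rng.choice(read_length, size=n_low, replace=False)
                    for pjj in pos:
                        qual[pjj] = int(rng.integers(0, 10))
                elif label == "ambiguous":
                    n_amb = int(read_length * 0.01) + 1 + int(
                        rng.integers(0, read_length // 10))
                    n_amb = min(n_amb, read_length)
                    pos = rng.choice(read_length, size=n_amb, replace=False)
                    s = list(seq)
                    for pjj in pos:
                        s[pjj] = "N"
                    seq = "".join(s)
            mates.append(ReadRecord(f"q{i:06d}", m + 1, seq, qual))
        out.append(((mates[0], mates[1]), label))
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def preset_depth_study(seed: int = 0) -> SimConfig:
    """Study conditions for the depth-saturation analysis.

    ~2 Mb genome: 200 annotated multi-exon genes with exponential
    abundances, plus 400 low-abundance unannotated intronic single-exon
    templates whose gradual recovery with depth drives the genome curve
    while the exome curve saturates.

    The divergence between the two curves only exists in a sampling
    regime set by the exponential abundance law: with mean annotated
    transcript depth d at the full library size, a transcript of
    relative abundance a crosses an assembly-depth threshold c at the
    size fraction f = c / (a d). The exome saturates early when
    c/d << 1 (here d ~ 600x the threshold: ~8 genes are expected in
    the first size segment — enough that Poisson noise cannot zero the
    initial slope — and ~0.4 in the last), while the unannotated
    crossing hump must sit late in the size range: with template
    abundance scale c / (0.9 d) the expected unannotated discovery
    slope in the final segment is several times the initial one, so
    the genome curve keeps rising where the exome curve has gone flat.
    """
    return SimConfig(
        n_genes=200,
        exon_count_range=(3, 5),
        exon_length_range=(100, 200),
        intron_length_range=(800, 3500),
        intergenic_length_range=(1500, 3500),
        unannotated_fraction=400 / 600,
        unannotated_placement="intronic",
        unannotated_length_range=(500, 1500),
        unannotated_abundance_scale=0.009,
        abundance_rate=1.0,
        seed=seed,
    )


def preset_gc_bias(seed: int = 0) -> SimConfig:
    """Study conditions for the GC-bias diagnostics.

    Long transcripts assembled from 2.5 kb segments whose GC targets
    are a stratified permutation of the 0.25-0.75 range (one segment
    per stratum, jittered within it), realized with exact GC
    composition per 100 b block. Every 100 b window then samples the
    whole GC range within every transcript, every transcript's mean
    bias weight equals the population mean by construction, and the
    windowed depth-ratio curve identifies the injected fragment-level
    bias up to one common normalization.
    """
    return SimConfig(
        n_genes=120,
        exon_count_range=(1, 1),
        exon_length_range=(25000, 25000),
        intron_length_range=(200, 400),
        intergenic_length_range=(200, 600),
        gc_range=(0.25, 0.75),
        gc_segment_length=2500,
        abundance_rate=1.0,
        fragment_mean=150.0,
        fragment_sd=15.0,
        seed=seed,
    )


def preset_completeness(seed: int = 0) -> SimConfig:
    """Study conditions for completeness/overlap analyses."""
    return SimConfig(
        n_genes=150,
        exon_count_range=(2, 6),
        exon_length_range=(150, 500),
        intron_length_range=(300, 1500),
        abundance_rate=1.0,
        seed=seed,
    )
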