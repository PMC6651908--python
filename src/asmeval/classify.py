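"""Scaffold classification: annotated/unannotated sweep, exon structure,
intronic assignment, and ORF content.

A scaffold is "annotated" at threshold t when some reference transcript
gives it an exon-overlap fraction strictly greater than t/100, where the
fraction's denominator is the scaffold length or the transcript length,
whichever is more favorable. Single- vs multi-exon status comes from
intron-sized target gaps in the retained alignment; unannotated
single-exon scaffolds are "intronic" when a strict majority of their
aligned bases fall inside the annotated intron union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from asmeval import intervals as iv
from asmeval.core import AnnotationSet, BlockAlignment, Transcript

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ClassificationParams:
    threshold_grid: tuple[int, ...] = tuple(range(101))
    min_intron_gap: int = 30
    max_query_gap: int = 10
    orf_min_scaffold_length: int = 300
    orf_min_aa: int = 100
    intronic_majority: float = 0.5  # strict majority
    report_threshold: int = 80

    def __post_init__(self) -> None:
        if any(t < 0 or t > 100 for t in self.threshold_grid):
            raise ValueError("threshold grid must lie within [0, 100]")
        if min((self.min_intron_gap, self.orf_min_scaffold_length,
                self.orf_min_aa)) <= 0:
            raise ValueError("lengths must be positive")


# ---------------------------------------------------------------------------
# Annotation fraction
# ---------------------------------------------------------------------------


def annotation_fraction(alignment: BlockAlignment,
                        transcript: Transcript) -> float:
    """Exon-overlap fraction of a scaffold alignment against one transcript.

    overlap = aligned target bases falling in the transcript's exons
    (block lengths are 1:1 between query and target, so these are also
    query bases); returns max(overlap/scaffold length,
    overlap/transcript spliced length).
    """
    if transcript.seqname != alignment.tname:
        return 0.0
    overlap = iv.total_length(
        iv.intersect(alignment.target_intervals, transcript.exons))
    if overlap == 0:
        return 0.0
    return max(overlap / alignment.qsize, overlap / transcript.length)


def _transcript_tree(annotation: AnnotationSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in annotation:
        s, e = t.span
        trees.setdefault(t.seqname, IntervalTree()).addi(s, e, t)
    return trees


def best_annotation_fraction(alignment: BlockAlignment,
                             annotation: AnnotationSet,
                             trees: Mapping[str, IntervalTree] | None = None,
                             ) -> tuple[float, str | None]:
    """Best fraction over candidate transcripts and the maximizing id."""
    if trees is None:
        trees = _transcript_tree(annotation)
    tree = trees.get(alignment.tname)
    if tree is None:
        return 0.0, None
    s, e = alignment.target_span
    best, best_id = 0.0, None
    for hit in sorted(tree.overlap(s, e),
                      key=lambda h: h.data.transcript_id):
        f = annotation_fraction(alignment, hit.data)
        if f > best:
            best, best_id = f, hit.data.transcript_id
    return best, best_id


# ---------------------------------------------------------------------------
# Exon structure and intronic calls
# ---------------------------------------------------------------------------


def exon_structure(alignment: BlockAlignment,
                   min_intron_gap: int = 30,
                   max_query_gap: int = 10) -> tuple[int, bool]:
    """(exon count, single-exon flag) of an alignment.

    A boundary between adjacent blocks counts as an intron when the
    target gap is at least ``min_intron_gap`` while the query gap is
    essentially zero (at most ``max_query_gap``, treating small gaps as
    assembly indels).
    """
    n_introns = 0
    for b1, b2 in zip(alignment.blocks, alignment.blocks[1:]):
        tgap = b2.tstart - b1.tend
        qgap = abs(b2.qstart - b1.qend)
        if tgap >= min_intron_gap and qgap <= max_query_gap:
            n_introns += 1
    return n_introns + 1, n_introns == 0


def intronic_fraction(alignment: BlockAlignment,
                      annotation: AnnotationSet) -> float:
    """Fraction of aligned target bases inside the global intron union."""
    intron_union = annotation.intron_union.get(alignment.tname, [])
    inside = iv.total_length(
        iv.intersect(alignment.target_intervals, intron_union))
    return inside / alignment.aligned_query_bases


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def _longest_orf_in_frame(seq: str) -> int:
    """Longest ATG..stop ORF in one frame, in aa (stop excluded)."""
    best = 0
    start: int | None = None
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in _STOPS:
            if start is not None:
                best = max(best, (i - start) // 3)
            start = None
        elif codon == "ATG" and start is None:
            start = i
    return best


def find_orfs(sequence: str, min_aa: int = 100) -> tuple[bool, int]:
    """Scan all six frames for ATG-to-stop ORFs.

    Returns (flag, longest ORF length in amino acids). Length counts
    the initial methionine and excludes the stop; an in-frame stop is
    required. Length-based denominator exclusions (scaffolds shorter
    than the minimum) are handled by the caller.
    """
    seq = sequence.upper()
    rc = seq.translate(_COMPLEMENT)[::-1]
    longest = 0
    for s in (seq, rc):
        for frame in range(3):
            longest = max(longest, _longest_orf_in_frame(s[frame:]))
    return longest >= min_aa, longest


# ---------------------------------------------------------------------------
# Record building and sweeps
# ---------------------------------------------------------------------------


def classify_scaffolds(alignments: Sequence[BlockAlignment],
                       annotation: AnnotationSet,
                       scaffold_sequences: Mapping[str, str] | None = None,
                       params: ClassificationParams | None = None,
                       ) -> pd.DataFrame:
    """Per-scaffold classification record table.

    One row per retained alignment: best annotation fraction and
    supporting transcript, exon count / single-exon flag, intronic base
    fraction, and (when sequences are supplied) ORF flag and longest ORF
    length. Threshold flags are derived downstream by
    :func:`classify_annotated`.
    """
    if params is None:
        params = ClassificationParams()
    trees = _transcript_tree(annotation)
    rows = []
    for a in alignments:
        frac, tid = best_annotation_fraction(a, annotation, trees)
        n_exons, single = exon_structure(a, params.min_intron_gap,
                                         params.max_query_gap)
        ifrac = intronic_fraction(a, annotation)
        row = dict(
            scaffold_id=a.qname,
            length=a.qsize,
            fraction=frac,
            best_transcript=tid,
            exon_count=n_exons,
            single_exon=single,
            intronic_fraction=ifrac,
            intronic=ifrac > params.intronic_majority,
        )
        if scaffold_sequences is not None:
            flag, aa = find_orfs(scaffold_sequences[a.qname],
                                 params.orf_min_aa)
            row["orf"] = flag
            row["orf_aa"] = aa
        rows.append(row)
    return pd.DataFrame(rows)


def classify_annotated(records: pd.DataFrame,
                       params: ClassificationParams | None = None,
                       ) -> pd.DataFrame:
    """Annotated/unannotated partition sizes over the threshold grid.

    Annotated at threshold t iff fraction > t/100 (strict). The
    annotated count is therefore non-increasing along the grid, and
    annotated + unannotated equals the retained scaffold count at every
    threshold.
    """
    if params is None:
        params = ClassificationParams()
    fracs = records["fraction"].to_numpy()
    rows = []
    for t in params.threshold_grid:
        annotated = fracs > t / 100.0
        rows.append(dict(threshold=t,
                         n_annotated=int(annotated.sum()),
                         n_unannotated=int((~annotated).sum())))
    return pd.DataFrame(rows)


def classify_intronic(records: pd.DataFrame,
                      threshold: int = 80,
                      params: ClassificationParams | None = None,
                      ) -> tuple[pd.Series, float]:
    """Intronic flags for unannotated single-exon scaffolds, plus SEI.

    SEI = intronic count / unannotated-single-exon count at the chosen
    threshold (NaN when the denominator is empty). Ties at exactly the
    majority fraction are non-intronic.
    """
    unann_se = records[
        (records["fraction"] <= threshold / 100.0) & records["single_exon"]
    ]
    flags = unann_se["intronic"]
    sei = float(flags.mean()) if len(flags) else float("nan")
    return flags, sei


def sweep_summary(records: pd.DataFrame,
                  params: ClassificationParams | None = None,
                  ) -> pd.DataFrame:
    """Per-threshold summary table of the classification sweep.

    Columns: threshold, n_annotated, n_unannotated, SE fractions in both
    categories, SEI among unannotated single-exon scaffolds, and (when
    ORF columns are present) ORF fractions among scaffolds passing the
    ORF length floor.
    """
    if params is None:
        params = ClassificationParams()
    has_orf = "orf" in records.columns
    rows = []
    for t in params.threshold_grid:
        annotated = records["fraction"] > t / 100.0
        ann, unann = records[annotated], records[~annotated]
        unann_se = unann[unann["single_exon"]]
        row = dict(
            threshold=t,
            n_annotated=len(ann),
            n_unannotated=len(unann),
            se_annotated=float(ann["single_exon"].mean()) if len(ann)
            else float("nan"),
            se_unannotated=float(unann["single_exon"].mean()) if len(unann)
            else float("nan"),
            sei=float(unann_se["intronic"].mean()) if len(unann_se)
            else float("nan"),
        )
        if has_orf:
            for name, part in (("orf_annotated", ann),
                               ("orf_unannotated", unann)):
                eligible = part[part["length"]
                                >= params.orf_min_scaffold_length]
                row[name] = (float(eligible["orf"].mean())
                             if len(eligible) else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def intron_length_summary(annotation: AnnotationSet,
                          bins: Sequence[int] = (0, 100, 1_000, 10_000,
                                                 100_000, 1_000_000),
                          ) -> pd.DataFrame:
    """Histogram of intron lengths with fractions >= 1 kb and >= 10 kb.

    Supports the cross-species reading of the genome-vs-exome curves:
    genomes rich in long introns accumulate far more genome-only
    coverage from intron-resident transcripts.
    """
    lengths = np.array([
        e - s for t in annotation for s, e in t.introns
    ])
    edges = list(bins) + [np.inf]
    counts, _ = (np.histogram(lengths, bins=edges) if len(lengths)
                 else (np.zeros(len(edges) - 1, dtype=int), None))
    hist = pd.DataFrame({
        "bin_start": bins,
        "count": counts,
    })
    hist.attrs["n_introns"] = int(len(lengths))
    hist.attrs["frac_ge_1kb"] = (
        float((lengths >= 1_000).mean()) if len(lengths) else float("nan"))
    hist.attrs["frac_ge_10kb"] = (
        float((lengths >= 10_000).mean()) if len(lengths) else float("nan"))
    return hist


def write_classification_tsvs(records: pd.DataFrame, summary: pd.DataFrame,
                              out_dir: str | Path) -> None:
    out = Path(out_dir)
    records.to_csv(out / "scaffold_records.tsv", sep="\t", index=False)
    summary.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
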