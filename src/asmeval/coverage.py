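"""Scaffold alignment filtering and genome/exome unique-base coverage curves.

A scaffold counts as correctly assembled when a *single* alignment
covers at least 98% of its length (summed block lengths of one
alignment, not the union over alignments — that distinction is what
makes the chimera filter meaningful). Coverage curves count each genome
position once, either anywhere ("genome" track) or restricted to the
global annotated exon union ("exome" track), across nested read
subsets of increasing size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval import intervals as iv
from asmeval import qc
from asmeval.core import AnnotationSet, BlockAlignment
from asmeval.intervals import Interval


@dataclass
class AlignmentFilterParams:
    min_aligned_fraction: float = 0.98
    best_hit_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_aligned_fraction <= 1.0:
            raise ValueError("min_aligned_fraction must lie in (0, 1]")


def _best_alignment(alns: Sequence[BlockAlignment]) -> BlockAlignment:
    # most matched bases; ties by fewest blocks, then lexicographic target
    return min(alns, key=lambda a: (-a.matches, len(a.blocks), a.tname))


def filter_alignments(alignments: Sequence[BlockAlignment],
                      params: AlignmentFilterParams | None = None,
                      ) -> tuple[list[BlockAlignment], dict[str, str]]:
    """Partition scaffolds into retained / chimeric / low-quality.

    Retained: the scaffold's best alignment alone reaches the minimum
    aligned-query fraction. Chimeric: no single alignment reaches it,
    but the union of all the scaffold's aligned query intervals does.
    Everything else is low-quality. Returns the retained alignments
    (best hit per scaffold when ``best_hit_only``) and a per-scaffold
    verdict map (every input scaffold receives exactly one verdict).
    """
    if params is None:
        params = AlignmentFilterParams()
    by_scaffold: dict[str, list[BlockAlignment]] = {}
    for a in alignments:
        by_scaffold.setdefault(a.qname, []).append(a)

    retained: list[BlockAlignment] = []
    verdicts: dict[str, str] = {}
    for qname, alns in by_scaffold.items():
        best = _best_alignment(alns)
        if best.aligned_query_fraction >= params.min_aligned_fraction:
            verdicts[qname] = "retained"
            if params.best_hit_only:
                retained.append(best)
            else:
                retained.extend(alns)
        else:
            union = iv.total_length(iv.merge(
                [ivl for a in alns for ivl in a.query_intervals]))
            if union / best.qsize >= params.min_aligned_fraction:
                verdicts[qname] = "chimeric"
            else:
                verdicts[qname] = "low_quality"
    return retained, verdicts


@dataclass
class CoverageResult:
    """Unique-base coverage of one subsample."""

    size_bp: int
    genome_bases: int
    exome_bases: int
    genome_norm: float = float("nan")
    exome_norm: float = float("nan")


def covered_union(alignments: Sequence[BlockAlignment]
                  ) -> dict[str, list[Interval]]:
    """Merged union of aligned target blocks, per target sequence."""
    by_seq: dict[str, list[Interval]] = {}
    for a in alignments:
        by_seq.setdefault(a.tname, []).extend(a.target_intervals)
    return {seq: iv.merge(ivls) for seq, ivls in by_seq.items()}


def unique_base_coverage(alignments: Sequence[BlockAlignment],
                         annotation: AnnotationSet | None = None,
                         ) -> tuple[int, int]:
    """(genome bases, exome bases) covered by at least one alignment.

    Each genome position counts once regardless of alignment
    multiplicity; the exome count intersects the covered union with the
    annotation's global exon union. Without an annotation the exome
    count is 0.
    """
    union = covered_union(alignments)
    genome = sum(iv.total_length(ivls) for ivls in union.values())
    if annotation is None:
        return genome, 0
    exome = sum(
        iv.total_length(iv.intersect(ivls,
                                     annotation.exon_union.get(seq, [])))
        for seq, ivls in union.items()
    )
    return genome, exome


def coverage_curve(reads: pd.DataFrame,
                   sizes: Sequence[int],
                   seed: int,
                   annotation: AnnotationSet | None,
                   alignments_by_transcript: Mapping[
                       str, Sequence[BlockAlignment]],
                   transcript_lengths: Mapping[str, int],
                   read_length: int = 100,
                   min_assembly_depth: float = 5.0,
                   ) -> list[CoverageResult]:
    """Genome/exome unique-base coverage across nested subsample sizes.

    Subsets are nested (one seeded permutation truncated at each target
    base count), so both coverage tracks are monotone non-decreasing.
    Assembly itself is out of scope: a transcript's scaffold alignments
    enter the union once the transcript's mean read depth in the subset
    reaches ``min_assembly_depth`` (a deliberately simple stand-in for a
    depth-limited assembler). Normalization follows the convention of
    dividing every value by the exome coverage of the largest subset.
    """
    if not sizes:
        raise ValueError("empty size list")
    sizes = sorted(int(s) for s in sizes)
    pair_table = pd.DataFrame({
        "pair_id": reads["pair_id"],
        "bases": 2 * read_length,
    })
    results = []
    for size in sizes:
        subset = qc.subsample_to_bases(pair_table, size, seed)
        sub_reads = reads.loc[subset.index]
        bases_per_tr = (
            sub_reads.groupby("transcript_id", sort=False)["pair_id"].count()
            * 2 * read_length
        )
        assembled = [
            tid for tid, b in bases_per_tr.items()
            if b / transcript_lengths[tid] >= min_assembly_depth
        ]
        alns = [a for tid in assembled
                for a in alignments_by_transcript.get(tid, [])]
        genome, exome = unique_base_coverage(alns, annotation)
        results.append(CoverageResult(size, genome, exome))

    norm = results[-1].exome_bases
    if norm > 0:
        for r in results:
            r.genome_norm = r.genome_bases / norm
            r.exome_norm = r.exome_bases / norm
    return results


def coverage_table(results: Sequence[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(size_bp=r.size_bp, genome_bases=r.genome_bases,
             exome_bases=r.exome_bases, genome_norm=r.genome_norm,
             exome_norm=r.exome_norm)
        for r in results
    ])


def write_coverage_tsv(results: Sequence[CoverageResult],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# unique-base coverage per subsample size\n")
        coverage_table(results).to_csv(fh, sep="\t", index=False)


def write_covered_bed(union: Mapping[str, Sequence[Interval]],
                      path: str | Path) -> None:
    """BED (0-based half-open) of the covered-position union."""
    with open(path, "w") as fh:
        for seq in sorted(union):
            for s, e in union[seq]:
                fh.write(f"{seq}\t{s}\t{e}\n")


def segment_slopes(results: Sequence[CoverageResult],
                   track: str = "exome") -> tuple[float, float]:
    """(initial, final) per-base slopes of a coverage curve track.

    Initial slope uses the first curve segment, final slope the last —
    the quantities behind the saturation ("plateau") diagnosis.
    """
    if len(results) < 3:
        raise ValueError("need at least three sizes to compare slopes")
    attr = f"{track}_bases"
    first = (getattr(results[1], attr) - getattr(results[0], attr)) / (
        results[1].size_bp - results[0].size_bp)
    last = (getattr(results[-1], attr) - getattr(results[-2], attr)) / (
        results[-1].size_bp - results[-2].size_bp)
    return first, last
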