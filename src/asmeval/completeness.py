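"""Transcript completeness and inter-library overlap of complete sets.

A reference transcript is "complete" when a single scaffold's
unambiguous top-scoring alignment covers at least 95% of the
transcript's spliced length. Completeness deliberately tolerates
scaffolds longer than the annotation (UTR-bearing assemblies): covered
positions are counted inside the transcript only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval import intervals as iv
from asmeval import qc
from asmeval.core import AnnotationSet, BlockAlignment, Transcript
from asmeval.intervals import Interval

log = logging.getLogger(__name__)


@dataclass
class CompletenessParams:
    min_covered_fraction: float = 0.95
    require_unambiguous_top_hit: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_covered_fraction <= 1.0:
            raise ValueError("min_covered_fraction must lie in (0, 1]")


def project_alignment_to_transcript(alignment: BlockAlignment,
                                    transcript: Transcript
                                    ) -> list[Interval]:
    """Covered spliced-transcript intervals of a genome-space alignment.

    Each aligned target block is intersected with the transcript's
    exons and mapped through the exon offsets into spliced coordinates;
    internal alignment gaps therefore do not count as covered.
    """
    if transcript.seqname != alignment.tname:
        return []
    covered: list[Interval] = []
    off = 0
    for es, ee in transcript.exons:
        for b in alignment.blocks:
            s, e = max(b.tstart, es), min(b.tend, ee)
            if s < e:
                covered.append((off + s - es, off + e - es))
        off += ee - es
    return iv.merge(covered)


def _candidate_scores(alignments: Sequence[BlockAlignment],
                      annotation: AnnotationSet,
                      ) -> pd.DataFrame:
    """Scaffold-vs-transcript coverage table derived from genome PSL."""
    from asmeval.classify import _transcript_tree

    trees = _transcript_tree(annotation)
    rows = []
    for a in alignments:
        tree = trees.get(a.tname)
        if tree is None:
            continue
        s, e = a.target_span
        for hit in tree.overlap(s, e):
            t: Transcript = hit.data
            covered = iv.total_length(project_alignment_to_transcript(a, t))
            if covered:
                rows.append((a.qname, t.transcript_id, covered, t.length))
    return pd.DataFrame(
        rows, columns=["scaffold_id", "transcript_id", "covered",
                       "transcript_length"],
    )


def complete_transcripts(alignments: Sequence[BlockAlignment],
                         annotation: AnnotationSet,
                         params: CompletenessParams | None = None,
                         ) -> set[str]:
    """Transcript ids completely assembled by some scaffold.

    Scaffold-vs-transcript alignments are derived by projecting
    genome-space alignments through the annotation; the score of one
    projection is its covered transcript bases. When the unambiguous
    top-hit rule is on, a scaffold whose best score ties its second best
    is discarded entirely.
    """
    if params is None:
        params = CompletenessParams()
    table = _candidate_scores(alignments, annotation)
    return complete_transcripts_from_table(table, params)


def complete_transcripts_from_table(table: pd.DataFrame,
                                    params: CompletenessParams | None = None,
                                    ) -> set[str]:
    """Completeness from a scaffold-vs-transcript coverage table.

    Needs columns ``scaffold_id, transcript_id, covered,
    transcript_length``; coverage exceeding the transcript length
    (possible in externally supplied alignments of UTR-bearing
    scaffolds) is clamped with a warning.
    """
    if params is None:
        params = CompletenessParams()
    if table.empty:
        return set()
    table = table.copy()
    over = table["covered"] > table["transcript_length"]
    if over.any():
        log.warning("clamping %d alignments longer than their transcript",
                    int(over.sum()))
        table.loc[over, "covered"] = table.loc[over, "transcript_length"]

    complete: set[str] = set()
    for _, grp in table.groupby("scaffold_id", sort=False):
        scores = grp["covered"].to_numpy()
        order = np.argsort(scores)[::-1]
        if (params.require_unambiguous_top_hit and len(scores) > 1
                and scores[order[0]] == scores[order[1]]):
            continue  # ambiguous top hit: scaffold discarded
        top = grp.iloc[order[0]]
        if top["covered"] >= (params.min_covered_fraction
                              * top["transcript_length"]):
            complete.add(top["transcript_id"])
    return complete


def completeness_by_size(reads: pd.DataFrame,
                         sizes: Sequence[int],
                         seed: int,
                         annotation: AnnotationSet,
                         scaffold_alignments: Sequence[BlockAlignment],
                         scaffold_sources: Mapping[str, str],
                         read_length: int = 100,
                         min_assembly_depth: float = 5.0,
                         params: CompletenessParams | None = None,
                         ) -> pd.DataFrame:
    """Complete-transcript counts (and sets) per nested subsample size.

    Uses the same depth-threshold assembly stand-in as the coverage
    curves: a transcript's scaffold exists in a subset once the
    transcript's mean read depth reaches ``min_assembly_depth``. Under
    nested subsets the counts are monotone non-decreasing.
    """
    lengths = {t.transcript_id: t.length for t in annotation}
    pair_table = pd.DataFrame({
        "pair_id": reads["pair_id"], "bases": 2 * read_length,
    })
    rows = []
    for size in sorted(int(s) for s in sizes):
        if len(reads) == 0:
            rows.append(dict(size_bp=size, n_complete=0, complete=set()))
            continue
        subset = qc.subsample_to_bases(pair_table, size, seed)
        sub = reads.loc[subset.index]
        bases = (sub.groupby("transcript_id", sort=False)["pair_id"].count()
                 * 2 * read_length)
        assembled = {
            tid for tid, b in bases.items()
            if tid in lengths and b / lengths[tid] >= min_assembly_depth
        }
        alns = [a for a in scaffold_alignments
                if scaffold_sources.get(a.qname) in assembled]
        complete = complete_transcripts(alns, annotation, params)
        rows.append(dict(size_bp=size, n_complete=len(complete),
                         complete=complete))
    return pd.DataFrame(rows)


def overlap_matrix(complete_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Row-normalized overlap of complete-transcript sets.

    Entry (row, col) = |complete(row) ∩ complete(col)| / |complete(row)|.
    Rows with empty complete sets yield NaN (undefined, not zero). The
    matrix is generally asymmetric.
    """
    names = list(complete_sets)
    if len(names) < 2:
        raise ValueError("need at least two libraries")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for r in names:
        denom = len(complete_sets[r])
        for c in names:
            mat.loc[r, c] = (
                len(complete_sets[r] & complete_sets[c]) / denom
                if denom else float("nan")
            )
    return mat
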