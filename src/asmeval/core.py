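"""Shared domain types and readers/writers for the standard formats.

Coordinate convention: everything in memory is 0-based half-open.
Conversion to and from external conventions happens only at the format
boundary — GFF3 is 1-based closed, PSL is 0-based half-open (with
minus-strand query starts expressed in the reversed-query frame, which
the reader normalizes to the plus-strand frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from asmeval import intervals as iv
from asmeval.intervals import Interval

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """A reference genome held in memory as name -> uppercase sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains illegal characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass
class Transcript:
    """One transcript: ordered, non-overlapping exons on one sequence."""

    transcript_id: str
    gene_id: str
    seqname: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bases."""
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: GenomeModel) -> str:
        seq = genome.sequences[self.seqname]
        s = "".join(seq[a:b] for a, b in self.exons)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def spliced_to_genome(self, pos: int) -> int:
        """Map a spliced-transcript coordinate to a genome coordinate."""
        off = 0
        for s, e in self.exons:
            if pos < off + (e - s):
                return s + (pos - off)
            off += e - s
        raise IndexError(f"{self.transcript_id}: spliced position {pos} "
                         f"outside transcript")

    def spliced_window_to_genome(self, start: int, end: int
                                 ) -> list[Interval]:
        """Project a spliced-coordinate window onto genome exon pieces."""
        out: list[Interval] = []
        off = 0
        for s, e in self.exons:
            elen = e - s
            lo = max(start, off)
            hi = min(end, off + elen)
            if lo < hi:
                out.append((s + lo - off, s + hi - off))
            off += elen
        return out

    def genome_to_spliced(self, pos: int) -> int | None:
        """Map a genome coordinate into spliced-transcript coordinates.

        Returns None for intronic/outside positions. Plus-strand spliced
        frame regardless of transcript strand (coverage analyses here are
        strand-blind).
        """
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None


class AnnotationSet:
    """Gene/transcript/exon model with derived union tracks.

    Derived tracks (all per sequence name, merged interval lists):
    ``exon_union``, ``intron_union`` (intronic positions not in any exon),
    and ``intergenic_union`` (positions in neither, requires genome
    lengths).
    """

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        genome: GenomeModel | None = None,
    ) -> None:
        self.transcripts: dict[str, Transcript] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
            if genome is not None and t.seqname not in genome:
                raise FormatError(
                    f"transcript {t.transcript_id!r} on unknown sequence "
                    f"{t.seqname!r}"
                )
            self.transcripts[t.transcript_id] = t
        self._lengths = genome.lengths if genome is not None else None

        by_seq: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            by_seq.setdefault(t.seqname, []).append(t)
        self.exon_union: dict[str, list[Interval]] = {}
        self.intron_union: dict[str, list[Interval]] = {}
        for seqname, ts in by_seq.items():
            exons = [e for t in ts for e in t.exons]
            introns = [i for t in ts for i in t.introns]
            self.exon_union[seqname] = iv.merge(exons)
            # intron track excludes positions exonic in any transcript
            self.intron_union[seqname] = iv.subtract(
                iv.merge(introns), self.exon_union[seqname]
            )

    @property
    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, []).append(t)
        return out

    @property
    def exome_size(self) -> int:
        """Total bases in the global exon union across sequences."""
        return sum(iv.total_length(u) for u in self.exon_union.values())

    @property
    def intergenic_union(self) -> dict[str, list[Interval]]:
        if self._lengths is None:
            raise ValueError("intergenic track requires a genome (lengths)")
        out = {}
        for seqname, length in self._lengths.items():
            genic = iv.merge(
                self.exon_union.get(seqname, [])
                + self.intron_union.get(seqname, [])
            )
            out[seqname] = iv.complement(genic, length)
        return out

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts.values())


@dataclass(frozen=True)
class Block:
    """One gapless aligned block: equal-length query and target pieces."""

    qstart: int
    tstart: int
    size: int

    @property
    def qend(self) -> int:
        return self.qstart + self.size

    @property
    def tend(self) -> int:
        return self.tstart + self.size


@dataclass
class BlockAlignment:
    """One scaffold-to-genome alignment as ordered co-linear blocks.

    Blocks are stored in target order; query starts are always in the
    plus-strand query frame (minus-strand PSL rows are normalized on
    read).
    """

    qname: str
    qsize: int
    tname: str
    tsize: int
    strand: str
    blocks: list[Block]
    matches: int

    def __post_init__(self) -> None:
        if sum(b.size for b in self.blocks) > self.qsize:
            raise ValueError(
                f"{self.qname}: aligned bases exceed query length"
            )
        for b1, b2 in zip(self.blocks, self.blocks[1:]):
            if b2.tstart < b1.tend:
                raise ValueError(f"{self.qname}: target blocks overlap")

    @property
    def aligned_query_bases(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def aligned_query_fraction(self) -> float:
        return self.aligned_query_bases / self.qsize

    @property
    def target_intervals(self) -> list[Interval]:
        return [(b.tstart, b.tend) for b in self.blocks]

    @property
    def query_intervals(self) -> list[Interval]:
        return sorted((b.qstart, b.qend) for b in self.blocks)

    @property
    def target_span(self) -> Interval:
        return (self.blocks[0].tstart, self.blocks[-1].tend)


@dataclass
class ReadRecord:
    """One sequencing read: identifier, mate index, bases, PHRED scores."""

    identifier: str
    mate: int
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.identifier}/{self.mate}: quality length != read length"
            )


@dataclass
class ReadPairPlacement:
    """Mapped placement of a read pair (leftmost coordinates, BAM-style)."""

    pair_id: str
    seqname: str
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    proper: bool = True


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeModel:
    """Load a FASTA file into a :class:`GenomeModel`.

    Lowercase bases are uppercased (logged); duplicate record names and
    characters outside {A,C,G,T,N} raise :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq)
        if any(c.islower() for c in seq):
            n_lower += 1
            seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r}: illegal character(s) {sorted(bad)}"
            )
        sequences[rec.id] = seq
    if n_lower:
        log.info("uppercased %d record(s) containing lowercase bases", n_lower)
    if not sequences:
        log.warning("FASTA file %s contained no records", path)
    return GenomeModel(sequences)


def write_fasta(model: GenomeModel | Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    recs = (
        model.sequences if isinstance(model, GenomeModel) else dict(model)
    )
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in recs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, genome: GenomeModel | None = None
              ) -> AnnotationSet:
    """Load gene/mRNA/exon features from GFF3 into an :class:`AnnotationSet`.

    GFF3 1-based closed coordinates are converted to internal 0-based
    half-open. Exons must lie within their parent transcript span.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = []
    for feat in db.all_features():
        if feat.featuretype not in ("mRNA", "transcript"):
            continue
        parents = list(db.parents(feat, featuretype="gene"))
        gene_id = parents[0].id if parents else feat.id
        exons = []
        for ex in db.children(feat, featuretype="exon", order_by="start"):
            s, e = ex.start - 1, ex.end
            if s < feat.start - 1 or e > feat.end:
                raise FormatError(
                    f"exon ({ex.start},{ex.end}) outside transcript "
                    f"{feat.id!r} span"
                )
            exons.append((s, e))
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        transcripts.append(
            Transcript(feat.id, gene_id, feat.seqid, feat.strand, exons)
        )
    return AnnotationSet(transcripts, genome=genome)


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Write an annotation back out as gene/mRNA/exon GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, ts in ann.genes.items():
            gs = min(t.span[0] for t in ts)
            ge = max(t.span[1] for t in ts)
            seqname, strand = ts[0].seqname, ts[0].strand
            fh.write(
                f"{seqname}\tasmeval\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in ts:
                s, e = t.span
                fh.write(
                    f"{t.seqname}\tasmeval\tmRNA\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (es, ee) in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.seqname}\tasmeval\texon\t{es + 1}\t{ee}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_NCOL = 21


def _parse_psl_row(fields: list[str], lineno: int) -> BlockAlignment:
    if len(fields) != _PSL_NCOL:
        raise FormatError(
            f"PSL line {lineno}: expected {_PSL_NCOL} columns, "
            f"got {len(fields)}"
        )
    matches = int(fields[0])
    strand = fields[8]
    qname, qsize = fields[9], int(fields[10])
    tname, tsize = fields[13], int(fields[14])
    nblocks = int(fields[17])
    sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
    qstarts = [int(x) for x in fields[19].rstrip(",").split(",")]
    tstarts = [int(x) for x in fields[20].rstrip(",").split(",")]
    if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
        raise FormatError(f"PSL line {lineno}: block count mismatch")
    blocks = []
    for size, qs, ts in zip(sizes, qstarts, tstarts):
        if qs + size > qsize:
            raise FormatError(
                f"PSL line {lineno}: block exceeds qSize for {qname!r}"
            )
        if strand.startswith("-"):
            # qStarts of minus-strand rows are in the reversed-query frame
            qs = qsize - (qs + size)
        blocks.append(Block(qs, ts, size))
    return BlockAlignment(qname, qsize, tname, tsize, strand[0], blocks,
                          matches)


def read_psl(path: str | Path) -> list[BlockAlignment]:
    """Read a 21-column PSL file (header lines tolerated and skipped)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            first = line.split("\t", 1)[0]
            if not first.lstrip("-").isdigit():
                continue  # header remnant
            out.append(_parse_psl_row(line.split("\t"), lineno))
    return out


def write_psl(alignments: Iterable[BlockAlignment], path: str | Path) -> None:
    """Write alignments as headerless 21-column PSL."""
    with open(path, "w") as fh:
        for a in alignments:
            blocks = a.blocks
            if a.strand == "-":
                qstarts = [a.qsize - b.qend for b in blocks]
            else:
                qstarts = [b.qstart for b in blocks]
            sizes = [b.size for b in blocks]
            tstarts = [b.tstart for b in blocks]
            aligned = sum(sizes)
            qstart = min(b.qstart for b in blocks)
            qend = max(b.qend for b in blocks)
            row = [
                a.matches, aligned - a.matches, 0, 0, 0, 0,
                max(0, len(blocks) - 1),
                blocks[-1].tend - blocks[0].tstart - aligned,
                a.strand, a.qname, a.qsize, qstart, qend,
                a.tname, a.tsize, blocks[0].tstart, blocks[-1].tend,
                len(blocks),
                ",".join(map(str, sizes)) + ",",
                ",".join(map(str, qstarts)) + ",",
                ",".join(map(str, tstarts)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# FASTQ and placement tables
# ---------------------------------------------------------------------------


def read_fastq_pairs(path1: str | Path, path2: str | Path
                     ) -> list[tuple[ReadRecord, ReadRecord]]:
    """Load a pair of FASTQ files into (mate1, mate2) record tuples."""
    pairs = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        pairs.append((
            ReadRecord(r1.id, 1, str(r1.seq),
                       list(r1.letter_annotations["phred_quality"])),
            ReadRecord(r2.id, 2, str(r2.seq),
                       list(r2.letter_annotations["phred_quality"])),
        ))
    return pairs


def write_fastq_pairs(pairs: Sequence[tuple[ReadRecord, ReadRecord]],
                      path1: str | Path, path2: str | Path) -> None:
    def _rec(r: ReadRecord) -> SeqRecord:
        rec = SeqRecord(Seq(r.sequence), id=r.identifier, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        return rec

    SeqIO.write([_rec(p[0]) for p in pairs], str(path1), "fastq")
    SeqIO.write([_rec(p[1]) for p in pairs], str(path2), "fastq")
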