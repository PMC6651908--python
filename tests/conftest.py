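"""Shared fixtures and toy-instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from asmeval.core import (
    AnnotationSet,
    Block,
    BlockAlignment,
    GenomeModel,
    Transcript,
)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def random_intervals(rng: np.random.Generator, length: int,
                     max_n: int = 6) -> list[tuple[int, int]]:
    """Unsorted, possibly overlapping half-open intervals within [0, length)."""
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length))
        e = int(rng.integers(s + 1, length + 1))
        out.append((s, e))
    return out


def random_disjoint_intervals(rng: np.random.Generator, length: int,
                              max_n: int = 4) -> list[tuple[int, int]]:
    """Sorted, pairwise-disjoint half-open intervals (valid exon lists)."""
    cuts = sorted(rng.choice(length + 1, size=2 * max_n, replace=False))
    out = []
    for s, e in zip(cuts[::2], cuts[1::2]):
        if rng.random() < 0.7 and s < e:
            out.append((int(s), int(e)))
    return out


def random_alignment(rng: np.random.Generator, qname: str, tname: str,
                     tsize: int) -> BlockAlignment:
    """A valid random block alignment onto [0, tsize)."""
    blocks = []
    qpos = 0
    tpos = int(rng.integers(0, max(1, tsize // 2)))
    for _ in range(int(rng.integers(1, 4))):
        size = int(rng.integers(1, 30))
        if tpos + size > tsize:
            break
        blocks.append(Block(qpos, tpos, size))
        qpos += size + int(rng.integers(0, 5))
        tpos += size + int(rng.integers(0, 40))
    if not blocks:
        blocks = [Block(0, 0, 1)]
        qpos = 1
    qsize = qpos + int(rng.integers(0, 10))
    matches = sum(b.size for b in blocks)
    return BlockAlignment(qname, qsize, tname, tsize, "+", blocks, matches)


@pytest.fixture
def toy_genome() -> GenomeModel:
    rng = np.random.default_rng(17)
    return GenomeModel({
        "chr1": random_seq(rng, 600),
        "chr2": random_seq(rng, 400),
    })


@pytest.fixture
def toy_annotation(toy_genome) -> AnnotationSet:
    ts = [
        Transcript("tA", "gA", "chr1", "+", [(10, 60), (100, 160), (200, 240)]),
        Transcript("tB", "gB", "chr1", "-", [(300, 380), (420, 500)]),
        Transcript("tC", "gC", "chr2", "+", [(50, 200)]),
    ]
    return AnnotationSet(ts, toy_genome)
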