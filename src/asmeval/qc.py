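"""Read filtering, clean-pair selection, deduplication, pooling, subsampling.

Implements SOAPnuke-style pair filters (adapter / low-quality /
ambiguous-base rules), the alignment-based clean-pair definition,
Picard-convention coordinate deduplication, library pooling, nested
base-count subsampling, and the per-step accounting report.

Counts throughout are in read *pairs* (SRA "spots").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from asmeval.core import ReadRecord

log = logging.getLogger(__name__)

PLACEMENT_COLUMNS = [
    "pair_id", "seq", "pos1", "strand1", "pos2", "strand2", "proper",
]

PAIR_COLUMNS = ["pair_id", "bases"]


@dataclass
class QcThresholds:
    """Pair-filter thresholds.

    A pair is dropped when either mate trips a rule. Rules, in recorded
    order: adapter contamination, low-quality bases, ambiguous bases.

    * low-quality: strictly more than ``max_low_quality_fraction`` of the
      bases below ``low_quality_phred``.
    * ambiguous: strictly more than ``max_ambiguous_fraction`` N's.
    * adapter: at least ``min_adapter_fraction`` of an adapter present
      with at most ``max_adapter_mismatches`` mismatches. Matching is
      anchored in read-through geometry: the match must start at the
      adapter's 5' end and terminate at the read's 3' end (an unanchored
      half-adapter-with-one-mismatch scan would fire on random sequence).
    """

    low_quality_phred: int = 10
    max_low_quality_fraction: float = 0.10
    max_ambiguous_fraction: float = 0.01
    adapters: tuple[str, ...] = ()
    min_adapter_fraction: float = 0.50
    max_adapter_mismatches: int = 1

    def __post_init__(self) -> None:
        for f in (self.max_low_quality_fraction, self.max_ambiguous_fraction,
                  self.min_adapter_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.low_quality_phred < 0:
            raise ValueError("PHRED cutoff must be >= 0")


def _has_anchored_adapter(read: str, adapter: str, min_fraction: float,
                          max_mismatches: int) -> bool:
    alen = len(adapter)
    kmin = max(1, math.ceil(min_fraction * alen))
    for k in range(min(alen, len(read)), kmin - 1, -1):
        tail = read[-k:]
        mism = sum(a != b for a, b in zip(tail, adapter[:k]))
        if mism <= max_mismatches:
            return True
    return False


def _mate_verdicts(read: ReadRecord, t: QcThresholds) -> dict[str, bool]:
    if not read.sequence:
        raise ValueError(f"empty read {read.identifier!r}")
    n = len(read.sequence)
    low = sum(q < t.low_quality_phred for q in read.qualities)
    amb = read.sequence.count("N")
    return {
        "adapter": any(
            _has_anchored_adapter(read.sequence, a, t.min_adapter_fraction,
                                  t.max_adapter_mismatches)
            for a in t.adapters
        ),
        "low_quality": low / n > t.max_low_quality_fraction,
        "ambiguous": amb / n > t.max_ambiguous_fraction,
    }


def filter_read_pair(pair: tuple[ReadRecord, ReadRecord],
                     t: QcThresholds) -> str:
    """Return ``keep`` or ``drop:<category>`` for one read pair.

    The recorded category is the first tripped rule in the order
    adapter, low-quality, ambiguous, considering both mates.
    """
    v1 = _mate_verdicts(pair[0], t)
    v2 = _mate_verdicts(pair[1], t)
    for rule in ("adapter", "low_quality", "ambiguous"):
        if v1[rule] or v2[rule]:
            return f"drop:{rule}"
    return "keep"


def filter_pairs(pairs: Sequence[tuple[ReadRecord, ReadRecord]],
                 t: QcThresholds
                 ) -> tuple[list[tuple[ReadRecord, ReadRecord]],
                            dict[str, int]]:
    """Filter a library; return kept pairs and per-category removal counts."""
    kept = []
    counts = {"adapter": 0, "low_quality": 0, "ambiguous": 0}
    for pair in pairs:
        verdict = filter_read_pair(pair, t)
        if verdict == "keep":
            kept.append(pair)
        else:
            counts[verdict.split(":", 1)[1]] += 1
    return kept, counts


# ---------------------------------------------------------------------------
# Placement-based filters
# ---------------------------------------------------------------------------


def clean_pair_filter(placements: pd.DataFrame,
                      max_span: int = 10_000) -> pd.Index:
    """Pair ids whose mates align consistently in location and direction.

    Kept pairs have both mates on the same sequence (one row per pair in
    the placement table; unpaired/improper rows are excluded and
    logged), in convergent orientation (opposite strands with the
    plus-strand mate leftmost), with outer span at most ``max_span``.
    """
    df = placements
    improper = ~df["proper"].astype(bool)
    if improper.any():
        log.info("excluding %d unpaired/improper placements",
                 int(improper.sum()))
    df = df[~improper]
    left = df[["pos1", "pos2"]].min(axis=1)
    right = df[["pos1", "pos2"]].max(axis=1)
    opposite = df["strand1"] != df["strand2"]
    plus_pos = np.where(df["strand1"] == "+", df["pos1"], df["pos2"])
    minus_pos = np.where(df["strand1"] == "-", df["pos1"], df["pos2"])
    convergent = opposite & (plus_pos <= minus_pos)
    ok = convergent & (right - left <= max_span)
    return pd.Index(df.loc[ok, "pair_id"])


def deduplicate(placements: pd.DataFrame) -> pd.Index:
    """Collapse pairs sharing both mates' coordinates and strands.

    Duplicate key: (sequence, mate-1 position+strand, mate-2
    position+strand). The representative of each group is the
    lexicographically smallest pair id. Idempotent by construction.
    """
    df = placements.sort_values("pair_id", kind="stable")
    kept = df.drop_duplicates(
        subset=["seq", "pos1", "strand1", "pos2", "strand2"], keep="first"
    )
    return pd.Index(kept["pair_id"])


# ---------------------------------------------------------------------------
# Subsampling and pooling
# ---------------------------------------------------------------------------


def subsample_to_bases(pairs: pd.DataFrame, target_bases: int,
                       seed: int) -> pd.DataFrame:
    """Uniformly subsample whole pairs until ``target_bases`` is reached.

    Pairs are drawn without replacement by truncating one seeded
    permutation, so subsets at increasing targets under the same seed
    are nested. The first pair crossing the target is included. If the
    library is smaller than the target the whole library is returned
    with a warning.

    ``pairs`` needs columns ``pair_id`` and ``bases`` (total bases of
    both mates).
    """
    if target_bases <= 0:
        raise ValueError("target_bases must be positive")
    if len(pairs) == 0:
        raise ValueError("cannot subsample an empty library")
    total = int(pairs["bases"].sum())
    if total < target_bases:
        log.warning(
            "library holds %d bases < target %d; returning whole library",
            total, target_bases,
        )
        return pairs.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    cum = np.cumsum(pairs["bases"].to_numpy()[order])
    n_take = int(np.searchsorted(cum, target_bases, side="left")) + 1
    return pairs.iloc[np.sort(order[:n_take])].copy()


def pool_libraries(libraries: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate pair tables, prefixing pair ids with the library name."""
    frames = []
    for name, df in libraries.items():
        if len(df) == 0:
            log.warning("library %r is empty; skipped", name)
            continue
        tagged = df.copy()
        tagged["library"] = name
        tagged["pair_id"] = name + ":" + tagged["pair_id"].astype(str)
        frames.append(tagged)
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS + ["library"])
    pooled = pd.concat(frames, ignore_index=True)
    if pooled["pair_id"].duplicated().any():
        raise ValueError("pair id collision after library prefixing")
    return pooled


# ---------------------------------------------------------------------------
# Step report
# ---------------------------------------------------------------------------


@dataclass
class StepReport:
    """Per-step read accounting with removal percentages.

    ``per_library``: input counts plus ``removed_<step>`` /
    ``pct_removed_<step>`` columns. ``aggregate``: per-platform column
    sums with aggregate removal percentages (libraries are summed before
    dividing). Percentages follow the convention pct at step k =
    100 * (count_{k-1} - count_k) / count_{k-1}, rounded to two
    decimals.
    """

    steps: list[str]
    per_library: pd.DataFrame
    aggregate: pd.DataFrame
    categories: pd.DataFrame | None = None

    def pct_removed(self, platform: str, step: str) -> float:
        row = self.aggregate.set_index("platform").loc[platform]
        return float(row[f"pct_removed_{step}"])

    def total(self, platform: str, step: str) -> int:
        row = self.aggregate.set_index("platform").loc[platform]
        return int(row[step])

    def category_pct(self, platform: str, category: str) -> float:
        """Aggregate share of raw reads removed under one filter category."""
        if self.categories is None:
            raise ValueError("no category counts supplied")
        cat = self.categories[self.categories["platform"] == platform]
        raw = self.total(platform, self.steps[0])
        return round(100.0 * cat[category].sum() / raw, 2)


def build_step_report(step_counts: pd.DataFrame,
                      category_counts: pd.DataFrame | None = None,
                      steps: Sequence[str] | None = None) -> StepReport:
    """Build the per-step accounting report from surviving-read counts.

    ``step_counts`` holds one row per library with columns ``platform``,
    ``library`` and one column per step (ordered, monotone
    non-increasing counts). ``category_counts`` optionally carries the
    filter-step removals split by category (adapter / low_quality /
    ambiguous); the category sums must equal the filter-step removal.
    """
    if steps is None:
        steps = [c for c in step_counts.columns
                 if c not in ("platform", "library")]
    steps = list(steps)
    counts = step_counts[steps].to_numpy()
    if (np.diff(counts, axis=1) > 0).any():
        raise ValueError("read counts increase across a preprocessing step")

    per_lib = step_counts.copy()
    for prev, cur in zip(steps, steps[1:]):
        removed = per_lib[prev] - per_lib[cur]
        per_lib[f"removed_{cur}"] = removed
        per_lib[f"pct_removed_{cur}"] = (
            100.0 * removed / per_lib[prev]
        ).round(2)

    agg = step_counts.groupby("platform", as_index=False)[steps].sum()
    for prev, cur in zip(steps, steps[1:]):
        agg[f"pct_removed_{cur}"] = (
            100.0 * (agg[prev] - agg[cur]) / agg[prev]
        ).round(2)

    if category_counts is not None:
        cats = [c for c in category_counts.columns
                if c not in ("platform", "library")]
        merged = step_counts.merge(category_counts,
                                   on=["platform", "library"])
        removed = merged[steps[0]] - merged[steps[1]]
        if not (merged[cats].sum(axis=1) == removed).all():
            log.warning("category counts do not sum to filter-step removals")
    return StepReport(steps, per_lib, agg, category_counts)


def write_report_tsv(report: StepReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-step read accounting (counts in pairs)\n")
        report.per_library.to_csv(fh, sep="\t", index=False)
        fh.write("# aggregate\n")
        report.aggregate.to_csv(fh, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement table missing columns: {sorted(missing)}")
    return df


def write_placements_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[PLACEMENT_COLUMNS].to_csv(path, sep="\t", index=False)
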