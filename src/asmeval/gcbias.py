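"""GC-bias diagnostics: gap regions, GC cumulants, windowed depth-ratio
curves, and abundance-ratio regression.

Three complementary views of composition bias between sequencing
libraries: (1) the GC content of assembled versus gap regions of
discordantly assembled transcripts (length-weighted empirical CDFs);
(2) the mean ratio of 100-base window depth to whole-transcript depth
as a function of window GC, on transcripts with unambiguous read
assignment (a flat curve at one means no bias); (3) ordinary least
squares of the log10 abundance ratio between two libraries on
transcript GC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from asmeval import intervals as iv
from asmeval.core import AnnotationSet
from asmeval.intervals import Interval

log = logging.getLogger(__name__)


@dataclass
class GcBiasParams:
    window_length: int = 100
    min_mean_depth: float = 10.0
    min_gap_bases: int = 10
    representativeness_segment_pct: int = 1
    tpm_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if min(self.min_mean_depth, self.min_gap_bases,
               self.tpm_threshold) < 0:
            raise ValueError("thresholds must be >= 0")


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases (NaN if the region is all N)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


# ---------------------------------------------------------------------------
# Gap regions and cumulants
# ---------------------------------------------------------------------------


def gap_regions(transcript_length: int,
                scaffold_cover: Sequence[Interval],
                read_cover: Sequence[Interval],
                min_gap_bases: int = 10,
                ) -> tuple[list[Interval], bool]:
    """Gap intervals of one transcript and its inclusion flag.

    A gap is a transcript stretch covered by neither scaffolds nor reads
    (read coverage alone vetoes a gap). The transcript enters the
    gap-vs-assembled comparison only when its total gap length reaches
    ``min_gap_bases``.
    """
    covered = iv.merge(list(scaffold_cover) + list(read_cover))
    gaps = iv.complement(covered, transcript_length)
    total = sum(e - s for s, e in gaps)
    return gaps, total >= min_gap_bases


def select_discordant_transcripts(
        complete_sets: Mapping[str, set[str]],
        platforms: Mapping[str, str],
) -> dict[str, set[str]]:
    """Per-platform sets of transcripts that platform uniformly misses.

    A transcript enters platform A's set when it is complete in no
    A-platform library but complete in at least one library of the
    other platform. Transcripts complete on both platforms, or nowhere,
    are excluded.
    """
    plats = sorted(set(platforms.values()))
    if len(plats) != 2:
        raise ValueError("exactly two platforms required")
    union: dict[str, set[str]] = {p: set() for p in plats}
    for lib, s in complete_sets.items():
        union[platforms[lib]] |= s
    return {
        plats[0]: union[plats[1]] - union[plats[0]],
        plats[1]: union[plats[0]] - union[plats[1]],
    }


def gc_cumulants(regions: Sequence[tuple[str, int, int]],
                 transcript_seqs: Mapping[str, str],
                 ) -> pd.DataFrame:
    """Length-weighted empirical CDF of per-region GC content.

    ``regions`` are (transcript_id, start, end) in spliced coordinates;
    GC is computed on the reference transcript sequence (for gap
    regions no assembled sequence exists, so the reference is the only
    symmetric choice). Returns a table with columns ``gc`` (sorted) and
    ``cum`` (cumulative length fraction). All-N regions are skipped.
    """
    rows = []
    for tid, s, e in regions:
        gc = gc_content(transcript_seqs[tid][s:e])
        if np.isnan(gc):
            log.info("skipping all-N region %s:%d-%d", tid, s, e)
            continue
        rows.append((gc, e - s))
    if not rows:
        raise ValueError("no usable regions")
    df = pd.DataFrame(rows, columns=["gc", "length"]).sort_values("gc")
    df["cum"] = df["length"].cumsum() / df["length"].sum()
    return df[["gc", "cum", "length"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Windowed depth-ratio curve
# ---------------------------------------------------------------------------


def _gc_histogram(gcs: Sequence[float], segment_pct: int) -> np.ndarray:
    edges = np.arange(0, 100 + segment_pct, segment_pct) / 100.0
    hist, _ = np.histogram(np.asarray(gcs), bins=edges)
    return hist


def select_bias_transcripts(annotation: AnnotationSet,
                            depth_tracks: Mapping[str, Mapping[str,
                                                               np.ndarray]],
                            params: GcBiasParams | None = None,
                            transcript_gc: Mapping[str, float] | None = None,
                            ) -> tuple[set[str], float]:
    """Transcripts eligible for the depth-ratio analysis, plus Spearman rho.

    Eligible transcripts have zero genomic overlap with any other
    annotated transcript (so reads assign unambiguously) and mean read
    depth of at least the threshold in *every* compared dataset. Rho is
    the Spearman correlation between the GC histograms (1% segments) of
    the selected set and the full transcript set — the
    representativeness check.
    """
    if params is None:
        params = GcBiasParams()
    # genomic-overlap exclusion via span sweep per sequence
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for t in annotation:
        spans.setdefault(t.seqname, []).append((*t.span, t.transcript_id))
    overlapping: set[str] = set()
    for seq_spans in spans.values():
        seq_spans.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(seq_spans, seq_spans[1:]):
            if s2 < e1:
                overlapping |= {id1, id2}

    selected = set()
    for t in annotation:
        if t.transcript_id in overlapping:
            continue
        ok = all(
            t.transcript_id in tracks
            and tracks[t.transcript_id].mean() >= params.min_mean_depth
            for tracks in depth_tracks.values()
        )
        if ok:
            selected.add(t.transcript_id)
    if not selected:
        raise ValueError(
            "no transcript passes the overlap/depth selection; lower "
            "min_mean_depth or deepen the libraries"
        )

    if transcript_gc is None:
        raise ValueError("transcript_gc required for the representativeness "
                         "check")
    all_gc = [transcript_gc[t.transcript_id] for t in annotation]
    sel_gc = [transcript_gc[tid] for tid in selected]
    seg = params.representativeness_segment_pct
    h_all = _gc_histogram(all_gc, seg)
    h_sel = _gc_histogram(sel_gc, seg)
    if len(selected) == len(annotation.transcripts):
        rho = 1.0
    else:
        rho = float(stats.spearmanr(h_all, h_sel).statistic)
    return selected, rho


@dataclass
class GcBiasCurve:
    """Mean depth ratio per integer GC-percent bin."""

    table: pd.DataFrame  # columns: gc_bin, mean_ratio, n_windows
    transcript_ids: set[str]
    spearman_rho: float | None = None

    @property
    def total_windows(self) -> int:
        return int(self.table["n_windows"].sum())

    def global_mean_ratio(self) -> float:
        t = self.table
        return float((t["mean_ratio"] * t["n_windows"]).sum()
                     / t["n_windows"].sum())


def gc_bias_curve(transcript_ids: Sequence[str],
                  depth: Mapping[str, np.ndarray],
                  transcript_seqs: Mapping[str, str],
                  params: GcBiasParams | None = None,
                  ) -> GcBiasCurve:
    """Windowed depth-ratio versus GC curve.

    Windows tile each transcript from its 5' end; a trailing partial
    window is discarded. Ratio = window mean depth / transcript mean
    depth (mean over raw positions of the whole transcript); window GC
    is binned to integer percent. Transcripts shorter than one window
    are skipped with a log message.
    """
    if params is None:
        params = GcBiasParams()
    w = params.window_length
    gc_bins: list[int] = []
    ratios: list[float] = []
    used: set[str] = set()
    for tid in transcript_ids:
        d = np.asarray(depth[tid], dtype=float)
        if len(d) < w:
            log.info("transcript %s shorter than one window; skipped", tid)
            continue
        tmean = d.mean()
        if tmean == 0:
            continue
        seq = transcript_seqs[tid]
        used.add(tid)
        n_win = len(d) // w
        for k in range(n_win):
            win = slice(k * w, (k + 1) * w)
            gc = gc_content(seq[win])
            if np.isnan(gc):
                continue
            gc_bins.append(int(round(100 * gc)))
            ratios.append(d[win].mean() / tmean)
    df = pd.DataFrame({"gc_bin": gc_bins, "ratio": ratios})
    table = (
        df.groupby("gc_bin")["ratio"].agg(["mean", "size"]).reset_index()
        .rename(columns={"mean": "mean_ratio", "size": "n_windows"})
    )
    return GcBiasCurve(table, used)


# ---------------------------------------------------------------------------
# Abundance and regression
# ---------------------------------------------------------------------------


def tpm_estimates(counts: Mapping[str, int],
                  lengths: Mapping[str, int],
                  fragment_length: int = 1) -> pd.Series:
    """Transcripts-per-million from unambiguous read counts.

    rate_i = count_i / effective length, with effective length =
    max(1, L_i - fragment_length + 1); TPM = 1e6 * rate_i / sum(rate).
    Transcripts absent from ``counts`` get zero. TPMs sum to 1e6.
    """
    tids = list(lengths)
    c = np.array([counts.get(t, 0) for t in tids], dtype=float)
    if c.sum() == 0:
        raise ValueError("zero total read count")
    eff = np.array([max(1, lengths[t] - fragment_length + 1) for t in tids],
                   dtype=float)
    rate = c / eff
    return pd.Series(1e6 * rate / rate.sum(), index=tids, name="tpm")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    stderr: float
    n_included: int
    included_fraction: float


def abundance_ratio_regression(tpm_a: pd.Series, tpm_b: pd.Series,
                               transcript_gc: Mapping[str, float],
                               params: GcBiasParams | None = None,
                               ) -> RegressionResult:
    """OLS of log10(TPM_a / TPM_b) on GC content (fraction in [0, 1]).

    Only transcripts with TPM at or above the threshold in *both*
    libraries enter the fit (the low-abundance tail is high-variance).
    A positive slope means library B is depleted at high GC relative to
    library A.
    """
    if params is None:
        params = GcBiasParams()
    common = tpm_a.index.intersection(tpm_b.index)
    a, b = tpm_a[common], tpm_b[common]
    mask = (a >= params.tpm_threshold) & (b >= params.tpm_threshold)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 transcripts pass the TPM threshold")
    included = common[mask]
    y = np.log10(a[included].to_numpy() / b[included].to_numpy())
    x = np.array([transcript_gc[t] for t in included])
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        n_included=int(mask.sum()),
        included_fraction=float(mask.sum() / len(common)),
    )
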