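"""Top-level orchestration: run all evaluation stages and write reports.

The pipeline runs either fully synthetically (a generator preset
produces genome, annotation, reads and scaffolds, and every downstream
stage is exercised) or on external inputs (FASTA + GFF3 + PSL), in
which case the read-dependent stages that need generator truth are
skipped and coverage/classification run on the supplied alignments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import asmeval
from asmeval import classify as cl
from asmeval import completeness as cp
from asmeval import coverage as cov
from asmeval import gcbias as gb
from asmeval import qc, synth
from asmeval.core import read_fasta, read_gff3, read_psl, write_fasta, \
    write_gff3, write_psl

log = logging.getLogger(__name__)

_PRESETS = {
    "depth-study": synth.preset_depth_study,
    "gc-bias": synth.preset_gc_bias,
    "completeness": synth.preset_completeness,
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    preset: str | None = "completeness"
    genome_fasta: str | None = None
    annotation_gff: str | None = None
    psl: str | None = None
    n_pairs: int = 50_000
    subsample_sizes: tuple[int, ...] = ()
    min_aligned_fraction: float = 0.98
    best_hit_only: bool = True
    report_threshold: int = 80
    min_assembly_depth: float = 5.0

    def validate(self) -> None:
        if self.preset is None:
            if self.genome_fasta is None or self.psl is None:
                raise ValueError(
                    "external mode needs at least a genome FASTA and a PSL")
            for p in (self.genome_fasta, self.annotation_gff, self.psl):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
        elif self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(_PRESETS)}")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the stages in order and write tabular outputs plus a log.

    Returns a report bundle (dict of the main result objects). Output
    tables land in ``config.out_dir``; the run log records the package
    version, the seed, and every threshold in effect.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    if config.preset is not None:
        cfg = _PRESETS[config.preset](seed=config.seed)
        genome, annotation, truth = synth.simulate_genome_annotation(cfg)
        reads, placements = synth.simulate_reads(genome, truth, cfg,
                                                 config.n_pairs)
        scaffolds, alignments, scaffold_df = synth.simulate_scaffolds(
            genome, truth, cfg)
        write_fasta(genome, out / "genome.fasta")
        write_gff3(annotation, out / "annotation.gff3")
        write_fasta(scaffolds, out / "scaffolds.fasta")
        write_psl(alignments, out / "scaffolds.psl")
        qc.write_placements_tsv(placements, out / "placements.tsv")

        # QC stage: clean pairs, dedup, step accounting
        clean = qc.clean_pair_filter(placements)
        dedup = qc.deduplicate(placements[placements["pair_id"].isin(clean)])
        steps = pd.DataFrame([{
            "platform": "synthetic", "library": config.preset,
            "raw": len(placements), "clean": len(clean),
            "deduplicated": len(dedup),
        }])
        report = qc.build_step_report(steps)
        qc.write_report_tsv(report, out / "qc_report.tsv")
        bundle["qc_report"] = report

        sizes = config.subsample_sizes or _default_sizes(
            len(reads), cfg.read_length)
        lengths = {tid: t.length
                   for tid, t in synth.all_transcript_objects(truth).items()}
        by_transcript: dict[str, list] = {}
        for a, src in zip(alignments, scaffold_df["sources"]):
            if "+" not in src:
                by_transcript.setdefault(src, []).append(a)
        curve = cov.coverage_curve(
            reads, sizes, config.seed, annotation, by_transcript, lengths,
            read_length=cfg.read_length,
            min_assembly_depth=config.min_assembly_depth)
        cov.write_coverage_tsv(curve, out / "coverage_curve.tsv")
        bundle["coverage_curve"] = curve

        retained, verdicts = cov.filter_alignments(
            alignments, cov.AlignmentFilterParams(
                config.min_aligned_fraction, config.best_hit_only))
        bundle["verdicts"] = verdicts
        params = cl.ClassificationParams(
            report_threshold=config.report_threshold)
        records = cl.classify_scaffolds(
            retained, annotation, scaffolds.sequences, params)
        summary = cl.sweep_summary(records, params)
        cl.write_classification_tsvs(records, summary, out)
        bundle["classification"] = records
        bundle["sweep"] = summary

        sources = dict(zip(scaffold_df["scaffold_id"],
                           scaffold_df["sources"]))
        comp = cp.completeness_by_size(
            reads, sizes, config.seed, annotation, retained, sources,
            read_length=cfg.read_length,
            min_assembly_depth=config.min_assembly_depth)
        comp[["size_bp", "n_complete"]].to_csv(
            out / "completeness_by_size.tsv", sep="\t", index=False)
        bundle["completeness"] = comp

        tr_objs = synth.all_transcript_objects(truth)
        seqs = {tid: t.spliced_sequence(genome)
                for tid, t in tr_objs.items()}
        depth = synth.transcript_read_depth(reads, lengths, cfg.read_length)
        gc_of = dict(zip(truth.transcripts["transcript_id"],
                         truth.transcripts["gc"]))
        gparams = gb.GcBiasParams()
        try:
            selected, rho = gb.select_bias_transcripts(
                annotation, {"run": depth}, gparams, gc_of)
            bcurve = gb.gc_bias_curve(sorted(selected), depth, seqs, gparams)
            bcurve.spearman_rho = rho
            bcurve.table.to_csv(out / "gc_bias_curve.tsv", sep="\t",
                                index=False)
            bundle["gc_bias_curve"] = bcurve
        except ValueError as exc:
            log.warning("GC-bias stage skipped: %s", exc)
    else:
        genome = read_fasta(config.genome_fasta)
        annotation = (read_gff3(config.annotation_gff, genome)
                      if config.annotation_gff else None)
        alignments = read_psl(config.psl)
        retained, verdicts = cov.filter_alignments(
            alignments, cov.AlignmentFilterParams(
                config.min_aligned_fraction, config.best_hit_only))
        bundle["verdicts"] = verdicts
        genome_b, exome_b = cov.unique_base_coverage(retained, annotation)
        result = cov.CoverageResult(0, genome_b, exome_b)
        cols = dict(genome_bases=genome_b)
        if annotation is not None:
            cols["exome_bases"] = exome_b
        pd.DataFrame([cols]).to_csv(out / "coverage.tsv", sep="\t",
                                    index=False)
        bundle["coverage"] = result
        if annotation is not None:
            params = cl.ClassificationParams(
                report_threshold=config.report_threshold)
            records = cl.classify_scaffolds(retained, annotation,
                                            params=params)
            summary = cl.sweep_summary(records, params)
            cl.write_classification_tsvs(records, summary, out)
            bundle["classification"] = records
            bundle["sweep"] = summary
        else:
            log.warning("no annotation supplied: exome-dependent stages "
                        "skipped")

    with open(out / "run_log.json", "w") as fh:
        json.dump({
            "asmeval_version": asmeval.__version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": {k: (v if not isinstance(v, Path) else str(v))
                       for k, v in dataclasses.asdict(config).items()},
        }, fh, indent=2, default=str)
    return bundle


def _default_sizes(n_pairs: int, read_length: int) -> tuple[int, ...]:
    total = n_pairs * 2 * read_length
    return tuple(int(total * f) for f in
                 (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0))
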