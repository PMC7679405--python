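"""End-to-end orchestration: collapse -> map -> filter -> assign ->
{spectrum/bias, ping-pong} -> DE -> concordance, plus the synthetic demo.

``analyze`` is the in-memory engine shared by the file-based
:func:`run_pipeline` (used by the CLI) and :func:`tissue_roundtrip` (used
by the acceptance checks).  Every run records stage row counts in a
manifest so conservation violations surface immediately, and reruns with
an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate, concordance, de, filters, formats, mapping
from . import pingpong as pp
from . import strandbias, synthgen
from .core import BLACKLIST_TYPES, AnnotatedGenome

STAGE_ORDER = ["collapse", "map", "filter", "assign", "spectrum",
               "pingpong", "de", "concord"]


@dataclass
class PipelineParams:
    """All stage parameters of one pipeline run."""

    seed_k: int = 16
    min_len: int = 23
    max_len: int = 29
    min_total: int = 10
    mincount_scope: str = "pooled"
    min_overlap_frac: float = 0.5
    weighting: str = "count"            # count | unique
    spectrum_min_len: int = 18
    spectrum_max_len: int = 35
    kmax: int = 20
    pp_weight_mode: str = "product"
    alpha_mode: str = "pvalue"          # pvalue | fdr
    alpha: float = 0.01
    gene_alpha: float = 0.05
    sense_filter: str = "antisense"


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output."""

    reads: list
    alignments: dict
    kept: list
    report: filters.FilterReport
    assignments: list
    composition: annotate.CompositionTable
    spectrum: list
    bias: strandbias.BiasResult | None
    histogram: pp.OverlapHistogram | None
    pingpong: pp.PingPongResult | None
    de_table: pd.DataFrame | None
    pairs: pd.DataFrame | None
    quadrants: concordance.QuadrantTable | None
    stage_counts: dict = field(default_factory=dict)


def analyze(
    reads: list,
    genome: AnnotatedGenome,
    params: PipelineParams,
    groups: pd.Series | None = None,
    gene_de: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every analysis stage on collapsed reads against a genome."""
    counts: dict = {"collapse": len(reads)}
    index = mapping.SeedIndex(genome.contigs, k=params.seed_k)
    alignments = mapping.map_reads(index, reads)
    counts["map"] = sum(1 for a in alignments.values() if a)

    blacklist = genome.features_of_type(*BLACKLIST_TYPES)
    kept, report = filters.run_filters(
        reads, alignments, blacklist,
        min_len=params.min_len, max_len=params.max_len,
        min_total=params.min_total, mincount_scope=params.mincount_scope,
        groups=None if groups is None else list(groups),
    )
    counts["filter"] = report.kept_n

    assignments = annotate.assign_all(
        kept, alignments, genome.features,
        min_overlap_frac=params.min_overlap_frac, weighting=params.weighting)
    composition = annotate.composition_summary(assignments)
    counts["assign"] = len(assignments)

    spectrum = strandbias.length_strand_spectrum(
        assignments, min_len=params.spectrum_min_len,
        max_len=params.spectrum_max_len)
    bias = strandbias.bias_test(spectrum) if spectrum else None
    counts["spectrum"] = len(spectrum)

    te_ids = {a.read_id for a in assignments if a.category == "transposon"}
    te_alignments = [a for rid in te_ids for a in alignments[rid]]
    weights = {a.read_id: a.weight for a in assignments}
    histogram = pp.overlap_histogram(
        te_alignments, weights, kmax=params.kmax,
        weight_mode=params.pp_weight_mode)
    try:
        ppres = pp.pingpong_zscore(histogram)
    except pp.DegenerateHistogramError:
        ppres = None
    counts["pingpong"] = int(sum(histogram.counts() > 0))

    de_table = pairs = quadrants = None
    if groups is not None and len(kept) > 0:
        matrix = pd.DataFrame(
            {r.id: r.counts for r in kept}, index=groups.index).T
        matrix.index.name = "feature"
        de_table = de.run_de(
            matrix, groups,
            de.DESettings(alpha_mode=params.alpha_mode, alpha=params.alpha))
        counts["de"] = int((de_table["direction"] != "ns").sum())
        if gene_de is not None:
            pairs, _ = concordance.antisense_pairs(
                de_table, assignments, gene_de,
                gene_alpha=params.gene_alpha,
                sense_filter=params.sense_filter)
            counts["concord"] = len(pairs)
            if len(pairs):
                quadrants = concordance.quadrant_counts(pairs)

    return PipelineResult(
        reads=reads, alignments=alignments, kept=kept, report=report,
        assignments=assignments, composition=composition, spectrum=spectrum,
        bias=bias, histogram=histogram, pingpong=ppres, de_table=de_table,
        pairs=pairs, quadrants=quadrants, stage_counts=counts)


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and parameters for a file-based run (the CLI's `all`)."""

    genome_fasta: str
    annotation_gff3: str
    fastq_paths: list[str]
    group_labels: list[str]
    outdir: str
    gene_de_tsv: str | None = None
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        for p in [self.genome_fasta, self.annotation_gff3, *self.fastq_paths]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if self.gene_de_tsv and not os.path.exists(self.gene_de_tsv):
            raise FileNotFoundError(self.gene_de_tsv)
        if len(self.group_labels) != len(self.fastq_paths):
            raise ValueError("one group label per FASTQ sample is required")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages from files, writing TSV outputs and a manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage
    named; outputs written before the failure are flagged stale in the
    partial manifest.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "complete": False,
    }
    mpath = os.path.join(config.outdir, "manifest.json")
    stage = "load"
    try:
        contigs = formats.read_fasta(config.genome_fasta)
        features = formats.read_gff3(config.annotation_gff3)
        genome = AnnotatedGenome(contigs=contigs, features=features)
        genome.validate()
        gene_de = (formats.read_tsv(config.gene_de_tsv)
                   if config.gene_de_tsv else None)
        stage = "collapse"
        reads, n_dropped = formats.collapse_reads(config.fastq_paths)
        groups = pd.Series(config.group_labels,
                           index=[f"s{j + 1}" for j in range(len(config.fastq_paths))])
        stage = "analyze"
        res = analyze(reads, genome, config.params, groups=groups,
                      gene_de=gene_de)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    out = config.outdir
    formats.write_tsv(res.report.to_frame(), os.path.join(out, "filter_report.tsv"))
    formats.write_tsv(annotate.assignments_to_frame(res.assignments),
                      os.path.join(out, "assignments.tsv"))
    formats.write_tsv(res.composition.to_frame(),
                      os.path.join(out, "composition.tsv"))
    formats.write_tsv(strandbias.spectrum_to_frame(res.spectrum),
                      os.path.join(out, "spectrum.tsv"))
    if res.bias is not None:
        formats.write_tsv(pd.DataFrame([dataclasses.asdict(res.bias)]),
                          os.path.join(out, "bias.tsv"))
    formats.write_tsv(pp.histogram_to_frame(res.histogram),
                      os.path.join(out, "pingpong_histogram.tsv"))
    if res.pingpong is not None:
        formats.write_tsv(pd.DataFrame([dataclasses.asdict(res.pingpong)]),
                          os.path.join(out, "pingpong.tsv"))
    if res.de_table is not None:
        formats.write_tsv(res.de_table.reset_index(),
                          os.path.join(out, "de_results.tsv"))
    if res.pairs is not None:
        formats.write_tsv(res.pairs, os.path.join(out, "concord_pairs.tsv"))
    if res.quadrants is not None:
        formats.write_tsv(concordance.quadrants_to_frame(res.quadrants),
                          os.path.join(out, "concord_quadrants.tsv"))
    flat = [a for alns in res.alignments.values() for a in alns]
    formats.write_bed6(flat, {r.id: r.total for r in res.reads},
                       os.path.join(out, "alignments.bed"))
    manifest["stages"] = res.stage_counts
    manifest["n_dropped_N"] = n_dropped
    manifest["complete"] = True
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Synthetic demo
# ---------------------------------------------------------------------------

DEMO_TISSUES = ("brain", "ovary")


def default_genome_spec(seed: int) -> synthgen.GenomeSpec:
    return synthgen.GenomeSpec(seed=seed)


def make_demo(outdir: str, seed: int = 0, n_reads: int = 20000,
              n_samples: int = 4) -> dict:
    """Write the full demo dataset: genome, annotation, FASTQ samples for
    the brain and ovary presets (first half group A, second half group B,
    with planted piRNA DE), and a fabricated gene-DE table per tissue.

    Returns a dict of written paths plus per-tissue pipeline configs.
    """
    os.makedirs(outdir, exist_ok=True)
    genome = synthgen.build_genome(default_genome_spec(seed))
    fasta = formats.write_fasta(genome.contigs, os.path.join(outdir, "genome.fa"))
    gff = formats.write_gff3(genome.features, os.path.join(outdir, "annotation.gff3"))
    paths = {"genome": fasta, "annotation": gff, "tissues": {}}
    for t, tissue in enumerate(DEMO_TISSUES):
        profile = synthgen.preset_profile(tissue, seed=seed * 7919 + t + 1)
        deplan = synthgen.preset_deplan(tissue, seed=seed * 104729 + t + 1)
        sim = synthgen.simulate_reads(genome, profile, n_reads,
                                      n_samples=n_samples, deplan=deplan)
        truth = synthgen.truth_table(sim)
        fastqs = []
        for j in range(n_samples):
            fq = os.path.join(outdir, f"{tissue}_s{j + 1}.fastq")
            formats.write_fastq(synthgen.reads_to_fastq_records(sim, j), fq)
            fastqs.append(fq)
        gene_de = synthgen.simulate_gene_de(truth, concordance=0.8,
                                            seed=seed * 31 + t)
        gde_path = os.path.join(outdir, f"{tissue}_gene_de.tsv")
        formats.write_tsv(gene_de, gde_path)
        truth_path = os.path.join(outdir, f"{tissue}_truth.tsv")
        formats.write_tsv(truth, truth_path)
        n_a = n_samples // 2
        config = PipelineConfig(
            genome_fasta=fasta, annotation_gff3=gff, fastq_paths=fastqs,
            group_labels=["A"] * n_a + ["B"] * (n_samples - n_a),
            outdir=os.path.join(outdir, f"{tissue}_out"),
            gene_de_tsv=gde_path, seed=seed,
            params=PipelineParams(
                alpha_mode="pvalue" if tissue == "brain" else "fdr",
                alpha=0.01 if tissue == "brain" else 0.05),
        )
        cfg_path = os.path.join(outdir, f"{tissue}_config.yaml")
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        paths["tissues"][tissue] = dict(
            fastqs=fastqs, gene_de=gde_path, truth=truth_path, config=cfg_path)
    return paths


def tissue_roundtrip(
    genome: AnnotatedGenome,
    tissue: str,
    seed: int,
    n_reads: int = 20000,
    n_samples: int = 4,
    with_de: bool = True,
    via_fastq: bool = True,
) -> tuple[PipelineResult, synthgen.ReadProfile, pd.DataFrame]:
    """Simulate one tissue preset and push it through the whole pipeline.

    Returns ``(result, profile, truth_table)``.  ``via_fastq`` round-trips
    the reads through FASTQ files and `collapse_reads` (as the acceptance
    setup prescribes); otherwise the simulated collapsed reads are analyzed
    directly.
    """
    profile = synthgen.preset_profile(tissue, seed=seed)
    deplan = synthgen.preset_deplan(tissue, seed=seed + 1) if with_de else None
    sim = synthgen.simulate_reads(genome, profile, n_reads,
                                  n_samples=n_samples, deplan=deplan)
    truth = synthgen.truth_table(sim)
    if via_fastq:
        with tempfile.TemporaryDirectory() as tmp:
            fqs = []
            for j in range(n_samples):
                fq = os.path.join(tmp, f"s{j + 1}.fastq")
                formats.write_fastq(synthgen.reads_to_fastq_records(sim, j), fq)
                fqs.append(fq)
            reads, _ = formats.collapse_reads(fqs)
    else:
        reads = [r for r, _ in sim]
    n_a = n_samples // 2
    groups = pd.Series(["A"] * n_a + ["B"] * (n_samples - n_a),
                       index=[f"s{j + 1}" for j in range(n_samples)])
    params = PipelineParams(
        alpha_mode="pvalue" if tissue.startswith("brain") else "fdr",
        alpha=0.01 if tissue.startswith("brain") else 0.05)
    gene_de = (synthgen.simulate_gene_de(truth, concordance=0.8, seed=seed + 2)
               if with_de else None)
    res = analyze(reads, genome, params,
                  groups=groups if with_de else None, gene_de=gene_de)
    return res, profile, truth
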