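"""End-to-end orchestration: filter -> clip -> trim -> collapse -> map ->
annotate -> cluster -> express -> test, with a run manifest.

Each stage is independently invocable through the library (and the CLI); the
pipeline fixes the order, logs per-stage record counts and verifies the
read-accounting conservation identity before writing the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .cluster_expression import (attach_counts, build_expression_matrix,
                                 call_clusters, composition_matrix,
                                 differential_table, write_clusters)
from .read_processing import (ProcessingParams, merge_tag_sets, process_fastq,
                              write_tag_counts, write_tag_fasta)
from .repeat_annotation import (annotate_tags, load_repeat_library,
                                write_annotation, write_hits_bed)
from .seqio import read_sequences, write_library_summaries


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    libraries: dict[str, str]          # library_id -> FASTQ path
    repeats_fasta: str
    categories_tsv: str
    output_dir: str
    rdna_fasta: Optional[str] = None
    trna_fasta: Optional[str] = None
    adapter3: str = ""
    adapter5: str = ""
    min_overlap: int = 6
    error_rate: float = 0.2
    max_homopolymer: int = 12
    min_length: int = 11
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.1
    min_rasirna_len: int = 16
    trna_min_identity: float = 0.95
    min_cluster_members: int = 2
    cluster_overlap_nt: int = 1
    focus_consensus: Optional[str] = None   # restrict expression/composition
    run_differential: bool = False
    seed: int = 0

    def processing_params(self) -> ProcessingParams:
        kwargs = {}
        if self.adapter3:
            kwargs["adapter3"] = self.adapter3
        if self.adapter5:
            kwargs["adapter5"] = self.adapter5
        return ProcessingParams(
            min_overlap=self.min_overlap, error_rate=self.error_rate,
            max_homopolymer=self.max_homopolymer, min_length=self.min_length,
            min_mean_quality=self.min_mean_quality,
            max_n_fraction=self.max_n_fraction, **kwargs,
        )

    def validate(self) -> None:
        if not self.libraries:
            raise ValueError("at least one library FASTQ is required")
        for lib, path in self.libraries.items():
            if not Path(path).exists():
                raise ValueError(f"library {lib!r}: missing FASTQ {path}")
        for label, path in (("repeats_fasta", self.repeats_fasta),
                            ("categories_tsv", self.categories_tsv)):
            if not Path(path).exists():
                raise ValueError(f"{label} does not exist: {path}")
        for opt in (self.rdna_fasta, self.trna_fasta):
            if opt and not Path(opt).exists():
                raise ValueError(f"contaminant file does not exist: {opt}")
        self.processing_params()          # range checks
        if not (0 < self.trna_min_identity <= 1):
            raise ValueError("trna_min_identity must be in (0, 1]")
        if self.min_cluster_members < 1:
            raise ValueError("min_cluster_members must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def recover_scenario(seed: int, scenario=None) -> dict:
    """Run the full analysis in memory on a simulated scenario.

    Generates the scenario for ``seed``, processes every stage library,
    merges and annotates the tags, calls clusters on the designated
    transposon consensus and builds the expression matrix for its rasiRNAs.
    Returns a dict with the truth object and every intermediate result;
    used by truth-aware recovery tests and the acceptance script.
    """
    import numpy as np

    from .read_processing import process_records
    from .synthetic_data import build_truth, simulate_libraries

    truth = build_truth(seed, scenario)
    rng = np.random.default_rng(seed + 1)
    libraries, read_truth = simulate_libraries(truth, rng)
    tag_sets, summaries, statuses = [], [], {}
    for stage, reads in libraries.items():
        records = ((rid, seq, [ord(c) - 33 for c in qual])
                   for rid, seq, qual in reads)
        tags, summary, status = process_records(records, stage)
        tag_sets.append(tags)
        summaries.append(summary)
        statuses[stage] = status
    tags = merge_tag_sets(tag_sets)
    records = annotate_tags(tags, truth.consensi, [truth.rdna], truth.trna)
    tags_by_id = {t.tag_id: t for t in tags}
    rasi = [r for r in records if r.is_rasirna]
    focus_hits = [h for r in rasi for h in r.hits
                  if h.consensus_id == truth.te_consensus_id]
    clusters, singletons = call_clusters(focus_hits)
    attach_counts(clusters, tags_by_id)
    focus_ids = sorted({h.tag_id for h in focus_hits})
    matrix = build_expression_matrix(tags, summaries, subset=focus_ids)
    return {
        "truth": truth, "read_truth": read_truth, "summaries": summaries,
        "statuses": statuses, "tags": tags, "tags_by_id": tags_by_id,
        "annotation": records, "rasi": rasi, "clusters": clusters,
        "singletons": singletons, "matrix": matrix,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.processing_params()
    manifest: dict = {"tool": "rasikit", "version": __version__,
                      "config": asdict(config), "stages": {}}

    # --- read processing, per library --------------------------------------
    tag_sets = []
    summaries = []
    lib_ids = sorted(config.libraries)
    for lib in lib_ids:
        tags, summary, statuses = process_fastq(config.libraries[lib], lib, params)
        tag_sets.append(tags)
        summaries.append(summary)
        manifest["stages"][f"process:{lib}"] = {
            "raw_reads": summary.raw_reads,
            "low_quality": summary.low_quality,
            "no_adapter": summary.no_adapter,
            "too_short": summary.too_short,
            "high_quality_reads": summary.high_quality_reads,
            "unique_tags": summary.unique_tags,
            "conservation_ok": True,   # LibrarySummary enforces the identity
        }
    tags = merge_tag_sets(tag_sets)
    write_library_summaries(summaries, outdir / "library_summaries.tsv")
    write_tag_fasta(tags, outdir / "tags.fa")
    write_tag_counts(tags, lib_ids, outdir / "tag_counts.tsv")
    manifest["stages"]["collapse"] = {"merged_unique_tags": len(tags)}

    # --- annotation ---------------------------------------------------------
    consensi = load_repeat_library(config.repeats_fasta, config.categories_tsv)
    rdna = [r.sequence for r in read_sequences(config.rdna_fasta, "fasta")] \
        if config.rdna_fasta else []
    trna = [r.sequence for r in read_sequences(config.trna_fasta, "fasta")] \
        if config.trna_fasta else []
    records = annotate_tags(tags, consensi, rdna, trna,
                            config.min_rasirna_len, config.trna_min_identity)
    tags_by_id = {t.tag_id: t for t in tags}
    all_hits = [h for r in records for h in r.hits]
    write_hits_bed(all_hits, tags_by_id, outdir / "hits.tsv")
    write_annotation(records, outdir / "annotation.tsv")
    n_rasi = sum(r.is_rasirna for r in records)
    manifest["stages"]["annotate"] = {
        "consensi": len(consensi),
        "tags_screened": len(records),
        "rDNA": sum(r.contaminant == "rDNA" for r in records),
        "tRNA": sum(r.contaminant == "tRNA" for r in records),
        "rasiRNAs": n_rasi,
        "mapping_hits": len(all_hits),
    }

    # --- clustering ---------------------------------------------------------
    rasi_ids = {r.tag_id for r in records if r.is_rasirna}
    rasi_hits = [h for r in records if r.is_rasirna for h in r.hits]
    clusters, singletons = call_clusters(rasi_hits, config.min_cluster_members,
                                         config.cluster_overlap_nt)
    attach_counts(clusters, tags_by_id)
    attach_counts(singletons, tags_by_id)
    write_clusters(clusters, outdir / "clusters.tsv")
    write_clusters(singletons, outdir / "singletons.tsv")
    manifest["stages"]["cluster"] = {"clusters": len(clusters),
                                     "singletons": len(singletons)}

    # --- expression ---------------------------------------------------------
    focus_ids = rasi_ids
    if config.focus_consensus:
        focus_ids = {h.tag_id for h in rasi_hits
                     if h.consensus_id == config.focus_consensus}
    matrix = build_expression_matrix(tags, summaries, subset=focus_ids)
    matrix.to_tsv(outdir / "expression.tsv")
    matrix.aggregate_percent.rename("aggregate_percent").to_csv(
        outdir / "aggregate_percent.tsv", sep="\t", index_label="library_id")
    manifest["stages"]["express"] = {
        "tags_in_matrix": len(matrix.values),
        "aggregate_percent": {k: float(v)
                              for k, v in matrix.aggregate_percent.items()},
    }
    if focus_ids:
        comp = composition_matrix([tags_by_id[t].sequence for t in sorted(focus_ids)])
        comp.to_tsv(outdir / "composition.tsv")
        manifest["stages"]["composition"] = {
            "positions": len(comp.fractions),
            "max_bias": {"position": comp.max_bias[0], "base": comp.max_bias[1],
                         "fraction": comp.max_bias[2]},
        }

    # --- differential testing ----------------------------------------------
    if config.run_differential and focus_ids:
        table = differential_table([tags_by_id[t] for t in sorted(focus_ids)],
                                   summaries)
        table.to_csv(outdir / "differential.tsv", sep="\t")
        manifest["stages"]["diff"] = {"tags_tested": len(table)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
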