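"""End-to-end orchestration of the comparative-genomics analysis.

One call runs every stage over a panel of annotated genomes — summary
statistics, CDS extraction and QC, single-copy orthology, per-gene codon
statistics, ANI/AAI/Mash relatedness, genetic-group classification, per-group
codon-bias analyses, Ka/Ks against a reference genome, and a neighbor-joining
tree — writing deterministic TSV/Newick outputs plus a reproducibility
manifest whose hash is stamped into every table.  A rerun with the same
config and inputs is bit-identical (timings go to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias_analysis, codon_stats, relatedness, seqio, substitution
from .orthology import reciprocal_best_hits
from .seqio import AnnotatedGenome, QCPolicy

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    inputs: list[str] = field(default_factory=list)
    format: str = "genbank"
    cds_inputs: list[str] = field(default_factory=list)  # for fasta format
    out_dir: str = "endosym_out"
    reference_genome_id: str | None = None
    min_gene_length: int = 90
    mash_k: int = 21
    mash_s: int = 1000
    mash_seed: int = 42
    mash_input: str = "cds"
    ani_min: float = 0.95
    aai_min: float = 0.90
    groups: str | dict[str, str] = "auto"  # "auto" or genome_id -> label
    rbh_candidates: int | None = 8
    seed: int = 0

    def validate(self) -> None:
        if self.format not in ("genbank", "fasta", "fasta+cds_fasta"):
            raise ValueError(f"unknown input format {self.format!r}")
        if self.mash_input not in ("cds", "genome"):
            raise ValueError("mash_input must be 'cds' or 'genome'")
        if not (0 < self.ani_min < 1 and 0 < self.aai_min < 1):
            raise ValueError("thresholds must be fractions in (0,1)")

    def manifest_hash(self) -> str:
        # the output location does not influence any computed value, so it
        # is excluded: reruns into different directories stay bit-identical
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _load_genomes(config: PipelineConfig) -> list[AnnotatedGenome]:
    genomes = []
    for i, path in enumerate(config.inputs):
        if config.format == "genbank":
            genomes.append(seqio.read_genome(path, "genbank"))
        else:
            genomes.append(seqio.read_genome(path, "fasta", cds_path=config.cds_inputs[i]))
    return genomes


def run_pipeline(config: PipelineConfig,
                 genomes: list[AnnotatedGenome] | None = None) -> Path:
    """Run all stages; returns the output directory.  ``genomes`` may be
    passed directly (e.g. a simulated panel) instead of ``config.inputs``."""
    config.validate()
    mhash = config.manifest_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"manifest={mhash}"
    log_lines: list[str] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(name, exc) from exc
        log_lines.append(f"{name}\t{time.perf_counter() - t0:.2f}s")
        logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)
        return result

    if genomes is None:
        genomes = stage("load", lambda: _load_genomes(config))
    if len(genomes) < 2:
        raise PipelineError("load", ValueError("need at least 2 genomes"))
    genomes = sorted(genomes, key=lambda g: g.id)

    summaries = stage("summarize", lambda: [seqio.summarize_genome(g) for g in genomes])
    seqio.write_table(seqio.summary_table(summaries), out / "summary.tsv", comment=stamp)

    qc = QCPolicy(min_length_nt=config.min_gene_length)
    drop_log: list = []

    def _extract():
        return {g.id: {c.locus_id: c for c in seqio.extract_cds(g, qc, drop_log=drop_log)}
                for g in genomes}

    cds_by_genome = stage("extract_cds", _extract)
    seqio.write_table(pd.DataFrame(drop_log, columns=["genome_id", "locus_id", "reason"]),
                      out / "qc_drop_log.tsv", comment=stamp)

    table = stage("orthology", lambda: reciprocal_best_hits(
        cds_by_genome, candidates=config.rbh_candidates))
    seqio.write_table(table.to_frame(), out / "orthologs.tsv", comment=stamp)

    profiles = stage("codon_stats", lambda: [
        codon_stats.gene_profile(c)
        for g in genomes for c in sorted(cds_by_genome[g.id].values(), key=lambda c: c.locus_id)])
    seqio.write_table(codon_stats.profile_table(profiles), out / "codon_stats.tsv", comment=stamp)

    dm = stage("relatedness", lambda: relatedness.distance_matrices(
        table, cds_by_genome, k=config.mash_k, s=config.mash_s,
        hash_seed=config.mash_seed, mash_input=config.mash_input,
        genome_sequences={g.id: g.sequence for g in genomes}))
    for name, mat in (("ani", dm.ani), ("aai", dm.aai), ("mash", dm.mash)):
        df = pd.DataFrame(mat, index=list(dm.genome_ids), columns=list(dm.genome_ids))
        df.insert(0, "genome_id", list(dm.genome_ids))
        seqio.write_table(df, out / f"{name}.tsv", comment=stamp)

    assignment = stage("classify", lambda: relatedness.classify_groups(
        dm.ani, dm.aai, list(dm.genome_ids), ani_min=config.ani_min, aai_min=config.aai_min))
    groups_df = pd.DataFrame(sorted(assignment.labels.items()),
                             columns=["genome_id", "group"])
    seqio.write_table(groups_df, out / "groups.tsv", comment=stamp)

    group_of = assignment.labels if config.groups == "auto" else dict(config.groups)

    def _bias():
        frames = []
        by_group: dict[str, list] = {}
        for p in profiles:
            by_group.setdefault(group_of[p.genome_id], []).append(p)
        for label in sorted(by_group):
            frames.append(bias_analysis.bias_report(by_group[label], label))
        return pd.concat(frames, ignore_index=True)

    seqio.write_table(stage("bias_analysis", _bias), out / "bias_groups.tsv", comment=stamp)

    reference = config.reference_genome_id or genomes[0].id

    def _kaks():
        results = substitution.kaks_vs_reference(table, cds_by_genome, reference)
        return substitution.kaks_table(results)

    seqio.write_table(stage("kaks", _kaks), out / "kaks.tsv", comment=stamp)

    tree = stage("nj_tree", lambda: relatedness.nj_tree(
        np.where(np.isfinite(dm.mash), dm.mash, 1.0), list(dm.genome_ids)))
    seqio.write_newick(tree, out / "tree.nwk")

    manifest = {"config": asdict(config), "manifest_hash": mhash,
                "n_genomes": len(genomes), "genome_ids": [g.id for g in genomes],
                "mash_params": dm.mash_params,
                "kaks_method": "NG86 (equal pathway weighting, Jukes-Cantor correction)",
                "reference_genome_id": reference}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
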