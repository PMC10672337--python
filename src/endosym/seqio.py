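"""Genome I/O and genome-level summary statistics.

Reads annotated genomes from GenBank flat files or from a genome-FASTA /
CDS-FASTA pair, extracts quality-controlled coding sequences, and computes
the summary quantities used to characterise reduced endosymbiont genomes
(length, GC%, feature counts, coding density).

Internal coordinates are 0-based half-open on the forward strand; GenBank's
1-based inclusive locations are converted on input.  For circular genomes a
single origin-spanning feature is represented with ``end > length`` and
sliced modularly on extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._genetic_code import STOP_CODONS, revcomp, translate_nt

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "tmRNA", "other")
_SKIP_GB_TYPES = {"source", "gene"}


@dataclass(frozen=True)
class Feature:
    """A typed annotation on the forward strand, 0-based half-open."""

    kind: str
    start: int
    end: int
    strand: int
    locus_id: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A genome sequence plus its typed features."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-IUPAC residues in {self.id}: {sorted(bad)}")
        limit = 2 * len(self.sequence) if self.topology == "circular" else len(self.sequence)
        for f in self.features:
            if f.end > limit:
                raise ValueError(f"feature {f.locus_id} outside genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_slice(self, feat: Feature) -> str:
        """Forward-strand sequence under a feature (modular for wrap-around)."""
        if feat.end <= len(self.sequence):
            return self.sequence[feat.start : feat.end]
        return self.sequence[feat.start :] + self.sequence[: feat.end - len(self.sequence)]


@dataclass(frozen=True)
class CodingSequence:
    """A strand-resolved, in-frame CDS and its translation (table 11)."""

    locus_id: str
    genome_id: str
    nt: str
    aa: str


@dataclass(frozen=True)
class QCPolicy:
    """Filters applied before any codon-level statistic is computed."""

    min_length_nt: int = 90
    allow_n: bool = False
    require_frame: bool = True
    drop_internal_stop: bool = True


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    length_bp: int
    gc_percent: float
    n_cds: int
    n_trna: int
    n_rrna: int
    coding_density_percent: float
    coding_density_cds_percent: float


# ---------------------------------------------------------------------------
# reading


def _gb_features(record: SeqRecord, length: int, topology: str) -> list[Feature]:
    feats: list[Feature] = []
    counter = 0
    for sf in record.features:
        if sf.type in _SKIP_GB_TYPES:
            continue
        kind = sf.type if sf.type in FEATURE_KINDS[:4] else "other"
        counter += 1
        locus = sf.qualifiers.get("locus_tag", [f"{record.id}_{counter:04d}"])[0]
        parts = sf.location.parts
        strand = int(sf.location.strand or 1)
        if len(parts) == 1:
            start, end = int(parts[0].start), int(parts[0].end)
        else:
            # only circular origin-spanning joins are kept
            p = sorted(parts, key=lambda q: int(q.start))
            first, last = p[-1], p[0]
            if topology == "circular" and len(parts) == 2 and int(first.end) == length and int(last.start) == 0:
                start, end = int(first.start), length + int(last.end)
            else:
                logger.warning("dropping compound-location feature %s", locus)
                continue
        feats.append(Feature(kind=kind, start=start, end=end, strand=strand, locus_id=locus))
    return feats


def _parse_fasta_header(desc: str) -> dict[str, str]:
    meta = {}
    for tok in desc.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_genome(path: str | Path, format: str = "genbank", cds_path: str | Path | None = None) -> AnnotatedGenome:
    """Read an annotated genome.

    ``format="genbank"`` parses a flat file; ``format="fasta"`` needs the
    companion ``cds_path`` whose headers carry ``start= end= strand= kind=``
    metadata (the convention :func:`write_genome_fasta` emits) or, failing
    that, CDS located by exact forward/reverse substring search.
    """
    path = Path(path)
    if format == "genbank":
        try:
            record = SeqIO.read(str(path), "genbank")
        except ValueError as exc:
            raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
        topology = record.annotations.get("topology", "linear")
        seq = str(record.seq).upper()
        genome = AnnotatedGenome(
            id=record.id, sequence=seq, topology=topology,
            features=_gb_features(record, len(seq), topology),
        )
        return genome
    if format in ("fasta", "fasta+cds_fasta"):
        if cds_path is None:
            raise ValueError("fasta format needs cds_path")
        record = SeqIO.read(str(path), "fasta")
        seq = str(record.seq).upper()
        topology = _parse_fasta_header(record.description).get("topology", "linear")
        feats: list[Feature] = []
        for cds in SeqIO.parse(str(cds_path), "fasta"):
            meta = _parse_fasta_header(cds.description)
            cseq = str(cds.seq).upper()
            if {"start", "end", "strand"} <= meta.keys():
                start, end = int(meta["start"]), int(meta["end"])
                strand = 1 if meta["strand"] in ("+", "+1", "1") else -1
            else:
                fwd = seq.find(cseq)
                if fwd >= 0:
                    start, end, strand = fwd, fwd + len(cseq), 1
                else:
                    rev = seq.find(revcomp(cseq))
                    if rev < 0:
                        raise ValueError(f"CDS {cds.id} not found in genome {record.id}")
                    start, end, strand = rev, rev + len(cseq), -1
            feats.append(Feature(kind=meta.get("kind", "CDS"), start=start, end=end,
                                 strand=strand, locus_id=cds.id))
        return AnnotatedGenome(id=record.id, sequence=seq, topology=topology, features=feats)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# CDS extraction and QC


def extract_cds(genome: AnnotatedGenome, qc: QCPolicy = QCPolicy(),
                drop_log: list | None = None) -> list[CodingSequence]:
    """Extract strand-resolved CDS passing QC; rejected loci go to ``drop_log``.

    QC drops genes whose length is not a codon multiple, shorter than the
    policy minimum, containing N, or with an internal stop codon.  Raises if
    nothing survives.
    """
    cds_feats = [f for f in genome.features if f.kind == "CDS"]
    if not cds_feats:
        raise ValueError(f"genome {genome.id} has no CDS features")
    out: list[CodingSequence] = []
    for f in cds_feats:
        nt = genome.feature_slice(f)
        if f.strand == -1:
            nt = revcomp(nt)
        reason = _qc_reason(nt, qc)
        if reason:
            logger.info("QC drop %s/%s: %s", genome.id, f.locus_id, reason)
            if drop_log is not None:
                drop_log.append((genome.id, f.locus_id, reason))
            continue
        aa = translate_nt(nt)
        if aa.endswith("*"):
            aa = aa[:-1]
        out.append(CodingSequence(locus_id=f.locus_id, genome_id=genome.id, nt=nt, aa=aa))
    if not out:
        raise ValueError(f"empty gene set for {genome.id} after QC")
    return out


def _qc_reason(nt: str, qc: QCPolicy) -> str | None:
    if qc.require_frame and len(nt) % 3:
        return f"length {len(nt)} not divisible by 3"
    if len(nt) < qc.min_length_nt:
        return f"length {len(nt)} < {qc.min_length_nt}"
    if not qc.allow_n and "N" in nt:
        return "contains N"
    if qc.drop_internal_stop and len(nt) % 3 == 0:
        for i in range(0, len(nt) - 3, 3):
            if nt[i : i + 3] in STOP_CODONS:
                return f"internal stop at codon {i // 3}"
    return None


# ---------------------------------------------------------------------------
# summary statistics


def _interval_union(intervals: list[tuple[int, int]], length: int) -> int:
    """Total bp covered by intervals on a genome of `length` (wraps folded in)."""
    segs: list[tuple[int, int]] = []
    for s, e in intervals:
        if e <= length:
            segs.append((s, e))
        else:  # origin-spanning
            segs.append((s, length))
            segs.append((0, e - length))
    segs.sort()
    covered = 0
    cur_s, cur_e = -1, -1
    for s, e in segs:
        if s > cur_e:
            covered += cur_e - cur_s if cur_e > cur_s else 0
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s if cur_e > cur_s else 0
    return covered


def summarize_genome(genome: AnnotatedGenome) -> GenomeSummary:
    """Length, GC%, feature counts and coding density of a genome.

    GC% is over unambiguous (non-N) positions.  The headline coding density
    is the union of *all* annotated feature intervals over genome length —
    the convention used for reduced genomes where RNA genes contribute
    materially; a CDS-only density is reported alongside.
    """
    seq = genome.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = sum(seq.count(b) for b in "GC")
    gc_percent = 100.0 * gc / acgt if acgt else 0.0
    all_iv = [(f.start, f.end) for f in genome.features]
    cds_iv = [(f.start, f.end) for f in genome.features if f.kind == "CDS"]
    n = len(seq)
    return GenomeSummary(
        genome_id=genome.id,
        length_bp=n,
        gc_percent=gc_percent,
        n_cds=sum(1 for f in genome.features if f.kind == "CDS"),
        n_trna=sum(1 for f in genome.features if f.kind == "tRNA"),
        n_rrna=sum(1 for f in genome.features if f.kind == "rRNA"),
        coding_density_percent=100.0 * _interval_union(all_iv, n) / n,
        coding_density_cds_percent=100.0 * _interval_union(cds_iv, n) / n,
    )


def summary_table(summaries: list[GenomeSummary]) -> pd.DataFrame:
    cols = ["genome_id", "length_bp", "gc_percent", "n_cds", "n_trna", "n_rrna",
            "coding_density_percent", "coding_density_cds_percent"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries], columns=cols)


# ---------------------------------------------------------------------------
# writing


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with deterministic column order; optional '#' header line."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_genome_fasta(genome: AnnotatedGenome, genome_path: str | Path, cds_path: str | Path) -> None:
    """Genome + CDS FASTA pair carrying coordinate metadata in headers."""
    with open(genome_path, "w") as fh:
        fh.write(f">{genome.id} topology={genome.topology}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(cds_path, "w") as fh:
        for f in genome.features:
            if f.kind != "CDS":
                continue
            nt = genome.feature_slice(f)
            if f.strand == -1:
                nt = revcomp(nt)
            strand = "+" if f.strand == 1 else "-"
            fh.write(f">{f.locus_id} start={f.start} end={f.end} strand={strand} kind=CDS\n")
            for i in range(0, len(nt), 70):
                fh.write(nt[i : i + 70] + "\n")


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write an annotated genome as a GenBank flat file (via Biopython)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA", "topology": genome.topology})
    n = len(genome.sequence)
    for f in genome.features:
        if f.end <= n:
            loc = FeatureLocation(f.start, f.end, strand=f.strand)
        else:
            loc = FeatureLocation(f.start, n, strand=f.strand) + FeatureLocation(0, f.end - n, strand=f.strand)
        record.features.append(SeqFeature(loc, type=f.kind if f.kind != "other" else "misc_feature",
                                          qualifiers={"locus_tag": [f.locus_id]}))
    SeqIO.write([record], str(path), "genbank")
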