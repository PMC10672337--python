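"""Nei–Gojobori (1986) synonymous / nonsynonymous substitution rates.

Counts synonymous and nonsynonymous *sites* per codon by the fraction of the
nine possible single-nucleotide changes that preserve the amino acid (changes
to a stop codon count as nonsynonymous), and synonymous / nonsynonymous
*differences* per codon pair by averaging over all minimal mutational
pathways with equal weights; pathways passing through a stop codon are
excluded, falling back to all pathways (stop steps counted nonsynonymous)
when every pathway is blocked.  Proportions are corrected with the
Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3).

All per-codon and per-codon-pair quantities are precomputed once at import,
so scoring an alignment is table lookups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import pandas as pd

from ._genetic_code import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from .orthology import CodonAlignment, codon_align
from .seqio import CodingSequence


def _sites(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                s += 1.0 / 3.0
    return s, 3.0 - s


NG86_SITES: dict[str, tuple[float, float]] = {c: _sites(c) for c in SENSE_CODONS}


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of a sense codon."""
    try:
        return NG86_SITES[codon]
    except KeyError:
        raise ValueError(f"not a sense codon: {codon!r}") from None


def _classify_step(a: str, b: str) -> str:
    """'syn', 'nonsyn' or 'stop' for a single-nucleotide codon change."""
    if b in STOP_CODONS or a in STOP_CODONS:
        return "stop"
    return "syn" if CODON_TO_AA[a] == CODON_TO_AA[b] else "nonsyn"


def _pathways(codon_a: str, codon_b: str):
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in permutations(diff):
        cur = codon_a
        steps = []
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        yield steps


def _differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    if codon_a == codon_b:
        return 0.0, 0.0
    open_paths: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for steps in _pathways(codon_a, codon_b):
        sd = nd = 0.0
        blocked = False
        for a, b in steps:
            kind = _classify_step(a, b)
            if kind == "stop":
                blocked = True
                nd += 1.0  # fallback accounting: stop steps are nonsynonymous
            elif kind == "syn":
                sd += 1.0
            else:
                nd += 1.0
        all_paths.append((sd, nd))
        if not blocked:
            open_paths.append((sd, nd))
    paths = open_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


NG86_DIFFS: dict[tuple[str, str], tuple[float, float]] = {
    (a, b): _differences(a, b) for a in SENSE_CODONS for b in SENSE_CODONS
}


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over equally weighted minimal pathways."""
    try:
        return NG86_DIFFS[(codon_a, codon_b)]
    except KeyError:
        raise ValueError(f"not sense codons: {codon_a!r}, {codon_b!r}") from None


@dataclass(frozen=True)
class KaKsResult:
    group_id: str
    genome_pair: tuple[str, str]
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float      # NaN when saturated/undefined
    ka: float
    omega: float   # NaN when Ks is 0 or missing
    flags: str = ""


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks(alignment: CodonAlignment, group_id: str = "", genome_pair: tuple[str, str] = ("a", "b")) -> KaKsResult:
    """NG86 Ka/Ks over the ungapped codon columns of a pairwise alignment.

    Sites are averaged over the two sequences; ps ≥ 3/4 (or pn) leaves the
    corresponding rate missing with a 'saturation' flag.
    """
    sa = na = sb = nb = sd = nd = 0.0
    ncols = 0
    for ca, cb in alignment.ungapped_codon_columns():
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        ncols += 1
        s1, n1 = NG86_SITES[ca]
        s2, n2 = NG86_SITES[cb]
        sa += s1; na += n1; sb += s2; nb += n2
        d = NG86_DIFFS[(ca, cb)]
        sd += d[0]; nd += d[1]
    if ncols == 0:
        raise ValueError("no ungapped codon columns")
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks, ka = _jc(ps), _jc(pn)
    flags = []
    if math.isnan(ks):
        flags.append("ks_saturation")
    if math.isnan(ka):
        flags.append("ka_saturation")
    if not math.isnan(ks) and ks > 0 and not math.isnan(ka):
        omega = ka / ks
    else:
        omega = math.nan
        if ks == 0:
            flags.append("ks_zero")
    return KaKsResult(group_id=group_id, genome_pair=genome_pair,
                      s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
                      ps=ps, pn=pn, ks=ks, ka=ka, omega=omega, flags=";".join(flags))


def kaks_vs_reference(table, cds_by_genome: dict[str, dict[str, CodingSequence]],
                      reference_genome_id: str) -> list[KaKsResult]:
    """One Ka/Ks result per (single-copy ortholog × non-reference genome),
    each against the designated reference; sorted by (ortholog, genome)."""
    if reference_genome_id not in cds_by_genome:
        raise ValueError(f"reference {reference_genome_id!r} not in panel")
    results: list[KaKsResult] = []
    for group in table.groups:
        ref_locus = group.members.get(reference_genome_id)
        if ref_locus is None:
            continue
        ref_cds = cds_by_genome[reference_genome_id][ref_locus]
        for gid in sorted(group.members):
            if gid == reference_genome_id:
                continue
            aln = table.get_alignment(group.group_id, reference_genome_id, gid)
            if aln is None:
                aln = codon_align(ref_cds, cds_by_genome[gid][group.members[gid]])
                table.cache_alignment(group.group_id, reference_genome_id, gid, aln)
            results.append(kaks(aln, group_id=group.group_id,
                                genome_pair=(reference_genome_id, gid)))
    results.sort(key=lambda r: (r.group_id, r.genome_pair))
    return results


def kaks_table(results: list[KaKsResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"ortholog": r.group_id, "reference": r.genome_pair[0],
                     "genome": r.genome_pair[1], "S": r.s_sites, "N": r.n_sites,
                     "Sd": r.sd, "Nd": r.nd, "Ka": r.ka, "Ks": r.ks,
                     "omega": r.omega, "flags": r.flags})
    return pd.DataFrame(rows, columns=["ortholog", "reference", "genome", "S", "N",
                                       "Sd", "Nd", "Ka", "Ks", "omega", "flags"])
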