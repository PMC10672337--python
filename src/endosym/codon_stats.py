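"""Per-gene codon composition statistics.

For each quality-controlled CDS: the 64-codon count vector, positional GC
content (GC1/GC2/GC3 and their GC12 mean), third-position base counts and
parity-rule-2 coordinates, GC at synonymous third positions (GC3s), Wright's
effective number of codons (ENC) and the theoretical no-selection ENC curve.

Stop codons never enter any per-gene statistic: a terminal stop is stripped
before counting and QC upstream removes internal stops.  ENC follows
Wright (1990): per-family codon homozygosity F = (nΣp² − 1)/(n − 1),
averaged within degeneracy classes (Ser, Leu, Arg counted as single 6-fold
families; Ile is the sole 3-fold family under the bacterial code), families
with n ≤ 1 skipped, a missing 3-fold mean imputed as the mean of the 2- and
4-fold means, and the result clamped to [20, 61].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._genetic_code import AA_TO_CODONS, CODON_INDEX, CODONS64, STOP_CODONS
from .seqio import CodingSequence

#: class constants of the ENC formula: degeneracy -> number of families
_ENC_CLASS_COUNTS = {2: 9, 3: 1, 4: 5, 6: 3}

_THIRD_BASE = np.array([c[2] for c in CODONS64])


def _build_masks():
    from ._genetic_code import CODON_TO_AA
    syn = np.zeros(64, dtype=bool)
    for i, c in enumerate(CODONS64):
        if c in STOP_CODONS:
            continue
        syn[i] = len(AA_TO_CODONS[CODON_TO_AA[c]]) > 1
    return syn


_SYN_THIRD_MASK = _build_masks()
_GC_THIRD = np.array([c[2] in "GC" for c in CODONS64])
_GC1 = np.array([c[0] in "GC" for c in CODONS64])
_GC2 = np.array([c[1] in "GC" for c in CODONS64])


@dataclass
class GeneCodonProfile:
    """Codon-composition summary of one gene."""

    locus_id: str
    genome_id: str
    n_codons: int
    counts: np.ndarray  # 64-vector in the fixed CODONS64 order
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    a3: int
    t3: int
    c3: int
    g3: int
    gc3s: float  # NaN when undefined
    enc: float   # NaN when undefined


def codon_counts(cds: CodingSequence) -> np.ndarray:
    """64-vector of codon counts; the terminal stop codon is excluded."""
    nt = cds.nt
    counts = np.zeros(64, dtype=np.int64)
    ncod = len(nt) // 3
    if ncod and nt[-3:] in STOP_CODONS:
        ncod -= 1
    for i in range(ncod):
        idx = CODON_INDEX.get(nt[3 * i : 3 * i + 3])
        if idx is not None:
            counts[idx] += 1
    return counts


def positional_gc(counts: np.ndarray) -> tuple[float, float, float, float]:
    """(GC1, GC2, GC3, GC12) fractions over the counted codons."""
    n = int(counts.sum())
    if n < 1:
        raise ValueError("no codons")
    gc1 = float(counts[_GC1].sum()) / n
    gc2 = float(counts[_GC2].sum()) / n
    gc3 = float(counts[_GC_THIRD].sum()) / n
    return gc1, gc2, gc3, (gc1 + gc2) / 2.0


def third_base_counts(counts: np.ndarray) -> tuple[int, int, int, int]:
    """(A3, T3, C3, G3) over all counted codons."""
    out = {b: 0 for b in "ATCG"}
    for i, c in enumerate(counts):
        if c:
            out[_THIRD_BASE[i]] += int(c)
    return out["A"], out["T"], out["C"], out["G"]


def pr2_coordinates(counts: np.ndarray) -> tuple[float, float]:
    """Parity-rule-2 point (x = G3/(G3+C3), y = A3/(A3+T3)); NaN when a
    denominator is zero (gene then excluded from PR2 plots)."""
    a3, t3, c3, g3 = third_base_counts(counts)
    x = g3 / (g3 + c3) if (g3 + c3) else math.nan
    y = a3 / (a3 + t3) if (a3 + t3) else math.nan
    return x, y


def gc3s(counts: np.ndarray) -> float:
    """GC fraction at synonymous third positions (Met, Trp, stops excluded);
    NaN for a gene made only of non-degenerate codons."""
    mask = _SYN_THIRD_MASK
    denom = int(counts[mask].sum())
    if denom == 0:
        return math.nan
    num = int(counts[mask & _GC_THIRD].sum())
    return num / denom


def enc(counts: np.ndarray) -> float:
    """Wright's effective number of codons, in [20, 61]; NaN if undefined."""
    fbar: dict[int, float] = {}
    for degeneracy, n_families in _ENC_CLASS_COUNTS.items():
        fs = []
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) != degeneracy:
                continue
            fam = np.array([counts[CODON_INDEX[c]] for c in codons], dtype=float)
            n = fam.sum()
            if n <= 1:
                continue
            p = fam / n
            fs.append((n * float(p @ p) - 1.0) / (n - 1.0))
        if fs:
            fbar[degeneracy] = float(np.mean(fs))
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(k not in fbar or fbar[k] <= 0.0 for k in _ENC_CLASS_COUNTS):
        return math.nan
    value = 2.0 + sum(_ENC_CLASS_COUNTS[k] / fbar[k] for k in _ENC_CLASS_COUNTS)
    return min(61.0, max(20.0, value))


def enc_expected(gc3s_value: float) -> float:
    """Theoretical ENC under mutation pressure alone:
    ENC_exp = 2 + s + 29 / (s² + (1 − s)²) with s = GC3s."""
    s = gc3s_value
    if not 0.0 <= s <= 1.0:
        raise ValueError("GC3s must be in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def gene_profile(cds: CodingSequence) -> GeneCodonProfile:
    """All per-gene statistics for one CDS."""
    counts = codon_counts(cds)
    gc1, gc2, gc3, gc12 = positional_gc(counts)
    a3, t3, c3, g3 = third_base_counts(counts)
    return GeneCodonProfile(
        locus_id=cds.locus_id, genome_id=cds.genome_id, n_codons=int(counts.sum()),
        counts=counts, gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12,
        a3=a3, t3=t3, c3=c3, g3=g3, gc3s=gc3s(counts), enc=enc(counts),
    )


def profile_table(profiles: list[GeneCodonProfile]) -> pd.DataFrame:
    cols = ["locus_id", "genome_id", "n_codons", "gc1", "gc2", "gc3", "gc12",
            "a3", "t3", "c3", "g3", "gc3s", "enc"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in profiles], columns=cols)
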