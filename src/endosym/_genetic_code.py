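"""Bacterial genetic code (translation table 11) lookups shared across modules.

Everything here is precomputed at import time from Biopython's codon table so
that per-codon operations downstream are dictionary lookups, not translations.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: fixed, deterministic codon order used for 64-vectors everywhere
CODONS64: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS64)}

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS64 if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (fixed order)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

#: degeneracy class of each amino acid (family size); Ser/Leu/Arg are 6,
#: Ile is the sole 3-fold family, Met/Trp are singletons.
AA_DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def translate_nt(nt: str) -> str:
    """Translate an in-frame CDS under table 11; stops rendered as '*'."""
    if len(nt) % 3:
        raise ValueError("length not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            out.append("*")
        else:
            aa = CODON_TO_AA.get(codon)
            if aa is None:
                out.append("X")
            else:
                out.append(aa)
    return "".join(out)
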