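"""Per-gene codon statistics against independent brute-force oracles."""

import math

import numpy as np
import pytest

from endosym._genetic_code import (AA_TO_CODONS, CODON_INDEX, CODON_TO_AA,
                                   SENSE_CODONS, STOP_CODONS)
from endosym.codon_stats import (codon_counts, enc, enc_expected, gc3s,
                                 gene_profile, positional_gc, pr2_coordinates)
from endosym.seqio import CodingSequence

from conftest import make_cds


def counts_from(codon_multiset: dict[str, int]) -> np.ndarray:
    v = np.zeros(64, dtype=np.int64)
    for c, n in codon_multiset.items():
        v[CODON_INDEX[c]] = n
    return v


# ---------------------------------------------------------------------------
# codon counts


@pytest.mark.parametrize("nt,expected", [
    ("ATGAAATAA", {"ATG": 1, "AAA": 1}),   # terminal stop excluded
    ("ATG", {"ATG": 1}),
])
def test_codon_counts_examples(nt, expected):
    cds = CodingSequence("L", "g", nt, "")
    assert codon_counts(cds).sum() == len(expected)
    for c, n in expected.items():
        assert codon_counts(cds)[CODON_INDEX[c]] == n


def test_codon_counts_sum_matches_length(rng):
    for _ in range(20):
        n = int(rng.integers(10, 200))
        cds = make_cds(n, rng)
        counts = codon_counts(cds)
        assert counts.sum() == len(cds.nt) // 3 - 1  # minus terminal stop


# ---------------------------------------------------------------------------
# positional GC and PR2


def test_positional_gc_hand_counts():
    gc1, gc2, gc3_, gc12 = positional_gc(counts_from({"ATG": 1, "GCC": 1}))
    assert (gc1, gc2, gc3_, gc12) == (0.5, 0.5, 1.0, 0.5)
    assert positional_gc(counts_from({"GCG": 7})) == (1.0, 1.0, 1.0, 1.0)


def test_positional_gc_against_per_base_recount(rng):
    cds = make_cds(1000, rng)
    counts = codon_counts(cds)
    core = cds.nt[: 3 * int(counts.sum())]
    # independent recount straight off the sequence
    exp = [sum(b in "GC" for b in core[p::3]) / (len(core) // 3) for p in range(3)]
    gc1, gc2, gc3_, gc12 = positional_gc(counts)
    assert (gc1, gc2, gc3_) == tuple(exp)
    assert gc12 == (gc1 + gc2) / 2


def test_pr2_coordinates():
    # third bases G:1 C:1 A:2 T:1
    v = counts_from({"AAG": 1, "AAC": 1, "AAA": 2, "AAT": 1})
    x, y = pr2_coordinates(v)
    assert x == 0.5 and y == pytest.approx(2 / 3)
    x, y = pr2_coordinates(counts_from({"AAA": 5}))
    assert y == 1.0 and math.isnan(x)
    x, y = pr2_coordinates(counts_from({"AAA": 1, "AAT": 1, "AAG": 1, "AAC": 1}))
    assert (x, y) == (0.5, 0.5)


# ---------------------------------------------------------------------------
# GC3s


def test_gc3s_excludes_nondegenerate_codons():
    assert gc3s(counts_from({"ATG": 1, "TTT": 2})) == 0.0
    assert gc3s(counts_from({"ATG": 1, "TTC": 2})) == 1.0
    assert math.isnan(gc3s(counts_from({"ATG": 3, "TGG": 2})))


def test_gc3s_against_per_codon_oracle(rng):
    for _ in range(30):
        cds = make_cds(int(rng.integers(20, 150)), rng)
        counts = codon_counts(cds)
        num = den = 0
        for c in SENSE_CODONS:
            if len(AA_TO_CODONS[CODON_TO_AA[c]]) == 1:
                continue
            den += counts[CODON_INDEX[c]]
            if c[2] in "GC":
                num += counts[CODON_INDEX[c]]
        assert gc3s(counts) == pytest.approx(num / den)


# ---------------------------------------------------------------------------
# ENC


def enc_oracle(counts: np.ndarray) -> float:
    """Straight-from-formula reimplementation of Wright's statistic."""
    fbar = {}
    for k in (2, 3, 4, 6):
        fs = []
        for aa, codons in AA_TO_CODONS.items():
            if len(codons) != k:
                continue
            ns = [counts[CODON_INDEX[c]] for c in codons]
            n = sum(ns)
            if n <= 1:
                continue
            f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
            fs.append(f)
        if fs:
            fbar[k] = sum(fs) / len(fs)
    if 3 not in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    val = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(61.0, max(20.0, val))


def test_enc_limits():
    uniform = counts_from({c: 164 for c in SENSE_CODONS})
    assert enc(uniform) == pytest.approx(61.0, abs=1e-6)
    one_per_aa = counts_from({codons[0]: 500 for codons in AA_TO_CODONS.values()})
    assert enc(one_per_aa) == pytest.approx(20.0, abs=1e-6)


def test_enc_matches_formula_oracle(rng):
    for _ in range(10):
        cds = make_cds(300, rng, gc3=float(rng.uniform(0.2, 0.6)))
        counts = codon_counts(cds)
        assert enc(counts) == pytest.approx(enc_oracle(counts), abs=1e-9)


def test_enc_invariant_to_within_family_label_permutation(rng):
    cds = make_cds(400, rng)
    counts = codon_counts(cds)
    permuted = counts.copy()
    for codons in AA_TO_CODONS.values():
        idx = [CODON_INDEX[c] for c in codons]
        family = counts[idx]
        permuted[idx] = family[rng.permutation(len(idx))]
    assert enc(permuted) == pytest.approx(enc(counts), abs=1e-12)


def test_enc_approaches_61_under_uniform_family_usage(rng):
    draws = rng.choice(len(SENSE_CODONS), size=10_000)
    counts = np.zeros(64, dtype=np.int64)
    for i in draws:
        counts[CODON_INDEX[SENSE_CODONS[i]]] += 1
    assert enc(counts) > 60.5


def test_enc_undefined_without_usable_families():
    assert math.isnan(enc(counts_from({"ATG": 5, "TGG": 3})))


# ---------------------------------------------------------------------------
# expected-ENC curve


@pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
def test_enc_expected_printed_formula(s, expected):
    assert enc_expected(s) == pytest.approx(expected)


def test_enc_expected_symmetry_about_half():
    for x in (0.1, 0.25, 0.4):
        assert enc_expected(x) - x == pytest.approx(enc_expected(1 - x) - (1 - x))


def test_gene_profile_consistency(rng):
    cds = make_cds(200, rng)
    p = gene_profile(cds)
    assert p.a3 + p.t3 + p.c3 + p.g3 == p.n_codons
    assert p.gc12 == (p.gc1 + p.gc2) / 2
    assert 20.0 <= p.enc <= 61.0
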