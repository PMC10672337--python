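"""Shared fixtures: small simulated panels and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from endosym.orthology import reciprocal_best_hits
from endosym.seqio import CodingSequence, extract_cds
from endosym.synthetic import (CladeSpec, PanelSpec, build_codon_profile,
                               generate_panel, sample_codons)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_cds(n_codons: int, rng, locus="g1", genome="x", gc3=0.3,
             skew=(0.5, 0.5), aa_freqs=None) -> CodingSequence:
    """Random QC-clean CDS sampled from a codon profile."""
    from endosym._genetic_code import translate_nt
    profile = build_codon_profile(gc3, skew, aa_freqs=aa_freqs)
    nt = "ATG" + sample_codons(profile, n_codons - 2, rng) + "TAA"
    return CodingSequence(locus_id=locus, genome_id=genome, nt=nt,
                         aa=translate_nt(nt).rstrip("*"))


@pytest.fixture(scope="session")
def small_panel():
    """Two 2-genome clades, 40 short genes: fast end-to-end substrate."""
    spec = PanelSpec(
        clades=[
            CladeSpec("AA", 2, branch_in=0.12, branch_within=0.01, omega=0.2,
                      gc3_target=0.20, pr2_skew=(0.6, 0.6)),
            CladeSpec("BB", 2, branch_in=0.12, branch_within=0.01, omega=0.2,
                      gc3_target=0.16, pr2_skew=(0.65, 0.6)),
        ],
        n_genes=40, mean_gene_len=150, seed=11)
    panel = generate_panel(spec)
    cds = {g.id: {c.locus_id: c for c in extract_cds(g)} for g in panel.genomes}
    table = reciprocal_best_hits(cds, candidates=6)
    return panel, cds, table


@pytest.fixture(scope="session")
def recovery_panel():
    """Three clades of 4/3/2 genomes, 200 genes, shallow within-clade and
    deep between-clade branches under strong purifying selection — the
    panel used for parameter-recovery checks."""
    spec = PanelSpec(
        clades=[
            CladeSpec("BM", 4, branch_in=0.15, branch_within=0.01, omega=0.1,
                      gc3_target=0.22, pr2_skew=(0.62, 0.60)),
            CladeSpec("AD", 3, branch_in=0.15, branch_within=0.01, omega=0.1,
                      gc3_target=0.17, pr2_skew=(0.65, 0.62)),
            CladeSpec("AL", 2, branch_in=0.15, branch_within=0.01, omega=0.1,
                      gc3_target=0.15, pr2_skew=(0.68, 0.65)),
        ],
        n_genes=200, mean_gene_len=300, seed=7)
    panel = generate_panel(spec)
    cds = {g.id: {c.locus_id: c for c in extract_cds(g)} for g in panel.genomes}
    table = reciprocal_best_hits(cds, candidates=8)
    return panel, cds, table
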