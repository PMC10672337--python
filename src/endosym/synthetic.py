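"""Synthetic annotated-genome panels with controlled codon bias and divergence.

The generator emulates the statistical structure of reduced, AT-rich
endosymbiont genome panels: a few hundred short genes, low GC, high coding
density, several clades whose tips are nearly identical within a clade and
85–90% identical between clades, strong purifying selection (acceptance
ratio omega ≪ 1) and clade-specific third-codon-position composition.

Codon profiles are parameterised by a target GC3 and PR2 skews
(A3/(A3+T3), G3/(G3+C3)): third-position base weights
wA = (1−g)·a, wT = (1−g)(1−a), wG = g·s, wC = g(1−s) are applied within each
synonymous family.  Sequence evolution is a rejection-sampled codon model:
per-site nucleotide proposals at rate t with HKY-style transition bias
kappa; proposals creating a stop are rejected, nonsynonymous proposals are
accepted with probability omega, synonymous ones always.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._genetic_code import AA_TO_CODONS, CODON_TO_AA, STOP_CODONS, revcomp, translate_nt
from .seqio import AnnotatedGenome, CodingSequence, Feature

#: amino-acid frequencies typical of AT-rich endosymbiont proteomes
#: (Ile/Lys/Leu/Asn-rich, Cys/Trp-poor)
DEFAULT_AA_FREQS: dict[str, float] = {
    "I": 0.125, "K": 0.125, "L": 0.10, "N": 0.095, "F": 0.075, "S": 0.07,
    "Y": 0.055, "E": 0.05, "V": 0.04, "G": 0.03, "T": 0.03, "D": 0.03,
    "A": 0.025, "Q": 0.025, "R": 0.02, "P": 0.02, "H": 0.02, "M": 0.022,
    "W": 0.008, "C": 0.005,
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"


@dataclass(frozen=True)
class CladeSpec:
    """Parameters of one clade of the simulated panel."""

    name: str
    n_genomes: int
    branch_in: float       # expected proposals/site, root -> clade ancestor
    branch_within: float   # clade ancestor -> each tip
    omega: float           # nonsynonymous acceptance probability
    kappa: float = 2.0     # transition/transversion rate ratio
    gc3_target: float = 0.18
    pr2_skew: tuple[float, float] = (0.62, 0.60)  # (A3/(A3+T3), G3/(G3+C3))

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.branch_in < 0 or self.branch_within < 0:
            raise ValueError("invalid clade spec")
        if not (self.omega >= 0 and self.kappa > 0 and 0 < self.gc3_target < 1):
            raise ValueError("invalid clade rates")
        if not all(0 < v < 1 for v in self.pr2_skew):
            raise ValueError("pr2_skew values must be in (0,1)")


def default_clades() -> list[CladeSpec]:
    """Three clades patterned on a whitefly-endosymbiont panel: one tight
    4-genome clade, a looser 3-genome clade and a 2-genome clade."""
    return [
        CladeSpec("BM", 4, branch_in=0.15, branch_within=0.005, omega=0.1,
                  gc3_target=0.22, pr2_skew=(0.62, 0.60)),
        CladeSpec("AD", 3, branch_in=0.15, branch_within=0.02, omega=0.1,
                  gc3_target=0.17, pr2_skew=(0.65, 0.62)),
        CladeSpec("AL", 2, branch_in=0.15, branch_within=0.03, omega=0.1,
                  gc3_target=0.15, pr2_skew=(0.68, 0.65)),
    ]


@dataclass
class PanelSpec:
    """Full specification of a synthetic genome panel."""

    clades: list[CladeSpec] = field(default_factory=default_clades)
    n_genes: int = 250
    mean_gene_len: int = 300       # codons
    seed: int = 0
    coding_density: float = 0.91
    intergenic_gc: float = 0.20

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.mean_gene_len < 40:
            raise ValueError("invalid panel spec")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelSpec":
        raw = json.loads(text)
        clades = [CladeSpec(**{**c, "pr2_skew": tuple(c["pr2_skew"])})
                  for c in raw.pop("clades")]
        return cls(clades=clades, **raw)


# ---------------------------------------------------------------------------
# codon profiles


@dataclass
class CodonProfile:
    """Per-amino-acid codon probabilities plus flat sampling arrays."""

    family_probs: dict[str, np.ndarray]
    aa_freqs: dict[str, float]
    base3_weights: dict[str, float]
    gc3_target: float
    expected_gc3: float
    codons: list[str] = field(default_factory=list)
    codon_probs: np.ndarray = field(default_factory=lambda: np.empty(0))


def _base3_weights(gc3_target: float, pr2_skew: tuple[float, float]) -> dict[str, float]:
    a_skew, g_skew = pr2_skew
    return {"A": (1 - gc3_target) * a_skew, "T": (1 - gc3_target) * (1 - a_skew),
            "G": gc3_target * g_skew, "C": gc3_target * (1 - g_skew)}


def build_codon_profile(gc3_target: float, pr2_skew: tuple[float, float] = (0.5, 0.5),
                        aa_freqs: dict[str, float] | None = None) -> CodonProfile:
    """Codon probability table hitting a target GC3 and PR2 skews.

    Within each synonymous family, codons are weighted by their
    third-position base weight.  The analytically expected GC3 of a long
    random gene (under ``aa_freqs``) must land within ±0.02 of the target —
    otherwise the joint targets are infeasible and an error names the
    binding constraint (non-degenerate Met/Trp third positions and the
    restricted third bases of 2- and 3-fold families bound what is
    reachable).
    """
    if not (0 < gc3_target < 1) or not all(0 < v < 1 for v in pr2_skew):
        raise ValueError("targets must be in (0, 1)")
    freqs = dict(DEFAULT_AA_FREQS if aa_freqs is None else aa_freqs)
    total = sum(freqs.values())
    freqs = {aa: f / total for aa, f in freqs.items()}
    w3 = _base3_weights(gc3_target, pr2_skew)
    family_probs: dict[str, np.ndarray] = {}
    expected_gc3 = 0.0
    for aa, codons in AA_TO_CODONS.items():
        w = np.array([w3[c[2]] for c in codons], dtype=float)
        p = w / w.sum()
        family_probs[aa] = p
        fam_gc3 = sum(pi for pi, c in zip(p, codons) if c[2] in "GC")
        expected_gc3 += freqs.get(aa, 0.0) * fam_gc3
    if abs(expected_gc3 - gc3_target) > 0.02:
        raise ValueError(
            f"infeasible joint targets: expected GC3 {expected_gc3:.3f} vs target "
            f"{gc3_target:.3f}; binding constraints are the fixed G third position of "
            "Met/Trp and the restricted third bases of 2-/3-fold families under the "
            "given amino-acid frequencies")
    flat_codons: list[str] = []
    flat_probs: list[float] = []
    for aa, codons in AA_TO_CODONS.items():
        for c, p in zip(codons, family_probs[aa]):
            flat_codons.append(c)
            flat_probs.append(freqs.get(aa, 0.0) * p)
    probs = np.array(flat_probs)
    return CodonProfile(family_probs=family_probs, aa_freqs=freqs, base3_weights=w3,
                        gc3_target=gc3_target, expected_gc3=expected_gc3,
                        codons=flat_codons, codon_probs=probs / probs.sum())


def sample_codons(profile: CodonProfile, n: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(profile.codons), size=n, p=profile.codon_probs)
    return "".join(profile.codons[i] for i in idx)


# ---------------------------------------------------------------------------
# ancestor construction


def _mean_profile(spec: PanelSpec) -> CodonProfile:
    gc3 = float(np.mean([c.gc3_target for c in spec.clades]))
    a = float(np.mean([c.pr2_skew[0] for c in spec.clades]))
    g = float(np.mean([c.pr2_skew[1] for c in spec.clades]))
    return build_codon_profile(gc3, (a, g))


@dataclass
class _Layout:
    """Genes + spacers + strands from which any tip genome is assembled."""

    gene_nt: list[str]          # strand-resolved 5'->3', incl. ATG and stop
    strands: list[int]
    spacers: list[str]          # n_genes + 1 of them


def _assemble(genome_id: str, layout: _Layout, topology: str = "circular") -> AnnotatedGenome:
    parts = [layout.spacers[0]]
    feats: list[Feature] = []
    pos = len(layout.spacers[0])
    for i, (nt, strand) in enumerate(zip(layout.gene_nt, layout.strands)):
        fwd = nt if strand == 1 else revcomp(nt)
        feats.append(Feature(kind="CDS", start=pos, end=pos + len(nt),
                             strand=strand, locus_id=f"G{i + 1:04d}"))
        parts.append(fwd)
        pos += len(nt)
        parts.append(layout.spacers[i + 1])
        pos += len(layout.spacers[i + 1])
    return AnnotatedGenome(id=genome_id, sequence="".join(parts),
                           topology=topology, features=feats)


def _make_layout(spec: PanelSpec, profile: CodonProfile, rng: np.random.Generator) -> _Layout:
    lens = np.clip(rng.gamma(9.0, spec.mean_gene_len / 9.0, size=spec.n_genes),
                   60, 5 * spec.mean_gene_len).astype(int)
    genes = ["ATG" + sample_codons(profile, int(L) - 2, rng) + "TAA" for L in lens]
    strands = [int(s) for s in rng.choice([1, -1], size=spec.n_genes)]
    total_coding = sum(len(g) for g in genes)
    total_spacer = max(0, round(total_coding / spec.coding_density) - total_coding)
    cuts = rng.multinomial(total_spacer, np.full(spec.n_genes + 1, 1.0 / (spec.n_genes + 1)))
    p_bg = np.array([(1 - spec.intergenic_gc) / 2, spec.intergenic_gc / 2,
                     spec.intergenic_gc / 2, (1 - spec.intergenic_gc) / 2])
    spacers = ["".join(np.array(list(_BASES))[rng.choice(4, size=int(c), p=p_bg)])
               for c in cuts]
    return _Layout(gene_nt=genes, strands=strands, spacers=spacers)


def generate_ancestor(spec: PanelSpec, rng: np.random.Generator | None = None) -> AnnotatedGenome:
    """Root genome of a panel: genes begin with ATG, end with a stop, carry
    no internal stops, and intergenic spacers are sized so the realised
    coding density matches the requested one."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    layout = _make_layout(spec, _mean_profile(spec), rng)
    return _assemble("ANC", layout)


# ---------------------------------------------------------------------------
# sequence evolution


def _propose(base: str, kappa: float, rng: np.random.Generator,
             w3: dict[str, float] | None) -> str:
    alts = [b for b in _BASES if b != base]
    w = np.array([kappa if _TRANSITION[base] == b else 1.0 for b in alts])
    if w3 is not None:
        w = w * np.array([w3[b] for b in alts])
    w = w / w.sum()
    return alts[rng.choice(3, p=w)]


def evolve_cds(cds: CodingSequence, t: float, kappa: float, omega: float,
               rng: np.random.Generator,
               base3_weights: dict[str, float] | None = None) -> CodingSequence:
    """Evolve one CDS along a branch of length ``t`` (expected proposals per
    site).  The terminal stop codon is held fixed; proposals creating a stop
    are rejected; nonsynonymous proposals are accepted with probability
    ``omega``.  ``base3_weights`` optionally biases third-position proposals
    toward a clade-specific composition."""
    if t < 0:
        raise ValueError("negative branch length")
    nt = list(cds.nt)
    n_sites = len(nt) - (3 if cds.nt[-3:] in STOP_CODONS else 0)
    if t > 0 and n_sites > 0:
        counts = rng.poisson(t, size=n_sites)
        events = np.repeat(np.arange(n_sites), counts)
        rng.shuffle(events)
        for pos in events:
            ci = 3 * (pos // 3)
            old_codon = "".join(nt[ci : ci + 3])
            new_base = _propose(nt[pos], kappa, rng,
                                base3_weights if pos % 3 == 2 else None)
            new_codon = old_codon[: pos % 3] + new_base + old_codon[pos % 3 + 1 :]
            if new_codon in STOP_CODONS:
                continue
            if CODON_TO_AA[new_codon] != CODON_TO_AA[old_codon] and rng.random() >= omega:
                continue
            nt[pos] = new_base
    new_nt = "".join(nt)
    aa = translate_nt(new_nt)
    if aa.endswith("*"):
        aa = aa[:-1]
    return CodingSequence(locus_id=cds.locus_id, genome_id=cds.genome_id,
                          nt=new_nt, aa=aa)


def _evolve_neutral(seq: str, t: float, kappa: float, rng: np.random.Generator) -> str:
    if not seq or t == 0:
        return seq
    out = list(seq)
    counts = rng.poisson(t, size=len(out))
    for pos in np.nonzero(counts)[0]:
        for _ in range(counts[pos]):
            out[pos] = _propose(out[pos], kappa, rng, None)
    return "".join(out)


# ---------------------------------------------------------------------------
# panel generation


@dataclass
class PanelResult:
    genomes: list[AnnotatedGenome]
    truth: pd.DataFrame           # genome_id, clade, branch_in, branch_within
    true_tree: str                # newick with true branch lengths
    spec: PanelSpec


def _evolve_layout(layout: _Layout, t: float, kappa: float, omega: float,
                   rng: np.random.Generator,
                   w3: dict[str, float] | None) -> _Layout:
    genes = []
    for i, nt in enumerate(layout.gene_nt):
        cds = CodingSequence(f"G{i + 1:04d}", "", nt, translate_nt(nt).rstrip("*"))
        genes.append(evolve_cds(cds, t, kappa, omega, rng, base3_weights=w3).nt)
    spacers = [_evolve_neutral(s, t, kappa, rng) for s in layout.spacers]
    return _Layout(gene_nt=genes, strands=layout.strands, spacers=spacers)


def generate_panel(spec: PanelSpec) -> PanelResult:
    """Evolve a panel of tip genomes from a common ancestor along a clade
    tree (root -> clade ancestors -> tips) and return them with the truth
    needed for parameter-recovery checks."""
    rng = np.random.default_rng(spec.seed)
    root = _make_layout(spec, _mean_profile(spec), rng)
    genomes: list[AnnotatedGenome] = []
    rows = []
    clade_parts = []
    for clade in spec.clades:
        w3 = _base3_weights(clade.gc3_target, clade.pr2_skew)
        clade_anc = _evolve_layout(root, clade.branch_in, clade.kappa, clade.omega, rng, w3)
        tip_frags = []
        for i in range(clade.n_genomes):
            gid = f"{clade.name}{i + 1}"
            tip = _evolve_layout(clade_anc, clade.branch_within, clade.kappa,
                                 clade.omega, rng, w3)
            genomes.append(_assemble(gid, tip))
            rows.append({"genome_id": gid, "clade": clade.name,
                         "branch_in": clade.branch_in,
                         "branch_within": clade.branch_within})
            tip_frags.append(f"{gid}:{clade.branch_within:g}")
        clade_parts.append(f"({','.join(tip_frags)}):{clade.branch_in:g}")
    tree = f"({','.join(clade_parts)});"
    truth = pd.DataFrame(rows, columns=["genome_id", "clade", "branch_in", "branch_within"])
    return PanelResult(genomes=genomes, truth=truth, true_tree=tree, spec=spec)
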