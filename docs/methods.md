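# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic-genome generator does
and does not emulate, and the numerical conventions that make runs
deterministic.

## Genome summaries

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
locations are converted on input. GC% is computed over unambiguous
(A/C/G/T) positions only. Coding density is the union of *all* annotated
feature intervals (CDS + RNA genes) divided by genome length — in heavily
reduced genomes the RNA genes are a material fraction of the chromosome,
and this union convention is what "coding density" usually denotes for
them; a CDS-only density is reported in the same table for comparison.
Compound (joined) GenBank locations are honoured only for a single
origin-spanning feature on a circular replicon; any other compound location
is dropped with a warning, since its intent cannot be reconstructed safely.

CDS quality control precedes every codon-level statistic: genes are dropped
when their length is not a multiple of 3, shorter than 90 nt, containing
ambiguous bases, or carrying an internal stop. Translation uses the
bacterial genetic code (table 11) throughout.

## Codon statistics

Stop codons never enter per-gene statistics; a terminal stop is stripped
before counting. PR2 coordinates use the third positions of **all** sense
codons (not 4-fold sites only). GC3s is computed over third positions of
codons with synonymous alternatives, i.e. excluding Met, Trp and stops;
this choice is recorded in output metadata because tools differ here.

ENC follows Wright (1990): per amino-acid family, codon homozygosity
F = (nΣp² − 1)/(n − 1); families with n ≤ 1 are skipped; F̄ₖ is the plain
mean within each degeneracy class; Ile is the single 3-fold family under
the bacterial code and Ser, Leu, Arg are treated as single 6-fold families;
a missing F̄₃ is imputed as the mean of F̄₂ and F̄₄; the result is clamped to
[20, 61]. With any class mean missing or zero the gene's ENC is reported as
missing rather than guessed.

The neutrality plot regresses GC12 on GC3 (ordinary least squares; R² is
the squared Pearson correlation). A constant GC3 is a degenerate regression
and raises; a constant GC12 yields slope 0 and R² 0 by definition. The ENC
plot reports the relative deviation (ENC_exp − ENC)/ENC_exp and flags genes
more than 5% (configurable) beneath the curve. The PR2 ellipse is the 95%
chi-square contour of the 2-D sample covariance; quadrant boundaries at
0.5 assign boundary points to the upper/right quadrant for determinism.

## Orthology

Single-copy orthologs are reciprocal best hits (RBH) on global protein
alignments: Needleman–Wunsch with BLOSUM62, gap open 11, extension 1 (the
first gapped position costs the open penalty). Because an exhaustive
all-vs-all search over ~250 genes × 9–10 genomes is millions of quadratic
alignments, the exact alignment is evaluated only for the proteins sharing
the most 4-mers with each query (8 candidates by default;
`candidates=None` restores the exhaustive search). At within-panel protein
identities of 80%+ the true ortholog dominates this ranking by a wide
margin; the test suite verifies 100% ortholog recovery on simulated panels
with known gene correspondence. Best-hit ties are broken by higher
alignment identity, then lexicographic locus id. Groups are connected
components of the best-hit graph kept only when they have exactly one
member per genome and all cross-genome pairs are mutual best hits; a
duplicated gene therefore invalidates its whole component instead of
silently selecting a copy.

Codon alignments are back-translations of the protein alignment (gaps in
whole codons); Ka/Ks, ANI and AAI use only the ungapped codon columns, the
pairwise analogue of multiple-alignment column trimming.

## Ka/Ks (NG86)

Synonymous site fractions per codon come from enumerating all nine
single-nucleotide mutants; changes to stop codons count as nonsynonymous.
Differences per codon pair average over all minimal mutational pathways
with equal weights, excluding pathways through stop codons and falling back
to all pathways (stop steps nonsynonymous) when every pathway is blocked.
Sites are averaged over the two sequences; proportions are Jukes–Cantor
corrected, with ps or pn ≥ 3/4 flagged as saturation and the corresponding
rate reported missing. ω = Ka/Ks is missing when Ks is zero or undefined.
All per-codon and per-codon-pair quantities are precomputed tables, so the
estimator is exact and fast. The method is fixed to classical NG86 — simple
counting, fully specifiable, no likelihood machinery — and is recorded in
the run manifest.

## Relatedness and grouping

ANI is the length-weighted mean nucleotide identity over ungapped codon
columns of all shared single-copy ortholog alignments; AAI is the
amino-acid identity over the same columns. This "ortholog alignment"
flavour of ANI/AAI matches analyses that feed single-copy orthologs to
identity calculators, not fragment-mapping tools, so two-decimal agreement
with the latter is expected but not bit-exact equality.

Mash distances use bottom-s MinHash sketches of canonical (strand-folded)
k-mers, k = 21 and s = 1000 (the common Mash defaults), with a 64-bit
splitmix64 finalizer as the hash (seeded; recorded in metadata). Jaccard
similarity is estimated from the bottom-s of the merged sketch and mapped
to distance by d = −ln(2j/(1+j))/k; disjoint sketches give +∞ (replaced by
1.0 when a tree is built). The default Mash input is the locus-sorted
concatenation of a genome's CDS; whole-genome sequence input is available.

Neighbor joining is the classical Saitou–Nei algorithm with two
deterministic conventions: Q-criterion ties resolve to the earliest pair in
label order, and a negative branch length is clamped to zero with the
deficit moved to the sibling branch (their sum, the joined distance, is
preserved). On additive matrices the generating topology and branch lengths
are recovered exactly (tested against dendropy-simulated trees and
cross-checked against scikit-bio's implementation).

Genetic groups are connected components of the graph with an edge wherever
ANI > ani_min and AAI > aai_min, strictly — a pair sitting exactly at a
threshold does not join. Components are the natural aggregation when only
pairwise criteria are stated; group labels are assigned by the smallest
member id so the partition is invariant to input order.

## Synthetic panels

The generator emulates the statistical structure of reduced AT-rich
endosymbiont panels: by default 250 genes of mean length 300 codons (gamma
distributed, 60–1500 codons), coding density 0.91, intergenic GC 0.20, and
a default amino-acid composition rich in Ile/Lys/Asn/Phe such that coding
GC lands near 24%. Codon profiles weight synonymous codons by
third-position base weights wA = (1−g)a, wT = (1−g)(1−a), wG = gs,
wC = g(1−s) for GC3 target g and PR2 skews (a, s). The weights are used
directly (no numeric solve), so the expected GC3 of a long gene deviates
slightly from the target through three binding constraints — Met/Trp third
positions are fixed at G, Ile has no G-ending codon, and 2-fold families
restrict third bases to one purine/pyrimidine pair. The profile builder
computes the expected GC3 analytically and raises when it misses the target
by more than 0.02, naming those constraints. A corollary worth knowing:
with all-sense-codon PR2, amino-acid composition alone shifts the PR2 point
(e.g. an excess of Lys/Glu/Gln over the pyrimidine-ending 2-fold families
drags G3/(G3+C3) down), so a "parity-neutral" panel requires a balanced
proteome, which is what the corresponding test constructs.

Evolution is a rejection-sampled codon model: each site receives
Poisson(t) nucleotide proposals, a proposal is a transition with relative
weight κ (default 2) or a transversion with weight 1, proposals creating a
stop are rejected, nonsynonymous proposals are accepted with probability ω,
synonymous ones always; the terminal stop codon is held fixed. Branch
length t therefore counts *proposals* per site; realised substitutions per
site are ≈ t·(fsyn + ω·fnonsyn) ≈ 0.3 t at ω = 0.1. Clade stems optionally
bias third-position proposals toward the clade's codon profile, which is
how clade-specific third-position composition arises. Panels evolve a root
genome along a star-of-clades tree (root → clade ancestors → tips);
intergenic spacers evolve neutrally. Defaults for the three clades (4, 3
and 2 genomes; within-clade branches 0.005–0.03, stems 0.15; ω = 0.1;
clade GC3 targets 0.22/0.17/0.15 with A/G-skewed third positions) are
chosen so that realised within-clade identity exceeds 99%, between-clade
identity sits near 90–92%, and Mash distances within/between groups fall in
clearly separated ranges — mirroring the empirical structure of published
whitefly-endosymbiont panels.

Not emulated: insertions/deletions, rearrangements, gene gain/loss,
recombination, rate heterogeneity across sites and lineages, and real
intergenic architecture. Passing recovery tests on these panels therefore
demonstrates the estimators and the pipeline plumbing, not robustness to
alignment-breaking evolution.

## Problem sizes and determinism

The parameter-recovery study runs at 200 genes × 9 genomes, large enough
that median Ka/Ks, classification and tree topology are stable run to run;
the MinHash accuracy check uses ten 50 kb pairs; NJ additivity is checked
on eight random 6-taxon trees and the within/between identity invariant on
four random two-clade specs. The rank correlation between 1 − ANI and Mash
distance is evaluated on a panel with three distinct clade depths: when all
between-clade branches are equal, between-pair distances are equal by
construction and their ranks carry no signal, so that comparison would
measure noise rather than agreement.

Every stochastic component takes an explicit seed (simulation specs, the
acceptance script's `--seed`, the fixed MinHash hash seed), and the
pipeline stamps a hash of its configuration into every output table;
rerunning a config is bit-identical. Known limitations: ANI/AAI are
computed on ortholog alignments only (no intergenic signal); the RBH
candidate prescreen can in principle miss a best hit between highly
divergent proteomes (use `candidates=None` there); Ka/Ks is a counting
estimator and modestly underestimates ω at the simulated depths; and the
expected-ENC comparison inherits ENC's small-gene noise for genes under
~100 codons.
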