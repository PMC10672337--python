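"""ANI/AAI, MinHash/Mash, neighbor joining, and group classification."""

import io
import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from endosym._genetic_code import revcomp, translate_nt
from endosym.orthology import OrthologGroup, OrthologTable
from endosym.relatedness import (Sketch, aai, ani, classify_groups,
                                 concatenated_cds, distance_matrices,
                                 mash_distance, nj_tree, sketch,
                                 sketch_jaccard)
from endosym.seqio import CodingSequence

from conftest import make_cds


def _one_gene_table(nt_a, nt_b):
    cds = {
        "A": {"L1": CodingSequence("L1", "A", nt_a, translate_nt(nt_a).rstrip("*"))},
        "B": {"L1": CodingSequence("L1", "B", nt_b, translate_nt(nt_b).rstrip("*"))},
    }
    table = OrthologTable(genome_ids=("A", "B"),
                          groups=[OrthologGroup("OG0001", {"A": "L1", "B": "L1"})])
    return table, cds


def test_ani_simple_mismatch_fraction():
    # 100 codons, two synonymous third-position mismatches -> 298/300
    nt_a = "ATG" + "AAA" * 99
    nt_b = "ATG" + "AAG" * 2 + "AAA" * 97
    table, cds = _one_gene_table(nt_a, nt_b)
    assert ani(table, cds, "A", "B") == pytest.approx(298 / 300)
    assert aai(table, cds, "A", "B") == 1.0
    assert ani(table, cds, "A", "A") == 1.0


def test_aai_single_substitution():
    # one nonsynonymous change in 10 residues
    nt_a = "ATG" + "AAA" * 9
    nt_b = "ATG" + "GAA" + "AAA" * 8
    table, cds = _one_gene_table(nt_a, nt_b)
    assert aai(table, cds, "A", "B") == pytest.approx(0.9)


def test_ani_requires_shared_orthologs():
    table = OrthologTable(genome_ids=("A", "B"), groups=[])
    with pytest.raises(ValueError, match="no shared"):
        ani(table, {}, "A", "B")


# ---------------------------------------------------------------------------
# sketching


def test_sketch_deterministic_and_strand_canonical(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    s1 = sketch(seq, "a")
    s2 = sketch(seq, "a")
    s3 = sketch(revcomp(seq), "a")
    assert np.array_equal(s1.hashes, s2.hashes)
    assert np.array_equal(s1.hashes, s3.hashes)
    assert mash_distance(s1, s2) == 0.0


def test_sketch_skips_n_and_rejects_short():
    with pytest.raises(ValueError, match="shorter than k"):
        sketch("ACGT", "x")
    s = sketch("A" * 30 + "N" + "C" * 30, "x", k=21)
    # windows overlapping the N are excluded
    assert s.hashes.size == len(np.unique(s.hashes))


def test_sketch_jaccard_tracks_exact_jaccard(rng):
    seq = "".join(rng.choice(list("ACGT"), p=[.38, .12, .12, .38], size=20000))
    mutated = list(seq)
    for i in rng.choice(len(seq), size=300, replace=False):
        mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
    mutated = "".join(mutated)

    def canonical_set(s, k=21):
        return {min(s[i:i + k], revcomp(s[i:i + k])) for i in range(len(s) - k + 1)}

    a, b = canonical_set(seq), canonical_set(mutated)
    exact = len(a & b) / len(a | b)
    est = sketch_jaccard(sketch(seq, "a"), sketch(mutated, "b"))
    assert abs(est - exact) <= 0.05


def test_mash_distance_closed_form():
    # engineered sketches: bottom-1000 of the union shares exactly 900
    shared = np.arange(900, dtype=np.uint64)
    sa = Sketch("a", 21, 1000, 42, np.concatenate([shared, np.arange(1000, 1100, dtype=np.uint64)]))
    sb = Sketch("b", 21, 1000, 42, np.concatenate([shared, np.arange(2000, 2100, dtype=np.uint64)]))
    j = sketch_jaccard(sa, sb)
    assert j == pytest.approx(0.9)
    assert mash_distance(sa, sb) == pytest.approx(-math.log(1.8 / 1.9) / 21)
    empty = Sketch("c", 21, 1000, 42, np.arange(5000, 6000, dtype=np.uint64))
    assert math.isinf(mash_distance(sa, empty))
    with pytest.raises(ValueError, match="mismatch"):
        mash_distance(sa, Sketch("d", 17, 1000, 42, shared))


# ---------------------------------------------------------------------------
# neighbor joining


def _bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial unrooted splits, each canonicalised to the side that
    excludes the lexicographically smallest taxon."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(t.label for t in tree.taxon_namespace)
    anchor = min(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def test_nj_three_taxa_exact_branch_lengths():
    d = np.array([[0, 5, 6], [5, 0, 7], [6, 7, 0]], float)
    nwk = nj_tree(d, ["A", "B", "C"])
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths == {"A": 2.0, "B": 3.0, "C": 4.0}


def test_nj_four_taxa_additive_topology():
    # tree ((A:1,B:2):1,(C:3,D:4):1) -> AB | CD split
    d = np.array([[0, 3, 6, 7],
                  [3, 0, 7, 8],
                  [6, 7, 0, 7],
                  [7, 8, 7, 0]], float)
    nwk = nj_tree(d, ["A", "B", "C", "D"])
    assert _bipartitions(nwk) & {frozenset({"A", "B"}), frozenset({"C", "D"})}


def test_nj_invariant_under_label_permutation(rng):
    n = 6
    base = rng.uniform(0.1, 1.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"T{i}" for i in range(n)]
    perm = list(rng.permutation(n))
    nwk1 = nj_tree(d, labels)
    nwk2 = nj_tree(d[np.ix_(perm, perm)], [labels[i] for i in perm])
    assert _bipartitions(nwk1) == _bipartitions(nwk2)


def test_nj_topology_matches_skbio_reference(rng):
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    n = 7
    base = rng.uniform(0.2, 1.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    labels = [f"T{i}" for i in range(n)]
    ours = _bipartitions(nj_tree(d, labels))
    ref = _bipartitions(str(skbio_nj(DistanceMatrix(d, labels)).write(io.StringIO()).getvalue()))
    assert ours == ref


def test_nj_recovers_random_additive_trees(rng):
    for rep in range(8):
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
            rng=__import__("random").Random(rep))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = max(edge.length, 0.05)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        d = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
        nwk = nj_tree(d, [t.label for t in taxa])
        true_bp = _bipartitions(tree.as_string(schema="newick"))
        assert true_bp <= _bipartitions(nwk)


# ---------------------------------------------------------------------------
# classification


def _paper_pattern():
    ids = ["AdSh", "AlDi", "AlFl", "BTB", "BTQ", "BTZ1", "BTZ3", "PeMo", "TrVa"]
    groups = {"AdSh": "AD", "PeMo": "AD", "TrVa": "AD",
              "AlDi": "AL", "AlFl": "AL",
              "BTB": "BM", "BTQ": "BM", "BTZ1": "BM", "BTZ3": "BM"}
    n = len(ids)
    ani_m = np.full((n, n), 0.88)
    aai_m = np.full((n, n), 0.82)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if groups[a] == groups[b]:
                ani_m[i, j] = 0.99 if groups[a] == "BM" else 0.96
                aai_m[i, j] = 0.99 if groups[a] == "BM" else 0.92
    np.fill_diagonal(ani_m, 1.0)
    np.fill_diagonal(aai_m, 1.0)
    return ids, groups, ani_m, aai_m


def test_classify_three_group_pattern():
    ids, truth, ani_m, aai_m = _paper_pattern()
    asg = classify_groups(ani_m, aai_m, ids)
    got = asg.groups()
    assert len(got) == 3
    members = {frozenset(v) for v in got.values()}
    expect = {frozenset(g for g in ids if truth[g] == lab) for lab in ("AD", "AL", "BM")}
    assert members == expect


def test_classify_edge_cases():
    single = classify_groups(np.array([[1.0]]), np.array([[1.0]]), ["solo"])
    assert single.labels == {"solo": "G1"}
    ones = np.ones((3, 3))
    allsame = classify_groups(ones, ones, ["a", "b", "c"])
    assert len(set(allsame.labels.values())) == 1


def test_classify_invariances():
    ids, _, ani_m, aai_m = _paper_pattern()
    base = classify_groups(ani_m, aai_m, ids).groups()
    perm = np.random.default_rng(3).permutation(len(ids))
    shuffled = classify_groups(ani_m[np.ix_(perm, perm)], aai_m[np.ix_(perm, perm)],
                               [ids[i] for i in perm]).groups()
    assert {frozenset(v) for v in base.values()} == {frozenset(v) for v in shuffled.values()}
    # raising thresholds inside the open between/within interval changes nothing
    tight = classify_groups(ani_m, aai_m, ids, ani_min=0.955, aai_min=0.91).groups()
    assert {frozenset(v) for v in tight.values()} == {frozenset(v) for v in base.values()}


def test_strict_inequality_at_threshold():
    # pair exactly AT the threshold must NOT join
    ani_m = np.array([[1.0, 0.95], [0.95, 1.0]])
    aai_m = np.array([[1.0, 0.95], [0.95, 1.0]])
    asg = classify_groups(ani_m, aai_m, ["a", "b"])
    assert asg.labels["a"] != asg.labels["b"]


# ---------------------------------------------------------------------------
# panel-level coherence


def test_distance_matrices_symmetry(small_panel):
    panel, cds, table = small_panel
    dm = distance_matrices(table, cds)
    for m in (dm.ani, dm.aai, dm.mash):
        assert np.allclose(m, m.T)
    assert np.allclose(np.diag(dm.ani), 1.0)
    assert np.allclose(np.diag(dm.mash), 0.0)


def test_one_minus_ani_tracks_mash_on_varied_depth_panel():
    """Rank agreement between 1−ANI and Mash distance needs genuinely
    varied divergences, so the panel mixes shallow and deep clades."""
    from endosym.seqio import extract_cds
    from endosym.synthetic import CladeSpec, PanelSpec, generate_panel

    spec = PanelSpec(
        clades=[CladeSpec("X", 3, 0.04, 0.01, 0.2, gc3_target=0.2),
                CladeSpec("Y", 3, 0.10, 0.02, 0.2, gc3_target=0.18),
                CladeSpec("Z", 3, 0.22, 0.04, 0.2, gc3_target=0.16)],
        n_genes=30, mean_gene_len=150, seed=17)
    panel = generate_panel(spec)
    cds = {g.id: {c.locus_id: c for c in extract_cds(g)} for g in panel.genomes}
    from endosym.orthology import reciprocal_best_hits
    table = reciprocal_best_hits(cds, candidates=6)
    dm = distance_matrices(table, cds)
    pairs = list(itertools.combinations(range(len(dm.genome_ids)), 2))
    rho = stats.spearmanr([1 - dm.ani[i, j] for i, j in pairs],
                          [dm.mash[i, j] for i, j in pairs]).statistic
    assert rho > 0.9
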