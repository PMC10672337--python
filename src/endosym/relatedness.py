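"""Pairwise genome relatedness and genetic-group classification.

ANI and AAI are length-weighted mean identities over the single-copy
ortholog alignments (nucleotide identity over ungapped codon columns;
amino-acid identity over the same gap-free columns).  Mash distance is
estimated from bottom-s MinHash sketches of canonical k-mers with the
joint-sketch Jaccard estimator, d = −ln(2j/(1+j))/k.  Genomes are grouped
by connected components of the graph whose edges require ANI and AAI to
exceed their thresholds strictly (the conventional >95% / >90% species-like
criteria), and a neighbor-joining tree summarises the Mash matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._genetic_code import translate_nt
from .orthology import OrthologTable, codon_align
from .seqio import CodingSequence

# ---------------------------------------------------------------------------
# ANI / AAI from ortholog alignments


def _pair_alignment(table: OrthologTable, cds_by_genome, group, a: str, b: str):
    aln = table.get_alignment(group.group_id, a, b)
    if aln is None:
        aln = codon_align(cds_by_genome[a][group.members[a]],
                          cds_by_genome[b][group.members[b]])
        table.cache_alignment(group.group_id, a, b, aln)
    return aln


def _identity_sums(table, cds_by_genome, a: str, b: str) -> tuple[int, int, int, int]:
    """(nt matches, nt columns, aa matches, aa columns) over all shared
    single-copy ortholog alignments of genomes a and b."""
    nt_match = nt_total = aa_match = aa_total = 0
    shared = [g for g in table.groups if a in g.members and b in g.members]
    if not shared:
        raise ValueError(f"no shared single-copy orthologs for {a}, {b}")
    for group in shared:
        aln = _pair_alignment(table, cds_by_genome, group, a, b)
        for ca, cb in aln.ungapped_codon_columns():
            nt_total += 3
            nt_match += sum(x == y for x, y in zip(ca, cb))
            aa_total += 1
            aa_match += translate_nt(ca) == translate_nt(cb)
    return nt_match, nt_total, aa_match, aa_total


def ani(table: OrthologTable, cds_by_genome, a: str, b: str) -> float:
    """Average nucleotide identity over shared single-copy orthologs,
    weighted by aligned (ungapped) length."""
    if a == b:
        return 1.0
    nt_match, nt_total, _, _ = _identity_sums(table, cds_by_genome, a, b)
    return nt_match / nt_total


def aai(table: OrthologTable, cds_by_genome, a: str, b: str) -> float:
    """Average amino-acid identity over the same ortholog alignments."""
    if a == b:
        return 1.0
    _, _, aa_match, aa_total = _identity_sums(table, cds_by_genome, a, b)
    return aa_match / aa_total


# ---------------------------------------------------------------------------
# MinHash sketching and Mash distance

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _SPLITMIX_GAMMA).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= _MIX1
    x ^= x >> np.uint64(27)
    x *= _MIX2
    x ^= x >> np.uint64(31)
    return x


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted ascending, ≤ s distinct uint64 values


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        raise ValueError(f"sequence shorter than k={k}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    win = win[valid].astype(np.uint64)
    shifts_f = np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)
    shifts_r = np.uint64(2) * np.arange(k, dtype=np.uint64)
    fwd = (win << shifts_f).sum(axis=1, dtype=np.uint64)
    rev = ((np.uint64(3) - win) << shifts_r).sum(axis=1, dtype=np.uint64)
    return np.minimum(fwd, rev)


def sketch(seq: str, genome_id: str = "", k: int = 21, s: int = 1000,
           hash_seed: int = 42) -> Sketch:
    """Bottom-s sketch of the canonical (strand-folded) k-mers of ``seq``;
    k-mers containing N are skipped."""
    canon = _canonical_kmer_codes(seq, k)
    if canon.size == 0:
        raise ValueError("no valid k-mers (all contain N)")
    seed = _splitmix64(np.array([hash_seed], dtype=np.uint64))[0]
    hashes = np.unique(_splitmix64(canon ^ seed))
    return Sketch(genome_id=genome_id, k=k, s=s, hash_seed=hash_seed, hashes=hashes[:s])


def sketch_jaccard(sa: Sketch, sb: Sketch) -> float:
    """Mash's joint-sketch Jaccard estimate: shared fraction of the bottom
    min(s, |union|) hashes of the merged sketches."""
    if (sa.k, sa.s, sa.hash_seed) != (sb.k, sb.s, sb.hash_seed):
        raise ValueError("sketch parameter mismatch")
    union = np.union1d(sa.hashes, sb.hashes)
    merged = union[: min(sa.s, union.size)]
    shared = np.isin(merged, sa.hashes, assume_unique=True) & \
        np.isin(merged, sb.hashes, assume_unique=True)
    return float(shared.sum()) / merged.size


def mash_distance(sa: Sketch, sb: Sketch) -> float:
    """Mash distance d = −ln(2j/(1+j))/k; +inf when no hashes are shared."""
    j = sketch_jaccard(sa, sb)
    if j == 0.0:
        return math.inf
    return max(0.0, -math.log(2.0 * j / (1.0 + j)) / sa.k)


def concatenated_cds(cds_map: dict[str, CodingSequence]) -> str:
    """Locus-sorted concatenation of a genome's CDS (the Mash default input)."""
    return "".join(cds_map[L].nt for L in sorted(cds_map))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: np.ndarray, labels: list[str]) -> str:
    """Classical Saitou–Nei neighbor joining; returns a Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch (their sum is preserved); ties in the Q criterion are
    broken by position in ``labels``.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("need a symmetric non-negative square matrix")
    if n != len(labels):
        raise ValueError("labels/matrix size mismatch")
    if n == 1:
        return f"({labels[0]}:0);"
    if n == 2:
        h = d[0, 1] / 2.0
        return f"({labels[0]}:{h:.10g},{labels[1]}:{h:.10g});"

    frags: list[str] = list(labels)         # newick fragment per active node
    inner: list[str | None] = [None] * n    # children string if internal
    dist = d.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (math.inf, -1, -1)
        for i in range(m):
            for jj in range(i + 1, m):
                if q[i, jj] < best[0] - 1e-12:
                    best = (q[i, jj], i, jj)
        _, i, jj = best
        a, b = active[i], active[jj]
        dij = sub[i, jj]
        li = 0.5 * dij + (r[i] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        children = f"{frags[a]}:{li:.10g},{frags[b]}:{lj:.10g}"
        frags.append(f"({children})")
        inner.append(children)
        new = len(frags)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (a, b):
                continue
            duk = 0.5 * (dist[a, kk] + dist[b, kk] - dij)
            dist[new - 1, kk] = dist[kk, new - 1] = max(0.0, duk)
        active = [x for x in active if x not in (a, b)] + [new - 1]

    a, b = active
    dab = max(0.0, dist[a, b])
    if inner[b] is not None:
        return f"({inner[b]},{frags[a]}:{dab:.10g});"
    if inner[a] is not None:
        return f"({inner[a]},{frags[b]}:{dab:.10g});"
    h = dab / 2.0
    return f"({frags[a]}:{h:.10g},{frags[b]}:{h:.10g});"


# ---------------------------------------------------------------------------
# genetic-group classification


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of a panel into genetic groups under ANI/AAI thresholds."""

    labels: dict[str, str]  # genome_id -> group label
    ani_min: float
    aai_min: float

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid in sorted(self.labels):
            out.setdefault(self.labels[gid], []).append(gid)
        return out


def classify_groups(ani_matrix: np.ndarray, aai_matrix: np.ndarray,
                    genome_ids: list[str], ani_min: float = 0.95,
                    aai_min: float = 0.90) -> GroupAssignment:
    """Connected components of the graph with an edge wherever BOTH
    ANI > ani_min and AAI > aai_min (strict inequalities)."""
    ani_m = np.asarray(ani_matrix, dtype=float)
    aai_m = np.asarray(aai_matrix, dtype=float)
    n = len(genome_ids)
    if ani_m.shape != (n, n) or aai_m.shape != (n, n):
        raise ValueError("matrix/panel size mismatch")
    graph = nx.Graph()
    graph.add_nodes_from(genome_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if ani_m[i, j] > ani_min and aai_m[i, j] > aai_min:
                graph.add_edge(genome_ids[i], genome_ids[j])
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    labels = {g: f"G{idx}" for idx, comp in enumerate(comps, start=1) for g in sorted(comp)}
    return GroupAssignment(labels=labels, ani_min=ani_min, aai_min=aai_min)


# ---------------------------------------------------------------------------
# panel-level matrices


@dataclass
class DistanceMatrices:
    genome_ids: tuple[str, ...]
    ani: np.ndarray
    aai: np.ndarray
    mash: np.ndarray
    mash_params: dict = field(default_factory=dict)


def distance_matrices(table: OrthologTable, cds_by_genome, k: int = 21,
                      s: int = 1000, hash_seed: int = 42,
                      mash_input: str = "cds",
                      genome_sequences: dict[str, str] | None = None) -> DistanceMatrices:
    """ANI, AAI and Mash matrices over a panel.

    ``mash_input`` is 'cds' (locus-sorted concatenated CDS, the default) or
    'genome' (requires ``genome_sequences``).
    """
    gids = table.genome_ids
    n = len(gids)
    ani_m = np.eye(n)
    aai_m = np.eye(n)
    mash_m = np.zeros((n, n))
    if mash_input == "genome":
        if genome_sequences is None:
            raise ValueError("mash_input='genome' needs genome_sequences")
        seqs = {g: genome_sequences[g] for g in gids}
    else:
        seqs = {g: concatenated_cds(cds_by_genome[g]) for g in gids}
    sketches = {g: sketch(seqs[g], genome_id=g, k=k, s=s, hash_seed=hash_seed) for g in gids}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = gids[i], gids[j]
            nt_match, nt_total, aa_match, aa_total = _identity_sums(table, cds_by_genome, a, b)
            ani_m[i, j] = ani_m[j, i] = nt_match / nt_total
            aai_m[i, j] = aai_m[j, i] = aa_match / aa_total
            mash_m[i, j] = mash_m[j, i] = mash_distance(sketches[a], sketches[b])
    return DistanceMatrices(genome_ids=gids, ani=ani_m, aai=aai_m, mash=mash_m,
                            mash_params={"k": k, "s": s, "hash_seed": hash_seed,
                                         "input": mash_input})
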