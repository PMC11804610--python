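"""Species grouping by ANI, concatenated alignments, NJ trees, congruence.

ANI between two genomes follows the conventional fragment recipe: the
query genome is cut into fixed-length fragments (default 1,000 bp), each
fragment is placed at its best location in the other genome by infix
edit-distance alignment (edlib), fragments below 30% identity are
discarded, and the directional means are symmetrized by averaging both
directions. Species groups are single-linkage components of the graph
with edges at ANI >= 95% (the conventional species boundary), the longest
assembly serving as group representative.

Tree building is a neighbor-joining engine on p-distances with pairwise
deletion of gap sites; ties in the Q-criterion break on the
lexicographically smallest taxon pair, so results are independent of
input order. Maximum-likelihood inference is out of scope — externally
built alignments (FASTA) and trees (Newick) can be imported instead.
Congruence between trees is quantified by the Robinson-Foulds distance
(bipartitions present in exactly one tree), normalized by 2(n-3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# ANI and species grouping

def compute_ani(
    genome_a: str,
    genome_b: str,
    fragment_len: int = 1000,
    min_identity: float = 0.30,
    min_fragment_fraction: float = 0.70,
) -> float:
    """Average nucleotide identity (percent) between two genome sequences.

    Fragments shorter than ``min_fragment_fraction * fragment_len`` (the
    trailing remainder) are skipped, mirroring the conventional coverage
    filter.
    """
    if len(genome_a) < fragment_len or len(genome_b) < fragment_len:
        raise ValueError("genome shorter than one fragment")

    def directional(query: str, target: str) -> float:
        identities = []
        for i in range(0, len(query), fragment_len):
            frag = query[i : i + fragment_len]
            if len(frag) < min_fragment_fraction * fragment_len:
                continue
            res = edlib.align(frag, target, mode="HW", task="distance")
            identity = 1.0 - res["editDistance"] / len(frag)
            if identity >= min_identity:
                identities.append(identity)
        if not identities:
            raise ValueError("no fragment passed the identity filter")
        return 100.0 * float(np.mean(identities))

    return (directional(genome_a, genome_b) + directional(genome_b, genome_a)) / 2.0


def ani_matrix(genomes: dict[str, str], fragment_len: int = 1000) -> pd.DataFrame:
    """Symmetric all-vs-all ANI matrix with a 100% diagonal."""
    ids = sorted(genomes)
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for a, b in itertools.combinations(ids, 2):
        ani = compute_ani(genomes[a], genomes[b], fragment_len)
        mat.loc[a, b] = ani
        mat.loc[b, a] = ani
    return mat


@dataclass
class SpeciesGroup:
    members: list[str]
    representative: str


def cluster_species(
    ani: pd.DataFrame,
    threshold: float = 95.0,
    assembly_lengths: dict[str, int] | None = None,
) -> list[SpeciesGroup]:
    """Single-linkage species groups at an ANI threshold (boundary inclusive).

    The representative is the longest assembly in the group (ties and
    missing lengths fall back to lexicographic order).
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    ids = list(ani.index)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        if ani.loc[a, b] >= threshold:
            parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    groups = []
    for members in comps.values():
        members = sorted(members)
        if assembly_lengths:
            rep = max(members, key=lambda m: (assembly_lengths.get(m, 0), m))
        else:
            rep = members[0]
        groups.append(SpeciesGroup(members, rep))
    groups.sort(key=lambda g: g.members[0])
    return groups


# ---------------------------------------------------------------------------
# Alignments

@dataclass
class ConcatAlignment:
    """Column-wise concatenation of per-locus alignments.

    ``locus_spans`` maps locus name to its half-open column interval in
    the concatenated matrix; taxa missing a locus carry all-gap spans.
    """

    taxa: list[str]
    rows: dict[str, str]
    locus_spans: dict[str, tuple[int, int]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def trim_columns(alignment: dict[str, str], max_gap_fraction: float = 0.5) -> dict[str, str]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``."""
    if not alignment:
        return {}
    taxa = list(alignment)
    width = len(alignment[taxa[0]])
    for t in taxa:
        if len(alignment[t]) != width:
            raise ValueError(f"ragged alignment: row {t}")
    keep = []
    for col in range(width):
        gaps = sum(1 for t in taxa if alignment[t][col] == "-")
        if gaps / len(taxa) <= max_gap_fraction:
            keep.append(col)
    return {t: "".join(alignment[t][c] for c in keep) for t in taxa}


def build_concat(
    loci_alignments: dict[str, dict[str, str]],
    taxa: list[str] | None = None,
    trim_gap_fraction: float | None = 0.5,
) -> ConcatAlignment:
    """Concatenate per-locus alignments with gap-filling for missing taxa.

    Each locus is column-trimmed first (set ``trim_gap_fraction=None`` to
    skip). A taxon absent from a locus — e.g. an outgroup lacking some of
    the island genes — has that locus's span filled with gaps.
    """
    if taxa is None:
        taxa = sorted({t for aln in loci_alignments.values() for t in aln})
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for locus in loci_alignments:
        aln = loci_alignments[locus]
        if len(aln) != len(set(aln)):
            raise ValueError(f"taxon present twice in locus {locus}")
        if trim_gap_fraction is not None:
            aln = trim_columns(aln, trim_gap_fraction)
        widths = {len(s) for s in aln.values()}
        if len(widths) > 1:
            raise ValueError(f"locus {locus}: rows of unequal length")
        width = widths.pop() if widths else 0
        for t in taxa:
            parts[t].append(aln.get(t, "-" * width))
        spans[locus] = (offset, offset + width)
        offset += width
    return ConcatAlignment(taxa=list(taxa), rows={t: "".join(p) for t, p in parts.items()}, locus_spans=spans)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites, with pairwise deletion of gap sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences of unequal length")
    comparable = diff = 0
    for x, y in zip(seq_a, seq_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) sites between sequences")
    return diff / comparable


def distance_matrix(concat: ConcatAlignment) -> pd.DataFrame:
    ids = concat.taxa
    mat = pd.DataFrame(0.0, index=ids, columns=ids, dtype=float)
    for a, b in itertools.combinations(ids, 2):
        d = p_distance(concat.rows[a], concat.rows[b])
        mat.loc[a, b] = d
        mat.loc[b, a] = d
    return mat


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Classic neighbor joining with a deterministic tie rule.

    At each step the pair minimizing the Q-criterion is joined; exact ties
    break on the lexicographically smallest (name_i, name_j) pair.
    Negative branch lengths are clamped to zero. Returns an unrooted tree
    (dendropy tree with a trifurcating seed node for >= 3 taxa).
    """
    names = list(dist.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = {(a, b): float(dist.loc[a, b]) for a in names for b in names if a != b}
    newick_of = {n: n for n in names}
    active = sorted(names)
    counter = 0
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (r - 2) * d[(i, j)] - row_sum[i] - row_sum[j]
            key = (q, min(i, j), max(i, j))
            if best is None or key < best:
                best = key
                pair = (i, j)
        i, j = pair
        li = d[(i, j)] / 2 + (row_sum[i] - row_sum[j]) / (2 * (r - 2))
        lj = d[(i, j)] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"__node{counter}"
        counter += 1
        for k in active:
            if k in (i, j):
                continue
            dk = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
            d[(new, k)] = d[(k, new)] = max(dk, 0.0)
        newick_of[new] = f"({newick_of[i]}:{li:.10f},{newick_of[j]}:{lj:.10f})"
        active = sorted([k for k in active if k not in (i, j)] + [new])
    a, b, c = active
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({newick_of[a]}:{la:.10f},{newick_of[b]}:{lb:.10f},{newick_of[c]}:{lc:.10f});"
    )
    return dendropy.Tree.get(data=newick, schema="newick")


def build_tree(concat: ConcatAlignment, method: str = "nj") -> dendropy.Tree:
    """Build a distance tree from a concatenated alignment."""
    if method != "nj":
        raise ValueError(f"unknown method {method!r}")
    if len(concat.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    return neighbor_joining(distance_matrix(concat))


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    tree.to_outgroup_position(node, update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Robinson-Foulds congruence

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf-name sets.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first leaf is the canonical representative.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaves - below) if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalization by 2(n-3).

    Requires identical leaf sets; trees are compared as unrooted.
    """
    leaves_a = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    ba, bb = _bipartitions(tree_a), _bipartitions(tree_b)
    rf = len(ba ^ bb)
    n = len(leaves_a)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


# ---------------------------------------------------------------------------
# IO

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_alignment_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_alignment_fasta(alignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")
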