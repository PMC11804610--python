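"""Colocalization clustering of hit ORFs and island classification.

Hit ORFs on the same contig belong to one gene cluster when consecutive
hit ORFs are separated by at most ``max_gap`` intervening non-hit ORFs
(default 3); clusters never span contigs and strand is ignored. A cluster
is an *hgl* island when it carries homologs of at least 7 distinct panel
genes — counted irrespective of the number of ORFs encoding them (gene
fusions still contribute each constituent label) and of copy number — an
extended island at >= 10, and a *nif* island at >= 5 distinct nif labels.
Clusters whose distinct-gene set is exactly the canonical 7-gene set
{hgdC, hgdB, hglE_A, hglF, hglG, hglC, hglA} are the compact, highly
conserved "hgl-like" islands, checked before the generic 7-9 label.

Within a genome, islands are ranked by extension: rank 1 is the island
with the most distinct panel-gene homologs ("first" island), rank 2 the
next ("second"), with deterministic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core_io import GenomeRecord
from .homology import HitAssignment, HitTable

CANONICAL_HGL_LIKE = frozenset(
    {"hgdC", "hgdB", "hglE_A", "hglF", "hglG", "hglC", "hglA"}
)

ISLAND_CLASSES = ("hgl_extended", "hgl", "hgl_like", "nif", "none")


@dataclass(frozen=True)
class IslandConfig:
    max_gap: int = 3
    min_hgl_genes: int = 7
    min_extended_genes: int = 10
    min_nif_genes: int = 5
    hgl_like_set: frozenset[str] = CANONICAL_HGL_LIKE
    # allow +-N labels around the canonical set when classifying hgl_like
    hgl_like_tolerance: int = 0


@dataclass
class GeneCluster:
    genome_id: str
    contig_id: str
    member_orfs: list[str]
    assignments: list[HitAssignment]
    ordinal_span: tuple[int, int]
    span: tuple[int, int]
    is_plasmid: bool = False

    @property
    def distinct_genes(self) -> frozenset[str]:
        return frozenset(a.gene_label for a in self.assignments)

    @property
    def copy_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.assignments:
            counts[a.gene_label] = counts.get(a.gene_label, 0) + 1
        return counts

    @property
    def total_bit_score(self) -> float:
        return sum(a.bit_score for a in self.assignments)


@dataclass
class Island:
    cluster: GeneCluster
    island_class: str
    panel_id: str
    rank: int | None = None


def cluster_hits(
    hit_table: HitTable, genome: GenomeRecord, max_gap: int = 3
) -> list[GeneCluster]:
    """Group hit ORFs into maximal colocalized clusters.

    Clusters are the connected components of the relation "same contig and
    at most ``max_gap`` intervening ORFs between consecutive hit ORFs".
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    index = genome.orf_index()
    plasmids = {c.contig_id for c in genome.contigs if c.is_plasmid}
    by_orf: dict[str, list[HitAssignment]] = {}
    for a in hit_table.assignments:
        if a.orf_id not in index:
            raise ValueError(f"hit ORF {a.orf_id} absent from genome {genome.genome_id}")
        by_orf.setdefault(a.orf_id, []).append(a)

    by_contig: dict[str, list[str]] = {}
    for orf_id in by_orf:
        by_contig.setdefault(index[orf_id].contig_id, []).append(orf_id)

    clusters: list[GeneCluster] = []
    for contig_id in sorted(by_contig):
        orf_ids = sorted(by_contig[contig_id], key=lambda o: index[o].ordinal)
        run: list[str] = []
        for orf_id in orf_ids:
            if run and index[orf_id].ordinal - index[run[-1]].ordinal - 1 > max_gap:
                clusters.append(_make_cluster(hit_table.genome_id, contig_id, run, by_orf, index, plasmids))
                run = []
            run.append(orf_id)
        if run:
            clusters.append(_make_cluster(hit_table.genome_id, contig_id, run, by_orf, index, plasmids))
    return clusters


def _make_cluster(genome_id, contig_id, orf_ids, by_orf, index, plasmids) -> GeneCluster:
    assignments = [a for o in orf_ids for a in sorted(by_orf[o], key=lambda a: a.gene_label)]
    ordinals = [index[o].ordinal for o in orf_ids]
    starts = [index[o].start for o in orf_ids]
    ends = [index[o].end for o in orf_ids]
    return GeneCluster(
        genome_id=genome_id,
        contig_id=contig_id,
        member_orfs=list(orf_ids),
        assignments=assignments,
        ordinal_span=(min(ordinals), max(ordinals)),
        span=(min(starts), max(ends)),
        is_plasmid=contig_id in plasmids,
    )


def count_distinct_genes(cluster: GeneCluster) -> int:
    """Distinct panel-gene labels in a cluster.

    Copies of a gene on several ORFs count once; a fused ORF carrying two
    labels contributes both.
    """
    return len(cluster.distinct_genes)


def classify_island(
    cluster: GeneCluster, panel_id: str, config: IslandConfig | None = None
) -> Island:
    config = config or IslandConfig()
    n = count_distinct_genes(cluster)
    if panel_id == "hgl":
        genes = cluster.distinct_genes
        sym_diff = len(genes ^ config.hgl_like_set)
        if n >= config.min_hgl_genes and sym_diff <= config.hgl_like_tolerance:
            cls = "hgl_like"
        elif n >= config.min_extended_genes:
            cls = "hgl_extended"
        elif n >= config.min_hgl_genes:
            cls = "hgl"
        else:
            cls = "none"
    elif panel_id == "nif":
        cls = "nif" if n >= config.min_nif_genes else "none"
    else:
        raise ValueError(f"unknown panel {panel_id!r}")
    return Island(cluster=cluster, island_class=cls, panel_id=panel_id)


def rank_islands(islands: list[Island]) -> list[Island]:
    """Assign extension ranks within one genome and panel.

    Rank 1 is the island with the largest distinct-gene count. Ties break
    by higher summed bit score, then leftmost start, then contig id.
    Clusters classified ``none`` are left unranked.
    """
    ranked = [i for i in islands if i.island_class != "none"]
    ranked.sort(
        key=lambda i: (
            -count_distinct_genes(i.cluster),
            -i.cluster.total_bit_score,
            i.cluster.span[0],
            i.cluster.contig_id,
        )
    )
    out = []
    for rank, isl in enumerate(ranked, start=1):
        out.append(replace_rank(isl, rank))
    out.extend(replace_rank(i, None) for i in islands if i.island_class == "none")
    return out


def replace_rank(island: Island, rank: int | None) -> Island:
    return Island(island.cluster, island.island_class, island.panel_id, rank)


def detect_islands(
    hit_table: HitTable,
    genome: GenomeRecord,
    panel_id: str,
    config: IslandConfig | None = None,
) -> list[Island]:
    """Cluster, classify, and rank in one call."""
    config = config or IslandConfig()
    clusters = cluster_hits(hit_table, genome, config.max_gap)
    islands = [classify_island(c, panel_id, config) for c in clusters]
    return rank_islands(islands)
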