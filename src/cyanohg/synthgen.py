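"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its config (seed included) and
returns ground truth sufficient to score the downstream stage. Genomes
are synthetic proteomes: panel proteins are generated once per run,
planted homologs are panel sequences mutated to a requested percent
identity (uniform random substitutions, no indels by default), and decoy
ORFs are random proteins. Peak lists place one peak per structure-adduct
pair at the theoretical m/z under ppm-scale jitter with lognormal
intensity noise plus decoy peaks kept >= 25 ppm from any target. Loci
evolve by a Jukes-Cantor-style symmetric substitution process over the
20-letter amino-acid alphabet on a known tree, without indels, so columns
align trivially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .core_io import ContigInfo, GenomeRecord, MorphologyLabel, OrfRecord
from .islands import IslandConfig
from .lipids import ADDUCTS, HGStructure, Peak, PeakList, monoisotopic_mass, predict_targets

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_panel_proteins(
    labels: Sequence[str],
    rng: np.random.Generator,
    length_range: tuple[int, int] = (120, 260),
) -> dict[str, str]:
    """One random protein per panel label, lengths uniform in range."""
    return {
        label: _random_protein(rng, int(rng.integers(length_range[0], length_range[1] + 1)))
        for label in labels
    }


def mutate_to_identity(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute uniformly chosen positions until the target identity.

    No indels; the number of substituted positions is
    round((1 - identity) * len).
    """
    if not 0.3 < identity <= 1.0:
        raise ValueError("identity must be in (0.3, 1.0]")
    n_sub = round((1.0 - identity) * len(protein))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    seq = list(protein)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Genome simulation

@dataclass(frozen=True)
class PlantedIslandSpec:
    """One island to plant: which panel genes, at what identity."""

    gene_labels: tuple[str, ...]
    identity: float = 0.85
    # decoy ORFs inserted after the i-th island ORF (exercises the gap rule)
    gap_pattern: tuple[int, ...] = ()
    # label pairs fused onto a single ORF
    fusions: tuple[tuple[str, str], ...] = ()
    # labels planted on an extra ORF copy
    duplications: tuple[str, ...] = ()
    on_plasmid: bool = False
    panel_id: str = "hgl"


@dataclass
class GenomeSimConfig:
    seed: int
    n_genomes: int = 1
    decoy_count: int = 50
    decoy_length_range: tuple[int, int] = (80, 300)
    decoy_similarity_cap: float = 0.30
    panel_labels: tuple[str, ...] = ()
    panel_length_range: tuple[int, int] = (120, 260)
    # genome index -> islands to plant there; absent indices get decoys only
    planted: dict[int, list[PlantedIslandSpec]] = field(default_factory=dict)


@dataclass(frozen=True)
class PlantedIsland:
    genome_id: str
    contig_id: str
    start_ordinal: int
    end_ordinal: int
    gene_labels: frozenset[str]
    expected_class: str
    panel_id: str


@dataclass
class SimulatedGenomes:
    genomes: list[GenomeRecord]
    truth: list[PlantedIsland]
    panel_sequences: dict[str, str]


def _expected_class(labels: frozenset[str], panel_id: str, config: IslandConfig) -> str:
    from .islands import classify_island, GeneCluster
    from .homology import HitAssignment

    dummy = GeneCluster(
        genome_id="truth",
        contig_id="truth",
        member_orfs=[f"o{i}" for i in range(len(labels))],
        assignments=[
            HitAssignment(f"o{i}", lab, 100.0, 1e-30, 1.0, (0, 10))
            for i, lab in enumerate(sorted(labels))
        ],
        ordinal_span=(0, max(len(labels) - 1, 0)),
        span=(1, 10),
    )
    return classify_island(dummy, panel_id, config).island_class


def simulate_genomes(config: GenomeSimConfig) -> SimulatedGenomes:
    """Generate synthetic proteome genomes with planted islands.

    Raises if a requested planting identity does not exceed the decoy
    similarity cap (the ground truth would be ambiguous).
    """
    rng = np.random.default_rng(config.seed)
    panel = make_panel_proteins(config.panel_labels, rng, config.panel_length_range)
    island_config = IslandConfig()
    genomes = []
    truth = []
    for g in range(config.n_genomes):
        genome_id = f"genome_{g:03d}"
        specs = config.planted.get(g, [])
        for spec in specs:
            if spec.identity <= config.decoy_similarity_cap:
                raise ValueError(
                    f"planting identity {spec.identity} not above decoy cap "
                    f"{config.decoy_similarity_cap}: ground truth ambiguous"
                )
        # build the ORF protein sequence of the contig: decoys with islands
        # inserted as consecutive blocks at random, non-overlapping offsets
        decoys = [
            ("decoy", _random_protein(rng, int(rng.integers(*config.decoy_length_range))))
            for _ in range(config.decoy_count)
        ]
        blocks = []  # (orf_entries, spec) per island
        for spec in specs:
            entries = []  # (labels_on_orf, protein)
            fused = {lab for pair in spec.fusions for lab in pair}
            for pair in spec.fusions:
                proteins = [mutate_to_identity(panel[lab], spec.identity, rng) for lab in pair]
                entries.append((tuple(pair), "".join(proteins)))
            for lab in spec.gene_labels:
                if lab in fused:
                    continue
                entries.append(((lab,), mutate_to_identity(panel[lab], spec.identity, rng)))
            for lab in spec.duplications:
                entries.append(((lab,), mutate_to_identity(panel[lab], spec.identity, rng)))
            # interleave gap decoys per gap_pattern (between entries only,
            # so the recorded island span starts and ends on hit ORFs)
            with_gaps = []
            for i, entry in enumerate(entries):
                with_gaps.append(entry)
                n_gap = (
                    spec.gap_pattern[i]
                    if i < len(spec.gap_pattern) and i < len(entries) - 1
                    else 0
                )
                for _ in range(n_gap):
                    with_gaps.append(
                        (("decoy",), _random_protein(rng, int(rng.integers(*config.decoy_length_range))))
                    )
            blocks.append((with_gaps, spec))

        orf_entries: list[tuple[tuple[str, ...], str]] = [
            (("decoy",), prot) for _, prot in decoys
        ]
        # insert island blocks at random positions, never inside an
        # already-placed island block
        spans: list[tuple[int, int, PlantedIslandSpec]] = []
        for entries, spec in blocks:
            allowed = [
                p
                for p in range(len(orf_entries) + 1)
                if not any(s < p <= e for s, e, _ in spans)
            ]
            pos = allowed[int(rng.integers(len(allowed)))]
            orf_entries[pos:pos] = entries
            spans = [
                (s + len(entries), e + len(entries), sp) if s >= pos else (s, e, sp)
                for s, e, sp in spans
            ]
            spans.append((pos, pos + len(entries) - 1, spec))

        contig_main = "contig_1"
        orfs = []
        cursor = 1
        for ordinal, (labels, protein) in enumerate(orf_entries):
            length_nt = 3 * (len(protein) + 1)
            orfs.append(
                OrfRecord(
                    orf_id=f"{genome_id}_orf{ordinal:04d}",
                    contig_id=contig_main,
                    ordinal=ordinal,
                    start=cursor,
                    end=cursor + length_nt - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    protein=protein,
                )
            )
            cursor += length_nt + 100
        contigs = [ContigInfo(contig_main, cursor, any(sp.on_plasmid for sp in specs))]
        genomes.append(GenomeRecord(genome_id, contigs, orfs))
        for start, end, spec in spans:
            labels = frozenset(
                lab
                for i in range(start, end + 1)
                for lab in orf_entries[i][0]
                if lab != "decoy"
            )
            truth.append(
                PlantedIsland(
                    genome_id=genome_id,
                    contig_id=contig_main,
                    start_ordinal=start,
                    end_ordinal=end,
                    gene_labels=labels,
                    expected_class=_expected_class(labels, spec.panel_id, island_config),
                    panel_id=spec.panel_id,
                )
            )
    return SimulatedGenomes(genomes=genomes, truth=truth, panel_sequences=panel)


def simulate_morphology(
    sim: SimulatedGenomes, label_noise_rate: float, seed: int
) -> list[MorphologyLabel]:
    """Morphology labels correlated with planted island content.

    A genome is labeled heterocytous iff it carries a planted island of
    expected class hgl or hgl_extended (hgl_like-only genomes count as
    negatives); each label flips with the noise rate.
    """
    if not 0.0 <= label_noise_rate < 0.5:
        raise ValueError("label noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    positive_genomes = {
        t.genome_id for t in sim.truth if t.expected_class in ("hgl", "hgl_extended")
    }
    negatives = ["unicellular", "filamentous", "baeocytous"]
    labels = []
    for genome in sim.genomes:
        positive = genome.genome_id in positive_genomes
        if rng.random() < label_noise_rate:
            positive = not positive
        morphology = (
            "heterocytous" if positive else negatives[int(rng.integers(len(negatives)))]
        )
        labels.append(MorphologyLabel(genome.genome_id, morphology))
    return labels


# ---------------------------------------------------------------------------
# Peak-list simulation

@dataclass
class LipidSimConfig:
    seed: int
    composition: dict[HGStructure, float] = field(default_factory=dict)
    ppm_jitter: float = 1.0  # sd of the m/z error, in ppm
    intensity_cv: float = 0.1  # lognormal coefficient of variation
    n_decoy_peaks: int = 20
    decoy_min_ppm: float = 25.0
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+")
    strain_id: str = "sim_strain"
    base_intensity: float = 1e6
    # relative response per adduct (second adducts are usually weaker)
    adduct_response: tuple[float, ...] = (1.0, 0.4)


@dataclass
class LipidTruth:
    nominal_shares: dict[HGStructure, float]
    realized_shares: dict[HGStructure, float]


def simulate_peaklist(config: LipidSimConfig) -> tuple[PeakList, LipidTruth]:
    """Generate a peak list from a ground-truth HG composition.

    Every structure-adduct pair yields one precursor peak at the
    theoretical m/z times (1 + eps), eps ~ Normal(0, ppm_jitter * 1e-6),
    with intensity proportional to the composition weight under lognormal
    noise, plus MS2 fragment entries. ``realized_shares`` records the
    per-structure share of total emitted precursor intensity, i.e. the
    composition actually present in the generated data.
    """
    if not config.composition:
        raise ValueError("empty composition")
    if any(w <= 0 for w in config.composition.values()):
        raise ValueError("composition weights must be > 0")
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.intensity_cv**2))
    total_w = sum(config.composition.values())
    peaks = []
    realized: dict[HGStructure, float] = {}
    target_mzs = []
    for structure in config.composition:
        weight = config.composition[structure] / total_w
        for i, target in enumerate(predict_targets(structure, config.adducts)):
            response = (
                config.adduct_response[i] if i < len(config.adduct_response) else 0.2
            )
            eps = rng.normal(0.0, config.ppm_jitter * 1e-6)
            mz = target.mz * (1.0 + eps)
            noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            intensity = config.base_intensity * weight * response * noise
            ms2 = tuple(
                frag * (1.0 + rng.normal(0.0, config.ppm_jitter * 1e-6))
                for frag in target.fragments
            )
            rt = float(rng.uniform(60.0, 1500.0))
            peaks.append(Peak(mz, rt, intensity, ms2))
            realized[structure] = realized.get(structure, 0.0) + intensity
            target_mzs.append(target.mz)
    target_arr = np.array(target_mzs)
    lo, hi = float(target_arr.min()) * 0.9, float(target_arr.max()) * 1.1
    n_placed = 0
    while n_placed < config.n_decoy_peaks:
        mz = float(rng.uniform(lo, hi))
        if np.min(np.abs(mz - target_arr) / target_arr) * 1e6 < config.decoy_min_ppm:
            continue
        peaks.append(
            Peak(mz, float(rng.uniform(60.0, 1500.0)), float(rng.uniform(1e3, 1e5)), ())
        )
        n_placed += 1
    total_realized = sum(realized.values())
    truth = LipidTruth(
        nominal_shares={s: w / total_w for s, w in config.composition.items()},
        realized_shares={s: v / total_realized for s, v in realized.items()},
    )
    return PeakList(config.strain_id, peaks), truth


# ---------------------------------------------------------------------------
# Loci simulation on a tree

@dataclass
class PhyloSimConfig:
    seed: int
    newick: str | None = None  # user tree; None -> random topology
    n_taxa: int = 8
    n_loci: int = 1
    sites_per_locus: int = 1000
    rate: float = 1.0  # scales branch lengths (substitutions/site)
    branch_length_range: tuple[float, float] = (0.02, 0.15)
    missing_taxon_rate: float = 0.0  # per locus, exercises gap filling


def random_tree(
    n_taxa: int, rng: np.random.Generator, branch_length_range: tuple[float, float]
) -> dendropy.Tree:
    """Random binary topology by sequential joining, U(range) edge lengths."""
    lo, hi = branch_length_range

    def bl() -> str:
        return f"{rng.uniform(lo, hi):.6f}"

    nodes = [f"T{i}:{bl()}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    return dendropy.Tree.get(data=newick, schema="newick")


def _evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 20-state substitution along a branch of length t.

    Substitution events are Poisson(t) per site; each event replaces the
    residue with a uniform draw from the other 19. The per-site
    probability of ending in a different state after k events is
    (19/20)(1 - (-1/19)^k).
    """
    k = rng.poisson(t, size=parent.size)
    stay = 1.0 / 20.0 + (19.0 / 20.0) * (-1.0 / 19.0) ** k
    change = rng.random(parent.size) >= stay
    child = parent.copy()
    offsets = rng.integers(1, 20, size=int(change.sum()))
    child[change] = (child[change] + offsets) % 20
    return child


def expected_p_distance(path_length: float) -> float:
    """Closed-form expected p-distance for the 20-state model."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * path_length / 19.0))


def simulate_loci(config: PhyloSimConfig) -> tuple[dendropy.Tree, dict[str, dict[str, str]]]:
    """Evolve per-locus alignments on a known tree (no indels).

    Returns the true tree and {locus: {taxon: sequence}}; with
    ``missing_taxon_rate`` > 0 a taxon may be absent from a locus, which
    downstream concatenation fills with gaps.
    """
    if config.rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(config.seed)
    if config.newick is not None:
        tree = dendropy.Tree.get(data=config.newick, schema="newick")
    else:
        tree = random_tree(config.n_taxa, rng, config.branch_length_range)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    loci: dict[str, dict[str, str]] = {}
    for locus_i in range(config.n_loci):
        root_seq = rng.integers(0, 20, size=config.sites_per_locus)
        states: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
        alignment: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            t = (node.edge.length or 0.0) * config.rate
            child = _evolve(states[id(node.parent_node)], t, rng)
            states[id(node)] = child
            if node.is_leaf():
                alignment[node.taxon.label] = aa[child].tobytes().decode()
        if config.missing_taxon_rate > 0:
            keep = {
                taxon: seq
                for taxon, seq in alignment.items()
                if rng.random() >= config.missing_taxon_rate
            }
            # never drop below 3 taxa
            alignment = keep if len(keep) >= 3 else alignment
        loci[f"locus_{locus_i:02d}"] = alignment
    return tree, loci


def simulate_genome_pair(
    length: int, substitution_rate: float, seed: int
) -> tuple[str, str]:
    """Nucleotide genome pair differing by i.i.d. substitutions (no indels).

    Expected ANI is 100 * (1 - substitution_rate).
    """
    rng = np.random.default_rng(seed)
    nt = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    a = rng.integers(0, 4, size=length)
    flip = rng.random(length) < substitution_rate
    offsets = rng.integers(1, 4, size=int(flip.sum()))
    b = a.copy()
    b[flip] = (b[flip] + offsets) % 4
    return nt[a].tobytes().decode(), nt[b].tobytes().decode()
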