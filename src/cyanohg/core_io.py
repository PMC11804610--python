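"""Domain types and file I/O shared by every pipeline stage.

Genomes enter as nucleotide FASTA plus a GFF3 of CDS features, or as a
simplified tabular dialect that already carries translated proteins
(convenient for simulated data, which then needs no FASTA round trip).
Coordinates in files are 1-based inclusive (GFF convention); all
clustering arithmetic downstream operates on ORF *ordinals* (0-based rank
along the contig by start coordinate), so the base-pair convention never
affects island detection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

MORPHOLOGIES = frozenset(
    {"unicellular", "baeocytous", "filamentous", "heterocytous", "ramified", "unknown"}
)

TABULAR_COLUMNS = ("genome_id", "contig_id", "orf_id", "start", "end", "strand", "protein")


@dataclass(frozen=True)
class OrfRecord:
    """One annotated ORF with its translated protein.

    ``ordinal`` is the 0-based rank of the ORF along its contig by start
    coordinate; it is the unit in which island gap rules are expressed.
    """

    orf_id: str
    contig_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ORF {self.orf_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.orf_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"ORF {self.orf_id}: empty protein")


@dataclass(frozen=True)
class ContigInfo:
    contig_id: str
    length: int
    is_plasmid: bool = False


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[ContigInfo]
    orfs: list[OrfRecord]

    def __post_init__(self) -> None:
        known = {c.contig_id: c.length for c in self.contigs}
        for orf in self.orfs:
            if orf.contig_id not in known:
                raise ValueError(f"ORF {orf.orf_id} on unknown contig {orf.contig_id}")
            if orf.end > known[orf.contig_id]:
                raise ValueError(
                    f"ORF {orf.orf_id} end {orf.end} exceeds contig "
                    f"{orf.contig_id} length {known[orf.contig_id]}"
                )

    def orfs_by_contig(self, contig_id: str) -> list[OrfRecord]:
        return sorted(
            (o for o in self.orfs if o.contig_id == contig_id), key=lambda o: o.ordinal
        )

    def orf_index(self) -> dict[str, OrfRecord]:
        return {o.orf_id: o for o in self.orfs}


@dataclass(frozen=True)
class PanelGene:
    gene_label: str
    sequence: str | None
    essential: bool


@dataclass
class QueryPanel:
    """Ordered query-gene panel (the hgl or nif reference gene set)."""

    panel_id: str
    genes: list[PanelGene]
    expected_size: int

    def __post_init__(self) -> None:
        labels = [g.gene_label for g in self.genes]
        if len(labels) != len(set(labels)):
            raise ValueError(f"panel {self.panel_id}: duplicate gene labels")

    @property
    def labels(self) -> list[str]:
        return [g.gene_label for g in self.genes]

    def with_sequences(self, sequences: dict[str, str]) -> "QueryPanel":
        genes = [
            PanelGene(g.gene_label, sequences[g.gene_label], g.essential)
            for g in self.genes
        ]
        return QueryPanel(self.panel_id, genes, self.expected_size)


@dataclass(frozen=True)
class MorphologyLabel:
    genome_id: str
    morphology: str

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")


def _assign_ordinals(orf_rows: list[dict]) -> list[OrfRecord]:
    """Sort per contig by (start, end, orf_id) and assign ordinals."""
    by_contig: dict[str, list[dict]] = {}
    for row in orf_rows:
        by_contig.setdefault(row["contig_id"], []).append(row)
    records: list[OrfRecord] = []
    for contig_id in sorted(by_contig):
        rows = sorted(by_contig[contig_id], key=lambda r: (r["start"], r["end"], r["orf_id"]))
        for ordinal, row in enumerate(rows):
            records.append(
                OrfRecord(
                    orf_id=row["orf_id"],
                    contig_id=contig_id,
                    ordinal=ordinal,
                    start=row["start"],
                    end=row["end"],
                    strand=row["strand"],
                    protein=row["protein"],
                )
            )
    return records


def _translate_cds(nt: str, strand: str) -> str:
    seq = Seq(nt)
    if strand == "-":
        seq = seq.reverse_complement()
    protein = str(seq.translate(table=11))
    return protein.rstrip("*")


def _parse_gff3_cds(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            orf_id = attrs.get("ID") or attrs.get("Name")
            if orf_id is None:
                raise ValueError(f"CDS feature without ID attribute: {line!r}")
            rows.append(
                {
                    "contig_id": parts[0],
                    "orf_id": orf_id,
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "protein": attrs.get("translation", ""),
                }
            )
    return rows


def read_genome(
    fasta_path: str | Path | None,
    annotation_path: str | Path,
    genome_id: str | None = None,
    plasmid_contigs: Iterable[str] = (),
) -> GenomeRecord:
    """Read a genome from FASTA + GFF3, or from the tabular dialect.

    When ``annotation_path`` ends in .gff/.gff3, CDS features are taken
    from it; proteins missing a ``translation`` attribute are translated
    from the FASTA using the bacterial code (table 11), reverse-complement
    first for minus-strand features. Otherwise the annotation is read as
    the tabular dialect (``genome_id contig_id orf_id start end strand
    protein``) and ``fasta_path`` may be None.
    """
    annotation_path = Path(annotation_path)
    plasmids = set(plasmid_contigs)
    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        if fasta_path is None:
            raise ValueError("GFF3 annotation requires a nucleotide FASTA")
        contig_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        rows = _parse_gff3_cds(annotation_path)
        seen: set[str] = set()
        for row in rows:
            if row["orf_id"] in seen:
                raise ValueError(f"duplicate CDS ID {row['orf_id']}")
            seen.add(row["orf_id"])
            contig = contig_seqs.get(row["contig_id"])
            if contig is None:
                raise ValueError(f"CDS {row['orf_id']} on contig absent from FASTA")
            if row["end"] > len(contig):
                raise ValueError(
                    f"CDS {row['orf_id']} end {row['end']} exceeds contig "
                    f"{row['contig_id']} length {len(contig)}"
                )
            if not row["protein"]:
                nt = contig[row["start"] - 1 : row["end"]]
                row["protein"] = _translate_cds(nt, row["strand"])
        contigs = [
            ContigInfo(cid, len(seq), cid in plasmids) for cid, seq in contig_seqs.items()
        ]
        gid = genome_id or annotation_path.stem
        return GenomeRecord(gid, contigs, _assign_ordinals(rows))
    return read_tabular_genome(annotation_path, plasmid_contigs=plasmids)


def read_tabular_genome(
    path: str | Path, plasmid_contigs: Iterable[str] = ()
) -> GenomeRecord:
    """Read the simplified tabular annotation dialect (TSV with header)."""
    plasmids = set(plasmid_contigs)
    rows = []
    genome_ids = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            genome_ids.add(rec["genome_id"])
            rows.append(
                {
                    "contig_id": rec["contig_id"],
                    "orf_id": rec["orf_id"],
                    "start": int(rec["start"]),
                    "end": int(rec["end"]),
                    "strand": rec["strand"],
                    "protein": rec["protein"],
                }
            )
            if rec.get("is_plasmid", "").lower() in ("1", "true", "yes"):
                plasmids.add(rec["contig_id"])
    if len(genome_ids) != 1:
        raise ValueError(f"tabular annotation must describe one genome, got {genome_ids}")
    seen: set[str] = set()
    for row in rows:
        if row["orf_id"] in seen:
            raise ValueError(f"duplicate ORF ID {row['orf_id']}")
        seen.add(row["orf_id"])
    contig_len = {}
    for row in rows:
        contig_len[row["contig_id"]] = max(contig_len.get(row["contig_id"], 0), row["end"])
    contigs = [ContigInfo(cid, ln, cid in plasmids) for cid, ln in sorted(contig_len.items())]
    return GenomeRecord(genome_ids.pop(), contigs, _assign_ordinals(rows))


def write_tabular_genome(genome: GenomeRecord, path: str | Path) -> None:
    plasmids = {c.contig_id for c in genome.contigs if c.is_plasmid}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABULAR_COLUMNS + ("is_plasmid",))
        for orf in sorted(genome.orfs, key=lambda o: (o.contig_id, o.ordinal)):
            writer.writerow(
                [
                    genome.genome_id,
                    orf.contig_id,
                    orf.orf_id,
                    orf.start,
                    orf.end,
                    orf.strand,
                    orf.protein,
                    "true" if orf.contig_id in plasmids else "false",
                ]
            )


def read_morphology_labels(path: str | Path) -> list[MorphologyLabel]:
    labels = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            labels.append(MorphologyLabel(rec["genome_id"], rec["morphology"]))
    return labels


def write_morphology_labels(labels: Sequence[MorphologyLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "morphology"])
        for lab in labels:
            writer.writerow([lab.genome_id, lab.morphology])


def load_panel(panel_id: str, sequences: dict[str, str] | None = None) -> QueryPanel:
    """Load a packaged panel definition (``hgl`` or ``nif``).

    The definition file carries gene labels and essentiality flags only;
    protein sequences are user- or generator-supplied, keyed by label.
    """
    expected = {"hgl": 19, "nif": 14}
    if panel_id not in expected:
        raise ValueError(f"unknown panel {panel_id!r}")
    text = resources.files("cyanohg.data").joinpath(f"{panel_id}_panel.tsv").read_text()
    genes = []
    for rec in csv.DictReader(text.splitlines(), delimiter="\t"):
        seq = sequences.get(rec["gene_label"]) if sequences else None
        genes.append(
            PanelGene(rec["gene_label"], seq, rec["essential"].lower() == "true")
        )
    panel = QueryPanel(panel_id, genes, expected[panel_id])
    if len(panel.genes) != panel.expected_size:
        raise ValueError(
            f"panel {panel_id} definition has {len(panel.genes)} genes, "
            f"expected {panel.expected_size}"
        )
    return panel


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


ISLAND_REPORT_COLUMNS = (
    "genome_id",
    "contig_id",
    "rank",
    "island_class",
    "distinct_gene_count",
    "gene_list",
    "orf_span",
    "start",
    "end",
    "is_plasmid",
)


def write_island_report(islands, path: str | Path, gff_path: str | Path | None = None) -> None:
    """Write the island report TSV plus a companion GFF3 of island intervals.

    One row per island: genome, contig, rank, class, distinct-gene count,
    gene list, ORF-ordinal span, bp interval, plasmid flag.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ISLAND_REPORT_COLUMNS)
        for isl in islands:
            cl = isl.cluster
            writer.writerow(
                [
                    cl.genome_id,
                    cl.contig_id,
                    isl.rank if isl.rank is not None else "",
                    isl.island_class,
                    len(cl.distinct_genes),
                    ",".join(sorted(cl.distinct_genes)),
                    f"{cl.ordinal_span[0]}-{cl.ordinal_span[1]}",
                    cl.span[0],
                    cl.span[1],
                    "true" if cl.is_plasmid else "false",
                ]
            )
    if gff_path is None:
        gff_path = path.with_suffix(".gff3")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, isl in enumerate(islands, 1):
            cl = isl.cluster
            attrs = (
                f"ID=island_{i};island_class={isl.island_class};"
                f"distinct_genes={len(cl.distinct_genes)};panel={isl.panel_id}"
            )
            fh.write(
                "\t".join(
                    [
                        cl.contig_id,
                        "cyanohg",
                        "genomic_island",
                        str(cl.span[0]),
                        str(cl.span[1]),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_island_gff(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read back island intervals: (contig, start, end, island_class)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            out.append((parts[0], int(parts[3]), int(parts[4]), attrs.get("island_class", "")))
    return out
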