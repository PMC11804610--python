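"""Protein-similarity search assigning query-panel gene labels to ORFs.

The backend is a local Smith-Waterman alignment (Bio.Align.PairwiseAligner)
scored with BLOSUM62 and BLAST-style affine gaps (a gap of length g costs
11 + g). Raw scores are converted to bit scores with fixed Karlin-Altschul
parameters for that scoring scheme (gapped lambda = 0.267, K = 0.041) and
E-values are computed against a configurable database size, by default the
total residue count of the scanned proteome. Hit tables produced by an
external search program can be imported from TSV and pass the same
validation, so the built-in aligner is replaceable.

One ORF may carry several gene labels when distinct, largely
non-overlapping aligned intervals each qualify — this keeps gene fusions
countable as their constituent genes. Interval selection runs before
threshold filtering so that tightening any threshold can only remove
assignments (monotonicity).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GenomeRecord, QueryPanel

GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Hits below this bit score are never materialized during a scan (the
# spurious-similarity regime for random proteins); the effective candidate
# floor is min(this, thresholds.min_bit_score) so lower user thresholds
# still work. Acceptance of a hit depends only on stronger hits, which
# keeps assignment counts monotone in every threshold.
SELECTION_MIN_BITS = 25.0


@dataclass(frozen=True)
class HitAssignment:
    """A query-gene label attached to one ORF, with alignment evidence.

    ``aligned_interval_on_orf`` is a 0-based half-open amino-acid interval
    on the ORF protein.
    """

    orf_id: str
    gene_label: str
    bit_score: float
    e_value: float
    query_coverage: float
    aligned_interval_on_orf: tuple[int, int]

    def __post_init__(self) -> None:
        if self.bit_score <= 0:
            raise ValueError("bit_score must be > 0")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class Thresholds:
    min_bit_score: float = 50.0
    max_e_value: float = 1e-5
    min_coverage: float = 0.3

    def passes(self, hit: HitAssignment) -> bool:
        return (
            hit.bit_score >= self.min_bit_score
            and hit.e_value <= self.max_e_value
            and hit.query_coverage >= self.min_coverage
        )


@dataclass
class HitTable:
    genome_id: str
    assignments: list[HitAssignment]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        for hit in self.assignments:
            if not self.thresholds.passes(hit):
                raise ValueError(
                    f"assignment {hit.orf_id}/{hit.gene_label} fails the recorded thresholds"
                )


def _make_aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(matrix_name)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        x = matrix.alphabet.index("X")
        matrix[x, :] = 0.0
        matrix[:, x] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: gap of length g costs open + g*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER: Align.PairwiseAligner | None = None


def _default_aligner() -> Align.PairwiseAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = _make_aligner(11.0, 1.0, "BLOSUM62")
    return _DEFAULT_ALIGNER


def bit_score(raw_score: float, lam: float = GAPPED_BLOSUM62_LAMBDA, k: float = GAPPED_BLOSUM62_K) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def e_value(bits: float, query_len: int, db_size: int) -> float:
    return query_len * db_size * 2.0 ** (-bits)


def align_pair(
    query: str,
    target: str,
    aligner: Align.PairwiseAligner | None = None,
    db_size: int | None = None,
) -> tuple[float, float, float, tuple[int, int]]:
    """Locally align a query-panel protein to an ORF protein.

    Returns (bit_score, e_value, query_coverage, interval_on_target); the
    interval is 0-based half-open in target amino acids. ``db_size``
    defaults to the target length (single-sequence search).
    """
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = aligner or _default_aligner()
    raw = aligner.score(query, target)
    if raw <= 0:
        return 0.0, math.inf, 0.0, (0, 0)
    aln = next(iter(aligner.align(query, target)))
    # aligned[0] holds blocks on the first align() argument (the query),
    # aligned[1] blocks on the second (the target ORF protein).
    qstart, qend = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    tstart, tend = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    coverage = (qend - qstart) / len(query)
    bits = bit_score(raw)
    ev = e_value(bits, len(query), db_size if db_size is not None else len(target))
    return bits, ev, coverage, (tstart, tend)


def _best_hits_per_gene(
    orf_id: str,
    protein: str,
    panel: QueryPanel,
    aligner: Align.PairwiseAligner,
    db_size: int,
    min_bits: float = SELECTION_MIN_BITS,
) -> list[HitAssignment]:
    hits = []
    for gene in panel.genes:
        if gene.sequence is None:
            raise ValueError(f"panel gene {gene.gene_label} has no sequence")
        # score-only pass first; the alignment path is only computed for
        # hits above the candidate floor
        raw = aligner.score(gene.sequence, protein)
        if raw <= 0 or bit_score(raw) < min_bits:
            continue
        bits, ev, cov, interval = align_pair(gene.sequence, protein, aligner, db_size)
        if bits <= 0 or interval[1] <= interval[0]:
            continue
        hits.append(
            HitAssignment(orf_id, gene.gene_label, bits, ev, cov, interval)
        )
    return hits


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def select_fusion_intervals(
    hits: Sequence[HitAssignment], max_overlap_fraction: float = 0.25
) -> list[HitAssignment]:
    """Greedy interval selection supporting fused ORFs.

    Hits are taken best-first; a further gene label is accepted on the same
    ORF only if its aligned interval overlaps every previously accepted
    interval by less than ``max_overlap_fraction`` of its own length.
    """
    accepted: list[HitAssignment] = []
    for hit in sorted(hits, key=lambda h: (-h.bit_score, h.gene_label)):
        length = hit.aligned_interval_on_orf[1] - hit.aligned_interval_on_orf[0]
        if length <= 0:
            continue
        ok = all(
            _overlap(hit.aligned_interval_on_orf, acc.aligned_interval_on_orf)
            < max_overlap_fraction * length
            for acc in accepted
        )
        if ok:
            accepted.append(hit)
    return accepted


def scan_genome(
    genome: GenomeRecord,
    panel: QueryPanel,
    thresholds: Thresholds | None = None,
    db_size: int | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> HitTable:
    """Query every ORF protein of a genome against a panel.

    For each ORF, the best hit per gene is kept, fusion-aware interval
    selection is applied, and the configured thresholds are enforced last.
    """
    thresholds = thresholds or Thresholds()
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    valid = set(AMINO_ACIDS) | {"X", "*", "B", "Z", "U"}
    if db_size is None:
        db_size = sum(len(o.protein) for o in genome.orfs)
    assignments: list[HitAssignment] = []
    for orf in genome.orfs:
        if not set(orf.protein) <= valid:
            bad = sorted(set(orf.protein) - valid)
            raise ValueError(f"ORF {orf.orf_id}: non-amino-acid characters {bad}")
        floor = min(SELECTION_MIN_BITS, thresholds.min_bit_score)
        hits = _best_hits_per_gene(orf.orf_id, orf.protein, panel, aligner, db_size, floor)
        for hit in select_fusion_intervals(hits):
            if thresholds.passes(hit):
                assignments.append(hit)
    return HitTable(genome.genome_id, assignments, thresholds)


HIT_TABLE_COLUMNS = (
    "orf_id",
    "gene_label",
    "bit_score",
    "e_value",
    "query_coverage",
    "interval_start",
    "interval_end",
)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                f"#genome_id={table.genome_id}",
                f"min_bit_score={table.thresholds.min_bit_score}",
                f"max_e_value={table.thresholds.max_e_value}",
                f"min_coverage={table.thresholds.min_coverage}",
            ]
        )
        writer.writerow(HIT_TABLE_COLUMNS)
        for hit in table.assignments:
            writer.writerow(
                [
                    hit.orf_id,
                    hit.gene_label,
                    f"{hit.bit_score:.4f}",
                    f"{hit.e_value:.6g}",
                    f"{hit.query_coverage:.6f}",
                    hit.aligned_interval_on_orf[0],
                    hit.aligned_interval_on_orf[1],
                ]
            )


def read_hit_table(path: str | Path) -> HitTable:
    """Import a hit table, e.g. from an external homology search."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta = dict(kv.split("=", 1) for kv in header if "=" in kv)
        genome_id = meta.get("#genome_id", "unknown")
        thresholds = Thresholds(
            float(meta.get("min_bit_score", 50.0)),
            float(meta.get("max_e_value", 1e-5)),
            float(meta.get("min_coverage", 0.3)),
        )
        reader = csv.DictReader(fh, delimiter="\t")
        assignments = [
            HitAssignment(
                rec["orf_id"],
                rec["gene_label"],
                float(rec["bit_score"]),
                float(rec["e_value"]),
                float(rec["query_coverage"]),
                (int(rec["interval_start"]), int(rec["interval_end"])),
            )
            for rec in reader
        ]
    return HitTable(genome_id, assignments, thresholds)
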