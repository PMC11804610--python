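"""Genome-level calls and the morphology benchmark.

Heterocyte capability is inferred from island content: by default a
genome is called capable when it carries an hgl or hgl_extended island.
Compact hgl-like islands are excluded from the default predictor — they
occur as the only island in strains that have lost heterocyte formation,
so counting them would produce false positives (configurable). An
alternative predictor additionally requires a nif island, reflecting the
genomic co-occurrence of the two heterocyte processes (HG biosynthesis
and nitrogen fixation).

The benchmark scores calls against observed morphology; heterocytous and
ramified strains form the positive class (ramified strains carry
heterocytes in their trichomes), and genomes of unknown morphology are
excluded.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core_io import MorphologyLabel
from .islands import Island

POSITIVE_MORPHOLOGIES = frozenset({"heterocytous", "ramified"})
PREDICTOR_MODES = ("hgl", "hgl_and_nif")


@dataclass(frozen=True)
class GenomeCall:
    genome_id: str
    has_hgl: bool
    has_hgl_like: bool
    has_nif: bool
    n_islands: int
    heterocyte_capable: bool

    def __post_init__(self) -> None:
        if self.heterocyte_capable and not self.has_hgl:
            raise ValueError("heterocyte_capable requires has_hgl")
        if self.n_islands < int(self.has_hgl):
            raise ValueError("n_islands inconsistent with has_hgl")


def call_genome(
    genome_id: str,
    islands: Sequence[Island],
    predictor_mode: str = "hgl",
    include_hgl_like: bool = False,
) -> GenomeCall:
    """Derive genome-level presence calls from classified islands.

    ``islands`` may mix the hgl- and nif-panel results of one genome.
    """
    if predictor_mode not in PREDICTOR_MODES:
        raise ValueError(f"unknown predictor mode {predictor_mode!r}")
    classes = [i.island_class for i in islands if i.island_class != "none"]
    has_extended_or_hgl = any(c in ("hgl", "hgl_extended") for c in classes)
    has_hgl_like = any(c == "hgl_like" for c in classes)
    has_hgl = has_extended_or_hgl or has_hgl_like
    has_nif = any(c == "nif" for c in classes)
    capable = has_extended_or_hgl or (include_hgl_like and has_hgl_like)
    if predictor_mode == "hgl_and_nif":
        capable = capable and has_nif
    return GenomeCall(
        genome_id=genome_id,
        has_hgl=has_hgl,
        has_hgl_like=has_hgl_like,
        has_nif=has_nif,
        n_islands=len(classes),
        heterocyte_capable=capable,
    )


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    tn: int
    discordant: list[tuple[str, bool, bool]]  # (genome_id, called, labeled)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def benchmark_morphology(
    calls: Iterable[GenomeCall], labels: Iterable[MorphologyLabel]
) -> BenchmarkResult:
    """Score heterocyte-capability calls against observed morphology."""
    call_map = {c.genome_id: c for c in calls}
    tp = fp = fn = tn = 0
    discordant = []
    seen = 0
    for label in labels:
        if label.morphology == "unknown":
            continue
        call = call_map.get(label.genome_id)
        if call is None:
            warnings.warn(f"morphology label for unknown genome {label.genome_id}; skipped")
            continue
        seen += 1
        positive = label.morphology in POSITIVE_MORPHOLOGIES
        if call.heterocyte_capable and positive:
            tp += 1
        elif call.heterocyte_capable and not positive:
            fp += 1
            discordant.append((label.genome_id, True, False))
        elif not call.heterocyte_capable and positive:
            fn += 1
            discordant.append((label.genome_id, False, True))
        else:
            tn += 1
    if seen == 0:
        raise ValueError("no labeled genomes to benchmark")
    return BenchmarkResult(tp, fp, fn, tn, discordant)


CALLS_COLUMNS = ("genome_id", "has_hgl", "has_hgl_like", "has_nif", "n_islands", "heterocyte_capable")


def write_calls(calls: Sequence[GenomeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALLS_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.genome_id,
                    str(c.has_hgl).lower(),
                    str(c.has_hgl_like).lower(),
                    str(c.has_nif).lower(),
                    c.n_islands,
                    str(c.heterocyte_capable).lower(),
                ]
            )


def write_benchmark(result: BenchmarkResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "value"])
        writer.writerow(["tp", result.tp])
        writer.writerow(["fp", result.fp])
        writer.writerow(["fn", result.fn])
        writer.writerow(["tn", result.tn])
        writer.writerow(["sensitivity", f"{result.sensitivity:.6f}"])
        writer.writerow(["specificity", f"{result.specificity:.6f}"])
        writer.writerow(["accuracy", f"{result.accuracy:.6f}"])
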