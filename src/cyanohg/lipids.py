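"""Heterocyte glycolipid (HG) structure enumeration and mass screening.

An HG is modeled as a long-chain alkyl backbone (C24-C32) glycosidically
bound at C1 to a sugar headgroup, with additional hydroxyl and keto
groups on the chain. Positions of the functional groups do not change the
molecular formula and are not modeled; a functionalization pattern is the
pair (n_hydroxyl, n_keto) where n_hydroxyl counts free hydroxyls
*excluding* the C1 oxygen (which always carries the headgroup, or a free
OH in the aglycone). Pattern labels follow the parent-chain nomenclature
of the field, which counts the C1 hydroxyl: "diol" therefore means one
free chain hydroxyl beside C1, "keto-ol" one keto group and no free
hydroxyl, and so on. The total functional-group count (C1 included) is
constrained to 1-4.

Molecular formula bookkeeping: alkane C_nH_{2n+2}, plus one oxygen for
the C1 position, plus O per hydroxyl, plus (O, -2H) per keto group, plus
(free sugar - H2O) per glycosidic residue. Monoisotopic masses use IUPAC
atomic masses embedded as constants.

Screening is targeted: theoretical precursor m/z values per adduct, with
diagnostic fragments from neutral loss of each sugar residue and
successive water losses, matched against a peak list within a ppm
tolerance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}
PROTON_MASS = 1.007276466
WATER = {"H": 2, "O": 1}

# free-sugar element counts; each glycosidic bond condenses out one water
SUGAR_FORMULAS: dict[str, dict[str, int]] = {
    "hexose": {"C": 6, "H": 12, "O": 6},
    "pentose": {"C": 5, "H": 10, "O": 5},
    "methylhexose": {"C": 7, "H": 14, "O": 6},
    "deoxyhexose": {"C": 6, "H": 12, "O": 5},
    # undetermined C6 sugar: hexose isomer — same formula, distinct name
    "hexose_isomer": {"C": 6, "H": 12, "O": 6},
}

# label -> (n_hydroxyl excluding C1, n_keto); labels name the parent chain
PATTERN_LABELS: dict[str, tuple[int, int]] = {
    "ol": (0, 0),
    "diol": (1, 0),
    "keto-ol": (0, 1),
    "triol": (2, 0),
    "keto-diol": (1, 1),
    "diketo-ol": (0, 2),
    "tetraol": (3, 0),
    "keto-triol": (2, 1),
    "diketo-diol": (1, 2),
    "triketo-ol": (0, 3),
}

DEFAULT_ADDUCTS_POSITIVE = ("[M+H]+", "[M+Na]+")
DEFAULT_ADDUCTS_NEGATIVE = ("[M-H]-",)
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (PROTON_MASS, "positive"),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - 0.000548579909, "positive"),
    "[M-H]-": (-PROTON_MASS, "negative"),
}


@dataclass(frozen=True)
class Headgroup:
    """Sugar headgroup; ``none`` marks the aglycone (AG)."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in SUGAR_FORMULAS and self.name not in ("none", "dipentose"):
            raise ValueError(f"unknown headgroup {self.name!r}")

    @property
    def residues(self) -> list[str]:
        if self.name == "none":
            return []
        if self.name == "dipentose":
            return ["pentose", "pentose"]
        return [self.name]


@dataclass(frozen=True)
class ChainSpec:
    carbon_count: int

    def __post_init__(self) -> None:
        if not 24 <= self.carbon_count <= 32:
            raise ValueError("chain length must be 24-32 carbons")

    @property
    def parity(self) -> str:
        return "even" if self.carbon_count % 2 == 0 else "odd"


@dataclass(frozen=True)
class FunctionalizationPattern:
    n_hydroxyl: int
    n_keto: int

    def __post_init__(self) -> None:
        if self.n_hydroxyl < 0 or self.n_keto < 0:
            raise ValueError("negative functional-group count")
        if not 1 <= self.n_functional_groups <= 4:
            raise ValueError("total functional groups (C1 included) must be 1-4")

    @property
    def n_functional_groups(self) -> int:
        """Total functional groups counting the C1 position."""
        return self.n_hydroxyl + self.n_keto + 1

    @property
    def label(self) -> str:
        for label, counts in PATTERN_LABELS.items():
            if counts == (self.n_hydroxyl, self.n_keto):
                return label
        return f"{self.n_keto}keto-{self.n_hydroxyl + 1}ol"

    @classmethod
    def from_label(cls, label: str) -> "FunctionalizationPattern":
        if label not in PATTERN_LABELS:
            raise ValueError(f"unknown functionalization label {label!r}")
        return cls(*PATTERN_LABELS[label])


@dataclass(frozen=True)
class HGStructure:
    headgroup: Headgroup
    chain: ChainSpec
    pattern: FunctionalizationPattern
    previously_reported: bool = False

    @property
    def name(self) -> str:
        prefix = "AG" if self.headgroup.name == "none" else f"{self.headgroup.name} HG"
        return f"{prefix}{self.chain.carbon_count} {self.pattern.label}"

    @property
    def formula(self) -> dict[str, int]:
        return molecular_formula(self)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


def molecular_formula(structure: HGStructure) -> dict[str, int]:
    """Element counts of an HG, AG, or HG analog."""
    n = structure.chain.carbon_count
    formula = {"C": n, "H": 2 * n + 2, "O": 1}  # alkane + C1 oxygen
    formula["O"] += structure.pattern.n_hydroxyl
    formula["O"] += structure.pattern.n_keto
    formula["H"] -= 2 * structure.pattern.n_keto
    for residue in structure.headgroup.residues:
        sugar = SUGAR_FORMULAS[residue]
        for el, cnt in sugar.items():
            formula[el] = formula.get(el, 0) + cnt
        formula["H"] -= WATER["H"]
        formula["O"] -= WATER["O"]
    if any(v < 0 for v in formula.values()):
        raise ValueError(f"impossible formula for {structure.name}: {formula}")
    return formula


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of element monoisotopic masses, in Da."""
    total = 0.0
    for el, cnt in formula.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {el!r}")
        total += cnt * MONOISOTOPIC_MASS[el]
    return total


def residue_mass(residue: str) -> float:
    """Mass of a glycosidic residue (free sugar minus water)."""
    sugar = SUGAR_FORMULAS[residue]
    return monoisotopic_mass(sugar) - monoisotopic_mass(WATER)


# ---------------------------------------------------------------------------
# Enumeration

@dataclass
class GridConfig:
    headgroups: list[str]
    chains: list[int]
    patterns: list[str]
    exclusions: list[tuple[str, int, str]] = field(default_factory=list)
    extras: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def expected_count(self) -> int:
        return (
            len(self.headgroups) * len(self.chains) * len(self.patterns)
            - len(self.exclusions)
            + len(self.extras)
        )


def load_grid(path: str | Path) -> GridConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _grid_from_dict(raw)


def _grid_from_dict(raw: dict) -> GridConfig:
    return GridConfig(
        headgroups=list(raw["headgroups"]),
        chains=[int(c) for c in raw["chains"]],
        patterns=list(raw["patterns"]),
        exclusions=[(h, int(c), p) for h, c, p in raw.get("exclusions", [])],
        extras=[(h, int(c), p) for h, c, p in raw.get("extras", [])],
    )


def published_grid_synthetic() -> GridConfig:
    """Packaged synthetic stand-in for the published 88-structure grid.

    The authoritative grid is a supplementary table not bundled with this
    package; this reconstruction (see the data file header) matches the
    published target count of 88 but its 8 extra entries beyond the
    obvious 80-structure product grid are in part fixed choices of this
    package rather than published values.
    """
    text = resources.files("cyanohg.data").joinpath("target_grid_synthetic.yaml").read_text()
    return _grid_from_dict(yaml.safe_load(text))


def previously_reported_synthetic() -> set[tuple[str, int, str]]:
    """Packaged synthetic stand-in registry of previously reported HGs."""
    text = resources.files("cyanohg.data").joinpath("previously_reported_synthetic.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    out = set()
    for rec in csv.DictReader(lines, delimiter="\t"):
        out.add((rec["headgroup"], int(rec["chain"]), rec["pattern"]))
    return out


def enumerate_structures(
    grid: GridConfig, reported: set[tuple[str, int, str]] | None = None
) -> list[HGStructure]:
    """Enumerate the target grid in deterministic (headgroup, chain,
    pattern) order, then any extra entries.

    Count = |headgroups| x |chains| x |patterns| - |exclusions| + |extras|.
    """
    if not grid.headgroups or not grid.chains or not grid.patterns:
        raise ValueError("empty grid axis")
    reported = reported or set()
    excluded = set(grid.exclusions)
    triples = [
        (h, c, p)
        for h in grid.headgroups
        for c in grid.chains
        for p in grid.patterns
        if (h, c, p) not in excluded
    ]
    triples.extend(grid.extras)
    return [
        HGStructure(
            Headgroup(h),
            ChainSpec(c),
            FunctionalizationPattern.from_label(p),
            previously_reported=(h, c, p) in reported,
        )
        for h, c, p in triples
    ]


# ---------------------------------------------------------------------------
# Target prediction and screening

@dataclass(frozen=True)
class TargetIon:
    structure: HGStructure
    adduct: str
    mz: float
    fragments: tuple[float, ...]


def predict_targets(
    structure: HGStructure,
    adducts: Sequence[str] = DEFAULT_ADDUCTS_POSITIVE,
    polarity: str | None = None,
) -> list[TargetIon]:
    """Precursor m/z per adduct with diagnostic fragment m/z values.

    Fragments are successive neutral losses of the sugar residues (absent
    for aglycones) and up to n_hydroxyl + 1 water losses from the
    precursor.
    """
    mass = structure.monoisotopic_mass
    water = monoisotopic_mass(WATER)
    targets = []
    for adduct in adducts:
        if adduct not in ADDUCTS:
            raise ValueError(f"unknown adduct {adduct!r}")
        delta, pol = ADDUCTS[adduct]
        if polarity is not None and pol != polarity:
            continue
        mz = mass + delta
        fragments: list[float] = []
        loss = 0.0
        for residue in structure.headgroup.residues:
            loss += residue_mass(residue)
            fragments.append(mz - loss)
        for k in range(1, structure.pattern.n_hydroxyl + 2):
            fragments.append(mz - k * water)
        targets.append(TargetIon(structure, adduct, mz, tuple(fragments)))
    return targets


@dataclass(frozen=True)
class Peak:
    mz: float
    rt_seconds: float
    intensity: float
    ms2: tuple[float, ...] = ()


@dataclass
class PeakList:
    strain_id: str
    peaks: list[Peak]


@dataclass(frozen=True)
class DetectedHG:
    structure: HGStructure
    adduct: str
    matched_mz: float
    ppm_error: float
    intensity: float


def ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def screen_peaks(
    peaklist: PeakList,
    targets: Sequence[TargetIon],
    ppm_tol: float = 3.0,
    fragment_ppm_tol: float = 10.0,
    ms2_required: bool = False,
) -> list[DetectedHG]:
    """Match theoretical targets against a peak list.

    A target is detected when a peak lies within ``ppm_tol`` of its
    precursor m/z (the lowest-|ppm| peak wins) and, if ``ms2_required``
    and the target has diagnostic fragments, at least one fragment is
    present in that peak's MS2 list within ``fragment_ppm_tol``.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    detections = []
    for target in targets:
        best: Peak | None = None
        best_ppm = None
        for peak in peaklist.peaks:
            err = ppm(peak.mz, target.mz)
            if abs(err) <= ppm_tol and (best is None or abs(err) < abs(best_ppm)):
                if ms2_required and target.fragments:
                    matched = any(
                        abs(ppm(obs, frag)) <= fragment_ppm_tol
                        for obs in peak.ms2
                        for frag in target.fragments
                    )
                    if not matched:
                        continue
                best, best_ppm = peak, err
        if best is not None:
            detections.append(
                DetectedHG(target.structure, target.adduct, best.mz, best_ppm, best.intensity)
            )
    return detections


# ---------------------------------------------------------------------------
# Abundance tables

@dataclass
class AbundanceTable:
    """Per-strain relative abundances (%) with grouped margins.

    Structure abundances sum to 100% per strain; each grouping margin
    (headgroup, chain length, functional-group count) also sums to 100%.
    """

    structures: pd.DataFrame
    by_headgroup: pd.DataFrame
    by_chain_length: pd.DataFrame
    by_functional_count: pd.DataFrame


def relative_abundance(detections_per_strain: Mapping[str, Sequence[DetectedHG]]) -> AbundanceTable:
    """Relative abundance of each structure in each strain.

    The intensity of a structure is the sum over its detected adducts;
    abundances are normalized to the summed intensity of all detected
    HGs of that strain.
    """
    rows = []
    for strain, detections in detections_per_strain.items():
        if not detections:
            raise ValueError(f"strain {strain}: no detections")
        intensity: dict[HGStructure, float] = {}
        for det in detections:
            intensity[det.structure] = intensity.get(det.structure, 0.0) + det.intensity
        total = sum(intensity.values())
        if total <= 0:
            raise ValueError(f"strain {strain}: zero total intensity")
        for structure, inten in intensity.items():
            rows.append(
                {
                    "strain": strain,
                    "structure": structure.name,
                    "headgroup": structure.headgroup.name,
                    "chain_length": structure.chain.carbon_count,
                    "n_functional_groups": structure.pattern.n_functional_groups,
                    "abundance": 100.0 * inten / total,
                }
            )
    df = pd.DataFrame(rows)
    structures = df.pivot_table(
        index="strain", columns="structure", values="abundance", aggfunc="sum", fill_value=0.0
    )

    def margin(col: str) -> pd.DataFrame:
        return df.pivot_table(
            index="strain", columns=col, values="abundance", aggfunc="sum", fill_value=0.0
        )

    return AbundanceTable(
        structures=structures,
        by_headgroup=margin("headgroup"),
        by_chain_length=margin("chain_length"),
        by_functional_count=margin("n_functional_groups"),
    )


SYMBOL_TO_PERCENT = {"+++": 90.0, "++": 40.0, "+": 15.0, "tr.": 1.0, "absent": 0.0}


def symbols_to_percent(symbol: str) -> float:
    """Convert a literature abundance symbol to percent."""
    if symbol not in SYMBOL_TO_PERCENT:
        raise ValueError(f"unknown abundance symbol {symbol!r}")
    return SYMBOL_TO_PERCENT[symbol]


# ---------------------------------------------------------------------------
# Peak-list IO (CSV/TSV; mzML ingestion is out of scope — convert upstream)

PEAKLIST_COLUMNS = ("strain_id", "mz", "rt_seconds", "intensity", "ms2_mz_list")


def read_peaklists(path: str | Path) -> list[PeakList]:
    delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    by_strain: dict[str, list[Peak]] = {}
    with open(path) as fh:
        for rec in csv.DictReader(fh, delimiter=delimiter):
            ms2 = tuple(
                float(x) for x in rec.get("ms2_mz_list", "").split(";") if x.strip()
            )
            by_strain.setdefault(rec["strain_id"], []).append(
                Peak(float(rec["mz"]), float(rec["rt_seconds"]), float(rec["intensity"]), ms2)
            )
    return [PeakList(strain, peaks) for strain, peaks in sorted(by_strain.items())]


def write_peaklists(peaklists: Sequence[PeakList], path: str | Path) -> None:
    delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(PEAKLIST_COLUMNS)
        for pl in peaklists:
            for peak in pl.peaks:
                writer.writerow(
                    [
                        pl.strain_id,
                        f"{peak.mz:.6f}",
                        f"{peak.rt_seconds:.2f}",
                        f"{peak.intensity:.4f}",
                        ";".join(f"{m:.6f}" for m in peak.ms2),
                    ]
                )
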