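import itertools

import numpy as np
import pytest

from cyanohg import lipids, synthgen
from cyanohg.lipids import (
    ChainSpec,
    FunctionalizationPattern,
    GridConfig,
    Headgroup,
    HGStructure,
    enumerate_structures,
    molecular_formula,
    monoisotopic_mass,
    predict_targets,
    relative_abundance,
    residue_mass,
    screen_peaks,
    symbols_to_percent,
)


def structure(headgroup, chain, pattern):
    return HGStructure(Headgroup(headgroup), ChainSpec(chain), FunctionalizationPattern.from_label(pattern))


class TestFormulas:
    def test_tetracosane_diol_aglycone(self):
        # tetracosane-1,3-diol: C24 alkane + the C1 hydroxyl oxygen + one
        # further chain hydroxyl
        assert structure("none", 24, "diol").formula == {"C": 24, "H": 50, "O": 2}

    def test_hexose_bound_tetracosaneol(self):
        # C24H50O2 + C6H12O6 - H2O
        assert structure("hexose", 24, "diol").formula == {"C": 30, "H": 60, "O": 7}

    def test_keto_ol_differs_from_diol_by_two_hydrogens(self):
        diol = structure("hexose", 26, "diol").formula
        keto = structure("hexose", 26, "keto-ol").formula
        assert diol["H"] - keto["H"] == 2
        assert diol["C"] == keto["C"] and diol["O"] == keto["O"]

    def test_dipentose_carries_two_residues(self):
        mono = structure("pentose", 24, "diol")
        di = structure("dipentose", 24, "diol")
        assert di.monoisotopic_mass - mono.monoisotopic_mass == pytest.approx(
            residue_mass("pentose"), abs=1e-9
        )

    @pytest.mark.parametrize("headgroup", ["hexose", "pentose", "methylhexose", "deoxyhexose"])
    def test_mass_additivity_over_glycosylation(self, headgroup):
        for chain, pattern in itertools.product((26, 30), ("diol", "keto-diol", "triol")):
            ag = structure("none", chain, pattern)
            hg = structure(headgroup, chain, pattern)
            assert hg.monoisotopic_mass == pytest.approx(
                ag.monoisotopic_mass + residue_mass(headgroup), abs=1e-6
            )

    def test_unknown_c6_sugar_is_hexose_isomer(self):
        a = structure("hexose", 26, "diol")
        b = structure("hexose_isomer", 26, "diol")
        assert a.formula == b.formula
        assert a.name != b.name


class TestMasses:
    def test_water(self):
        assert monoisotopic_mass({"H": 2, "O": 1}) == pytest.approx(18.01056, abs=1e-4)

    def test_tetracosane_diol_mass(self):
        assert structure("none", 24, "diol").monoisotopic_mass == pytest.approx(370.3811, abs=1e-3)

    def test_hexose_residue_mass(self):
        assert residue_mass("hexose") == pytest.approx(162.05282, abs=1e-4)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass({"Xx": 1})


class TestEnumeration:
    def test_single_cell_grid(self):
        grid = GridConfig(["hexose"], [26], ["diol"])
        assert len(enumerate_structures(grid)) == 1

    def test_product_formula_for_full_grid(self):
        grid = GridConfig(
            ["hexose", "pentose", "methylhexose", "deoxyhexose"],
            [26, 28, 30, 32],
            ["diol", "keto-ol", "keto-diol", "triol", "diketo-ol"],
        )
        assert len(enumerate_structures(grid)) == 80

    def test_count_matches_product_minus_exclusions_on_random_grids(self, rng):
        headgroups = ["hexose", "pentose", "methylhexose", "deoxyhexose", "hexose_isomer"]
        patterns = list(lipids.PATTERN_LABELS)
        for _ in range(50):
            hs = list(rng.choice(headgroups, size=int(rng.integers(1, 5)), replace=False))
            cs = list(rng.choice([24, 26, 27, 28, 29, 30, 32], size=int(rng.integers(1, 5)), replace=False))
            ps = list(rng.choice(patterns, size=int(rng.integers(1, 5)), replace=False))
            cells = [(h, int(c), p) for h, c, p in itertools.product(hs, cs, ps)]
            n_excl = int(rng.integers(0, len(cells) + 1))
            excl_idx = rng.choice(len(cells), size=n_excl, replace=False)
            exclusions = [cells[i] for i in excl_idx]
            grid = GridConfig([str(h) for h in hs], [int(c) for c in cs], [str(p) for p in ps], exclusions)
            got = enumerate_structures(grid)
            assert len(got) == len(hs) * len(cs) * len(ps) - n_excl == grid.expected_count

    def test_deterministic_order(self):
        grid = GridConfig(["pentose", "hexose"], [28, 26], ["keto-ol", "diol"])
        names = [s.name for s in enumerate_structures(grid)]
        assert names[0] == "pentose HG28 keto-ol"
        assert names == [
            "pentose HG28 keto-ol", "pentose HG28 diol",
            "pentose HG26 keto-ol", "pentose HG26 diol",
            "hexose HG28 keto-ol", "hexose HG28 diol",
            "hexose HG26 keto-ol", "hexose HG26 diol",
        ]

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            enumerate_structures(GridConfig([], [26], ["diol"]))

    def test_packaged_synthetic_grid_enumerates_88_targets(self):
        grid = lipids.published_grid_synthetic()
        structures = enumerate_structures(grid, lipids.previously_reported_synthetic())
        assert len(structures) == 88
        assert sum(s.previously_reported for s in structures) == 19
        # masses must all be computable and distinct names present
        assert len({s.name for s in structures}) == 88


class TestPatterns:
    def test_functional_count_includes_the_c1_position(self):
        assert FunctionalizationPattern.from_label("diol").n_functional_groups == 2
        assert FunctionalizationPattern.from_label("keto-ol").n_functional_groups == 2
        assert FunctionalizationPattern.from_label("keto-triol").n_functional_groups == 4
        assert FunctionalizationPattern.from_label("ol").n_functional_groups == 1

    def test_over_functionalized_pattern_rejected(self):
        with pytest.raises(ValueError):
            FunctionalizationPattern(4, 0)


class TestTargets:
    def test_protonated_adduct_offset(self):
        s = structure("hexose", 26, "diol")
        targets = predict_targets(s, ["[M+H]+"])
        assert targets[0].mz == pytest.approx(s.monoisotopic_mass + 1.00728, abs=1e-4)

    def test_hexose_loss_fragment_present(self):
        s = structure("hexose", 28, "keto-diol")
        t = predict_targets(s, ["[M+H]+"])[0]
        assert any(abs(t.mz - f - 162.0528) < 1e-3 for f in t.fragments)

    def test_aglycone_has_no_sugar_loss_fragment(self):
        s = structure("none", 26, "diol")
        t = predict_targets(s, ["[M+H]+"])[0]
        # only water losses remain: n_hydroxyl + 1 of them
        water = monoisotopic_mass({"H": 2, "O": 1})
        assert len(t.fragments) == s.pattern.n_hydroxyl + 1
        for k, frag in enumerate(t.fragments, start=1):
            assert frag == pytest.approx(t.mz - k * water, abs=1e-9)

    def test_polarity_filter(self):
        s = structure("hexose", 26, "diol")
        neg = predict_targets(s, ["[M+H]+", "[M-H]-"], polarity="negative")
        assert [t.adduct for t in neg] == ["[M-H]-"]


def simulate(composition, seed=5, **kw):
    config = synthgen.LipidSimConfig(seed=seed, composition=composition, **kw)
    return synthgen.simulate_peaklist(config)


def targets_for(structures):
    return [t for s in structures for t in predict_targets(s)]


class TestScreening:
    def test_generated_composition_detected_exactly(self):
        a = structure("hexose", 26, "diol")
        b = structure("hexose", 26, "keto-ol")
        others = [structure("hexose", 28, "diol"), structure("pentose", 30, "triol")]
        peaklist, _ = simulate({a: 0.7, b: 0.3}, ppm_jitter=1.0)
        detections = screen_peaks(peaklist, targets_for([a, b] + others), ppm_tol=3.0)
        assert {d.structure for d in detections} == {a, b}

    def test_tolerance_below_jitter_detects_nothing(self):
        a = structure("hexose", 26, "diol")
        peaklist, _ = simulate({a: 1.0}, seed=8, ppm_jitter=8.0)
        # jitter drawn at 8 ppm sd essentially never lands within 0.05 ppm
        detections = screen_peaks(peaklist, targets_for([a]), ppm_tol=0.05)
        assert detections == []

    def test_decoys_far_away_never_match(self):
        a = structure("hexose", 26, "diol")
        peaklist, _ = simulate({a: 1.0}, n_decoy_peaks=200)
        detections = screen_peaks(peaklist, targets_for([a]), ppm_tol=3.0)
        # decoys are kept >= 25 ppm from any target
        assert all(abs(d.ppm_error) < 5 for d in detections)

    def test_detection_monotone_in_tolerance(self):
        comp = {
            structure("hexose", 26, "diol"): 0.4,
            structure("pentose", 28, "keto-ol"): 0.4,
            structure("methylhexose", 30, "triol"): 0.2,
        }
        peaklist, _ = simulate(comp, ppm_jitter=2.0)
        targets = targets_for(list(comp))
        sizes = [
            len(screen_peaks(peaklist, targets, ppm_tol=tol))
            for tol in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert sizes == sorted(sizes)

    def test_ms2_requirement_uses_diagnostic_fragments(self):
        a = structure("hexose", 26, "diol")
        peaklist, _ = simulate({a: 1.0}, ppm_jitter=0.5)
        with_ms2 = screen_peaks(peaklist, targets_for([a]), ms2_required=True)
        assert {d.structure for d in with_ms2} == {a}
        stripped = lipids.PeakList(
            peaklist.strain_id,
            [lipids.Peak(p.mz, p.rt_seconds, p.intensity, ()) for p in peaklist.peaks],
        )
        assert screen_peaks(stripped, targets_for([a]), ms2_required=True) == []


class TestAbundance:
    def test_single_structure_is_100_percent(self):
        a = structure("hexose", 26, "diol")
        det = lipids.DetectedHG(a, "[M+H]+", 500.0, 0.1, 1e6)
        tab = relative_abundance({"s1": [det]})
        assert tab.structures.loc["s1", a.name] == pytest.approx(100.0)

    def test_70_30_intensities(self):
        a = structure("hexose", 26, "diol")
        b = structure("hexose", 28, "keto-ol")
        tab = relative_abundance(
            {
                "s1": [
                    lipids.DetectedHG(a, "[M+H]+", 1.0, 0.0, 700.0),
                    lipids.DetectedHG(b, "[M+H]+", 1.0, 0.0, 300.0),
                ]
            }
        )
        assert tab.structures.loc["s1", a.name] == pytest.approx(70.0)
        assert tab.structures.loc["s1", b.name] == pytest.approx(30.0)

    def test_margins_each_sum_to_100(self):
        rng = np.random.default_rng(3)
        structures = [
            structure("hexose", 26, "diol"),
            structure("pentose", 28, "keto-ol"),
            structure("hexose", 30, "triol"),
            structure("deoxyhexose", 26, "keto-diol"),
        ]
        dets = [
            lipids.DetectedHG(s, "[M+H]+", 1.0, 0.0, float(rng.uniform(10, 1000)))
            for s in structures
        ]
        tab = relative_abundance({"s1": dets})
        for margin in (tab.structures, tab.by_headgroup, tab.by_chain_length, tab.by_functional_count):
            assert margin.loc["s1"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_total_intensity_is_an_error(self):
        a = structure("hexose", 26, "diol")
        with pytest.raises(ValueError):
            relative_abundance({"s1": [lipids.DetectedHG(a, "[M+H]+", 1.0, 0.0, 0.0)]})

    def test_composition_recovery_within_one_percent(self):
        """Dirichlet ground-truth compositions recovered at 1-ppm jitter."""
        rng = np.random.default_rng(31)
        pool = enumerate_structures(lipids.published_grid_synthetic())
        worst = 0.0
        for trial in range(100):
            k = int(rng.integers(3, 9))
            # isobaric structures (e.g. methylhexose HG_n vs hexose HG_n+1)
            # are indistinguishable by precursor mass alone; compositions
            # are drawn mass-resolvable, as precursor-only screening assumes
            chosen: list[HGStructure] = []
            for i in rng.permutation(len(pool)):
                cand = pool[i]
                if all(abs(cand.monoisotopic_mass - c.monoisotopic_mass) > 0.02 for c in chosen):
                    chosen.append(cand)
                if len(chosen) == k:
                    break
            weights = rng.dirichlet(np.ones(k) * 2.0) + 0.01
            comp = dict(zip(chosen, weights))
            peaklist, truth = simulate(comp, seed=int(rng.integers(2**31)), ppm_jitter=1.0)
            # window at +-5 sd of the jitter so Gaussian tails do not clip
            # whole adducts out of a structure's intensity
            detections = screen_peaks(peaklist, targets_for(chosen), ppm_tol=5.0)
            tab = relative_abundance({"s": detections})
            for s, share in truth.realized_shares.items():
                got = tab.structures.loc["s", s.name]
                worst = max(worst, abs(got - 100.0 * share))
        assert worst < 1.0


class TestSymbols:
    @pytest.mark.parametrize(
        "symbol,percent",
        [("+++", 90.0), ("++", 40.0), ("+", 15.0), ("tr.", 1.0), ("absent", 0.0)],
    )
    def test_literature_symbol_mapping(self, symbol, percent):
        assert symbols_to_percent(symbol) == percent

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            symbols_to_percent("++++")


class TestPeaklistIO:
    def test_round_trip_csv(self, tmp_path):
        a = structure("hexose", 26, "diol")
        peaklist, _ = simulate({a: 1.0}, n_decoy_peaks=3)
        path = tmp_path / "peaks.csv"
        lipids.write_peaklists([peaklist], path)
        again = lipids.read_peaklists(path)
        assert len(again) == 1
        assert len(again[0].peaks) == len(peaklist.peaks)
        assert again[0].peaks[0].mz == pytest.approx(peaklist.peaks[0].mz, abs=1e-5)
        assert len(again[0].peaks[0].ms2) == len(peaklist.peaks[0].ms2)
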