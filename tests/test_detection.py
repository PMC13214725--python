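import numpy as np
import pandas as pd
import pytest

from proteoheat import (IntensityMatrix, SimConfig, ValidationError,
                        annotate_tracks, classify_track, detection_counts,
                        find_on_off, find_switch_like, generate_dataset)
from proteoheat.detection import DetectionProfile, contrast_conditions, profiles_from_matrix

from conftest import design_24


def mask_from_cells(design, cells):
    """One-protein mask: cells maps (class, day) -> detected count (out of 6)."""
    meta = design.table
    row = np.zeros(len(meta), dtype=bool)
    for (klass, day), k in cells.items():
        idx = meta.index[(meta["tolerance_class"] == klass) & (meta["day"] == day)]
        row[meta.index.get_indexer(idx[:k])] = True
    return pd.DataFrame([row], index=["P1"], columns=meta.index)


class TestDetectionCounts:
    def test_fully_observed_class_level(self):
        design = design_24()
        mask = mask_from_cells(design, {(c, d): 6 for c in ("tolerant", "sensitive")
                                        for d in (0, 6)})
        prof = detection_counts(mask, design, level="class")[0]
        assert all(prof.counts[cell] == (6, 6) for cell in prof.counts)

    def test_single_cell_detection(self):
        design = design_24()
        mask = mask_from_cells(design, {("tolerant", 0): 6})
        prof = detection_counts(mask, design, level="class")[0]
        assert prof.counts[("tolerant", 0)] == (6, 6)
        for cell in (("tolerant", 6), ("sensitive", 0), ("sensitive", 6)):
            assert prof.counts[cell] == (0, 6)

    def test_genotype_level_totals(self):
        design = design_24()
        mask = mask_from_cells(design, {("tolerant", 0): 4})
        profs = detection_counts(mask, design, level="genotype")
        totals = {cell: kn[1] for cell, kn in profs[0].counts.items()}
        assert set(totals.values()) == {3}
        assert len(totals) == 8  # 4 genotypes x 2 days

    def test_counts_match_brute_force(self, small_dataset):
        matrix, design, _ = small_dataset
        profs = detection_counts(matrix.mask, design, level="class")
        meta = design.table
        rng = np.random.default_rng(0)
        for i in rng.choice(len(profs), size=25, replace=False):
            prof = profs[i]
            for (klass, day), (k, n) in prof.counts.items():
                samples = meta.index[(meta["tolerance_class"] == klass)
                                     & (meta["day"] == day)]
                expect = int(matrix.mask.loc[prof.protein_id, samples].sum())
                assert (k, n) == (expect, len(samples))

    def test_unknown_sample_rejected(self):
        design = design_24()
        mask = pd.DataFrame([[True]], index=["P1"], columns=["mystery"])
        with pytest.raises(ValidationError, match="mystery"):
            detection_counts(mask, design)


class TestClassifyTrack:
    def test_reliable_in_both_conditions_is_intensity_driven(self):
        # 3/3 and 2/3 per genotype in both conditions passes the >=2/3 rule
        prof = DetectionProfile("x", {
            ("g1", 0): (3, 3), ("g2", 0): (2, 3),
            ("g1", 6): (3, 3), ("g2", 6): (2, 3)})
        track = classify_track(prof, [("g1", 0), ("g2", 0)], [("g1", 6), ("g2", 6)])
        assert track == "intensity_driven"

    def test_large_frequency_gap_is_detection_driven(self):
        prof = DetectionProfile("x", {("A", 0): (6, 6), ("A", 6): (1, 6)})
        assert classify_track(prof, [("A", 0)], [("A", 6)]) == "detection_driven"

    def test_symmetric_low_detection_is_none(self):
        prof = DetectionProfile("x", {("A", 0): (3, 6), ("A", 6): (3, 6)})
        assert classify_track(prof, [("A", 0)], [("A", 6)]) == "none"

    def test_one_unreliable_genotype_fails_reliability(self):
        prof = DetectionProfile("x", {
            ("g1", 0): (3, 3), ("g2", 0): (1, 3),
            ("g1", 6): (3, 3), ("g2", 6): (3, 3)})
        track = classify_track(prof, [("g1", 0), ("g2", 0)], [("g1", 6), ("g2", 6)])
        assert track != "intensity_driven"

    def test_partition_every_dap_gets_exactly_one_track(self, small_dataset):
        matrix, design, _ = small_dataset
        daps = pd.DataFrame(index=matrix.protein_ids[:100])
        out = annotate_tracks(daps, matrix.mask, design, "sensitive_day")
        assert out["track"].isin(["intensity_driven", "detection_driven", "none"]).all()


class TestOnOff:
    def test_binary_pattern_is_candidate(self):
        # the worked pattern: 6/6 at both days in one class, 0/6 in the other
        design = design_24()
        mask = mask_from_cells(design, {("sensitive", 0): 6, ("sensitive", 6): 6})
        profs = detection_counts(mask, design, level="class")
        out = find_on_off(profs, design)
        assert list(out.index) == ["P1"]
        assert out.loc["P1", "on_class"] == "sensitive"
        assert out.loc["P1", "sensitive_day0"] == "6/6"
        assert out.loc["P1", "tolerant_day6"] == "0/6"

    def test_ubiquitous_protein_is_not_candidate(self):
        design = design_24()
        mask = mask_from_cells(design, {(c, d): 6 for c in ("tolerant", "sensitive")
                                        for d in (0, 6)})
        assert find_on_off(detection_counts(mask, design), design).empty

    def test_off_max_threshold_semantics(self):
        design = design_24()
        cells = {("sensitive", 0): 6, ("sensitive", 6): 6, ("tolerant", 0): 1}
        profs = detection_counts(mask_from_cells(design, cells), design)
        assert find_on_off(profs, design, off_max=0).empty
        assert list(find_on_off(profs, design, off_max=1).index) == ["P1"]


class TestSwitchLike:
    def test_mirror_image_crossover_flagged_with_orientation(self):
        design = design_24()
        cells = {("tolerant", 0): 6, ("tolerant", 6): 1,
                 ("sensitive", 0): 0, ("sensitive", 6): 5}
        profs = detection_counts(mask_from_cells(design, cells), design)
        out = find_switch_like(profs, design)
        assert list(out.index) == ["P1"]
        assert out.loc["P1", "high_at_baseline"] == "tolerant"

    def test_stable_detection_not_flagged(self):
        design = design_24()
        mask = mask_from_cells(design, {(c, d): 6 for c in ("tolerant", "sensitive")
                                        for d in (0, 6)})
        assert find_switch_like(detection_counts(mask, design), design).empty

    def test_planted_patterns_recovered_exactly_in_noiseless_mode(self):
        cfg = SimConfig(seed=9, n_proteins=300, n_day_effect=0, n_class_effect=0,
                        n_interaction=0, n_on_off=7, n_switch_like=7,
                        missing_target=0.0)
        matrix, design, registry = generate_dataset(cfg)
        profs = profiles_from_matrix(matrix, design)
        on_off = find_on_off(profs, design)
        switch = find_switch_like(profs, design)
        assert sorted(on_off.index) == sorted(registry.ids("on_off"))
        assert sorted(switch.index) == sorted(registry.ids("switch_like"))

    def test_deterministic_over_repeated_runs(self, small_dataset):
        matrix, design, _ = small_dataset
        runs = [find_switch_like(profiles_from_matrix(matrix, design), design)
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0], runs[1])


def test_contrast_conditions_cells():
    design = design_24()
    a, b = contrast_conditions(design, "baseline_class", level="class")
    assert a == [("tolerant", 0)] and b == [("sensitive", 0)]
    a, b = contrast_conditions(design, "sensitive_day", level="genotype")
    assert set(a) == {("S1", 6), ("S2", 6)} and set(b) == {("S1", 0), ("S2", 0)}
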