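import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen import examples
from poolscreen.stats import (
    MutationRecord,
    compare_detection,
    deduplicate,
    density_report,
    detection_comparison_from_counts,
    distance_between_changes,
    expected_per_plant,
    min_detectable_allele_fraction,
    mutation_density_per_kb,
    round_half_away,
    screen_report,
    spectrum_summary,
)


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (15.734, 1, 15.7),
        (2.0833, 1, 2.1),
        (74.247, 0, 74),
        (43.4595, 1, 43.5),
        (105.916, 0, 106),
        (0.25, 1, 0.3),   # half away from zero
        (-0.25, 1, -0.3),
        (62.457, 1, 62.5),
    ])
    def test_round_half_away(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestDeduplicate:
    def test_worked_example_26_records_18_unique(self):
        unique, groups = deduplicate(examples.HRM_LN_RECORDS)
        assert len(examples.HRM_LN_RECORDS) == 26
        assert len(unique) == 18
        dup_sizes = sorted(len(m) for m in groups.values() if len(m) > 1)
        assert dup_sizes == [2, 2, 2, 2, 3, 3]

    def test_all_distinct_identity(self):
        recs = [MutationRecord(f"L{i}", "c", i, "G", "A") for i in range(5)]
        unique, _ = deduplicate(recs)
        assert len(unique) == 5

    def test_same_position_different_alt_not_collapsed(self):
        recs = [MutationRecord("L1", "c", 10, "G", "A"),
                MutationRecord("L2", "c", 10, "G", "T")]
        unique, _ = deduplicate(recs)
        assert len(unique) == 2

    @given(st.lists(st.tuples(st.integers(1, 30),
                              st.sampled_from("ACGT")), max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_bounded(self, sites):
        recs = [MutationRecord(f"L{i}", "c", pos, "G", alt)
                for i, (pos, alt) in enumerate(sites)]
        unique, _ = deduplicate(recs)
        again, _ = deduplicate(unique)
        assert len(again) == len(unique) <= len(recs)


class TestDensity:
    def test_worked_example(self):
        assert mutation_density_per_kb(18, 1144) == 15.7

    @pytest.mark.parametrize("n,region,expected", [(0, 1000, 0.0),
                                                   (1, 1000, 1.0)])
    def test_trivial(self, n, region, expected):
        assert mutation_density_per_kb(n, region) == expected

    def test_zero_region_rejected(self):
        with pytest.raises(ValueError):
            mutation_density_per_kb(1, 0)


class TestDistance:
    def test_average_line(self):
        assert distance_between_changes(12_796, 950_068_807) == (74.2, 74)

    def test_range_endpoints(self):
        assert distance_between_changes(21_861, 950_068_807) == (43.5, 43)
        assert distance_between_changes(8_970, 950_068_807) == (105.9, 106)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            distance_between_changes(0)


class TestExpectedPerPlant:
    def test_amplicon_panel_totals(self):
        # oracle: 561/30269*950068807/1536 = 11463.8 -> 11464
        assert expected_per_plant(561, 30_269, 950_068_807, 1536) == 11_464

    def test_zero_changes(self):
        assert expected_per_plant(0, 100, 1000, 10) == 0

    def test_doubling_plants_halves(self):
        a = expected_per_plant(600, 30_000, 900_000_000, 1536)
        b = expected_per_plant(600, 30_000, 900_000_000, 3072)
        assert abs(a - 2 * b) <= 1


class TestSpectrumSummary:
    def test_wgs_category_counts(self):
        s = spectrum_summary(examples.WGS_CATEGORY_COUNTS)
        assert s.total == 153_554
        assert s.transitions == 114_106
        assert s.transversions == 39_448
        assert s.ts_tv_ratio == 2.89
        assert s.percentages["G>A+C>T"] == 69.3
        assert s.percentages["T>A+A>T"] == 17.8
        assert s.percentages["T>C+A>G"] == 5.0
        assert s.percentages["G>T+C>A"] == 3.9
        assert s.percentages["A>C+T>G"] == 3.0
        assert s.percentages["C>G+G>C"] == 1.0

    def test_single_mutation_ratio_undefined(self):
        s = spectrum_summary([("G", "A")])
        assert s.percentages["G>A"] == 100.0
        assert s.ts_tv_ratio is None

    def test_percentages_sum_near_100(self):
        s = spectrum_summary(examples.WGS_CATEGORY_COUNTS)
        assert abs(sum(s.percentages.values()) - 100.0) <= 0.3

    def test_multinomial_recovery(self):
        import numpy as np

        from poolscreen.simulate import SUBSTITUTION_CLASSES, SpectrumModel

        spectrum = SpectrumModel.default()
        rng = np.random.default_rng(5)
        n = 10_000
        draws = rng.choice(len(SUBSTITUTION_CLASSES), size=n,
                           p=spectrum.as_array())
        muts = [tuple(SUBSTITUTION_CLASSES[i].split(">")) for i in draws]
        s = spectrum_summary(muts)
        for cls in SUBSTITUTION_CLASSES:
            p = spectrum.proportions[cls]
            se = np.sqrt(p * (1 - p) / n)
            observed = s.counts.get(cls, 0) / n
            assert abs(observed - p) <= 3 * se + 1e-12

    def test_mixed_category_rejected(self):
        with pytest.raises(ValueError):
            spectrum_summary({"G>A+A>T": 5})


class TestCompareDetection:
    def test_gene_row_worked_example(self):
        comparison = detection_comparison_from_counts(
            {"Glyma20g25000": (37, 14, 4, 19)})
        row = comparison.rows[0]
        assert row.pct_a == 48.6
        assert row.pct_b == 89.2

    def test_five_gene_totals(self):
        comparison = detection_comparison_from_counts(
            examples.DETECTION_COMPARISON_COUNTS,
            examples.DETECTION_COMPARISON_REGION_BP)
        assert comparison.total == 107
        assert comparison.pct_a == 62.5
        assert comparison.pct_b == 90.3
        # pooled-count variant differs, kept for transparency
        assert comparison.pct_a_pooled == 59.8
        assert comparison.pct_b_pooled == 89.7

    def test_identical_sets_are_100_percent(self):
        calls = {"g1": {(1, "A"), (2, "T")}, "g2": {(5, "G")}}
        comparison = compare_detection(calls, calls, {})
        assert comparison.pct_a == 100.0
        assert comparison.pct_b == 100.0

    def test_symmetry_under_swap(self):
        a = {"g1": {(1, "A"), (2, "T")}, "g2": {(5, "G"), (6, "C")}}
        b = {"g1": {(2, "T"), (3, "G")}, "g2": {(5, "G")}}
        ab = compare_detection(a, b, {})
        ba = compare_detection(b, a, {})
        assert ab.pct_a == ba.pct_b
        assert ab.pct_b == ba.pct_a
        assert ab.a_only == ba.b_only

    def test_empty_gene_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            comparison = compare_detection({"g1": {(1, "A")}, "g2": set()},
                                           {"g2": set()}, {})
        assert len(comparison.rows) == 1

    def test_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            detection_comparison_from_counts({"g": (10, 5, 2, 1)})


class TestMinDetectableFraction:
    def test_het_pool_16(self):
        assert min_detectable_allele_fraction(16, "het") == 1 / 32

    def test_het_pool_4(self):
        assert min_detectable_allele_fraction(4, "het") == 1 / 8

    def test_hom_pool_16(self):
        assert min_detectable_allele_fraction(16, "hom") == 1 / 16

    def test_zero_pool_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_allele_fraction(0, "het")


class TestScreenReport:
    def test_duplicate_letters_span_six_groups(self):
        rows = screen_report(examples.HRM_LN_RECORDS)
        letters = sorted({r.duplicate_tag for r in rows if r.duplicate_tag})
        assert letters == ["a", "b", "c", "d", "e", "f"]
        # letters assigned in positional order
        first_letter_pos = {}
        for r in rows:
            if r.duplicate_tag and r.duplicate_tag not in first_letter_pos:
                first_letter_pos[r.duplicate_tag] = r.pos
        assert list(first_letter_pos) == sorted(
            first_letter_pos, key=first_letter_pos.get)

    def test_no_duplicates_no_letters(self):
        recs = [MutationRecord(f"L{i}", "c", 10 + i, "G", "A")
                for i in range(4)]
        assert all(not r.duplicate_tag for r in screen_report(recs))

    def test_deterministic(self):
        assert screen_report(examples.HRM_LN_RECORDS) == screen_report(
            list(reversed(examples.HRM_LN_RECORDS)))


class TestDensityReport:
    def test_fields(self):
        rep = density_report(18, 1144)
        assert rep.mutations_per_kb == 15.7
        assert rep.kb_per_mutation == 0.1
        assert rep.genome_bp == 950_068_807
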