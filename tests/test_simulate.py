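import warnings

import numpy as np
import pytest

from poolscreen.simulate import (
    SUBSTITUTION_CLASSES,
    Amplicon,
    ReadSimConfig,
    SpectrumModel,
    amplicons_from_reference,
    assign_indexes,
    build_layout,
    build_toy_reference,
    expected_mutations_per_plant,
    revcomp,
    simulate_pool_reads,
    simulate_population,
)


class TestToyReference:
    def test_single_forward_gene_translates_cleanly(self):
        ref = build_toy_reference(1, 300, seed=7)
        assert len(ref.sequences) == 1
        (gm,) = ref.gene_models
        assert gm.strand == "+"
        cds = gm.spliced_cds(ref.sequences[gm.seq_name])
        assert len(cds) == 300
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")
        internal = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
        assert not set(internal) & {"TAA", "TAG", "TGA"}

    def test_seeded_determinism(self):
        a = build_toy_reference(2, 300, seed=7)
        b = build_toy_reference(2, 300, seed=7)
        assert a.sequences == b.sequences
        assert a.gene_models == b.gene_models

    def test_both_strands_present(self):
        ref = build_toy_reference(2, 300, seed=7)
        assert {gm.strand for gm in ref.gene_models} == {"+", "-"}

    def test_reverse_gene_cds_also_valid(self):
        ref = build_toy_reference(2, 300, seed=7)
        gm = next(g for g in ref.gene_models if g.strand == "-")
        cds = gm.spliced_cds(ref.sequences[gm.seq_name])
        assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")

    @pytest.mark.parametrize("n_genes,length", [(0, 300), (1, 30), (1, 301)])
    def test_invalid_arguments_rejected(self, n_genes, length):
        with pytest.raises(ValueError):
            build_toy_reference(n_genes, length, seed=7)


class TestSpectrumModel:
    def test_default_normalizes_to_one(self):
        s = SpectrumModel.default()
        assert abs(sum(s.proportions.values()) - 1.0) < 1e-9

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            SpectrumModel({"G>A": 0.5})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            SpectrumModel({"G>X": 1.0})


class TestPopulation:
    def test_ref_bases_match_reference(self, toy_reference):
        pop = simulate_population(toy_reference, 16, per_round_density=2e-3,
                                  seed=3)
        for ev in pop.all_events():
            assert toy_reference.sequences[ev.seq_name][ev.pos - 1] == ev.ref
            assert ev.ref != ev.alt

    def test_round1_shared_within_family_round2_not(self, toy_reference):
        pop = simulate_population(toy_reference, 8, per_round_density=5e-3,
                                  seed=5, m1_family_size=4)
        fam1 = pop.plant_ids[:4]
        r1_sites = {}
        for plant in fam1:
            for ev in pop.events[plant]:
                if ev.origin == "round1":
                    r1_sites.setdefault((ev.seq_name, ev.pos, ev.alt), []).append(plant)
        # at least one round-1 site is shared by two siblings at this density
        assert any(len(v) > 1 for v in r1_sites.values())

    def test_sibling_transmission_rate(self):
        """Monte-Carlo check of the selfing transmission model: conditional
        on one sibling carrying a round-1 mutation, another sibling of the
        same M1 family carries it with probability 3/4 (>= 1/4 required)."""
        ref = build_toy_reference(1, 60, seed=1)
        carried = total = 0
        for seed in range(400):
            pop = simulate_population(ref, 2, per_round_density=5e-3,
                                      seed=seed, m1_family_size=2)
            a, b = pop.plant_ids
            sites_b = {(e.seq_name, e.pos, e.alt) for e in pop.events[b]
                       if e.origin == "round1"}
            for ev in pop.events[a]:
                if ev.origin != "round1":
                    continue
                total += 1
                carried += (ev.seq_name, ev.pos, ev.alt) in sites_b
        assert total > 100
        rate = carried / total
        se = np.sqrt(0.75 * 0.25 / total)
        assert rate >= 0.25
        assert abs(rate - 0.75) < 4 * se

    def test_zygosity_mix(self, toy_reference):
        pop = simulate_population(toy_reference, 64, per_round_density=3e-3,
                                  seed=9)
        zygs = [ev.zygosity for ev in pop.all_events()]
        hom = zygs.count("hom") / len(zygs)
        # 1/3 expected under 1:2 hom:het given carriage
        assert abs(hom - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / len(zygs))

    def test_mean_count_matches_expectation(self, toy_reference):
        """Empirical per-plant count within 3 SE of the analytic expectation
        over 20 seeds (binomial/Poisson expectation oracle)."""
        density = 2e-3
        expected = expected_mutations_per_plant(density, toy_reference.total_bp)
        counts = []
        for seed in range(26):
            pop = simulate_population(toy_reference, 16,
                                      per_round_density=density, seed=seed)
            counts.extend(len(v) for v in pop.events.values())
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se

    def test_spectrum_recovery(self, toy_reference):
        """Each class proportion within 3 SE of its configured value over
        >= 10,000 simulated mutations."""
        spectrum = SpectrumModel.default()
        # count unique drawn sites so family-shared round-1 copies (which
        # are correlated) do not inflate the sample; use a genome large
        # relative to the density so collision redraws stay negligible
        ref = build_toy_reference(6, 900, seed=77)
        events = set()
        for seed in range(18):
            pop = simulate_population(ref, 64,
                                      per_round_density=1.5e-3, seed=seed,
                                      spectrum=spectrum)
            events.update((seed, e.seq_name, e.pos, e.ref, e.alt)
                          for e in pop.all_events())
        n = len(events)
        assert n >= 10_000
        for cls in SUBSTITUTION_CLASSES:
            p = spectrum.proportions[cls]
            observed = sum(1 for _, _, _, ref, alt in events
                           if f"{ref}>{alt}" == cls) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se + 1e-12, cls

    def test_impossible_spectrum_warns_and_yields_nothing(self):
        ref = build_toy_reference(1, 60, seed=1)
        seq = ref.sequences[next(iter(ref.sequences))]
        no_g = seq.replace("G", "A")
        ref.sequences[next(iter(ref.sequences))] = no_g
        ref.gene_models = []
        spectrum = SpectrumModel({"G>A": 1.0})
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pop = simulate_population(ref, 4, spectrum=spectrum,
                                      per_round_density=1e-3, seed=1)
        assert sum(len(v) for v in pop.events.values()) == 0
        assert any("no eligible sites" in str(w.message) for w in caught)

    def test_invalid_arguments(self, toy_reference):
        with pytest.raises(ValueError):
            simulate_population(toy_reference, 10, per_round_density=1e-3,
                                m1_family_size=4)
        with pytest.raises(ValueError):
            simulate_population(toy_reference, 8, per_round_density=0.0)

    def test_excessive_density_errors(self):
        ref = build_toy_reference(1, 60, seed=1)
        with pytest.raises(RuntimeError, match="collision"):
            simulate_population(ref, 4, per_round_density=1.5, seed=0,
                                m1_family_size=4)


class TestLayout:
    def test_full_scale_layout(self):
        layout = build_layout(1536, 4, 4)
        assert len(layout.tier1_pools) == 384
        assert len(layout.tier2_pools) == 96
        groups = layout.plants_in_tier2(layout.tier2_pools[0])
        assert len(groups) == 4
        assert all(len(v) == 4 for v in groups.values())

    def test_minimal_layout(self):
        layout = build_layout(16, 4, 4)
        assert len(layout.tier1_pools) == 4
        assert len(layout.tier2_pools) == 1

    def test_non_divisible_errors_without_padding(self):
        with pytest.raises(ValueError):
            build_layout(10, 4, 4)

    def test_padding_fills_with_blanks(self):
        layout = build_layout(10, 4, 4, pad=True)
        assert layout.n_plants == 16
        assert sum(1 for p in layout.plants if p.startswith("PAD")) == 6

    def test_roundtrip_membership(self):
        layout = build_layout(64, 4, 4)
        for plant in layout.plants:
            pool = layout.tier2_of_plant(plant)
            candidates = [p for grp in layout.plants_in_tier2(pool).values()
                          for p in grp]
            assert plant in candidates
            assert len(candidates) == 16


class TestIndexes:
    def test_96_pools_use_all_12x8_combinations(self):
        layout = assign_indexes(build_layout(1536, 4, 4))
        pairs = set(layout.index_pairs.values())
        assert len(pairs) == 96
        assert len(layout.index_pairs) == 96

    def test_small_assignment(self):
        layout = build_layout(64, 4, 4)
        layout = assign_indexes(layout, ("a", "b"), ("x", "y"))
        assert set(layout.index_pairs.values()) == {
            ("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")}

    def test_insufficient_labels(self):
        layout = build_layout(97 * 16, 4, 4)
        with pytest.raises(ValueError):
            assign_indexes(layout)


class TestPoolReads:
    def test_het_allele_fraction_near_1_over_32(self, small_world):
        """Observed mutant fraction of a single-het-carrier site within 3
        binomial SE of 1/32 at high depth and zero error rate."""
        from poolscreen.readprep import align_gapless, trim_reads

        result = simulate_pool_reads(
            small_world["reference"], small_world["amplicons"],
            small_world["population"], small_world["layout"],
            small_world["read_config"])
        checked = 0
        for rec in result.truth_in_amplicons():
            if rec.origin == "background" or len(rec.lines) != 1:
                continue
            if rec.zygosities != ("het",):
                continue
            pool = rec.pools[0]
            pairs, _ = trim_reads(result.reads[pool])
            pileups, _ = align_gapless(pairs, small_world["reference"].sequences)
            p = pileups[rec.seq_name]
            i = rec.pos - 1
            bi = "ACGT".index(rec.alt)
            alt = int(p.raw[bi, :, i].sum())
            cov = int(p.raw[:, :, i].sum())
            f = 1 / 32
            se = np.sqrt(f * (1 - f) / cov)
            assert abs(alt / cov - f) < 3.5 * se
            checked += 1
            if checked >= 3:
                break
        assert checked > 0

    def test_error_free_unmutated_pool_matches_reference(self):
        ref = build_toy_reference(1, 60, seed=2)
        pop = simulate_population(ref, 16, per_round_density=1e-5, seed=2)
        for p in pop.plant_ids:  # force an unmutated pool
            pop.events[p] = []
        layout = assign_indexes(build_layout(16, plant_ids=pop.plant_ids))
        rs = simulate_pool_reads(ref, amplicons_from_reference(ref), pop,
                                 layout,
                                 ReadSimConfig(mean_depth_per_pool=200.0,
                                               error_rate=0.0, seed=3))
        seq = ref.sequences["amp01"]
        for pair in rs.reads["pool001"]:
            assert pair.seq1 in seq or revcomp(pair.seq1) in seq
            assert pair.seq2 in seq or revcomp(pair.seq2) in seq

    def test_amplicon_outside_reference_rejected(self, small_world):
        bad = [Amplicon("bad", "amp01", 1, 10_000)]
        with pytest.raises(ValueError):
            simulate_pool_reads(small_world["reference"], bad,
                                small_world["population"],
                                small_world["layout"],
                                small_world["read_config"])

    def test_truth_bijective_with_population(self, small_world):
        rs = simulate_pool_reads(
            small_world["reference"], small_world["amplicons"],
            small_world["population"], small_world["layout"],
            small_world["read_config"])
        pop_pairs = {((e.seq_name, e.pos, e.ref, e.alt), e.line_id)
                     for e in small_world["population"].all_events()}
        truth_pairs = set()
        for rec in rs.truth:
            if rec.origin == "background":
                continue
            for line in rec.lines:
                truth_pairs.add(((rec.seq_name, rec.pos, rec.ref, rec.alt), line))
        assert pop_pairs == truth_pairs

    def test_seeded_reads_identical(self, small_world):
        kw = dict(
            reference=small_world["reference"],
            amplicons=small_world["amplicons"],
            population=small_world["population"],
            layout=small_world["layout"],
            config=small_world["read_config"],
        )
        a = simulate_pool_reads(**kw)
        b = simulate_pool_reads(**kw)
        assert a.reads == b.reads
        assert a.truth == b.truth
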