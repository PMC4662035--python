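"""Deconvolution of pool calls to plants and end-to-end benchmarking.

A PASS call in a tier-2 pool narrows the carrier to the pool's plants
(grouped by tier-1 pool so follow-up can test four sub-pools first); the
carrier and its zygosity are then confirmed by per-plant genotyping,
modeled here as an error-free lookup against the simulation truth.
``run_benchmark`` exercises the whole pipeline — simulate, trim, align,
call, background-filter, annotate, deconvolve, confirm — against known
ground truth over several seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import mean, stdev

from poolscreen.background import FilterConfig, apply_background_filter, build_background_filter
from poolscreen.caller import (
    LINE_RELAXED,
    CallerConfig,
    PoolVariantCall,
    call_pool_variants,
    passing_sites,
)
from poolscreen.effects import annotate_effect
from poolscreen.readprep import AlignConfig, TrimConfig, align_gapless, trim_reads
from poolscreen.simulate import (
    Amplicon,
    MutationEvent,
    PoolingLayout,
    Population,
    PoolReadSet,
    ReadSimConfig,
    ReferenceSet,
    SpectrumModel,
    amplicons_from_reference,
    assign_indexes,
    build_layout,
    build_toy_reference,
    expected_mutations_per_plant,
    simulate_pool_reads,
    simulate_population,
)


def deconvolve(call: PoolVariantCall, layout: PoolingLayout) -> dict[str, list[str]]:
    """Candidate plants for a pool call, grouped by tier-1 pool."""
    return layout.plants_in_tier2(call.pool_id)


def confirm_by_genotype(call: PoolVariantCall, candidate_plants: list[str],
                        population: Population) -> list[tuple[str, str]]:
    """Candidates whose genotype carries the called alt, with zygosity."""
    confirmed = []
    for plant in candidate_plants:
        if plant not in population.events:
            continue  # padding placeholder
        geno = population.genotype_at(plant, call.seq_name, call.pos)
        if geno is not None and geno[1] == call.alt:
            confirmed.append((plant, geno[2]))
    return confirmed


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    pass_calls: list[PoolVariantCall]  # genomic coordinates, after filtering
    background_sites: set
    n_background_removed: int
    effects: dict
    confirmations: dict  # (pool_id, site) -> list of (plant, zygosity)
    readset: PoolReadSet
    align_stats: dict
    trim_pairs_in: int = 0
    trim_pairs_out: int = 0


def run_pipeline(reference: ReferenceSet, amplicons: list[Amplicon],
                 population: Population, layout: PoolingLayout,
                 read_config: ReadSimConfig,
                 caller_config: CallerConfig | None = None,
                 trim_config: TrimConfig | None = None,
                 align_config: AlignConfig | None = None,
                 filter_config: FilterConfig | None = None,
                 apply_filter: bool = True) -> PipelineResult:
    caller_config = caller_config or CallerConfig()
    trim_config = trim_config or TrimConfig()
    align_config = align_config or AlignConfig()
    readset = simulate_pool_reads(reference, amplicons, population, layout,
                                  read_config)
    refs = {amp.name: reference.sequences[amp.seq_name][amp.start - 1:amp.end]
            for amp in amplicons}
    offsets = {amp.name: (amp.seq_name, amp.start - 1) for amp in amplicons}

    pass_calls: list[PoolVariantCall] = []
    relaxed_sets = []
    align_stats = {}
    pairs_in = pairs_out = 0
    for pool_id in layout.tier2_pools:
        pairs, report = trim_reads(readset.reads.get(pool_id, []), trim_config)
        pairs_in += report.pairs_in
        pairs_out += report.pairs_out
        pileups, stats = align_gapless(pairs, refs, align_config)
        align_stats[pool_id] = stats
        pool_calls: list[PoolVariantCall] = []
        relaxed: set = set()
        for amp_name, pileup in pileups.items():
            seq_name, off = offsets[amp_name]
            for call in call_pool_variants(pileup, caller_config, pool_id):
                pool_calls.append(replace(call, seq_name=seq_name,
                                          pos=call.pos + off))
            for call in call_pool_variants(pileup, LINE_RELAXED, pool_id):
                if call.filter_status == "PASS":
                    relaxed.add((seq_name, call.pos + off, call.alt))
        pass_calls.extend(c for c in pool_calls if c.filter_status == "PASS")
        relaxed_sets.append(relaxed)

    background_sites: set = set()
    n_removed = 0
    if apply_filter and len(relaxed_sets) >= (filter_config or FilterConfig()).min_units:
        background_sites = build_background_filter(relaxed_sets, filter_config)
        pass_calls, n_removed = apply_background_filter(pass_calls, background_sites)

    effects = {}
    for call in pass_calls:
        site = call.site
        if site not in effects:
            mut = MutationEvent("query", call.seq_name, call.pos, call.ref,
                                call.alt, "het", "round2")
            effects[site] = annotate_effect(mut, reference.gene_models, reference)

    confirmations = {}
    for call in pass_calls:
        groups = deconvolve(call, layout)
        candidates = [p for grp in groups.values() for p in grp]
        confirmations[(call.pool_id, call.site)] = confirm_by_genotype(
            call, candidates, population)

    return PipelineResult(pass_calls, background_sites, n_removed, effects,
                          confirmations, readset, align_stats, pairs_in, pairs_out)


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkReport:
    sensitivity: float
    sensitivity_sd: float
    fdr: float
    fdr_sd: float
    sensitivity_het: float
    sensitivity_hom: float
    recovered_density_per_bp: float
    configured_density_per_bp: float
    seeds: list[int] = field(default_factory=list)
    per_seed: list[dict] = field(default_factory=list)


def _score_seed(result: PipelineResult, population: Population,
                layout: PoolingLayout, edge_margin: int = 3) -> dict:
    """Score one pipeline run against simulation truth.

    ``edge_margin`` excludes the outermost bases of each amplicon from the
    sensitivity denominator: read end-trimming removes them from every
    read, so no caller can observe them (the real assay's amplicon sizes
    likewise exclude primer sequence).
    """
    truth = [rec for rec in result.readset.truth_in_amplicons(edge_margin)
             if rec.origin != "background"]
    confirmed_pairs = set()
    for (pool_id, site), plants in result.confirmations.items():
        for plant, _zyg in plants:
            confirmed_pairs.add((site, plant))
    n_det = {"het": 0, "hom": 0}
    n_tot = {"het": 0, "hom": 0}
    detected_mutations = 0
    for rec in truth:
        site = (rec.seq_name, rec.pos, rec.alt)
        any_detected = False
        for plant, zyg in zip(rec.lines, rec.zygosities):
            if plant not in layout.tier1:
                continue
            n_tot[zyg] += 1
            if (site, plant) in confirmed_pairs:
                n_det[zyg] += 1
                any_detected = True
        detected_mutations += bool(any_detected)
    false_calls = sum(1 for key, plants in result.confirmations.items()
                      if not plants)
    n_calls = len(result.confirmations)
    total_det = n_det["het"] + n_det["hom"]
    total_tot = n_tot["het"] + n_tot["hom"]
    return {
        "sensitivity": total_det / total_tot if total_tot else float("nan"),
        "sensitivity_het": n_det["het"] / n_tot["het"] if n_tot["het"] else float("nan"),
        "sensitivity_hom": n_det["hom"] / n_tot["hom"] if n_tot["hom"] else float("nan"),
        "fdr": false_calls / n_calls if n_calls else 0.0,
        "n_true_pairs": total_tot,
        "n_detected_pairs": total_det,
        "detected_per_plant_bp": total_det,
    }


def run_benchmark(n_plants: int = 64, n_genes: int = 2, gene_length: int = 300,
                  per_round_density: float = 2e-3,
                  spectrum: SpectrumModel | None = None,
                  read_config: ReadSimConfig | None = None,
                  caller_config: CallerConfig | None = None,
                  n_seeds: int = 3, base_seed: int = 0,
                  n_background_polymorphisms: int = 0) -> BenchmarkReport:
    """Run the full pipeline over several seeds and score it against truth."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    read_config = read_config or ReadSimConfig(mean_depth_per_pool=6400.0,
                                               error_rate=0.0)
    per_seed = []
    seeds = [base_seed + i for i in range(n_seeds)]
    amp_bp = 0
    total_true = total_det = 0
    for seed in seeds:
        reference = build_toy_reference(n_genes, gene_length, seed=seed)
        population = simulate_population(
            reference, n_plants, spectrum, per_round_density, seed=seed + 1,
            n_background_polymorphisms=n_background_polymorphisms)
        layout = assign_indexes(build_layout(n_plants,
                                             plant_ids=population.plant_ids))
        result = run_pipeline(reference, amplicons_from_reference(reference),
                              population, layout,
                              replace(read_config, seed=seed + 2),
                              caller_config)
        score = _score_seed(result, population, layout)
        score["seed"] = seed
        per_seed.append(score)
        amp_bp += reference.total_bp
        total_true += score["n_true_pairs"]
        total_det += score["n_detected_pairs"]

    def agg(key):
        vals = [s[key] for s in per_seed if s[key] == s[key]]
        return (mean(vals) if vals else float("nan"),
                stdev(vals) if len(vals) > 1 else 0.0)

    sens, sens_sd = agg("sensitivity")
    fdr, fdr_sd = agg("fdr")
    sens_het, _ = agg("sensitivity_het")
    sens_hom, _ = agg("sensitivity_hom")
    configured = expected_mutations_per_plant(per_round_density, 1)
    recovered = total_det / (amp_bp * n_plants) if amp_bp else float("nan")
    return BenchmarkReport(sens, sens_sd, fdr, fdr_sd, sens_het, sens_hom,
                           recovered, configured, seeds, per_seed)
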