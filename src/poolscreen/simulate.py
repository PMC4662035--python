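"""Synthetic data generation with known ground truth.

Builds toy amplicon references with gene models, simulates a doubly
EMS-treated selfing population (first-round mutations shared within M1
families, second-round mutations private to each plant), lays plants out
into two pooling tiers with dual index labels, and draws pooled paired-end
reads with a smooth non-uniform depth profile and i.i.d. substitution
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")

#: The 12 directed single-base substitution classes, in the conventional
#: EMS-spectrum order (most to least frequent for alkylating mutagens).
SUBSTITUTION_CLASSES = (
    "G>A", "C>T", "T>A", "A>T", "T>C", "A>G",
    "G>T", "C>A", "A>C", "T>G", "C>G", "G>C",
)

#: Default class percentages for a twice-EMS-treated soybean population
#: (per-class share of all base changes observed across 12 re-sequenced
#: lines). They are normalized on use since the printed one-decimal values
#: sum to 100.1.
DEFAULT_SPECTRUM_PERCENTAGES = (
    34.8, 34.6, 9.1, 8.7, 2.5, 2.4, 2.0, 1.9, 1.5, 1.5, 0.6, 0.5,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model over one reference sequence.

    ``cds_intervals`` are 1-based inclusive genomic intervals, sorted
    ascending and non-overlapping. ``phase`` is the phase of the first
    interval in translation order (GFF3 convention).
    """

    gene_id: str
    seq_name: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")
        ivals = tuple(tuple(iv) for iv in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivals)
        last_end = 0
        for start, end in ivals:
            if start > end:
                raise ValueError(f"interval ({start}, {end}) has start > end")
            if start <= last_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            last_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    @property
    def is_partial(self) -> bool:
        """True when the in-frame CDS length is not a codon multiple."""
        return (self.cds_length - self.phase) % 3 != 0

    def spliced_cds(self, genomic_seq: str) -> str:
        """CDS sequence in translation order (reverse-complemented for '-')."""
        parts = [genomic_seq[start - 1:end] for start, end in self.cds_intervals]
        cds = "".join(parts)
        return revcomp(cds) if self.strand == "-" else cds

    def cds_position(self, pos: int) -> int | None:
        """1-based position within the spliced CDS, or None outside the CDS."""
        offset = 0
        if self.strand == "+":
            for start, end in self.cds_intervals:
                if start <= pos <= end:
                    return offset + (pos - start) + 1
                offset += end - start + 1
            return None
        for start, end in reversed(self.cds_intervals):
            if start <= pos <= end:
                return offset + (end - pos) + 1
            offset += end - start + 1
        return None


@dataclass
class ReferenceSet:
    """Reference sequences plus their gene models."""

    sequences: dict[str, str]
    gene_models: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        if not self.sequences:
            raise ValueError("reference has no sequences")
        for name, seq in self.sequences.items():
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"sequence {name!r} is empty or not ACGT")
        for gm in self.gene_models:
            if gm.seq_name not in self.sequences:
                raise ValueError(f"gene {gm.gene_id}: unknown sequence {gm.seq_name}")
            seq_len = len(self.sequences[gm.seq_name])
            for start, end in gm.cds_intervals:
                if start < 1 or end > seq_len:
                    raise ValueError(f"gene {gm.gene_id}: CDS outside sequence")

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class SpectrumModel:
    """Proportions over the 12 directed substitution classes."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
        props = {c: float(self.proportions.get(c, 0.0)) for c in SUBSTITUTION_CLASSES}
        if any(p < 0 for p in props.values()):
            raise ValueError("proportions must be non-negative")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        object.__setattr__(self, "proportions", props)

    @classmethod
    def from_percentages(cls, percentages=DEFAULT_SPECTRUM_PERCENTAGES) -> "SpectrumModel":
        """Build from per-class percentages, normalizing to sum 1."""
        total = float(sum(percentages))
        if total <= 0:
            raise ValueError("percentages must have positive sum")
        return cls({c: p / total for c, p in zip(SUBSTITUTION_CLASSES, percentages)})

    @classmethod
    def default(cls) -> "SpectrumModel":
        return cls.from_percentages()

    def as_array(self) -> np.ndarray:
        return np.array([self.proportions[c] for c in SUBSTITUTION_CLASSES])


@dataclass(frozen=True)
class MutationEvent:
    """One induced single-base change carried by one plant."""

    line_id: str
    seq_name: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"
    origin: str  # "round1" | "round2" | "background"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


@dataclass
class PoolingLayout:
    """Two-tier pooling: plants -> tier-1 pools -> indexed tier-2 pools."""

    n_plants: int
    tier1_size: int
    tier2_size: int
    tier1: dict[str, str]  # plant_id -> tier1 pool id
    tier2: dict[str, str]  # tier1 pool id -> tier2 pool id
    index_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def tier1_pools(self) -> list[str]:
        return sorted(set(self.tier1.values()))

    @property
    def tier2_pools(self) -> list[str]:
        return sorted(set(self.tier2.values()))

    @property
    def plants(self) -> list[str]:
        return sorted(self.tier1)

    def tier2_of_plant(self, plant_id: str) -> str:
        return self.tier2[self.tier1[plant_id]]

    def plants_in_tier2(self, pool_id: str) -> dict[str, list[str]]:
        """Plants of one tier-2 pool, grouped by their tier-1 pool."""
        groups: dict[str, list[str]] = {}
        t1_pools = [t1 for t1, t2 in self.tier2.items() if t2 == pool_id]
        if not t1_pools:
            raise KeyError(f"unknown tier-2 pool {pool_id!r}")
        for t1 in sorted(t1_pools):
            groups[t1] = sorted(p for p, t in self.tier1.items() if t == t1)
        return groups


@dataclass(frozen=True)
class ReadSimConfig:
    """Knobs for pooled paired-end read simulation."""

    read_length: int = 250
    mean_depth_per_pool: float = 3200.0
    error_rate: float = 0.002
    depth_dispersion: float = 0.5
    fragment_mean: float = 350.0
    fragment_sd: float = 100.0
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.mean_depth_per_pool < 0:
            raise ValueError("mean_depth_per_pool must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    """A PCR target region on one reference sequence (1-based inclusive)."""

    name: str
    seq_name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class Population:
    """Simulated plants with their mutation events and shared background sites."""

    plant_ids: list[str]
    events: dict[str, list[MutationEvent]]
    background_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    m1_family_size: int = 4

    def all_events(self):
        for plant in self.plant_ids:
            yield from self.events[plant]

    def genotype_at(self, plant_id: str, seq_name: str, pos: int):
        """(ref, alt, zygosity) for a plant at a site, or None if wild type.

        Background polymorphisms are carried homozygous by every plant.
        """
        for seq, p, ref, alt in self.background_sites:
            if seq == seq_name and p == pos:
                return ref, alt, "hom"
        for ev in self.events[plant_id]:
            if ev.seq_name == seq_name and ev.pos == pos:
                return ev.ref, ev.alt, ev.zygosity
        return None


@dataclass(frozen=True)
class TruthRecord:
    """One simulated variant with its carriers and the pools it lands in."""

    seq_name: str
    pos: int
    ref: str
    alt: str
    lines: tuple[str, ...]
    zygosities: tuple[str, ...]
    origin: str
    pools: tuple[str, ...]


@dataclass
class PoolReadSet:
    """Per-tier-2-pool reads plus the ground truth behind them."""

    reads: dict[str, list[ReadPair]]
    truth: list[TruthRecord]
    amplicons: list[Amplicon]

    def truth_in_amplicons(self, margin: int = 0) -> list[TruthRecord]:
        """Truth records inside the amplicons.

        ``margin`` excludes positions within that many bases of an amplicon
        boundary; with end-trimming of reads the outermost template bases
        are structurally unobservable (they are cut from every read), like
        the primer-proximal bases of a real amplicon.
        """
        out = []
        for rec in self.truth:
            for amp in self.amplicons:
                if (rec.seq_name == amp.seq_name
                        and amp.start + margin <= rec.pos <= amp.end - margin):
                    out.append(rec)
                    break
        return out


# ---------------------------------------------------------------------------
# reference construction


def _random_cds(rng: np.random.Generator, n_internal_codons: int) -> str:
    codons = []
    while len(codons) < n_internal_codons:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def build_toy_reference(n_genes: int, gene_length: int, seed: int = 0,
                        flank: int = 60, intron_length: int = 81) -> ReferenceSet:
    """Construct a toy reference: one gene per sequence, alternating strand.

    ``gene_length`` is the CDS length (start and stop codons included) and
    must be >= 60 and divisible by 3. Genes with a CDS of at least 120 bp
    are split into two CDS intervals by an intron so spliced-coordinate
    mapping is exercised. Genes alternate between '+' and '-' strands.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_length < 60 or gene_length % 3 != 0:
        raise ValueError("gene_length must be >= 60 and divisible by 3")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    for i in range(n_genes):
        seq_name = f"amp{i + 1:02d}"
        gene_id = f"gene{i + 1:02d}"
        strand = "+" if i % 2 == 0 else "-"
        cds = _random_cds(rng, gene_length // 3 - 2)
        oriented = cds if strand == "+" else revcomp(cds)
        left = "".join(rng.choice(list(BASES), flank))
        right = "".join(rng.choice(list(BASES), flank))
        if gene_length >= 120:
            # split the genomic CDS in two, in genomic orientation
            cut = (gene_length // 2) // 3 * 3 + 1  # keep a stable cut point
            intron = "".join(rng.choice(list(BASES), intron_length))
            part1, part2 = oriented[:cut], oriented[cut:]
            seq = left + part1 + intron + part2 + right
            s1 = flank + 1
            e1 = flank + len(part1)
            s2 = e1 + intron_length + 1
            e2 = s2 + len(part2) - 1
            intervals = ((s1, e1), (s2, e2))
        else:
            seq = left + oriented + right
            intervals = ((flank + 1, flank + gene_length),)
        sequences[seq_name] = seq
        models.append(GeneModel(gene_id, seq_name, strand, intervals, phase=0))
    ref = ReferenceSet(sequences, models)
    ref.validate()
    return ref


def amplicons_from_reference(reference: ReferenceSet) -> list[Amplicon]:
    """One amplicon spanning each full reference sequence."""
    return [Amplicon(name, name, 1, len(seq))
            for name, seq in reference.sequences.items()]


# ---------------------------------------------------------------------------
# population simulation


def expected_mutations_per_plant(per_round_density: float, genome_bp: int) -> float:
    """Analytic expectation of carried mutations per plant under the
    transmission model (two rounds, each event carried with probability 3/4)."""
    return 2 * 0.75 * per_round_density * genome_bp


def _eligible_positions(reference: ReferenceSet) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Positions (1-based) of each source base, per sequence."""
    out: dict[str, list[tuple[str, np.ndarray]]] = {b: [] for b in BASES}
    for name, seq in reference.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for b in BASES:
            pos = np.nonzero(arr == ord(b))[0] + 1
            if pos.size:
                out[b].append((name, pos))
    return out


class _SiteSampler:
    """Draws (class, seq, pos) sites following a substitution spectrum."""

    def __init__(self, reference: ReferenceSet, spectrum: SpectrumModel,
                 rng: np.random.Generator):
        self.rng = rng
        eligible = _eligible_positions(reference)
        self.classes = []
        probs = []
        self.sites: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}
        dropped = []
        for cls in SUBSTITUTION_CLASSES:
            p = spectrum.proportions[cls]
            if p <= 0:
                continue
            src = cls[0]
            chunks = eligible[src]
            if not chunks:
                dropped.append(cls)
                continue
            names: list[str] = []
            seq_idx = []
            positions = []
            for name, pos in chunks:
                idx = len(names)
                names.append(name)
                seq_idx.append(np.full(pos.size, idx))
                positions.append(pos)
            self.sites[cls] = (names, np.concatenate(seq_idx), np.concatenate(positions))
            self.classes.append(cls)
            probs.append(p)
        if dropped:
            warnings.warn(
                f"no eligible sites for substitution classes {dropped}; "
                "their probability mass is dropped",
                stacklevel=3,
            )
        total = sum(probs)
        self.total_mass = total
        self.probs = np.array(probs) / total if total > 0 else np.array([])

    def draw(self, n: int) -> list[tuple[str, str, int, str, str]]:
        """n sites as (class, seq_name, pos, ref, alt)."""
        if n == 0 or not self.classes:
            return []
        cls_idx = self.rng.choice(len(self.classes), size=n, p=self.probs)
        out = []
        for ci in cls_idx:
            cls = self.classes[ci]
            names, seq_idx, positions = self.sites[cls]
            j = self.rng.integers(positions.size)
            out.append((cls, names[seq_idx[j]], int(positions[j]), cls[0], cls[2]))
        return out


def _draw_unique_sites(sampler: _SiteSampler, n: int, taken: set,
                       max_attempts_factor: int = 100):
    """Draw n sites avoiding (seq, pos) already in `taken`; error on too
    many collisions."""
    if not sampler.classes:
        return []
    out = []
    attempts = 0
    budget = max(1, n) * max_attempts_factor
    while len(out) < n:
        need = n - len(out)
        attempts += need
        if attempts > budget:
            raise RuntimeError(
                "mutation density too high: site collision redraws exceeded "
                f"{max_attempts_factor}x the target count"
            )
        for site in sampler.draw(need):
            _, seq, pos, _, _ = site
            if (seq, pos) in taken:
                continue
            taken.add((seq, pos))
            out.append(site)
            if len(out) == n:
                break
    return out


def simulate_population(
    reference: ReferenceSet,
    n_plants: int = 1536,
    spectrum: SpectrumModel | None = None,
    per_round_density: float = 1e-4,
    m1_family_size: int = 4,
    seed: int = 0,
    n_background_polymorphisms: int = 0,
) -> Population:
    """Simulate a doubly mutagenized selfing population.

    Round-1 mutations are drawn once per M1 family (``n_plants`` must be a
    multiple of ``m1_family_size``) and transmitted to each descendant with
    probability 3/4, homozygous:heterozygous 1:2 given transmission.
    Round-2 mutations are drawn per plant and kept under the same 1:2:1
    selfing segregation (carried with probability 3/4). ``per_round_density``
    is the expected number of *drawn* events per bp per round; see
    :func:`expected_mutations_per_plant` for the carried expectation.
    Optionally plants share ``n_background_polymorphisms`` homozygous
    cultivar polymorphisms at sites disjoint from induced mutations.
    """
    if per_round_density <= 0:
        raise ValueError("per_round_density must be positive")
    if n_plants < 1 or n_plants % m1_family_size != 0:
        raise ValueError("n_plants must be a positive multiple of m1_family_size")
    reference.validate()
    spectrum = spectrum or SpectrumModel.default()
    rng = np.random.default_rng(seed)
    sampler = _SiteSampler(reference, spectrum, rng)
    genome_bp = reference.total_bp
    lam = per_round_density * genome_bp

    plant_ids = [f"L{i + 1:04d}" for i in range(n_plants)]
    events: dict[str, list[MutationEvent]] = {p: [] for p in plant_ids}

    background: list[tuple[str, int, str, str]] = []
    taken_global: set = set()
    if n_background_polymorphisms:
        uniform = SpectrumModel({c: 1 / 12 for c in SUBSTITUTION_CLASSES})
        bg_sampler = _SiteSampler(reference, uniform, rng)
        for _, seq, pos, ref_b, alt in _draw_unique_sites(
                bg_sampler, n_background_polymorphisms, taken_global):
            background.append((seq, pos, ref_b, alt))

    n_families = n_plants // m1_family_size
    for fam in range(n_families):
        members = plant_ids[fam * m1_family_size:(fam + 1) * m1_family_size]
        fam_taken = set(taken_global)
        n1 = rng.poisson(lam)
        fam_sites = _draw_unique_sites(sampler, n1, fam_taken)
        for _, seq, pos, ref_b, alt in fam_sites:
            for plant in members:
                if rng.random() < 0.75:
                    zyg = "hom" if rng.random() < 1 / 3 else "het"
                    events[plant].append(
                        MutationEvent(plant, seq, pos, ref_b, alt, zyg, "round1"))
        for plant in members:
            plant_taken = set(fam_taken)
            n2 = rng.poisson(lam)
            for _, seq, pos, ref_b, alt in _draw_unique_sites(sampler, n2, plant_taken):
                if rng.random() < 0.75:
                    zyg = "hom" if rng.random() < 1 / 3 else "het"
                    events[plant].append(
                        MutationEvent(plant, seq, pos, ref_b, alt, zyg, "round2"))
    for plant in plant_ids:
        events[plant].sort(key=lambda ev: (ev.seq_name, ev.pos))
    return Population(plant_ids, events, background, m1_family_size)


# ---------------------------------------------------------------------------
# pooling layout


def build_layout(n_plants: int, tier1_size: int = 4, tier2_size: int = 4,
                 plant_ids: list[str] | None = None, pad: bool = False) -> PoolingLayout:
    """Assign plants to tier-1 pools (``tier1_size`` plants each) and tier-1
    pools to tier-2 pools (``tier2_size`` tier-1 pools each), in order."""
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    block = tier1_size * tier2_size
    if plant_ids is not None and len(plant_ids) != n_plants:
        raise ValueError("plant_ids length must equal n_plants")
    ids = list(plant_ids) if plant_ids is not None else [
        f"L{i + 1:04d}" for i in range(n_plants)]
    if n_plants % block != 0:
        if not pad:
            raise ValueError(
                f"n_plants={n_plants} not divisible by "
                f"tier1_size*tier2_size={block}; enable pad to fill with blanks")
        n_pad = block - n_plants % block
        ids += [f"PAD{i + 1:04d}" for i in range(n_pad)]
    tier1: dict[str, str] = {}
    tier2: dict[str, str] = {}
    for i, plant in enumerate(ids):
        t1 = f"t1_{i // tier1_size + 1:04d}"
        t2 = f"pool{i // block + 1:03d}"
        tier1[plant] = t1
        tier2[t1] = t2
    return PoolingLayout(len(ids), tier1_size, tier2_size, tier1, tier2)


DEFAULT_I7_LABELS = tuple(f"N7{i:02d}" for i in range(1, 13))
DEFAULT_I5_LABELS = tuple(f"S5{i:02d}" for i in range(1, 9))


def assign_indexes(layout: PoolingLayout,
                   i7_labels=DEFAULT_I7_LABELS,
                   i5_labels=DEFAULT_I5_LABELS) -> PoolingLayout:
    """Assign a unique (i7, i5) dual-index pair to each tier-2 pool,
    row-major over i7 then i5."""
    pools = layout.tier2_pools
    if len(i7_labels) * len(i5_labels) < len(pools):
        raise ValueError(
            f"{len(i7_labels)}x{len(i5_labels)} index labels cannot cover "
            f"{len(pools)} pools")
    pairs = {}
    for k, pool in enumerate(pools):
        pairs[pool] = (i7_labels[k // len(i5_labels)], i5_labels[k % len(i5_labels)])
    return replace(layout, index_pairs=pairs)


# ---------------------------------------------------------------------------
# pooled read simulation


def _depth_weights(length: int, dispersion: float, rng: np.random.Generator,
                   window: int = 50) -> np.ndarray:
    """Smooth multiplicative depth field, lower near amplicon ends."""
    noise = rng.normal(0.0, 1.0, length)
    if length >= window:
        kernel = np.ones(window) / window
        smooth = np.convolve(noise, kernel, mode="same")
        # restore unit variance lost to averaging
        smooth *= np.sqrt(window)
    else:
        smooth = noise
    mult = np.exp(dispersion * smooth)
    idx = np.arange(length, dtype=float)
    left = 0.3 + 0.7 * np.minimum(1.0, (idx + 1) / window)
    right = 0.3 + 0.7 * np.minimum(1.0, (length - idx) / window)
    mult *= left * right
    return mult / mult.sum()


def _apply_mutations(base: np.ndarray, muts, which_hap: dict, hap: int,
                     amp_start: int) -> np.ndarray:
    seq = base.copy()
    for ev in muts:
        if ev.zygosity == "hom" or which_hap[(ev.pos, ev.alt)] == hap:
            seq[ev.pos - amp_start] = ord(ev.alt)
    return seq


def simulate_pool_reads(
    reference: ReferenceSet,
    amplicons: list[Amplicon],
    population: Population,
    layout: PoolingLayout,
    config: ReadSimConfig,
) -> PoolReadSet:
    """Draw paired-end reads for every tier-2 pool over every amplicon.

    Reads are drawn uniformly from the ``2 * pool_size`` haplotypes of the
    pool, so a heterozygous mutation carried by one plant of a 16-plant
    pool has expected allele fraction 1/32. Fragment centers follow a
    seeded smooth depth field; fragment orientation is random so both
    strands are observed.
    """
    reference.validate()
    for amp in amplicons:
        if amp.seq_name not in reference.sequences:
            raise ValueError(f"amplicon {amp.name}: unknown sequence {amp.seq_name}")
        if amp.start < 1 or amp.end > len(reference.sequences[amp.seq_name]):
            raise ValueError(f"amplicon {amp.name}: outside reference")
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    qual = chr(33 + config.base_quality)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)

    reads: dict[str, list[ReadPair]] = {}
    pools_of_variant: dict[tuple[str, int, str, str], set[str]] = {}

    for pool_id in layout.tier2_pools:
        groups = layout.plants_in_tier2(pool_id)
        plants = [p for grp in groups.values() for p in grp]
        real_plants = [p for p in plants if p in population.events]
        if not real_plants:
            raise ValueError(f"tier-2 pool {pool_id} contains no plants")
        pair_list: list[ReadPair] = []
        for amp in amplicons:
            amp_seq = reference.sequences[amp.seq_name][amp.start - 1:amp.end]
            base = np.frombuffer(amp_seq.encode(), dtype=np.uint8).copy()
            for seq, pos, _, alt in population.background_sites:
                if seq == amp.seq_name and amp.start <= pos <= amp.end:
                    base[pos - amp.start] = ord(alt)
            haplotypes = []
            for plant in real_plants:
                muts = [ev for ev in population.events[plant]
                        if ev.seq_name == amp.seq_name and amp.start <= ev.pos <= amp.end]
                for ev in muts:
                    key = (ev.seq_name, ev.pos, ev.ref, ev.alt)
                    pools_of_variant.setdefault(key, set()).add(pool_id)
                which_hap = {(ev.pos, ev.alt): int(rng.integers(2)) for ev in muts}
                for hap in (0, 1):
                    haplotypes.append(
                        _apply_mutations(base, muts, which_hap, hap, amp.start)
                        if muts else base)
            L = amp.length
            n_pairs = int(round(config.mean_depth_per_pool * L / (2.0 * rl)))
            if n_pairs == 0:
                continue
            weights = _depth_weights(L, config.depth_dispersion, rng)
            centers = rng.choice(L, size=n_pairs, p=weights)
            frag_lens = np.clip(
                np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)),
                min(L, rl), L).astype(int)
            starts = np.clip(centers - frag_lens // 2, 0, L - frag_lens)
            hap_idx = rng.integers(0, len(haplotypes), n_pairs)
            flips = rng.random(n_pairs) < 0.5
            for i in range(n_pairs):
                frag = haplotypes[hap_idx[i]][starts[i]:starts[i] + frag_lens[i]]
                fwd = frag[:rl]
                rev = np.frombuffer(
                    revcomp(frag.tobytes().decode()).encode(), dtype=np.uint8)[:rl]
                r1, r2 = (rev, fwd) if flips[i] else (fwd, rev)
                if config.error_rate > 0:
                    r1 = _inject_errors(r1, config.error_rate, rng, base_codes)
                    r2 = _inject_errors(r2, config.error_rate, rng, base_codes)
                name = f"{pool_id}:{amp.name}:{i}"
                pair_list.append(ReadPair(
                    name,
                    r1.tobytes().decode(), qual * len(r1),
                    r2.tobytes().decode(), qual * len(r2)))
        reads[pool_id] = pair_list

    truth = _collect_truth(population, layout, pools_of_variant)
    return PoolReadSet(reads, truth, list(amplicons))


def _inject_errors(read: np.ndarray, rate: float, rng: np.random.Generator,
                   base_codes: np.ndarray) -> np.ndarray:
    n_err = rng.binomial(read.size, rate)
    if n_err == 0:
        return read
    out = read.copy()
    pos = rng.choice(read.size, size=n_err, replace=False)
    for p in pos:
        choices = base_codes[base_codes != out[p]]
        out[p] = rng.choice(choices)
    return out


def _collect_truth(population: Population, layout: PoolingLayout,
                   pools_of_variant) -> list[TruthRecord]:
    carriers: dict[tuple[str, int, str, str], list[tuple[str, str, str]]] = {}
    for ev in population.all_events():
        key = (ev.seq_name, ev.pos, ev.ref, ev.alt)
        carriers.setdefault(key, []).append((ev.line_id, ev.zygosity, ev.origin))
    records = []
    for key, members in sorted(carriers.items()):
        seq, pos, ref, alt = key
        lines = tuple(m[0] for m in members)
        zygs = tuple(m[1] for m in members)
        origin = members[0][2]
        pools = pools_of_variant.get(key)
        if pools is None:
            pools = {layout.tier2_of_plant(line) for line in lines
                     if line in layout.tier1}
        records.append(TruthRecord(seq, pos, ref, alt, lines, zygs, origin,
                                   tuple(sorted(pools))))
    for seq, pos, ref, alt in sorted(population.background_sites):
        pools = tuple(layout.tier2_pools)
        records.append(TruthRecord(
            seq, pos, ref, alt, ("*",), ("hom",), "background", pools))
    records.sort(key=lambda r: (r.seq_name, r.pos, r.alt))
    return records
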