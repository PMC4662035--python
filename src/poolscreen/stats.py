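"""Mutation summaries: deduplication, spectra, densities, method comparison.

All percentages and densities reported here use round-half-away-from-zero
at the stated number of decimals, matching the conventions of printed
mutant-library summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from poolscreen.effects import TRANSITIONS, TRANSVERSIONS, classify_substitution

#: Chromosome-scale assembly size used to extrapolate per-plant counts.
DEFAULT_GENOME_BP = 950_068_807
DEFAULT_N_PLANTS = 1536


def round_half_away(x: float, ndigits: int = 0):
    """Round half away from zero; returns int when ndigits == 0."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(d) if ndigits == 0 else float(d)


# ---------------------------------------------------------------------------
# records and deduplication


@dataclass(frozen=True)
class MutationRecord:
    """One screened mutation in one line, as reported by a retrieval method."""

    line_id: str
    seq_name: str
    pos: int
    ref: str
    alt: str
    zygosity: str = ""
    region: str = ""
    amplicon_size: int = 0
    substitution: str = ""  # e.g. "Asp20Asn" or "Syn"

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.seq_name, self.pos, self.alt)


def _site_of(record) -> tuple[str, int, str]:
    if hasattr(record, "site"):
        return record.site
    return (record.seq_name, record.pos, record.alt)


def deduplicate(records: Sequence) -> tuple[list, dict]:
    """Collapse records sharing (seq_name, pos, alt).

    Returns ``(unique, groups)`` where ``unique`` holds one representative
    per site ordered by position and ``groups`` maps each site to all its
    member records. Records at the same position with different alt
    alleles stay distinct.
    """
    groups: dict[tuple[str, int, str], list] = {}
    for rec in records:
        groups.setdefault(_site_of(rec), []).append(rec)
    unique = [members[0] for site, members in sorted(groups.items())]
    return unique, groups


# ---------------------------------------------------------------------------
# densities and expectations


@dataclass(frozen=True)
class DensityReport:
    n_unique_mutations: int
    region_bp: int
    mutations_per_kb: float
    kb_per_mutation: float | None
    genome_bp: int = DEFAULT_GENOME_BP
    n_plants: int = DEFAULT_N_PLANTS


def mutation_density_per_kb(n_unique: int, region_bp: int) -> float:
    """Mutations per kilobase over a screened region, one decimal."""
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    return round_half_away(n_unique / region_bp * 1000.0, 1)


def distance_between_changes(n_changes: int, genome_bp: int = DEFAULT_GENOME_BP
                             ) -> tuple[float, int]:
    """Average kb between base changes given a per-plant genome-wide count.

    Returns the distance both at one decimal and as the nearest integer.
    """
    if n_changes <= 0:
        raise ValueError("n_changes must be positive")
    kb = genome_bp / n_changes / 1000.0
    return round_half_away(kb, 1), round_half_away(kb, 0)


def expected_per_plant(n_changes_in_library: int, region_bp: int,
                       genome_bp: int = DEFAULT_GENOME_BP,
                       n_plants: int = DEFAULT_N_PLANTS) -> int:
    """Genome-wide base changes expected per plant, extrapolated from the
    number found in the library over a screened region."""
    if region_bp <= 0 or genome_bp <= 0 or n_plants <= 0:
        raise ValueError("region_bp, genome_bp and n_plants must be positive")
    return round_half_away(
        n_changes_in_library / region_bp * genome_bp / n_plants, 0)


def density_report(n_unique: int, region_bp: int,
                   genome_bp: int = DEFAULT_GENOME_BP,
                   n_plants: int = DEFAULT_N_PLANTS) -> DensityReport:
    per_kb = mutation_density_per_kb(n_unique, region_bp)
    kb_per = (round_half_away(region_bp / n_unique / 1000.0, 1)
              if n_unique > 0 else None)
    return DensityReport(n_unique, region_bp, per_kb, kb_per, genome_bp, n_plants)


def min_detectable_allele_fraction(n_plants_in_pool: int, zygosity: str,
                                   ploidy: int = 2) -> float:
    """Expected allele fraction of a single mutant plant in a DNA pool.

    A heterozygote contributes 1 of the ploidy * n chromosome copies in
    the pool; a homozygote contributes ploidy copies.
    """
    if n_plants_in_pool < 1:
        raise ValueError("pool size must be >= 1")
    if zygosity == "het":
        return 1.0 / (ploidy * n_plants_in_pool)
    if zygosity == "hom":
        return 1.0 / n_plants_in_pool
    raise ValueError(f"bad zygosity {zygosity!r}")


# ---------------------------------------------------------------------------
# spectrum summary


@dataclass(frozen=True)
class SpectrumSummary:
    counts: dict[str, int]
    total: int
    percentages: dict[str, float]  # one decimal per input category
    transitions: int
    transversions: int
    ts_tv_ratio: float | None  # two decimals; None when transversions == 0


def _category_kind(category: str) -> str:
    """transition/transversion kind of a class or '+'-joined class group."""
    kinds = set()
    for cls in category.split("+"):
        cls = cls.strip()
        if cls in TRANSITIONS:
            kinds.add("transition")
        elif cls in TRANSVERSIONS:
            kinds.add("transversion")
        else:
            raise ValueError(f"unknown substitution class {cls!r}")
    if len(kinds) != 1:
        raise ValueError(f"category {category!r} mixes transitions and transversions")
    return kinds.pop()


def spectrum_summary(mutations) -> SpectrumSummary:
    """Summarize substitution classes.

    ``mutations`` is either an iterable of objects with ``ref``/``alt``
    attributes (or bare (ref, alt) pairs), or a mapping from substitution
    category to count, where a category is a class like ``"G>A"`` or a
    homogeneous group like ``"G>A+C>T"``.
    """
    if isinstance(mutations, dict):
        counts = {k: int(v) for k, v in mutations.items()}
    else:
        counts = {}
        for m in mutations:
            ref, alt = (m.ref, m.alt) if hasattr(m, "ref") else m
            cls, _ = classify_substitution(ref, alt)
            counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    ts = sum(c for cat, c in counts.items() if _category_kind(cat) == "transition")
    tv = total - ts
    percentages = {cat: round_half_away(100.0 * c / total, 1) if total else 0.0
                   for cat, c in counts.items()}
    ratio = round_half_away(ts / tv, 2) if tv > 0 else None
    return SpectrumSummary(counts, total, percentages, ts, tv, ratio)


# ---------------------------------------------------------------------------
# method comparison


@dataclass(frozen=True)
class GeneDetectionRow:
    gene: str
    region_bp: int
    total: int
    common: int
    a_only: int
    b_only: int
    pct_a: float  # rounded to one decimal
    pct_b: float
    pct_a_raw: float = field(repr=False, default=0.0)
    pct_b_raw: float = field(repr=False, default=0.0)


@dataclass(frozen=True)
class DetectionComparison:
    rows: list[GeneDetectionRow]
    total: int
    common: int
    a_only: int
    b_only: int
    #: unweighted mean of the per-gene unrounded percentages, one decimal
    pct_a: float
    pct_b: float
    #: pooled-count percentages for transparency
    pct_a_pooled: float
    pct_b_pooled: float


def _gene_row(gene: str, region_bp: int, total: int, common: int,
              a_only: int, b_only: int) -> GeneDetectionRow:
    pct_a_raw = 100.0 * (common + a_only) / total
    pct_b_raw = 100.0 * (common + b_only) / total
    return GeneDetectionRow(gene, region_bp, total, common, a_only, b_only,
                            round_half_away(pct_a_raw, 1),
                            round_half_away(pct_b_raw, 1),
                            pct_a_raw, pct_b_raw)


def _totals(rows: list[GeneDetectionRow]) -> DetectionComparison:
    if not rows:
        raise ValueError("no gene rows to compare")
    total = sum(r.total for r in rows)
    common = sum(r.common for r in rows)
    a_only = sum(r.a_only for r in rows)
    b_only = sum(r.b_only for r in rows)
    pct_a = round_half_away(sum(r.pct_a_raw for r in rows) / len(rows), 1)
    pct_b = round_half_away(sum(r.pct_b_raw for r in rows) / len(rows), 1)
    return DetectionComparison(
        rows, total, common, a_only, b_only, pct_a, pct_b,
        round_half_away(100.0 * (common + a_only) / total, 1),
        round_half_away(100.0 * (common + b_only) / total, 1))


def compare_detection(calls_a: dict[str, set], calls_b: dict[str, set],
                      region_bp: dict[str, int]) -> DetectionComparison:
    """Per-gene and overall agreement between two call sets.

    ``calls_a``/``calls_b`` map gene id to a set of (pos, alt)-style keys.
    The totals row sums counts but averages the per-gene unrounded
    percentages (unweighted), which is how mixed-length gene panels are
    conventionally summarized; pooled-count percentages are also carried.
    Genes whose union is empty are skipped.
    """
    rows = []
    for gene in sorted(set(calls_a) | set(calls_b)):
        a = set(calls_a.get(gene, ()))
        b = set(calls_b.get(gene, ()))
        if not a | b:
            import warnings

            warnings.warn(f"gene {gene}: no calls in either set, skipped")
            continue
        common = len(a & b)
        rows.append(_gene_row(gene, region_bp.get(gene, 0), len(a | b),
                              common, len(a - b), len(b - a)))
    return _totals(rows)


def detection_comparison_from_counts(
        gene_counts: dict[str, tuple[int, int, int, int]],
        region_bp: dict[str, int] | None = None) -> DetectionComparison:
    """Build a comparison from per-gene (total, common, a_only, b_only)."""
    region_bp = region_bp or {}
    rows = []
    for gene, (total, common, a_only, b_only) in gene_counts.items():
        if total != common + a_only + b_only:
            raise ValueError(f"gene {gene}: total != common + a_only + b_only")
        rows.append(_gene_row(gene, region_bp.get(gene, 0), total, common,
                              a_only, b_only))
    return _totals(rows)


# ---------------------------------------------------------------------------
# per-line screening report


@dataclass(frozen=True)
class ScreenReportRow:
    line_id: str
    region: str
    amplicon_size: int
    base_change: str
    zygosity: str
    seq_name: str
    pos: int
    substitution: str
    duplicate_tag: str  # "", "a", "b", ...


def _letters():
    i = 0
    while True:
        # a, b, ..., z, aa, ab, ...
        n, out = i, ""
        while True:
            out = chr(ord("a") + n % 26) + out
            n = n // 26 - 1
            if n < 0:
                break
        yield out
        i += 1


def screen_report(records: Sequence[MutationRecord]) -> list[ScreenReportRow]:
    """Rows sorted by position; duplicated sites lettered a, b, ... in
    positional order."""
    ordered = sorted(records, key=lambda r: (r.seq_name, r.pos, r.alt, r.line_id))
    _, groups = deduplicate(ordered)
    tags: dict[tuple[str, int, str], str] = {}
    letters = _letters()
    for site, members in sorted(groups.items()):
        if len(members) > 1:
            tags[site] = next(letters)
    return [ScreenReportRow(
        r.line_id, r.region, r.amplicon_size, f"{r.ref}>{r.alt}", r.zygosity,
        r.seq_name, r.pos, r.substitution, tags.get(r.site, ""))
        for r in ordered]
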