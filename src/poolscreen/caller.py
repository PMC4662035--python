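"""Low-frequency single-nucleotide variant calling in indexed pools.

A pool column yields a PASS call for an alternative allele when the column
coverage, alternative read count, alternative allele fraction, and
both-strand support all clear their thresholds. The default frequency
threshold is exactly 2/96 — two variant reads at the minimum accepted pool
coverage of 96 reads — so the limiting case itself passes. Quality gating
happens per read at pileup time (see :mod:`poolscreen.readprep`): bases
failing the quality predicates contribute to coverage but not to variant
evidence; calls rescued only by unqualified bases are flagged QUALITY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from poolscreen.readprep import StrandedPileup

_BASES = "ACGT"


@dataclass(frozen=True)
class CallerConfig:
    min_coverage: int = 96
    min_alt_reads: int = 2
    min_frequency: float = 2.0 / 96.0
    require_both_strands: bool = True
    central_quality_min: int = 20
    neighborhood_radius: int = 5
    neighborhood_quality_min: int = 15
    max_mismatches_in_window: int = 2
    max_alt_alleles: int = 4

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.min_frequency < 1:
            raise ValueError("min_frequency must be in (0, 1)")

    def alt_reads_required(self, coverage: int) -> int:
        """Smallest alt-read count passing both count and fraction thresholds."""
        by_freq = math.ceil(self.min_frequency * coverage - 1e-12)
        return max(self.min_alt_reads, by_freq)


#: Per-line stringent calling: stand-in for a probabilistic caller at
#: "coverage >= 5, variant probability 40 %" (allele fraction used as the
#: probability proxy).
LINE_STRINGENT = CallerConfig(
    min_coverage=5, min_alt_reads=1, min_frequency=0.40,
    require_both_strands=True, max_alt_alleles=4)

#: Per-line relaxed calling: "coverage >= 2, variant probability 10 %,
#: maximum expected variants four"; no strand requirement.
LINE_RELAXED = CallerConfig(
    min_coverage=2, min_alt_reads=1, min_frequency=0.10,
    require_both_strands=False, max_alt_alleles=4)


@dataclass(frozen=True)
class PoolVariantCall:
    pool_id: str
    seq_name: str
    pos: int  # 1-based
    ref: str
    alt: str
    coverage: int
    alt_count_f: int
    alt_count_r: int
    frequency: float
    filter_status: str  # PASS | LOW_COV | LOW_FREQ | STRAND | QUALITY

    @property
    def alt_count(self) -> int:
        return self.alt_count_f + self.alt_count_r

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.seq_name, self.pos, self.alt)


def _status(coverage: int, alt_f: int, alt_r: int, config: CallerConfig) -> str:
    alt = alt_f + alt_r
    if coverage < config.min_coverage:
        return "LOW_COV"
    if alt < config.min_alt_reads or (coverage > 0 and alt / coverage < config.min_frequency):
        return "LOW_FREQ"
    if config.require_both_strands and (alt_f < 1 or alt_r < 1):
        return "STRAND"
    return "PASS"


def call_pool_variants(pileup: StrandedPileup, config: CallerConfig | None = None,
                       pool_id: str = "pool") -> list[PoolVariantCall]:
    """Evaluate every column of a stranded pileup.

    Emits one record per (column, alternative allele) with at least one
    supporting read, at most ``max_alt_alleles`` per column ranked by
    qualified support (ties by base order). Indels are never emitted.
    """
    config = config or CallerConfig()
    calls: list[PoolVariantCall] = []
    depth = pileup.raw.sum(axis=(0, 1))
    for i in np.nonzero(depth > 0)[0]:
        ref_b = pileup.ref[i]
        cov = int(depth[i])
        alts = []
        for bi, base in enumerate(_BASES):
            if base == ref_b:
                continue
            raw_f = int(pileup.raw[bi, 0, i])
            raw_r = int(pileup.raw[bi, 1, i])
            if raw_f + raw_r == 0:
                continue
            q_f = int(pileup.qualified[bi, 0, i])
            q_r = int(pileup.qualified[bi, 1, i])
            alts.append((base, q_f, q_r, raw_f, raw_r))
        alts.sort(key=lambda a: (-(a[1] + a[2]), a[0]))
        for base, q_f, q_r, raw_f, raw_r in alts[:config.max_alt_alleles]:
            status = _status(cov, q_f, q_r, config)
            if status != "PASS" and _status(cov, raw_f, raw_r, config) == "PASS":
                status = "QUALITY"
            calls.append(PoolVariantCall(
                pool_id, pileup.seq_name, int(i) + 1, ref_b, base, cov,
                q_f, q_r, (q_f + q_r) / cov if cov else 0.0, status))
    return calls


def call_line_variants(pileup: StrandedPileup, relaxed: bool = False,
                       line_id: str = "line") -> list[PoolVariantCall]:
    """Per-line (non-pooled) calling with stringent or relaxed thresholds."""
    config = LINE_RELAXED if relaxed else LINE_STRINGENT
    return call_pool_variants(pileup, config, pool_id=line_id)


def passing_sites(calls: list[PoolVariantCall]) -> set[tuple[str, int, str]]:
    return {c.site for c in calls if c.filter_status == "PASS"}


# ---------------------------------------------------------------------------
# detection power


def _both_strand_prob(k: np.ndarray) -> np.ndarray:
    """P(at least one of k alt reads on each strand), strands i.i.d. 1/2."""
    with np.errstate(over="ignore"):
        p = 1.0 - 2.0 * 0.5 ** k
    return np.where(k >= 1, p, 0.0)


def detection_power(pool_size: int, zygosity: str, coverage: int,
                    error_rate: float = 0.0,
                    config: CallerConfig | None = None,
                    ploidy: int = 2) -> float:
    """Exact probability that a true mutant in the pool yields a PASS call.

    The mutant allele fraction is 1/(ploidy*pool_size) for a heterozygous
    carrier and 1/pool_size for a homozygous one; sequencing errors add
    ``error_rate/3`` to the mutant allele's effective fraction. Alt reads
    fall on each strand independently with probability 1/2.
    """
    config = config or CallerConfig()
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if coverage < 1 or coverage < config.min_coverage:
        return 0.0
    if zygosity == "het":
        f = 1.0 / (ploidy * pool_size)
    elif zygosity == "hom":
        f = 1.0 / pool_size
    else:
        raise ValueError(f"bad zygosity {zygosity!r}")
    f = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
    return _pass_probability(coverage, f, config)


def false_call_probability(coverage: int, error_rate: float,
                           config: CallerConfig | None = None) -> float:
    """Probability a mutation-free column yields a PASS call for one given
    alternative base, whose reads arise from errors at rate error_rate/3."""
    config = config or CallerConfig()
    if coverage < 1 or coverage < config.min_coverage:
        return 0.0
    return _pass_probability(coverage, error_rate / 3.0, config)


def _pass_probability(coverage: int, allele_fraction: float,
                      config: CallerConfig) -> float:
    k_req = config.alt_reads_required(coverage)
    k = np.arange(coverage + 1)
    pmf = sp_stats.binom.pmf(k, coverage, allele_fraction)
    ok = k >= k_req
    strand = _both_strand_prob(k) if config.require_both_strands else np.ones_like(k, float)
    return float((pmf * ok * strand).sum())
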