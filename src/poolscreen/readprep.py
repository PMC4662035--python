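"""Read cleaning and gapless alignment into stranded pileups.

Trimming removes fixed terminal bases, applies modified-Mott quality
trimming at an error-probability limit, drops reads with too many
ambiguous bases, and discards pairs whose surviving mates are too short.
Alignment is exact-match 31-mer seeding plus ungapped extension; accepted
reads accumulate per-strand base counts. Bases failing per-read quality
predicates (central quality, neighborhood quality, neighborhood mismatch
count) still count toward coverage but not toward variant evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from poolscreen.simulate import ReadPair, revcomp

_BASE_INDEX = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}


@dataclass(frozen=True)
class TrimConfig:
    quality_limit: float = 0.01  # error-probability threshold for Mott trimming
    ambiguous_limit: int = 2  # max N per read
    end_trim: int = 3  # nt removed from each end
    min_pair_length: int = 50  # min surviving length per mate

    def __post_init__(self) -> None:
        if (self.quality_limit < 0 or self.ambiguous_limit < 0
                or self.end_trim < 0 or self.min_pair_length < 0):
            raise ValueError("trim parameters must be non-negative")


@dataclass
class TrimReport:
    pairs_in: int = 0
    pairs_out: int = 0
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0


def _quality_error_probs(qual: str) -> np.ndarray:
    phred = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33.0
    return 10.0 ** (-phred / 10.0)


def _mott_trim(seq: str, qual: str, limit: float) -> tuple[str, str]:
    """Keep the contiguous segment maximizing sum(limit - p_error)."""
    if not seq:
        return "", ""
    score = limit - _quality_error_probs(qual)
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for i, s in enumerate(score):
        run_sum += s
        if run_sum <= 0.0:
            run_sum = 0.0
            run_start = i + 1
        elif run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    return seq[best[0]:best[1]], qual[best[0]:best[1]]


def _trim_one(seq: str, qual: str, config: TrimConfig) -> tuple[str, str]:
    t = config.end_trim
    seq, qual = seq[t:len(seq) - t], qual[t:len(qual) - t]
    return _mott_trim(seq, qual, config.quality_limit)


def trim_reads(pairs: list[ReadPair], config: TrimConfig | None = None
               ) -> tuple[list[ReadPair], TrimReport]:
    """Clean read pairs; a pair survives only if both mates do."""
    config = config or TrimConfig()
    report = TrimReport()
    out: list[ReadPair] = []
    for pair in pairs:
        report.pairs_in += 1
        report.reads_in += 2
        report.bases_in += len(pair.seq1) + len(pair.seq2)
        s1, q1 = _trim_one(pair.seq1, pair.qual1, config)
        s2, q2 = _trim_one(pair.seq2, pair.qual2, config)
        if s1.count("N") > config.ambiguous_limit or s2.count("N") > config.ambiguous_limit:
            continue
        if len(s1) < config.min_pair_length or len(s2) < config.min_pair_length:
            continue
        out.append(ReadPair(pair.name, s1, q1, s2, q2))
        report.pairs_out += 1
        report.reads_out += 2
        report.bases_out += len(s1) + len(s2)
    return out, report


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignConfig:
    seed_length: int = 31
    min_length_fraction: float = 0.9
    min_identity: float = 0.96
    # per-read base-quality predicates (evidence gating, CLC-style)
    central_quality_min: int = 20
    neighborhood_radius: int = 5
    neighborhood_quality_min: int = 15
    max_mismatches_in_window: int = 2


@dataclass
class AlignStats:
    reads_in: int = 0
    placed: int = 0
    unmapped: int = 0
    nonspecific: int = 0
    low_identity: int = 0
    broken_pair: int = 0

    @property
    def excluded(self) -> int:
        return self.unmapped + self.nonspecific + self.low_identity + self.broken_pair


class StrandedPileup:
    """Per-position, per-strand base counts over one reference sequence.

    ``raw`` counts every placed base; ``qualified`` counts only bases
    passing the per-read quality predicates. Shapes are (4 bases, 2
    strands, length) with strand 0 = forward, 1 = reverse.
    """

    def __init__(self, seq_name: str, ref: str):
        self.seq_name = seq_name
        self.ref = ref
        self.ref_codes = np.frombuffer(ref.encode(), dtype=np.uint8)
        L = len(ref)
        self.raw = np.zeros((4, 2, L), dtype=np.int64)
        self.qualified = np.zeros((4, 2, L), dtype=np.int64)
        self.qual_sum = np.zeros((4, 2, L), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ref)

    def depth(self) -> np.ndarray:
        return self.raw.sum(axis=(0, 1))

    def column(self, pos: int) -> dict:
        """Counts at a 1-based position as {(base, strand): raw count}."""
        i = pos - 1
        counts = {}
        for bi, base in enumerate("ACGT"):
            for si, strand in enumerate("FR"):
                counts[(base, strand)] = int(self.raw[bi, si, i])
        return {"seq_name": self.seq_name, "pos": pos, "ref": self.ref[i],
                "counts": counts, "coverage": int(self.raw[:, :, i].sum())}

    def add_read(self, start0: int, read: np.ndarray, quals: np.ndarray,
                 strand: int, config: AlignConfig) -> None:
        """Accumulate one placed read (already in reference orientation)."""
        L = len(self.ref)
        lo = max(0, -start0)
        hi = min(len(read), L - start0)
        if hi <= lo:
            return
        read = read[lo:hi]
        quals = quals[lo:hi]
        pos = np.arange(start0 + lo, start0 + hi)
        mismatch = (read != self.ref_codes[pos]).astype(float)
        win = 2 * config.neighborhood_radius + 1
        kernel = np.ones(win)
        counts = np.convolve(np.ones_like(mismatch), kernel, mode="same")
        mm_window = np.convolve(mismatch, kernel, mode="same")
        q_window = np.convolve(quals.astype(float), kernel, mode="same") / counts
        ok = ((quals >= config.central_quality_min)
              & (q_window >= config.neighborhood_quality_min)
              & (mm_window <= config.max_mismatches_in_window))
        base_idx = np.full(read.size, -1)
        for code, bi in _BASE_INDEX.items():
            base_idx[read == code] = bi
        keep = base_idx >= 0
        bi = base_idx[keep]
        pk = pos[keep]
        np.add.at(self.raw[:, strand, :], (bi, pk), 1)
        qk = ok[keep]
        np.add.at(self.qualified[:, strand, :], (bi[qk], pk[qk]), 1)
        np.add.at(self.qual_sum[:, strand, :], (bi, pk), quals[keep])


def _build_seed_index(references: dict[str, str], k: int) -> dict[str, list]:
    index: dict[str, list] = {}
    for name, seq in references.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((name, i))
    return index


def _place_read(seq: str, index: dict, references: dict[str, str],
                config: AlignConfig):
    """Best gapless placement or a failure reason.

    Returns (seq_name, start0, strand, oriented_read) on success, else a
    string in {"unmapped", "low_identity", "nonspecific"}.
    """
    k = config.seed_length
    if len(seq) < k:
        return "unmapped"
    candidates: set[tuple[str, int, int]] = set()
    for strand, oriented in ((0, seq), (1, revcomp(seq))):
        offsets = list(range(0, len(oriented) - k + 1, k))
        if offsets[-1] != len(oriented) - k:
            offsets.append(len(oriented) - k)
        for off in offsets:
            for name, hit in index.get(oriented[off:off + k], ()):
                candidates.add((name, hit - off, strand))
    if not candidates:
        return "unmapped"
    best_score = -1
    best: list[tuple[str, int, int]] = []
    any_candidate = False
    for name, start0, strand in candidates:
        oriented = seq if strand == 0 else revcomp(seq)
        ref = references[name]
        lo = max(0, -start0)
        hi = min(len(oriented), len(ref) - start0)
        overlap = hi - lo
        if overlap < config.min_length_fraction * len(oriented):
            continue
        r = np.frombuffer(oriented.encode(), dtype=np.uint8)[lo:hi]
        t = np.frombuffer(ref.encode(), dtype=np.uint8)[start0 + lo:start0 + hi]
        matches = int((r == t).sum())
        if matches / overlap < config.min_identity:
            continue
        any_candidate = True
        if matches > best_score:
            best_score = matches
            best = [(name, start0, strand)]
        elif matches == best_score:
            best.append((name, start0, strand))
    if not any_candidate:
        return "low_identity"
    if len(best) > 1:
        # equal-scoring distinct placements: non-specific, drop
        return "nonspecific"
    name, start0, strand = best[0]
    return (name, start0, strand, seq if strand == 0 else revcomp(seq))


def align_gapless(pairs: list[ReadPair], references: dict[str, str],
                  config: AlignConfig | None = None
                  ) -> tuple[dict[str, StrandedPileup], AlignStats]:
    """Place read pairs on amplicon references and build stranded pileups.

    Both mates must place on the same reference; otherwise the whole pair
    is excluded (broken pairs are ignored).
    """
    config = config or AlignConfig()
    index = _build_seed_index(references, config.seed_length)
    pileups = {name: StrandedPileup(name, seq) for name, seq in references.items()}
    stats = AlignStats()
    for pair in pairs:
        stats.reads_in += 2
        res1 = _place_read(pair.seq1, index, references, config)
        res2 = _place_read(pair.seq2, index, references, config)
        fail1 = isinstance(res1, str)
        fail2 = isinstance(res2, str)
        if fail1 or fail2 or res1[0] != res2[0]:
            for res, fail in ((res1, fail1), (res2, fail2)):
                if not fail:
                    stats.broken_pair += 1
                elif res == "unmapped":
                    stats.unmapped += 1
                elif res == "low_identity":
                    stats.low_identity += 1
                else:
                    stats.nonspecific += 1
            continue
        for res, quals in ((res1, pair.qual1), (res2, pair.qual2)):
            name, start0, strand, oriented = res
            q = np.frombuffer(quals.encode(), dtype=np.uint8).astype(float) - 33.0
            if strand == 1:
                q = q[::-1]
            pileups[name].add_read(
                start0, np.frombuffer(oriented.encode(), dtype=np.uint8),
                q, strand, config)
            stats.placed += 1
    return pileups, stats
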