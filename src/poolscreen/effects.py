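"""Amino-acid effect annotation of single-base changes.

Maps a genomic substitution into the spliced CDS of a gene model
(honoring strand and phase), recomputes the affected codon under the
standard nuclear code, and classifies it as synonymous, missense,
nonsense, or stop_loss. Labels follow the three-letter "Asp20Asn"
convention, with synonymous changes written as "Syn".
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from poolscreen.simulate import GeneModel, MutationEvent, ReferenceSet, revcomp

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

TRANSITIONS = ("G>A", "C>T", "T>C", "A>G")
TRANSVERSIONS = ("T>A", "A>T", "G>T", "C>A", "A>C", "T>G", "C>G", "G>C")


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Directed substitution class and transition/transversion kind."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    kind = ("transition"
            if ({ref, alt} <= _PURINES or {ref, alt} <= _PYRIMIDINES)
            else "transversion")
    return f"{ref}>{alt}", kind


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def _aa_token(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


@dataclass(frozen=True)
class EffectCall:
    mutation: MutationEvent
    gene_id: str | None
    effect: str  # synonymous | missense | nonsense | stop_loss | noncoding
    aa_ref: str = ""
    aa_pos: int = 0
    aa_alt: str = ""
    label: str = ""
    partial_cds: bool = False

    @property
    def is_coding_change(self) -> bool:
        return self.effect in ("missense", "nonsense", "stop_loss")


def annotate_effect(mutation: MutationEvent, gene_models: list[GeneModel],
                    reference: ReferenceSet) -> EffectCall:
    """Classify one substitution against the first gene model whose CDS
    contains it; positions in no CDS are noncoding."""
    seq = reference.sequences.get(mutation.seq_name)
    if seq is None:
        raise ValueError(f"unknown sequence {mutation.seq_name!r}")
    if seq[mutation.pos - 1] != mutation.ref:
        raise ValueError(
            f"reference mismatch at {mutation.seq_name}:{mutation.pos}: "
            f"expected {mutation.ref}, reference has {seq[mutation.pos - 1]}")
    for gm in gene_models:
        if gm.seq_name != mutation.seq_name:
            continue
        cds_pos = gm.cds_position(mutation.pos)
        if cds_pos is None:
            continue
        return _annotate_in_gene(mutation, gm, seq, cds_pos)
    return EffectCall(mutation, None, "noncoding")


def _annotate_in_gene(mutation: MutationEvent, gm: GeneModel, seq: str,
                      cds_pos: int) -> EffectCall:
    cds = gm.spliced_cds(seq)
    ref_base = mutation.ref if gm.strand == "+" else revcomp(mutation.ref)
    alt_base = mutation.alt if gm.strand == "+" else revcomp(mutation.alt)
    assert cds[cds_pos - 1] == ref_base
    coding_pos = cds_pos - gm.phase
    partial = gm.is_partial
    if coding_pos < 1:
        # inside the CDS feature but upstream of the first full codon
        return EffectCall(mutation, gm.gene_id, "noncoding", partial_cds=partial)
    codon_idx = (coding_pos - 1) // 3  # 0-based
    within = (coding_pos - 1) % 3
    codon_start = gm.phase + codon_idx * 3
    codon = cds[codon_start:codon_start + 3]
    if len(codon) < 3:
        return EffectCall(mutation, gm.gene_id, "noncoding", partial_cds=True)
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(alt_codon)
    aa_pos = codon_idx + 1
    if aa_ref == aa_alt:
        effect, label = "synonymous", "Syn"
    elif aa_alt == "*":
        effect = "nonsense"
        label = f"{_aa_token(aa_ref)}{aa_pos}*"
    elif aa_ref == "*":
        effect = "stop_loss"
        label = f"*{aa_pos}{_aa_token(aa_alt)}"
    else:
        effect = "missense"
        label = f"{_aa_token(aa_ref)}{aa_pos}{_aa_token(aa_alt)}"
    return EffectCall(mutation, gm.gene_id, effect, _aa_token(aa_ref), aa_pos,
                      _aa_token(aa_alt), label, partial)
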