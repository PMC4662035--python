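"""Bundled worked-example data from a soybean EMS mutant-library screen.

These small tables (an HRM screen of the leaflet-shape locus *Ln* /
Glyma20g25000, a five-gene HRM vs. indexed-amplicon-sequencing comparison
panel, and genome-wide substitution-category counts from 12 re-sequenced
lines) serve as fixed inputs for tests and for the acceptance report.
"""

from __future__ import annotations

from poolscreen.stats import MutationRecord

#: Chromosome-scale soybean assembly size (bp) used for extrapolations.
GENOME_BP = 950_068_807
#: Library size (number of M2' plants).
N_PLANTS = 1536

#: Genome-wide base changes per re-sequenced line: average, minimum, maximum.
PER_LINE_BASE_CHANGES = {"average": 12_796, "min": 8_970, "max": 21_861}

#: Substitution-category counts over all 153,554 base changes in the 12
#: re-sequenced lines, grouped into complementary pairs.
WGS_CATEGORY_COUNTS = {
    "G>A+C>T": 106_480,
    "T>A+A>T": 27_306,
    "T>C+A>G": 7_626,
    "G>T+C>A": 5_981,
    "A>C+T>G": 4_578,
    "C>G+G>C": 1_583,
}

#: Indexed-amplicon panel: total unique base changes found and total
#: amplicon size (bp) across the seven screened genes.
AMPLICON_PANEL = {"n_base_changes": 561, "region_bp": 30_269}


def _rec(line, region, size, change, mode, pos, subst):
    ref, alt = change.split(">")
    return MutationRecord(line, "Gm20", pos, ref, alt, mode, region, size, subst)


#: The 26 mutant lines found by HRM screening of four exons of
#: Glyma20g25000 (amplicon sizes 332 + 231 + 114 + 467 = 1144 bp).
HRM_LN_RECORDS = [
    _rec("EnT-0541", "Ln_ex1", 332, "G>A", "het", 34_688_627, "Met1Ile"),
    _rec("EnT-0685", "Ln_ex1", 332, "C>T", "het", 34_688_652, "Leu10Phe"),
    _rec("EnT-1168", "Ln_ex1", 332, "G>A", "hom", 34_688_672, "Syn"),
    _rec("EnT-0112", "Ln_ex1", 332, "G>A", "hom", 34_688_682, "Asp20Asn"),
    _rec("EnT-0044", "Ln_ex1", 332, "G>A", "het", 34_688_682, "Asp20Asn"),
    _rec("EnT-1589", "Ln_ex1", 332, "G>A", "het", 34_688_682, "Asp20Asn"),
    _rec("EnT-1376", "Ln_ex1", 332, "G>A", "het", 34_688_686, "Gly21Asp"),
    _rec("EnT-0621", "Ln_ex1", 332, "G>A", "het", 34_688_686, "Gly21Asp"),
    _rec("EnT-1048", "Ln_ex1", 332, "C>T", "hom", 34_688_696, "Syn"),
    _rec("EnT-1306", "Ln_ex1", 332, "C>T", "hom", 34_688_696, "Syn"),
    _rec("EnT-0987", "Ln_ex1", 332, "C>T", "hom", 34_688_713, "Ser30Phe"),
    _rec("EnT-0160", "Ln_ex1", 332, "C>T", "het", 34_688_719, "Ser32Phe"),
    _rec("EnT-0634", "Ln_ex2", 231, "G>A", "hom", 34_689_275, "Gly40Ser"),
    _rec("EnT-0749", "Ln_ex2", 231, "G>A", "hom", 34_689_275, "Gly40Ser"),
    _rec("EnT-0439", "Ln_ex2", 231, "C>T", "het", 34_689_313, "Syn"),
    _rec("EnT-1084", "Ln_ex2", 231, "G>A", "het", 34_689_360, "Gly68Glu"),
    _rec("EnT-1281", "Ln_ex3", 114, "C>T", "het", 34_689_704, "Ala102Val"),
    _rec("EnT-1312", "Ln_ex3", 114, "A>T", "het", 34_689_710, "His104Leu"),
    _rec("EnT-0601", "Ln_ex4", 467, "G>A", "hom", 34_690_049, "Syn"),
    _rec("EnT-0155", "Ln_ex4", 467, "G>A", "het", 34_690_058, "Syn"),
    _rec("EnT-0687", "Ln_ex4", 467, "C>T", "hom", 34_690_175, "Syn"),
    _rec("EnT-0862", "Ln_ex4", 467, "C>T", "hom", 34_690_175, "Syn"),
    _rec("EnT-1619", "Ln_ex4", 467, "G>A", "het", 34_690_246, "Gly213Asp"),
    _rec("EnT-1265", "Ln_ex4", 467, "C>T", "hom", 34_690_247, "Syn"),
    _rec("EnT-0510", "Ln_ex4", 467, "C>T", "het", 34_690_247, "Syn"),
    _rec("EnT-0383", "Ln_ex4", 467, "C>T", "het", 34_690_247, "Syn"),
]

#: Combined amplicon length (bp) of the four screened Ln exons.
HRM_LN_REGION_BP = 1144

#: Five-gene comparison of HRM (method A) and indexed amplicon sequencing
#: (method B): gene -> (total, common, a_only, b_only).
DETECTION_COMPARISON_COUNTS = {
    "Glyma20g25000": (37, 14, 4, 19),
    "Glyma08g46520": (22, 13, 1, 8),
    "Glyma06g23026": (12, 7, 0, 5),
    "Glyma20g22160": (24, 12, 4, 8),
    "Glyma11g15580": (12, 7, 2, 3),
}

#: Compared region length (bp) per gene in the five-gene panel.
DETECTION_COMPARISON_REGION_BP = {
    "Glyma20g25000": 1144,
    "Glyma08g46520": 487,
    "Glyma06g23026": 305,
    "Glyma20g22160": 1187,
    "Glyma11g15580": 380,
}
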