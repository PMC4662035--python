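"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; FASTQ, GFF3, VCF v4.2, layout CSV and pileup TSV via
small dedicated codecs with deterministic ordering and gzip support
(any path ending in ``.gz``). Malformed records raise ValueError naming
the offending record or line.
"""

from __future__ import annotations

import csv
import gzip
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from poolscreen.caller import CallerConfig, PoolVariantCall
from poolscreen.readprep import StrandedPileup
from poolscreen.simulate import GeneModel, PoolingLayout, ReadPair, ReferenceSet, TruthRecord


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with open_text(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# FASTQ


def write_fastq_pairs(pairs: list[ReadPair], path1, path2) -> None:
    with open_text(path1, "wt") as f1, open_text(path2, "wt") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{pair.qual2}\n")


def _read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    with open_text(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(
                    f"{path}: truncated or malformed FASTQ at record "
                    f"{header.strip() or len(out) + 1!r}")
            if len(seq) != len(qual):
                raise ValueError(f"{path}: length mismatch in record {header.strip()}")
            out.append((header[1:].strip(), seq, qual))
    return out


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("mate files differ in record count")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
        name = n1.rsplit("/", 1)[0]
        if n2.rsplit("/", 1)[0] != name:
            raise ValueError(f"mate name mismatch: {n1} vs {n2}")
        pairs.append(ReadPair(name, s1, q1, s2, q2))
    return pairs


# ---------------------------------------------------------------------------
# GFF3


def _cds_phases(gm: GeneModel) -> list[int]:
    """Phase of each genomic CDS interval, in genomic order."""
    ivals = list(gm.cds_intervals)
    order = ivals if gm.strand == "+" else ivals[::-1]
    phases = []
    consumed = 0
    for start, end in order:
        phase = (3 - (consumed - gm.phase) % 3) % 3 if consumed else gm.phase
        phases.append(phase)
        consumed += end - start + 1
    return phases if gm.strand == "+" else phases[::-1]


def write_gff3(reference: ReferenceSet, path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in reference.sequences.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gm in reference.gene_models:
            lo = min(s for s, _ in gm.cds_intervals)
            hi = max(e for _, e in gm.cds_intervals)
            fh.write(f"{gm.seq_name}\tpoolscreen\tgene\t{lo}\t{hi}\t.\t"
                     f"{gm.strand}\t.\tID={gm.gene_id}\n")
            fh.write(f"{gm.seq_name}\tpoolscreen\tmRNA\t{lo}\t{hi}\t.\t"
                     f"{gm.strand}\t.\tID={gm.gene_id}.t1;Parent={gm.gene_id}\n")
            for (start, end), phase in zip(gm.cds_intervals, _cds_phases(gm)):
                fh.write(f"{gm.seq_name}\tpoolscreen\tCDS\t{start}\t{end}\t.\t"
                         f"{gm.strand}\t{phase}\tID={gm.gene_id}.cds;"
                         f"Parent={gm.gene_id}.t1\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse CDS features grouped by Parent into gene models."""
    cds: dict[str, dict] = {}
    with open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_name, _, ftype, start, end, _, strand, phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            parent = attr.get("Parent", attr.get("ID", f"anon{lineno}"))
            gene_id = parent.rsplit(".t1", 1)[0]
            entry = cds.setdefault(gene_id, {"seq": seq_name, "strand": strand,
                                             "ivals": []})
            entry["ivals"].append((int(start), int(end), int(phase)))
    models = []
    for gene_id, entry in cds.items():
        ivals = sorted(entry["ivals"])
        first = ivals[0] if entry["strand"] == "+" else ivals[-1]
        models.append(GeneModel(gene_id, entry["seq"], entry["strand"],
                                tuple((s, e) for s, e, _ in ivals),
                                phase=first[2]))
    return sorted(models, key=lambda g: g.gene_id)


# ---------------------------------------------------------------------------
# layout CSV


def write_layout_csv(layout: PoolingLayout, path) -> None:
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["plant_id", "tier1_pool", "tier2_pool", "i7", "i5"])
        for plant in layout.plants:
            t1 = layout.tier1[plant]
            t2 = layout.tier2[t1]
            i7, i5 = layout.index_pairs.get(t2, ("", ""))
            writer.writerow([plant, t1, t2, i7, i5])


def read_layout_csv(path) -> PoolingLayout:
    tier1: dict[str, str] = {}
    tier2: dict[str, str] = {}
    index_pairs: dict[str, tuple[str, str]] = {}
    with open_text(path, "rt") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            tier1[row["plant_id"]] = row["tier1_pool"]
            tier2[row["tier1_pool"]] = row["tier2_pool"]
            if row.get("i7"):
                index_pairs[row["tier2_pool"]] = (row["i7"], row["i5"])
    if not tier1:
        raise ValueError(f"{path}: empty layout")
    t1_sizes = {t1: sum(1 for v in tier1.values() if v == t1)
                for t1 in set(tier1.values())}
    t2_sizes = {t2: sum(1 for v in tier2.values() if v == t2)
                for t2 in set(tier2.values())}
    return PoolingLayout(len(tier1), max(t1_sizes.values()),
                         max(t2_sizes.values()), tier1, tier2, index_pairs)


# ---------------------------------------------------------------------------
# VCF


_VCF_HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"


def write_truth_vcf(truth: list[TruthRecord], reference: ReferenceSet, path) -> None:
    with open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolscreen-simulator\n")
        for name, seq in reference.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=LINE,Number=.,Type=String,Description="Carrier plants">\n')
        fh.write('##INFO=<ID=ZYG,Number=.,Type=String,Description="Zygosity per carrier">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="round1|round2|background">\n')
        fh.write('##INFO=<ID=POOL,Number=.,Type=String,Description="Tier-2 pools hit">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in truth:
            info = (f"LINE={','.join(rec.lines)};ZYG={','.join(rec.zygosities)};"
                    f"ORIGIN={rec.origin};POOL={','.join(rec.pools)}")
            fh.write(f"{rec.seq_name}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t"
                     f"PASS\t{info}\n")


def read_truth_vcf(path) -> list[TruthRecord]:
    records = []
    with open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: short VCF line")
            info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
            records.append(TruthRecord(
                fields[0], int(fields[1]), fields[3], fields[4],
                tuple(info.get("LINE", "").split(",")),
                tuple(info.get("ZYG", "").split(",")),
                info.get("ORIGIN", ""),
                tuple(info.get("POOL", "").split(",")) if info.get("POOL") else ()))
    return records


def write_calls_vcf(calls: list[PoolVariantCall], path,
                    config: CallerConfig | None = None,
                    contigs: dict[str, int] | None = None) -> None:
    config = config or CallerConfig()
    with open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolscreen-caller (allele-fraction threshold "
                 "stand-in for probabilistic variant detection)\n")
        fh.write(f"##poolscreen_min_coverage={config.min_coverage}\n")
        fh.write(f"##poolscreen_min_frequency={config.min_frequency:.6f}\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for flt, desc in [("LOW_COV", "coverage below minimum"),
                          ("LOW_FREQ", "variant reads or fraction below minimum"),
                          ("STRAND", "missing support on one strand"),
                          ("QUALITY", "supported only by quality-failed bases")]:
            fh.write(f'##FILTER=<ID={flt},Description="{desc}">\n')
        fh.write('##INFO=<ID=POOL,Number=1,Type=String,Description="Pool id">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
        fh.write('##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Alt reads, forward">\n')
        fh.write('##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Alt reads, reverse">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt fraction">\n')
        # one record per (pool, site); the sample column holds that pool's data
        fh.write(_VCF_HEADER.format(sample="SAMPLE"))
        ordered = sorted(calls, key=lambda c: (c.seq_name, c.pos, c.alt, c.pool_id))
        for c in ordered:
            fmt = f"{c.coverage}:{c.alt_count_f}:{c.alt_count_r}:{c.frequency:.6f}"
            fh.write(f"{c.seq_name}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t"
                     f"{c.filter_status}\tPOOL={c.pool_id}\tDP:ADF:ADR:AF\t{fmt}\n")


def read_calls_vcf(path) -> list[PoolVariantCall]:
    calls = []
    with open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: short VCF line")
            info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
            dp, adf, adr, af = fields[9].split(":")
            calls.append(PoolVariantCall(
                info.get("POOL", "pool"), fields[0], int(fields[1]), fields[3],
                fields[4], int(dp), int(adf), int(adr), float(af), fields[6]))
    return calls


# ---------------------------------------------------------------------------
# pileup TSV


_PILEUP_COLUMNS = [f"{b}_{s}" for b in "ACGT" for s in "FR"]


def write_pileup_tsv(pileup: StrandedPileup, path, append: bool = False) -> None:
    mode = "at" if append else "wt"
    with open_text(path, mode) as fh:
        if not append:
            fh.write("seq\tpos\tref\t" + "\t".join(_PILEUP_COLUMNS) + "\t"
                     + "\t".join("q" + c for c in _PILEUP_COLUMNS) + "\n")
        for i in range(len(pileup)):
            raw = [str(int(pileup.raw[bi, si, i]))
                   for bi in range(4) for si in range(2)]
            qual = [str(int(pileup.qualified[bi, si, i]))
                    for bi in range(4) for si in range(2)]
            fh.write(f"{pileup.seq_name}\t{i + 1}\t{pileup.ref[i]}\t"
                     + "\t".join(raw) + "\t" + "\t".join(qual) + "\n")


def read_pileup_tsv(path) -> dict[str, StrandedPileup]:
    rows: dict[str, list] = {}
    with open_text(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["seq", "pos", "ref"] + _PILEUP_COLUMNS + [
            "q" + c for c in _PILEUP_COLUMNS]
        if header != expected:
            raise ValueError(f"{path}: unexpected pileup header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.setdefault(fields[0], []).append(fields)
    pileups = {}
    for seq_name, seq_rows in rows.items():
        seq_rows.sort(key=lambda f: int(f[1]))
        ref = "".join(f[2] for f in seq_rows)
        pileup = StrandedPileup(seq_name, ref)
        for f in seq_rows:
            i = int(f[1]) - 1
            vals = list(map(int, f[3:11]))
            qvals = list(map(int, f[11:19]))
            for j, (bi, si) in enumerate((b, s) for b in range(4) for s in range(2)):
                pileup.raw[bi, si, i] = vals[j]
                pileup.qualified[bi, si, i] = qvals[j]
        pileups[seq_name] = pileup
    return pileups


# ---------------------------------------------------------------------------
# misc


def write_json(obj, path) -> None:
    with open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
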