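# poolscreen

Indexed pooled amplicon sequencing for retrieving point mutants from
EMS-mutagenized plant populations — as a fully simulated, tested pipeline.

A mutant library is built by mutagenizing seeds twice and selfing; DNA from
the plants is pooled in two tiers (4 plants per tier-1 pool, 4 tier-1 pools
per dual-indexed tier-2 pool of 16 plants). Target genes are amplified per
pool and deep-sequenced; a single heterozygous mutant plant then shows up at
an expected allele fraction of 1/32. `poolscreen` implements every stage of
that screen with known ground truth:

- **`poolscreen.simulate`** — toy references with gene models; a doubly
  mutagenized selfing population (round-1 mutations shared within M1
  families, round-2 private; 1:2 hom:het given transmission) following a
  configurable 12-class substitution spectrum; two-tier pooling layouts
  with 12 x 8 dual index labels; pooled paired-end reads with smooth
  non-uniform depth and i.i.d. base errors, plus a truth VCF.
- **`poolscreen.readprep`** — read cleaning (3-nt end trim, modified-Mott
  quality trimming at error probability 0.01, ambiguous-base and pair-length
  filters) and gapless 31-mer-seeded alignment (length fraction >= 0.9,
  identity >= 0.96, broken pairs ignored) into stranded pileups.
- **`poolscreen.caller`** — threshold caller for low-frequency pool variants:
  coverage >= 96, >= 2 variant reads, frequency >= 2/96, support on both
  strands, per-read quality gating; plus exact binomial detection power.
- **`poolscreen.background`** — cross-sample filter removing variants shared
  by >= 20 % of units (cultivar polymorphisms vs. induced mutations).
- **`poolscreen.effects`** — codon-level annotation (synonymous / missense /
  nonsense / stop_loss) with "Asp20Asn"-style labels, strand- and
  phase-aware.
- **`poolscreen.stats`** — deduplication, spectrum summaries (Ts/Tv),
  mutations-per-kb, distance-between-changes, expected mutations per plant,
  and two-method detection comparisons.
- **`poolscreen.benchmark`** — deconvolution of pool calls to candidate
  plants, genotype confirmation, and an end-to-end benchmark against
  simulation truth (sensitivity, FDR, density recovery).
- **`poolscreen.examples`** — bundled worked-example tables (an HRM screen
  of a soybean leaflet-shape locus, a five-gene method-comparison panel,
  genome-wide substitution-category counts) used by tests and the
  acceptance report.

## CLI

```sh
poolscreen simulate --plants 64 --genes 2 --seed 1 --outdir out/
poolscreen trim  --in1 out/pool001_R1.fastq --in2 out/pool001_R2.fastq \
                 --out1 t1.fastq --out2 t2.fastq
poolscreen align --reference out/reference.fasta --in1 t1.fastq --in2 t2.fastq \
                 --out pileup.tsv
poolscreen call  --pileup pileup.tsv --pool-id pool001 --out calls.vcf
poolscreen filter --calls calls.vcf --unit-vcf u1.vcf --unit-vcf u2.vcf \
                 --out filtered.vcf
poolscreen annotate --calls filtered.vcf --reference out/reference.fasta \
                 --gff out/genes.gff3 --out effects.tsv
poolscreen stats --calls filtered.vcf --region-bp 1002 --out stats.json
poolscreen deconvolve --calls filtered.vcf --layout out/layout.csv --out deconv.tsv
poolscreen benchmark --plants 32 --seeds 3 --out bench.json
poolscreen report --calls-a hrm.vcf --calls-b ampseq.vcf --out compare.json
```

All commands are deterministic given `--seed`; sequence files may be
gzipped (`.gz`).

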