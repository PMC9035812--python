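# migkit

Desk-scale toolkit for MIG-seq style reduced-representation genotyping
analysis. MIG-seq amplifies the regions between microsatellites (SSRs), so
how much of a genome it can interrogate is tied to how many SSR loci the
genome carries. `migkit` packages the computational side of that workflow,
with a synthetic-data generator standing in for sequencing data:

- **simulate** — genomes seeded with SSR loci of the four targeted motif
  classes (ACT, TTG, GTG, GT), inbred accession panels diverged at a chosen
  pairwise nucleotide diversity, F2 / RIL crosses with interference-free
  meiosis, additive phenotypes, and overdispersed MIG-seq coverage
  (lognormal per-locus amplification weights + Poisson sampling) with
  depth-dependent missingness. Every truth table is returned alongside the
  writable FASTA/BED/VCF/TSV outputs.
- **ssr_scan** — a perfect-tandem-repeat scanner for di-/tri-nucleotide
  motifs with rotation/reverse-complement canonicalization, targeted-class
  counting, and Pearson correlation of per-genome metrics.
- **depth_profile** — mapped-base counts at depth thresholds from per-base
  depth TSVs (`chrom  pos  depth`), per-0.5-Gb normalization, and
  per-variant DP quantile summaries.
- **genotype_qc** — per-cell depth masking, genotype-rate / quality / het
  site filters, individual missingness filters, parental-replicate marker
  extraction, and het-to-missing conversion, with `f2` / `ril` / `panel`
  presets.
- **diversity** — all-pairs nucleotide diversity (SNP differences over
  bases jointly covered at DP ≥ 5), group-stratified threshold summaries,
  and the linear marker-count ⇄ diversity extrapolation.
- **het_accuracy** — virtual-F1 construction by hypergeometric subsampling
  and merging of parental marker depths, a minimal allele-depth caller, and
  error/missing curves over min-DP 1..20 with an exact analytic oracle
  (P(hom call at depth d) = 2^(1−d)).
- **linkage** — two-point recombination fractions (F2 EM over the 9-class
  table; RIL with the r = R/(2−2R) selfing correction), Kosambi distances,
  map summaries, segregation-distortion χ², and a single-marker LOD scan
  with a permutation-based genome-wide threshold.
- **pipeline / cli** — a config-driven end-to-end run with deterministic,
  checksummed outputs.

## CLI

All stages are exposed as subcommands of `migkit`:

```bash
migkit simulate --length-bp 400000 --ssr-density 120 --seed 1 --out sim/
migkit scan-ssr --fasta sim/genome.fasta --out-bed loci.bed --out-summary ssr.tsv
migkit depth-profile --depth-tsv sim/depth_acc001.tsv --min-dp 10 --out depth.tsv
migkit qc --vcf sim/panel.vcf --population panel --out-vcf f.vcf --out-markers m.tsv
migkit diversity --vcf sim/panel.vcf --depth-dir sim/ --min-dp 5 --out pairs.tsv
migkit linkage --vcf cross.vcf --population RIL --out-prefix ril
migkit qtl-scan --vcf cross.vcf --phenotypes pheno.tsv --permutations 1000 --out lod.tsv
migkit run-all --config config.yaml --seed 1 --out run/
```

`run-all` writes every table plus `manifest.json` recording the config,
seed, version, and a sha256 per output; reruns with the same config are
byte-identical.

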