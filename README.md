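# enhsnp

Cell-type-resolved enhancer maps meet GWAS SNP lists.

Genome-wide association studies mostly flag non-coding variants, which are
unreadable without regulatory annotation. `enhsnp` implements the classic
integration recipe: take per-sample enhancer peak sets (e.g. H3K4me1 /
H3K27ac ChIP-seq peaks), establish which samples are the same cell type by
per-nucleotide concordance, merge each cell type's enhancers, and then ask
whether disease-associated SNPs pile up in one cell type's enhancers more
than common background SNPs do. The cell type with the strongest enrichment
is a candidate driver of the disease, and the SNPs inside its enhancers are
candidates for being functional. It is written for computational geneticists
and epigenomicists who have peak BEDs and SNP tables and want the statistics
without the plumbing.

## The statistics

**Peak-set concordance.** Two peak sets A and B over an assembly of G bases
induce per-base confusion counts — TP (bases in both), FP/FN (bases in one
only), TN (bases in neither) — summarised by the Matthews correlation
coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

Samples with pairwise MCC above a cutoff (default 0.55) are clustered into
cell types (connected components; average-linkage hierarchical mode
available), singletons are flagged as outliers, and each cluster's peaks
are merged into one enhancer set per cell type.

**SNP enrichment.** For a disease SNP set D (n_D SNPs, k_D inside region R)
and a background set B (n_B, k_B):

```
enrichment e = (k_D / n_D) / (k_B / n_B)
```

with two-sided significance from the uncorrected Pearson chi-square test
(df = 1) on the 2×2 table. The same statistic serves enhancers per cell
type, chromatin-state segmentations, and genomic context classes
(cds / 5′-UTR / 3′-UTR / intron / intergenic from gene models). On top:
LD expansion of lead SNPs at an r² threshold (default 0.8), sharing
profiles (which cell types' enhancers cover each SNP), enrichment
stratified by how many additional cell types share the enhancer, and TFBS
overlap fractions of SNPs inside vs outside enhancers.

A first-class synthetic-data generator emulates all inputs — peak sets with
planted cell-type structure, SNPs with LD blocks and a planted enrichment
fold, TFBSs preferentially placed in enhancers — so the whole pipeline is
testable end-to-end with no downloads.

## Worked example

Simulate a dataset (two 1-Mb chromosomes, 4 cell types × 2 replicates, a
2× enrichment fold planted in cell type 0), then run the pipeline:

```bash
enhsnp simulate --seed 1 --out demo_data
enhsnp run \
  --snps demo_data/disease.snps --background demo_data/background.snps \
  --peaks t0_r0=demo_data/peaks_t0_r0.bed --peaks t0_r1=demo_data/peaks_t0_r1.bed \
  --peaks t1_r0=demo_data/peaks_t1_r0.bed --peaks t1_r1=demo_data/peaks_t1_r1.bed \
  --peaks t2_r0=demo_data/peaks_t2_r0.bed --peaks t2_r1=demo_data/peaks_t2_r1.bed \
  --peaks t3_r0=demo_data/peaks_t3_r0.bed --peaks t3_r1=demo_data/peaks_t3_r1.bed \
  --chrom-sizes demo_data/chrom.sizes --genes demo_data/genes.refflat \
  --tfbs demo_data/tfbs.bed --out demo_out
cat demo_out/enrichment_enhancers.tsv
```

```
region	k_d	n_d	k_b	n_b	enrichment	chi2	p_value	degenerate
cluster0	623	2500	6576	50000	1.8947688564476886	278.6728590710187	1.4615226512523568e-62	
cluster3	384	2500	6542	50000	1.1739529195964535	10.769962636948396	0.0010316059202676456	
cluster2	375	2500	6473	50000	1.1586590452649468	8.85618407370858	0.002920975735965183	
cluster1	355	2500	6542	50000	1.0852950168144297	2.5986277144205796	0.10695628949672953	
```

Cell type 0's enhancers (cluster0) carry the disease SNPs at nearly twice
the background rate — this seed's estimate of the planted fold 2.0 is 1.89,
within sampling error, at p ≈ 10⁻⁶² — while the other three cell types sit
near enrichment 1. Their mild excess (~1.1–1.17) is real and expected:
enhancers shared across all cell types belong to cluster0's merged set too,
so they carry part of the planted signal into every cluster — exactly the
dilution that motivates the stratified analysis, which isolates
cell-type-specific enhancers. The run
directory also contains the MCC matrix (within-type entries ≈ 0.78,
between-type ≈ 0.18), the cluster assignment (the eight replicates collapse
to the four true cell types at cutoff 0.55), the sharing matrix and
histogram, the stratified enrichment series, the TFBS overlap table (ratio
3.79 for this seed against the planted 4:1), the SNP region-class
distribution, and a `run_report.json` manifest.

Each stage is also a library call (`enhsnp.mcc_matrix`,
`enhsnp.snp_set_enrichment`, …) and an independent subcommand
(`simulate`, `annotate`, `mcc`, `cluster`, `enrich`, `stratify`, `tfbs`,
`run`, `report`); published contingency counts can be fed directly via
`enhsnp enrich --counts`.

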