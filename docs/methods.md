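# Methods

This note records the models, conventions, parameter choices and known
limitations behind `enhsnp`, in the order the pipeline runs.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED-native) internally; SNP tables in
1-based (VCF) convention are converted on read via `one_based=True` /
`--one-based-snps`, which subtracts 1. A SNP is a length-1 interval; interval
membership of a position `p` in `[start, end)` is `start <= p < end`, so the
left boundary is inside and the right boundary is not. Abutting intervals
(`[0,10)`, `[10,20)`) coalesce on merge: every downstream statistic is
per-nucleotide, and abutment does not change base coverage. Peak and TFBS
strand is ignored (ChIP-seq peaks are unstranded); strand is honored only in
gene-model-based classification.

The algebra (merge, intersection, complement, membership) runs on sorted
int64 numpy arrays per chromosome: O(n log n) merge, O(n+m) intersection.
Correctness is pinned in the test suite to an exhaustive boolean-array
oracle on ≤10 kb toy genomes (exact equality of base counts) and
cross-checked once against `bedtools intersect`.

## Region classification

Five classes: `cds`, `utr5`, `utr3`, `intron`, `intergenic`. Per transcript:
exonic positions inside the CDS bounds are `cds`; exonic positions 5′ of the
CDS in transcription order are `utr5` (3′ → `utr3`), with the orientation
taken from the transcript strand; non-exonic positions inside the transcript
are `intron`; positions in no transcript are `intergenic`. Where
transcripts disagree, the fixed precedence `cds > utr5 > utr3 > intron`
decides — a coding consequence dominates biologically, and the result is
independent of transcript input order. Exonic bases of non-coding
transcripts (CDS-less models) classify as `intron`: the five-class scheme
has no ncRNA-exon bucket, and "genic but non-coding" is the closest honest
label. This is a documented package choice for a case that the five-class
scheme leaves genuinely open. Unstranded gene models are rejected at load;
CDS bounds must begin and end inside exons (their middle legitimately spans
introns).

## Enrichment statistic

`e = (k_D/n_D) / (k_B/n_B)` with significance from the uncorrected Pearson
chi-square on the 2×2 table, df = 1, two-sided. No Yates continuity
correction (at genome-scale counts it is irrelevant; for the published
tables the uncorrected statistic is what reproduces the printed values) and
no multiple-testing adjustment by default (an optional Bonferroni column is
available). Degenerate cases are value states, not crashes: `k_B = 0` is an
explicit undefined flag (never infinity), `k_D = 0` with `k_B > 0` is a
genuine enrichment of 0 with the test skipped, and a region covering every
SNP of both sets returns e = 1, p = 1. Disease and background sets must be
disjoint by rsID; the pipeline subtracts the disease set from the background
on load.

Full-precision p-values are what the analysis carries. The table formatter
additionally exposes a "printed p" convention — the chi-square survival
function evaluated at the statistic rounded to 2 decimals — because
historical enrichment tables were typically produced that way (e.g.
sf(0.60) = 0.4386 vs sf(0.599) = 0.4390), and reproducing a printed table
requires reproducing its rounding pathway.

Chromatin-state enrichment runs the same statistic once per segmentation
label; same-label segments may overlap (they merge), different-label
overlaps are rejected because they make the per-base state ill-defined.
Stratified enrichment restricts the region to SNP positions covered by the
focal cell type and exactly k (mode `exact`) or at most k (mode
`cumulative`) other cell types; both modes exist because "shared with up to
k others" and "shared with exactly k others" are both defensible readings
of sharing-stratified analyses, and neither is asserted as canonical. LD
expansion unions lead SNPs with proxies at r² ≥ threshold (default 0.8),
deduplicated by rsID (first lead wins); proxies without coordinates are
dropped with a warning.

## MCC concordance and clustering

Confusion counts use the whole assembly: TN counts every base covered by
neither sample, with no exclusion of assembly gaps (the choice is
documented rather than configurable; on the synthetic genomes there are no
gaps, and on real genomes including gaps deflates all MCCs roughly equally,
which a rank-based cutoff tolerates). Counts are exact Python integers; the
MCC is evaluated in double precision after casting, with relative error
< 1e−12 at 3-Gb scale (the denominator product ~1e38 is far inside double
range). A zero marginal (empty sample, or a sample covering the whole
genome) makes the MCC undefined; this propagates as a flagged NaN value —
not 0, not an exception — so one empty file cannot silently distort
clustering: it becomes a singleton outlier.

Clustering is connected components of the graph with an edge where
MCC > cutoff (default 0.55). Components are deterministic and
parameter-free beyond the cutoff, which is why they are the default; an
average-linkage hierarchical mode (tree cut at distance 1 − cutoff) is
selectable for sensitivity analysis. Cluster merging is the union of member
peak sets ("merged" read literally); an intersection mode is available via
the interval algebra for sensitivity analysis.

## Synthetic data generator

The generator emulates the statistical structure of a multi-sample
enhancer/GWAS study; defaults define the study conditions.

* **Genome**: 2 × 1 Mb chromosomes. Small enough that the full test suite
  runs in about a minute on one CPU, large enough that every statistic has
  thousands of informative bases/SNPs.
* **Peaks**: a shared pool (80 peaks) common to all cell types plus a
  specific pool (170 peaks) per type, placed without overlap; peak lengths
  ~ N(1000, 200²) bp truncated at 200. Each of 4 cell types × 2 replicates
  is its type's master set after 15% peak dropout and ±100 bp boundary
  jitter, clipped at chromosome bounds. These rates put within-type MCC
  near 0.78 and between-type MCC near 0.2, bracketing the 0.55 cutoff the
  clustering uses — the regime the method is designed for.
* **SNPs**: 50,000 background SNPs uniform over the genome; 125 disease
  lead SNPs each with 19 LD proxies (2,500 disease SNPs total, the scale of
  an LD-expanded GWAS list). Every disease SNP independently falls inside
  the focal cell type's merged emitted enhancers with probability f·q
  (q ≈ 0.128 = enhancer fraction of the genome, f the planted fold,
  default 2), else uniformly outside. Proxies inherit the *bias* (the same
  probability), not the lead's realized placement — this keeps the
  estimator's sampling error exactly binomial at n = 2,500, which is what
  the recovery tests assert. Proxies live within a 100 kb window centred on
  their lead (widened only in the rare case the window lacks the required
  compartment; the truth file records such relocations) and carry
  r² ~ U(0.8, 1). With `plant_in="specific"` the fold is planted only in
  focal-specific (non-shared) peaks, the configuration under which
  stratum-0 enrichment must exceed pooled enrichment.
* **TFBS**: per pooled merged enhancer, one site (200 bp, fully inside)
  with probability 0.8; per mean-enhancer-length window of the non-enhancer
  genome, probability 0.2 (partial trailing windows get proportionally
  reduced probability). This makes the per-base site density in each
  compartment exactly proportional to its placement probability, so the
  in/out overlap-fraction ratio of uniformly-placed SNPs estimates the
  planted 4:1 without geometric bias; the probabilities are high enough
  that the ratio's sampling error at 2,500 disease SNPs stays useful.
* **Gene models**: 40 non-overlapping transcripts, 2–5 exons of 100–400 bp,
  introns 200–2000 bp, CDS boundaries inside the terminal exons, random
  strand.
* **Determinism**: one config seed; each stage derives its own stream from
  (seed, crc32(stage name)), so adding a stage never perturbs earlier
  outputs and identical configs give byte-identical files. The truth file
  (JSON) records the planted partition, per-SNP enhancer membership, the
  lead→proxy map and the planted folds, and round-trips exactly against the
  emitted BEDs.

What the generator does **not** emulate: read-level noise and peak-calling
artifacts (peaks are emitted directly), realistic coalescent LD (blocks are
rectangular windows with uniform r²), chromosomal covariates such as gene
density or GC, and assembly gaps. Passing recovery tests therefore show the
statistics are implemented correctly and unbiased under clean planted
structure — not that real ChIP-seq peak sets will reach any particular MCC,
nor that real GWAS lists will show any particular fold.

## Numerical and testing choices

* Published-table reproduction is exact at printed precision: enrichments
  to 2 decimals, exact p-values to 4 decimals via the printed-p convention
  above, "<0.0001" rows as p ≤ 1e−4.
* Fold recovery is asserted within 3 standard errors by the delta method on
  both binomial fractions, over 20 seeds per fold with a ≥95% pass rate;
  the TFBS ratio within 3 SEs on the log scale over 10 seeds.
* Cluster recovery is exact partition equality over 20 seeds (≥95%), plus
  an injected empty sample that must come out a flagged singleton.
* Hypothesis property tests run derandomized; all simulation tests use
  fixed seeds. Problem sizes in the tests (400 kb–2 Mb genomes) were chosen
  so the default suite completes in about a minute.

## Known limitations

* Connected components chain clusters: two cell types bridged by one
  intermediate sample merge. The hierarchical mode mitigates but does not
  define the default.
* The enrichment test treats SNPs as independent; LD-expanded lists violate
  this in real data (proxies travel together), so real-data p-values are
  anti-conservative. The synthetic generator deliberately plants
  independent placements to keep the estimator calibrated; analyses of real
  LD-expanded lists should interpret p-values accordingly (e.g. thin to
  leads, or permute at the block level — out of scope here).
* TN includes unmappable/gap bases on real assemblies; MCC values are then
  systematically slightly deflated.
* No multiple-testing correction by default across tissues/states; the
  Bonferroni column is opt-in.
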