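# Methods

## The analysis model

The pipeline treats enhancer reprogramming as a paired differential-signal
problem on genomic intervals. Its assumptions, stated explicitly:

* **Enhancer definition.** A putative enhancer is an H3K27ac peak that
  overlaps (≥ 1 bp) an H3K4me1 peak and lies at least `tss_min_dist_bp`
  (default 2500) from every annotated TSS. Distance is measured from the
  interval's occupied bases — the half-open `end` coordinate is not a base,
  so the last base is `end − 1` — and a peak at exactly the minimum distance
  is retained ("at least"). The H3K27ac peak's own coordinates define the
  region ("anchor = k27ac"), because enhancer signal is quantified as
  H3K27ac RPKM and the counting region should be the H3K27ac peak; clipping
  to the geometric intersection of the two marks is available as
  `anchor = "geometric"`.
* **Coordinates.** BED convention throughout: 0-based, half-open. GTF input
  (1-based, inclusive) is converted at the reader; the TSS of a − strand
  gene is the annotated gene end − 1. Abutting half-open intervals share no
  base and are never merged (bedtools semantics).
* **Consensus catalogs.** The union of per-sample enhancer calls is merged
  *first*, support is then counted per merged region (number of samples
  contributing ≥ 1 bp; a region bridging two samples' peaks via a third
  counts each sample once), and regions with support < `min_support`
  (default 2) are dropped. Merging before filtering makes support
  well-defined on one canonical region set; the alternative order differs
  only at region boundaries.
* **Paired differential test.** Signal is RPKM
  (`count / (length_kb × library_size_M)`). The test statistic is a
  classical paired *t* on per-patient differences of
  log₂(RPKM + pseudocount), pseudocount 0.01 RPKM: the log stabilises
  variance and makes the fold-change and the test coherent. p-values are
  BH-adjusted over the tested universe. The reported log₂FC is the ratio of
  group mean RPKMs (plus pseudocount), which is robust to single-pair
  zeros; the mean per-pair log-ratio is available via
  `log2fc_mode = "paired_mean"`. Classification uses strict inequalities:
  SOE if log₂FC > 0.75 and p_adj < 0.05, CDE mirrored. Degenerate rules:
  all-zero differences → (t = 0, p = 1); zero spread with nonzero mean →
  (±∞ sentinel, p = 0).
* **Tested universe.** Both gained and lost regions must be testable, so the
  universe is the union of the tumor and normal catalogs, re-merged. When
  counts live on a fixed region grid (as with the synthetic cohorts, where
  read-level counting is out of scope), the universe is realised as the
  grid regions overlapping (≥ 1 bp) that merged union. No expression floor
  is applied before BH.
* **Saturation.** The full-cohort SOE set is the reference; for each
  subsample size k, replicate subsets of k patients are drawn without
  replacement with replicate generators seeded from `(seed, k, replicate)`,
  so runs are reproducible and parallelisable. Recovery is the recovered
  fraction of reference SOEs; an empty reference reports recovery 1.0 with
  a flag. Random subsets (not ordered accrual) are used and labelled as
  such.
* **Funnel.** Four stages compose deterministically: (1) SOEs with ≥ 1 bp
  overlap with cluster-specific accessibility peaks, coordinates preserved;
  (2) genes whose TSS lies in `[start − 200 kb, end + 200 kb)` of a
  surviving locus (left edge closed), protein-coding by default — linking
  is measured from the overlap-stage loci, and TSS-based linking is the
  default (gene-body-edge linking is a recognised alternative, flagged in
  metadata); (3) the logical AND of the bulk filter (Wilcoxon signed-rank
  across pairs, BH over all genes, group-mean log₂FC > 1, p_adj < 0.05) and
  the cluster filter (Mann–Whitney rank-sum target-cluster-vs-rest,
  Bonferroni by default, log₂FC > 1 — the funnel's own threshold; the
  conventional single-cell marker setting log₂FC > 0.25 is available as
  `cluster_log2fc = 0.25`); (4) Pearson correlation with each of the four
  master TFs across *tumor* samples only (co-expression is a within-tumor
  claim), BH-adjusted per TF over the candidate list entering the stage —
  not transcriptome-wide, matching the set-intersection construction — kept
  only if r > 0.5 and p_adj < 0.05 for all four. The TFs themselves are
  excluded from the candidate pool: they anchor the test and their
  self-correlation is trivially 1. Spearman is available by configuration.
  A zero-variance expression vector makes r undefined; the pair fails with
  a flag instead of raising.

## Statistical kernels

The paired *t* is computed in closed form (vectorised across regions) with
the t CDF from scipy; BH and Bonferroni adjustments come from statsmodels /
direct formula; the Mann–Whitney test wraps scipy (exact for tie-free groups
of ≤ 12, asymptotic with tie and continuity corrections otherwise). The
Wilcoxon signed-rank test is implemented in-package: zero differences are
dropped, |differences| are mid-ranked, and the exact two-sided p for up to
25 remaining pairs comes from a dynamic program over doubled ranks
(mid-ranks are half-integers, so doubling makes sums integral) that
enumerates all 2ⁿ sign assignments implicitly; above 25 pairs a normal
approximation with tie and continuity corrections is used. The exact branch
is required because tied differences are routine in expression data and the
widely used exact implementations decline ties. Tests cross-check the exact
branch against explicit 2ⁿ enumeration (with ties) and against scipy on
tie-free cases; the approximation agrees with the exact distribution to
about 0.01–0.02 in mid-range p at n ≈ 20, which is the accuracy a
continuity-corrected normal approximation delivers.

## The synthetic cohort

`oncoenh.simulate` generates cohorts with the structure the analysis
assumes; defaults are the study conditions.

* **Design.** 18 matched ChIP-seq pairs (`n_patients`) forming a subset of
  59 matched expression pairs (`n_rna_pairs`) — histone-mark profiling
  typically covers fewer patients than RNA-seq, and the co-expression filter
  needs the larger cohort for r estimates stable enough to compare against
  a 0.5 threshold.
* **Geometry.** One 10 Mb toy chromosome with 500 regions (800–1200 bp) on
  a regular grid. TSSs are placed in inter-region bands ≥ 2.5 kb + jitter
  margin from any region, so that TSS proximity is a *planted* property:
  5% of regions deliberately carry a promoter-proximal gene and must be
  removed by the TSS filter. Two isolation zones (±~220 kb) surround the
  oncogene's enhancer and the "no-overlap" decoy's enhancer so that linking
  outcomes are attributable to a single locus.
* **Peaks.** Each true region emits a peak per sample per mark with
  probability `detection_prob` (0.9), boundaries jittered ±50 bp, plus a
  few spurious single-mark peaks per sample. With detection probability 1
  and zero jitter the tumor catalog equals the planted grid exactly (a
  tested invariant).
* **Counts.** Negative binomial (size 10; var = μ + μ²/10 — Poisson is too
  narrow for biological replicates) with mean = baseline RPKM
  (log₂ ~ N(3, 1)) × shared lognormal patient factor (σ = 0.3) × 2^(planted
  log₂FC, tumor only) × length_kb × library_M. Library sizes are lognormal
  around 2 × 10⁷. The shared patient factor is what makes the paired test
  the right analysis; it cancels exactly in the per-pair log differences.
* **Planted effects.** 10% SOEs with log₂FC ~ N(1.5, 0.3), 10% CDEs
  mirrored, the rest stable.
* **Expression.** A latent per-tumor "squamous activity" drives the four
  master-TF vectors and designated target genes on the log₂ scale with
  pairwise correlation `tf_target_corr` (0.8); normal samples carry
  independent noise. Tumor-upregulated genes get +2 log₂ units. The four
  decoys violate exactly one funnel criterion each: no cluster-peak overlap
  in linking range; no bulk upregulation; no cluster upregulation; no TF
  correlation.
* **Cluster data.** Cluster-specific accessibility peaks cover the forced
  SOEs (oncogene and three linked decoys) plus ~40% of other eligible SOEs;
  a 3-cluster × 100-cell matrix upregulates designated genes (+2.5 log₂) in
  the "squamous" cluster.
* **Determinism.** All randomness flows from one `numpy` generator seeded
  by `SimConfig.seed`; emitted files use fixed formatting (integer counts,
  6-decimal reals, LF newlines) and are byte-identical across runs.

What the generator does **not** emulate: real peak-caller behaviour
(width/score distributions, local background), GC and mappability biases,
copy-number alterations inflating enhancer signal, tumor purity gradients,
cell-type mixtures in the bulk signal, or genuine single-cell count
sparsity (cluster cells are lognormal, not zero-inflated counts). Passing
tests therefore demonstrate that the *statistics and plumbing* behave as
specified under the assumed model, not that thresholds are optimal for any
particular real cohort.

## Problem sizes and runtime choices

The test suite and acceptance script use 500-region cohorts (2000 regions ×
20 replicates for null calibration, on a 40 Mb toy genome to preserve grid
geometry), 25 saturation replicates per k, and 1000 random toy genomes for
the interval oracles. These sizes give stable estimates (binomial 99% CI of
the type-I rate at 2000 regions is ±0.013) while keeping a full run in
seconds.

## Known limitations and open choices

* The order "merge, then support, then filter" and the k27ac-anchored
  common peak are deliberate resolutions of genuinely ambiguous procedure
  descriptions; both are recorded in run metadata and configurable where
  alternatives exist.
* SOE/CDE status is defined by the quantitative test, not by catalog
  presence/absence; per-region tumor/normal support counts are retained in
  the catalogs so a presence/absence reading can be audited.
* The IHC proportion bins as conventionally printed leave 25–26% formally
  unassigned; this implementation closes each bin at its upper edge
  (≤ 25 → 1, ≤ 50 → 2, ≤ 75 → 3, else 4).
* The saturation analysis reports recovery of the *final* SOE definition;
  it does not model accrual order or batch effects across enrolment.
* p-value calibration of the paired *t* on log-NB counts is approximate at
  very low means; with the default baselines (≥ ~1 RPKM) the null type-I
  rate sits inside the binomial 99% band (a tested property).
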