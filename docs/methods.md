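# Methods

## Study design assumed throughout

All statistical machinery assumes a paired two-condition design: each of
`n` donors (default 7) contributes one rifampin-treated and one
vehicle-treated sample. Donors are blocks; the quantity of interest for
every feature is the per-donor treatment effect — log₂(rifampin/vehicle)
for counts, ΔΔCt = Ct_rifampin − Ct_vehicle for cycle thresholds — and
inference is on the mean of those per-donor effects.

## miRNA Ct preprocessing

Order is fixed: merge technical duplicates → remove controls → detection
filter → quantile normalization → differential test. Feature count is
non-increasing through the first three stages.

- **Duplicate merge.** Exactly two technical replicates per biological
  sample are required. Both detected → mean; both undetected → the ceiling
  Ct (default 40, configurable); exactly one detected → the detectable
  value. After merging no missing values remain.
- **Controls.** Features whose names start with U6 or RNU
  (case-insensitive, configurable patterns) are dropped. Removal precedes
  normalization; the order is configurable but removal-first is the
  default because control abundances would otherwise distort the common
  reference distribution.
- **Detection.** A feature is kept if its merged Ct is below the cutoff
  (default 35) in at least `min_samples` (default 4) samples of **either**
  treatment arm. The rule reads the per-sample value as the
  duplicate-averaged Ct, i.e. the merge has already been applied.
- **Quantile normalization.** Every sample column is mapped onto the
  vector of rank-wise cross-sample means. Ties within a column receive the
  mean of the reference values their positions span (verified against
  limma's `normalizeQuantiles(ties=TRUE)` on a frozen example). The
  transform is idempotent and permutation-equivariant in samples.
- **Differential test.** The blocked two-way layout (treatment fixed,
  donor as block) reduces, for two paired conditions, to a one-sample
  t-test of the per-donor ΔΔCt against zero; that is what
  `MirnaDifferential.fit()` computes, with BH adjustment across retained
  features. A zero-variance feature with nonzero effect gets the smallest
  representable p and a warning; an all-zero feature gets p = 1. Effect
  vectors are exposed in the abundance orientation (−ΔΔCt) by default, so
  a positive value means induction; Ct orientation is available because Ct
  is inversely related to log₂ abundance and published sign conventions
  vary.

## RNA-seq fold changes and subset FDR

- **CPM.** count × 10⁶ / library size. The library size defaults to the
  column sum but can be overridden (e.g. when the matrix holds a gene
  subset of a deeper library); the synthetic sample sheets carry a
  `library_size` column for exactly this reason — with subset column sums
  as libraries, strongly induced genes depress every other gene's CPM in
  the treated arm (composition bias) and manufacture false positives.
- **Expressed filter.** Keep genes with CPM ≥ `min_reads` (default 10) in
  **all** samples of at least one arm. The quantifier (all / any / ≥ k) is
  configurable because the underlying rule ("at least 10 reads present
  after CPM normalization") does not pin it down.
- **Per-donor log₂ fold change.** log₂(rif/veh) on CPM values. A zero is
  replaced by the minimum nonzero normalized value of the whole matrix
  (global mode, default) or of the gene's row (per-gene mode); the
  substitution touches only zeros.
- **Tests.** Default: one-sample t on per-donor log₂FC (donor-paired).
  Alternative pooled mode: an exact binomial test of the summed treated
  counts against the library-size ratio — the reading under which
  deep-coverage data can produce astronomically small p-values that a
  7-donor t-test cannot. The mode is recorded in the results object.
- **Subset FDR.** BH step-up q-values are computed over the catalogue
  genes present in the matrix only (statsmodels `multipletests`). Genes
  outside the catalogue get no q and cannot shift catalogue q-values.
- **Display convention.** Mean linear fold f = 2^(mean log₂FC) is shown
  signed-reciprocally: f for f ≥ 1, −1/f otherwise, so magnitudes are
  always ≥ 1, reductions are negative, and exactly 1 (no change) prints
  as 1.0.

## Exact permutation Spearman at small n

The correlation engine is built for 7-point effect vectors, where normal
theory is indefensible and the full permutation null is cheap: p is the
fraction of all n! orderings of one vector's ranks whose |ρ| reaches the
observed |ρ| (two-sided by the |ρ| tail, which equals twice the one-sided
tail under the symmetric tie-free null). Ranks are average ranks; with
ties the enumeration permutes the observed rank multiset, each of the n!
orderings keeping equal weight. Enumeration is capped at n = 8 (40 320
permutations); beyond that the t-approximation is used only on explicit
request, with a warning. Numerically, ρ is affine in the inner product of
the centered ranks, so the 5040 dot products collapse to one cached
matrix product; the |ρ| threshold is applied with a 10⁻⁹ guard so
lattice-equal permutations are never dropped to floating-point error.
Significant records are split into positive/negative panels and can be
restricted to features whose own differential q < 0.05.

## Promoter windows and condition-unique peaks

Annotation rows are UCSC refGene convention (0-based half-open). The TSS
is txStart+1 on the plus strand and txEnd on the minus strand, reported
1-based. Promoter windows are TSS ± flank (default 2000 bases), clipped at
base 1, computed per isoform; a gene "has a binding site" if any isoform
window is hit, and the per-gene report keeps the isoform with the smallest
|signed distance| (ties: lexicographic transcript id). Peaks are BED
half-open; "unique to treatment" means zero shared bases with every
control peak, so a book-ended peak survives. Overlap requires ≥ 1 shared
base; the peak center (start+end)/2 is kept at 0.5-base resolution, and
the signed center-to-TSS distance is oriented by transcription direction
(downstream positive) by default, with a purely genomic mode available
because published tables do not disambiguate the convention. A center can
legitimately lie outside the window while its interval reaches in, so
|distance| may exceed the flank. The interval index is an interval tree,
but the contract is the naive all-pairs scan, and the test suite holds the
two equal on random fixtures.

## ΔΔCt quantification

ΔCt = Ct_reference − Ct_target (reference-minus-target), ΔΔCt =
ΔCt_treated − ΔCt_control, fold = 2^ΔΔCt. This sign pairing is the
published protocol's and is internally consistent: a one-cycle drop of the
target under treatment doubles the estimate. The more common
target-minus-reference ΔCt with 2^(−ΔΔCt) gives identical folds; both
conventions flip together, and the implementation documents this rather
than "correcting" it. SEM is computed on per-replicate ΔΔCt values and
carried to the fold scale as the asymmetric band 2^(mean ± SEM), because
averaging linear folds is biased; the SEM of per-replicate folds is
reported alongside for comparison. Significance is a two-sample t-test
between conditions' ΔCt values (default 4 biologic replicates per
condition).

## Synthetic data generator

The generator emulates the paired seven-donor hepatocyte study with a
fully serializable truth manifest; one integer seed determines every byte
of output.

- **Counts.** Baseline expression is log-uniform in CPM (background
  5–500; planted transporters 2000–10000 — hepatic transporter mRNAs are
  abundant, and this keeps Poisson rank noise below the planted donor
  spread). Two multiplicative donor factors are drawn per gene and shared
  by the donor's two libraries: a log-normal baseline (σ = 0.3 log₂) and a
  gamma factor with CV² = dispersion (default 0.1). Counts are Poisson
  around the resulting means, so each count is marginally negative
  binomial with dispersion 0.1 while the biological factors cancel inside
  a donor's rifampin/vehicle ratio — the property that lets the real
  paired design resolve sub-2-fold effects with extreme significance.
  Planted genes carry per-donor log₂ effects equal to the target fold plus
  a fixed symmetric spread (σ = 0.2 log₂, a permuted grid), giving the
  donor-to-donor response variation that makes cross-feature correlations
  meaningful. The default manifest plants 21 fold changes (12.67 down to
  ±1.34). Library sizes equal the nominal depth (default 10⁶) and are
  written to the sample sheet. A few non-catalogue genes exercise the
  subset-FDR contract, and designated genes are forced to zero in the
  vehicle arm to exercise zero replacement.
- **Ct matrices.** Technical duplicates with Gaussian replicate noise
  (σ = 0.25 cycles), censored to undetected at the ceiling (40). A coupled
  miRNA's ΔΔCt is a linear — hence monotone — transform of its partner
  gene's per-donor log₂ effect: −ΔΔCt_d = sign × (1.5 + 8·(e_d − ē))
  cycles. Centering around a 1.5-cycle base shift and planting regulated
  features mid-dynamic-range (24–30 Ct, against a 20–34 background)
  keeps both conditions inside the densely supported part of the Ct
  distribution, where quantile normalization preserves cross-donor
  ordering; outliers pinned to the sparse tails of the reference grid
  would otherwise lose their donor ranking. 300 background miRNAs
  approximate the scale of a retained OpenArray panel. Features with true
  Ct ≈ 39 survive the ceiling but fail detection; features above the
  ceiling exercise the both-undetected merge rule.
- **Peaks and annotation.** A synthetic chromosome with evenly spaced,
  non-overlapping gene models (random strands, 1–2 isoforms). Flagged
  genes receive a treated-only peak intersecting their ±2 kb window — one
  with its center beyond the flank to exercise that boundary case — and
  the peak sets include treated decoys overlapping control peaks (removed
  by uniqueness), control-only peaks, and intergenic treated-unique peaks.

What the generator does **not** emulate: GC/length biases, isoform-level
quantification, batch structure across OpenArray runs, miRNA target
(seed-site) relationships, or any attempt to fit the real deposited data.
Passing tests on synthetic data therefore demonstrate the correctness of
the analysis rules and the recoverability of planted effects under the
stated noise model, not performance on the real study's raw data.

## Numerical and degenerate-input choices

- Zero-variance effect vectors: differential tests report p = 1 when the
  effect is exactly zero and the smallest representable double (with a
  warning) when it is not; correlation raises an error, since ρ is
  undefined for a constant vector.
- BH q-values are clipped monotone by the standard step-up; q ≥ p always.
- Promoter windows at a chromosome start clip to base 1.
- Chromosome naming style mismatches ("chr1" vs "1") between peaks and
  windows abort with a normalization hint instead of silently reporting
  zero overlaps.
- All thresholds (ceiling 40, cutoff 35, 4-of-7, CPM ≥ 10, flank 2000,
  α = 0.05, q < 0.05) are configuration defaults, not constants.

## Problem sizes in the test suite

The suite runs the full synthetic study at the default conditions (7
donors, depth 10⁶, 21 planted folds) once, plus 200 reduced null studies
(depth 10⁵, 80 background genes, 3 planted folds) for the empirical FDR
check, 100 random interval fixtures against the naive oracle, and 500-draw
Monte-Carlo power checks; these sizes keep the whole suite under a minute
of statistical work while leaving every estimate's Monte-Carlo error well
below the margins being asserted. The empirical FDR assertion allows the
mean false-discovery proportion its two Monte-Carlo standard errors above
the nominal 0.05, which is the correct form for an inequality checked by
simulation.

## Known limitations

- The exact-permutation engine is factorial in n and capped at n = 8.
- The blocked ANOVA is implemented only in its two-condition (paired
  t-test) reduction; multi-condition layouts are out of scope.
- The pooled binomial test ignores donor structure and overdispersion and
  is provided for compatibility, not recommended for inference.
- The packaged transporter catalogue is a synthetic-completed assembly:
  the family scaffold and the clinically relevant subset are real gene
  symbols, but family membership is filled with systematically named
  members and should be replaced with a curated list for real analyses.
- Reproducing published peak counts or fold-change tables requires the
  original external datasets, which the package deliberately does not
  download or embed.
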