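# Methods

This note documents the statistical models, parameter defaults, numerical
choices, and known limitations of each stage of the `recurdrift` pipeline.
Nothing here states an empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Somatic SNV filter cascade

Candidate somatic calls from tumor samples — most without a matched
normal — are cleaned by five filters applied in a fixed order, each removal
attributed to the first failing filter:

1. *Population allele frequency.* Both population frequencies (gnomAD-style
   and SweFreq-style columns) must be exactly 0 or missing. Missing is
   encoded as absent and is deliberately distinct from 0; both pass.
2. *Allelic depth.* Tumor alt support ≥ 2; when a matched normal exists its
   alt support must be ≤ 1.
3. *Coverage.* Tumor depth ≥ 10; matched normal depth ≥ 10 when present.
4. *Panel of normals.* The variant key (chrom, pos, ref, alt) must not
   occur in the blacklist built from keys seen in ≥ 2 distinct normal
   samples. Variant identity always includes both alleles; multi-allelic
   records must be decomposed upstream.
5. *Purity-scaled probability ratio.* With purity *t* ∈ (0, 1], alt support
   *s* and depth *c*, two binomial model comparisons are made:
   heterozygous (p_cancer = 0.5·t vs p_background = 0.5) and homozygous
   (t vs 1.0). The statistic is log₂[2·P(s; c, p_cancer)/P(s; c,
   p_background)], computed in log space via the log-gamma pmf so high
   depths cannot underflow. The variant is kept when any *defined* model's
   ratio exceeds the threshold (default −1). Samples without a purity
   estimate skip this filter entirely.

**Zero-background guard.** The homozygous background pmf P(s; c, 1.0) is
zero whenever s < c, which taken literally would make the homozygous branch
keep every subclonal variant and render the filter vacuous. A model whose
background pmf is exactly zero is therefore declared non-informative and
excluded from the keep disjunction; if every model is non-informative the
variant is kept. The evaluation object exposes both ratios (including the
`None` non-informative flag) so the literal behavior can be reconstructed.

The factor 2 inside the ratio is implemented as written, so at the −1
threshold the background model is 4× more likely than the cancer model; the
threshold is an exposed parameter.

The kept set is the conjunction of the five predicates and is therefore
invariant under filter reordering; only the attribution counts depend on
the order (property-tested).

After the cascade, the cancer-gene SNV list is restricted by annotation:
impact MODERATE or HIGH, excluding synonymous, UTR, and up-/downstream
consequence terms. The cascade runs first and the restriction second; both
steps are separate functions so the order can be changed by the caller.

## Mutational signatures

Contexts are pyrimidine-centered: a purine reference base is
reverse-complemented together with its flanks, mapping the 192 raw
(ref, alt, flank) combinations two-to-one onto 96 classes. Flanking bases
come from the variant records; no reference-genome lookup happens inside
the module.

Refitting solves min‖m − S·w‖₂ subject to w ≥ 0 with the Lawson–Hanson
active-set algorithm (`scipy.optimize.nnls`), which is deterministic and
bit-reproducible on one platform, then normalizes w to fractions. The fit
satisfies the Karush–Kuhn–Tucker conditions (tested) and, for spectra that
are exact nonnegative combinations of signature columns, has zero residual.
An all-zero spectrum returns all-zero fractions with an `empty_spectrum`
flag rather than an error.

Signature short-listing keeps the top half of signatures by mean fraction
across samples — "first and second quartiles" read as the *upper* two
quartiles, with ties at the median retained, since the point of the step is
to keep signatures with enough contribution. The direction is a documented
reading, not a derivation.

Per-patient evolution is delta = fraction(IBTR) − fraction(PT); because
both vectors lie on the simplex, deltas sum to zero.

## Copy number

Coverage is tallied in fixed 10-kb, 0-based half-open bins. The GC-bias
curve is fit by locally weighted regression of coverage on GC fraction
(`statsmodels` lowess, bandwidth 0.3, 3 bisquare re-weighting iterations)
and evaluated by interpolation; a degenerate GC range falls back to a flat
curve with a warning. Adjusted coverage is coverage × median(fit)/fit(gc),
which preserves the sample's median; bins with non-positive fitted
expectation are masked and stay excluded from centering, segmentation and
everything downstream (no imputation).

Log₂ ratios use the matched normal on the same bin grid when available,
otherwise the sample's own median adjusted coverage, and are then
median-centered.

**Simplified CBS.** Per chromosome, the segmenter recursively finds the
contiguous arc maximizing the two-sample t statistic against its complement
(vectorized scan over all arcs; arcs and complements must each hold ≥
`min_bins` = 5 bins and may not strand a shorter fragment at an end). The
split is accepted when its permutation p-value — the fraction of
within-interval permutations whose own max-arc statistic reaches the
observed one — is below `alpha` = 0.01 with `n_perm` = 1000 permutations
and sequential early stopping once acceptance is impossible. Adjacent
segments whose means differ by less than `merge_epsilon` = 0.2 are merged
afterwards; this prunes occasional spurious micro-segments well below the
±0.75 calling threshold while leaving real events (the smallest amplitude
of interest) untouched. The algorithm family is standard; the parameter
defaults are this package's own and are all exposed. Zero-variance splits
are capped at a large finite statistic so permutation comparisons stay
well-defined.

Gene mapping takes the unweighted mean of `mean_log2` over all segments
overlapping at least one exon of the gene (exon intervals only, not gene
bodies; unweighted because no exon-length weighting is specified anywhere
and the plain averaging rule is the simplest consistent choice). Genes
without any overlapping segment are omitted.

**CN scale.** Per-gene CN entering the paired comparison is reported on the
relative copy-ratio scale 2^(mean log₂) with diploid baseline 1. On this
scale the minimum-CN rule (both pair members ≥ 0.5) excludes deeply deleted
genes only, and ΔCN = CN(IBTR) − CN(PT) with gain > +0.75 / loss < −0.75
behaves sensibly for diploid-baseline genes: a recurrence-only one-copy
gain over a diploid region moves ΔCN from 0 to ≈ 1. Interpreting the 0.5
minimum on the centered log₂ scale instead would render almost every gene
not-evaluable (a diploid gene sits at log₂ ≈ 0 < 0.5) and no loss could
ever be called from a diploid baseline, so the ratio scale is the default;
`scale="log2"` substitutes the literal log₂ reading. `delta_cn_calls`
itself is pure threshold arithmetic on whatever scale its inputs carry.

## Multi-omic drift

Each layer's feature × sample matrix is reduced to complete-case rows
(any row with a missing value anywhere is dropped) so every pairwise
comparison within a layer uses the same feature set. Drift per patient is
1 − cosine similarity between the pair's two columns: range [0, 2],
zero exactly for positively proportional profiles, and invariant to
positive per-column scaling — hence no cross-layer or per-column
normalization is applied before the computation. Layers are processed
independently.

Pair co-clustering is operationalized as *mutual nearest neighbors* on the
full sample × sample cosine-dissimilarity matrix: a pair co-clusters iff
each member's nearest other sample is its partner, which is exactly the
condition for the two leaves to join first under single-linkage and an
explicit, testable surrogate for "the pair forms its own clade" in the
dendrogram. The dendrogram itself uses average linkage by default
(configurable) and can be exported as Newick text.

## Clinical associations and histo-score

* Fisher exact tests are two-sided by the probability-mass definition
  (summing all tables with the observed margins whose hypergeometric
  probability does not exceed the observed table's) — the convention that
  reproduces the reference cohort-description p-values; a zero margin
  returns p = 1 with a warning.
* Chi-square tests are Pearson without continuity correction (validated by
  the df = 2 identity p = exp(−χ²/2) and by the printed grade-table value).
  Levels absent from both groups are dropped before testing; a table left
  with fewer than two informative rows or columns is reported as
  not-evaluable (NaN) rather than an error.
* Wilcoxon–Mann–Whitney is exact for tie-free combined samples of ≤ 20,
  otherwise the normal approximation with tie correction; all-tied input
  returns p = 1 with a warning.
* Benjamini–Hochberg adjustment is applied within an explicitly declared
  family (one `group_association_family` call = one family); families are
  never inferred.
* Spearman uses average ranks and the two-sided t-approximation p-value.
* The histo-score is z(Ki-67 %) + z(leukocyte %), standardized by the
  cohort mean and sample standard deviation (ddof = 1); a zero-variance
  marker raises an error naming the degenerate marker.
* Median splits assign scores ≤ median to the "low" group (ties low); an
  all-one-group split warns as degenerate.
* The log-rank test is the standard two-group 1-df chi-square
  (`lifelines`); no events at all returns p = 1 with a warning.
* Missing clinical categories are dropped pairwise per test and each result
  records the n actually used.

## Synthetic cohort generator

The generator emulates the statistical structure of a 27-pair
primary/recurrence cohort on a small synthetic genome (chrA 10 Mb, chrB
8 Mb; names and coordinates never pretend to be a real reference build).
Defaults, chosen once as desk-scale stand-ins for a shallow-WGS breast
cohort: purity uniform on (0.3, 0.9), variant depth Poisson with mean 30,
300 clonal variants per pair plus 60 primary-private and 100
recurrence-private (recurrences gain more than they lose), 10% germline
contaminants, 5% recurrent artifacts, bin coverage mean 100 with 5%
proportional Gaussian noise, RNA 12,750 and protein 4,640 features
(matching the complete-case table sizes of the study design this emulates),
drift σ = 0.5, and one recurrence-only gain plus one loss.

Mechanics worth knowing:

* All randomness flows from per-patient substreams seeded as
  `(seed, patient_index)`, so adding patients never perturbs earlier ones,
  and two runs with the same config are byte-identical.
* A variant site's strand representation is fixed at the site level (half
  are emitted purine-centered), so shared variants carry the identical key
  in both pair members while still exercising pyrimidine normalization.
* Clonal (shared) variants draw their contexts from the *primary* mixture —
  they arose in the ancestral clone — so a recurrence sample's aggregate
  spectrum follows the count-weighted blend of the two mixtures; the truth
  set records that blend as the recurrence's expected fractions.
* Somatic alt support is Binomial(depth, purity·CCF/2) with CCF = 1 (no
  subclonal structure is simulated); germline contaminants sit at VAF 0.5
  with population AF uniform(0.01, 0.5); artifacts sit at VAF 0.3 with
  clean population AF and are planted in exactly two of the five simulated
  normals.
* Expression: per-feature Gaussian baselines (RNA mean 8, protein mean 20,
  sd 2 across features; sd 1 across patients), a +0.5 shift on a fixed 5%
  feature subset for ER-negative patients as a group effect, and
  IBTR = PT + N(0, drift_sigma) per feature. This makes the expected
  cosine drift monotone in drift_sigma, which the property tests exploit.
* The GC-bias curve used for cohort bins is a smooth unimodal function of
  GC with a 2× dynamic range; the GC track itself is Beta(20, 20) per bin
  and shared genome-wide across samples.
* Clinical tables draw biomarker frequencies (ER+ 0.65, PgR+ 0.45, Ki-67
  high 0.55, ERBB2 amplified 0.18, and primary-to-recurrence switch
  probabilities of 0.22/0.26 for PgR/Ki-67) in line with a recurrence
  cohort's published marginals; recurrence-free survival times are
  log-normal (median ≈ 27 months) with all events observed.

Cohort configurations round-trip through YAML
(`recurdrift.io.load_config_yaml` / `save_config_yaml`); every key is
optional and falls back to the defaults above:

```yaml
n_patients: 27
purity_range: [0.3, 0.9]
depth_mean: 30.0
n_shared_variants: 300
n_private_pt: 60
n_private_ibtr: 100
signature_mix_pt: [0.6, 0.3, 0.1]     # simplex over the signature matrix
signature_mix_ibtr: [0.3, 0.3, 0.4]
cn_events:
  - {chrom: chrA, start: 2000000, end: 3000000, log2_shift: 1.0, target: IBTR}
drift_sigma: 0.5
germline_af_fraction: 0.10
pon_artifact_fraction: 0.05
seed: 0
chrom_lengths: {chrA: 10000000, chrB: 8000000}
```

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: subclonal phylogenies and copy-number-driven
VAF distortion, indels and structural variants, linkage between variant
positions and the expression matrix, realistic GC sequence composition,
mappability artifacts, batch effects, or informative censoring. Tests built
on it establish that each stage recovers the structure it targets under its
stated noise model, not field performance on patient data.

## Problem sizes used by the checks

The acceptance script and heavy tests run: the six contingency tables at
their printed counts; the purity-filter grid over all s ≤ c ≤ 25 and ten
purity levels; signature refits over 20 seeds of 5,000-draw multinomial
spectra from 2–4 signature mixtures; copy-number recovery over 10 seeds of
a 1-patient, 5-Mb, 500-bin pair with one injected +1.0 log₂ event spanning
10 genes at 10% bin noise; and drift over 20 seeds × 4 drift levels of
small 2–4-patient cohorts. These sizes keep the whole suite in the
single-digit minutes on one CPU while leaving every statistic's sampling
error far below its acceptance margin.

## Known limitations

* The simplified CBS lacks DNAcopy's hybrid p-value, MAD-based undo, and
  smoothing; on very long tracks the O(n²) arc scan dominates runtime.
* The quartile direction in signature short-listing and the CN scale of the
  minimum-CN rule are documented readings of ambiguous prose, exposed as
  options rather than hard-coded certainties.
* Cosine drift is purity-confounded in real tumors; no purity adjustment is
  applied here.
* The Fisher two-sided convention differs from the doubled-one-tail
  definition used by some software; the alternative is one line away via
  `scipy.stats.fisher_exact` but is not exposed as a package option.
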