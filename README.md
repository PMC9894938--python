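# recurdrift

Paired primary-tumor / in-breast-recurrence multi-omic evolution analysis.

When a breast cancer recurs in the same breast (an ipsilateral recurrence),
the recurrent tumor has evolved from its primary: it gains and loses somatic
mutations and copy-number segments, its mutational processes shift, and its
transcriptome and proteome drift away from the primary's. `recurdrift`
implements the full analysis chain for matched primary/recurrence (PT/IBTR)
pairs:

1. **Somatic SNV filter cascade** (`variant_filters`) — five filters in
   fixed order: population allele frequency (must be 0 or missing in gnomAD
   and SweFreq), allelic depth (tumor alt support ≥ 2, normal ≤ 1), coverage
   (≥ 10 reads, tumor and matched normal), a panel-of-normals blacklist
   (variants seen in ≥ 2 normal samples), and a tumor-purity-scaled binomial
   probability-ratio filter. For a sample with purity *t*, alt support *s*
   and depth *c*, the last filter evaluates

   log₂ [ 2 · P(s; c, p_cancer) / P(s; c, p_background) ]

   with (p_cancer, p_background) = (0.5·t, 0.5) for the heterozygous model
   and (t, 1.0) for the homozygous model, where P(k; n, p) is the binomial
   pmf; the variant is kept if any defined model's log₂ ratio exceeds −1.
2. **Mutational-signature refitting** (`mutational_signatures`) — SNVs are
   classified into the 96 pyrimidine-centered trinucleotide contexts; the
   count spectrum **m** is refit against a reference signature matrix **S**
   (COSMIC v2 layout) by non-negative least squares, min‖**m** − **S w**‖₂
   s.t. **w** ≥ 0, and reported as fractions **w**/Σw. Signatures are
   short-listed by mean contribution (top two quartiles), and per-patient
   evolution is the contribution delta fraction(IBTR) − fraction(PT).
3. **Copy-number chain** (`copy_number`) — coverage in 10-kb bins is
   GC-corrected with a robust lowess curve, converted to median-centered
   log₂ ratios (vs matched normal or the sample's own median), segmented by
   a simplified circular binary segmentation, mapped to genes through exon
   overlap, and compared within pairs: ΔCN = CN(IBTR) − CN(PT) with gain
   > +0.75, loss < −0.75, and both values ≥ 0.5 (relative copy-ratio scale,
   diploid = 1).
4. **Multi-omic drift** (`omics_drift`) — per patient and per layer (CN,
   RNA, protein), dissimilarity = 1 − cosine similarity between the pair's
   complete-case feature columns, plus hierarchical clustering with
   mutual-nearest-neighbor pair co-clustering flags.
5. **Clinical associations** (`clinical_assoc`) — Fisher exact / chi-square
   contingency tests, Wilcoxon rank-sum with Benjamini–Hochberg adjustment,
   Spearman correlation, the histo-score
   z(Ki-67 %) + z(infiltrating-leukocyte %), median-split grouping, and the
   two-group log-rank test on recurrence-free survival.
6. **Synthetic cohort generator** (`synthetic_cohort`) — a fully seeded
   paired cohort with known ground truth (clonal structure, signature
   mixtures, injected CN events, drift level) so every stage is testable
   without patient data.

## Worked example

```python
import numpy as np
from recurdrift import variant_filters as vf, mutational_signatures as ms
from recurdrift import copy_number as cn, omics_drift as od
from recurdrift.synthetic_cohort import (
    CNEvent, CohortConfig, random_signature_matrix, simulate_cohort)
from recurdrift.io import variants_from_frame

sigs = random_signature_matrix(k=3, seed=11)
config = CohortConfig(
    n_patients=4, seed=42,
    signature_mix_pt=[0.6, 0.3, 0.1], signature_mix_ibtr=[0.3, 0.3, 0.4],
    chrom_lengths={"chrA": 3_000_000, "chrB": 2_000_000},
    cn_events=[CNEvent("chrA", 1_000_000, 2_000_000, 1.0, "IBTR")],
    n_rna_features=2000, n_protein_features=800)
bundle, truth = simulate_cohort(config, sigs)

# 1. filter cascade
pon = vf.build_panel_of_normals(bundle.normal_variant_sets)
purity = {r["sample_id"]: vf.PurityEstimate(r["sample_id"], r["purity"])
          for r in bundle.purity.to_dict("records")}
kept = {}
for sample in ("P00_PT", "P00_IBTR"):
    records = variants_from_frame(bundle.variant_tables[sample])
    kept[sample], report = vf.apply_cascade(records, purity[sample], pon)
    print(sample, "kept", report.surviving, "of", report.input_count,
          "removed:", report.removed)

# 2. SNV turnover and signature refit
gains, losses, shared = vf.snv_gain_loss(
    {v.key for v in kept["P00_PT"]}, {v.key for v in kept["P00_IBTR"]})
print("SNV turnover: gains", len(gains), "losses", len(losses),
      "shared", len(shared))
for sample in ("P00_PT", "P00_IBTR"):
    spectrum = ms.build_spectrum(kept[sample], sample)
    contrib = ms.fit_contributions(spectrum, sigs)
    print(sample, "signature fractions", np.round(contrib.fractions, 3))

# 3. paired copy-number calls
segs = {}
for role in ("PT", "IBTR"):
    bins = bundle.coverage_bins[f"P00_{role}"]
    model = cn.fit_gc_model(bins)
    track = cn.compute_log2_ratios(bins, cn.adjust_coverage(bins, model),
                                   sample_id=role)
    segs[role] = cn.segment_track(track, seed=42)
calls = cn.paired_gene_cn_calls(segs["PT"], segs["IBTR"], bundle.gene_exons)
print("CN gains:", sorted(c.gene for c in calls if c.call == "gain"))

# 4. expression drift per pair
drift = od.pair_dissimilarities(od.OmicsMatrix("RNA", bundle.expression),
                                bundle.pairs)
print("RNA drift:", {d.patient_id: round(d.value, 5) for d in drift})
```

Output:

```
P00_PT kept 351 of 421 removed: {'population_af': 46, 'allelic_depth': 0, 'coverage': 0, 'pon': 15, 'tpes': 9}
P00_IBTR kept 387 of 461 removed: {'population_af': 46, 'allelic_depth': 0, 'coverage': 0, 'pon': 15, 'tpes': 13}
SNV turnover: gains 103 losses 67 shared 284
P00_PT signature fractions [0.533 0.375 0.092]
P00_IBTR signature fractions [0.497 0.336 0.166]
CN gains: ['G0010', 'G0011', 'G0012', 'G0013', 'G0014', 'G0015', 'G0016', 'G0017', 'G0018', 'G0019']
RNA drift: {'P00': 0.00191, 'P01': 0.00177, 'P02': 0.0018, 'P03': 0.00187}
```

Reading the numbers: the cascade removed all 46 planted germline
contaminants by their population frequency and all 15 recurrent artifacts
via the panel of normals; the purity filter trimmed a handful of
implausible-support calls. The recurrence gains more variants than it loses
(103 vs 67), its fitted signature fractions shift toward the third process
(0.092 → 0.166, consistent with the configured mixture change blended over
the clonal background), the injected 1-Mb recurrence-only amplification is
called as a gain on exactly the ten genes it covers, and per-pair
expression drift is small and uniform at the configured noise level.

A thin CLI mirrors the library: `recurdrift simulate | filter-variants |
signatures | cn | drift | associate | histoscore` (see `--help`).

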