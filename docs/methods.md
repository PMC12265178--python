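# Methods

This note records the statistical procedures implemented in
`periscope`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Preprocessing

Genes detected (count > 0) in fewer than 50% of samples are removed;
the boundary is inclusive (a gene detected in exactly half the samples
is kept). "Detected" is defined as a nonzero count because bulk
RNA-seq zero-inflation at typical depth makes a presence/absence
threshold at zero the least arbitrary choice; the fraction is
configurable. The filter is applied once per analysis cohort, not per
comparison subset.

Two transforms are offered. `log_cpm` is `log2(1e6·count/library + 1)`
(pseudocount 1, base 2). `vst_like` then applies one strictly
increasing elementwise map `t(x) = ∫ dx/√v(x)`, where `v(·)` is the
pooled mean–variance trend estimated by a running mean of per-gene
variances over mean-sorted genes (window `max(5, n_genes/20)`, variance
floor `max(1e-3, 5% of the median variance)`). Because the map is a
single monotone function of the value, per-sample gene ranks, per-gene
equality across samples, and column-permutation equivariance are all
preserved exactly; the parametric dispersion-model variance-stabilizing
transforms used with negative-binomial count models share these
properties but fit the trend differently. With fewer than 3 samples or
10 genes the trend is not identifiable and the transform falls back to
log-CPM.

Batch adjustment is location-only: per gene, each batch's
mean is shifted onto the pooled mean. A protected grouping (e.g.
clinical subtype) can be supplied; its per-group gene means are
restored after centering so the biological contrast of interest is not
absorbed into the batch term. Location-scale count-model batch
correction is out of scope; the option exists so that multi-batch
inputs are not silently confounded. Single-sample batches pass through
with a warning.

## Single-sample enrichment and preranked GSEA

The single-sample score ranks each sample's genes by expression
(descending, ties broken by gene id so the result is independent of
input order), assigns rank values N…1, and walks the list: in-set
positions add `rank^w / Σ_in-set rank^w`, out-of-set positions subtract
`1/(N−m)`. The score is the sum of the running-sum curve (the area
between the curve and zero), optionally divided by the max−min spread
of all raw scores in the call. The weight default 0.25 follows the
single-sample GSEA convention. Scores depend on expression only
through ranks, so they are invariant to any monotone per-sample
transform. A set equal to the whole universe has decrement 0 and is
uninformative by construction. Sets with fewer than `min_set_size`
(default 5) genes present are dropped with a warning.

Gene ranking for contrasts uses the Welch t statistic (unpaired) or a
one-sample t on per-patient differences (paired longitudinal design),
which preserves the signed-ranking semantics that a count-model Wald
statistic would provide while staying closed-form; the tests verify
ranking agreement with simulated true effects, not with any external
tool. Zero-variance genes receive a finite sentinel (±1e12, sign of
the mean difference) rather than ±∞ so downstream weighted sums stay
finite.

Preranked GSEA computes the weighted Kolmogorov running-sum extremum
(weight 1 on |statistic|), with the extremum chosen as the earliest
position within 1e-12 of the maximal |deviation| so near-ties between
the positive and negative excursions resolve deterministically. The
null is gene-label permutation (random m-subsets of positions),
matching the convention of preranked enrichment tools; p-values use
additive smoothing `(1+hits)/(1+n_same_sign)` over same-sign
permutations and can never be 0; NES divides ES by the mean |null ES|
of the same sign; BH adjustment runs across exactly the sets scored in
one call. The leading edge is the in-set genes at or before (positive
ES) or strictly after (negative ES) the extremum.

Bootstrap stability resamples samples with replacement within each
contrast group (stratification by a grouping such as subtype is
supported and used by default in cohort analyses), reruns ranking +
GSEA, and reports per set how often it is called (padj < α) in either
direction; the stability fraction is `max(n_pos, n_neg)/n_iter` with 50
iterations by default. Degenerate draws (a group collapsing to one
distinct sample) are redrawn up to 10 times.

## TCR diversity

Shannon diversity uses natural log over read-count proportions (reads,
not unique clones, define pᵢ), with no evenness normalization.
Repertoires with H = 0 or fewer than 10 clones are excluded as low
quality; the clone-count boundary is strict (exactly 10 is retained)
and filters are applied after duplicate-CDR3 rows are merged.
Longitudinal deltas are `H(early) − H(baseline)` per patient; a
negative delta indicates clonal expansion.

## Deconvolution

Cell fractions are estimated per sample by non-negative least squares
`min ‖xᵀR − b‖, x ≥ 0` over a cell-type × signature-gene reference,
after scaling the sample's signature-gene vector to unit total (so
coefficients are comparable across library sizes). Log-scale input is
exponentiated back to linear scale first. NNLS is used because the
recovery properties we rely on (exact noise-free recovery for full-rank
references, unbiasedness under count noise) are testable from first
principles; support-vector regression variants of reference-based
deconvolution are not reimplemented and no concordance with them is
claimed. `relative` mode renormalizes coefficients to sum to one;
`absolute` mode reports raw coefficients (no external scaling constant
is applied). The reference builder restricts profiles to the union of
marker genes, scales each cell type to equal total, reports the
condition number, and rejects collinear profile pairs. A combined
classical+non-classical monocyte row is exposed for monocyte-abundance
contrasts.

## PICS clustering

Samples (baseline + early treatment) are clustered by agglomerative
linkage on Euclidean distances between their immune-cell score
vectors. Scores are z-scored per set before the distance computation
(flag to disable): without standardization the partition is dominated
by whichever sets have the largest score spread. The linkage default
is `complete` (the common default of hierarchical clustering in R-based
workflows), with `ward` and `average` available. Samples are
processed in sorted-id order and clusters relabelled by first
appearance, so the partition is independent of input column order.
The tree is cut to exactly k clusters (k = 7 by default, a config
input, not an estimated quantity).

Clusters are annotated by supertype: a supertype (T cell, myeloid, B
cell, NK) is included in the cluster name when the mean centroid score
of its member sets exceeds the global mean by more than the margin
(default 0 — any positive excess), ordered by decreasing excess
("Myeloid-NK-T cell"); clusters with no elevated supertype are named
"Mixed". New samples are assigned by nearest centroid (ties to the
lower cluster index), giving a reusable classifier alongside the
fit-time partition. Composition change is, per subtype × arm, the
fraction of patients whose cluster label differs between two
timepoints; patients missing either timepoint are omitted.

## Composite scores

The T-cell composite is the mean of per-gene z-scores (ddof 1) across
the scoring cohort — the standard signature-score convention chosen
because the score should be location/scale-free per gene; a
single-set enrichment score is available as an alternative through the
chemotaxis path. All samples passed in one call form the z-scoring
cohort (baseline and on-treatment together, whole cohort rather than
within subtype), so longitudinal deltas are on a common scale. The
19-gene effector panel is a required input on real data; the synthetic
truth designates a 19-gene cytotoxic-effector marker block as its
counterpart. Zero-variance panel genes contribute 0 and missing panel
genes are logged and skipped. The leukocyte-chemotaxis score is the
single-set single-sample enrichment score of a chemotaxis program gene
set.

## Response model

Features per patient: TNBC indicator; Δ T-cell composite
(early − baseline), TNBC only; baseline T-cell composite, HR+ only;
baseline TCR Shannon (raw H, untransformed); Δ chemotaxis score, HR+
only. Subtype conditioning is interaction masking: each raw feature is
centered on the mean over the training-cohort patients it applies to,
then set to exactly 0 for the non-applicable subtype. Centering makes
the masked zeros equal to "at the training mean", so masking does not
inject an artificial subtype offset; test cohorts are centered with the
training means.

The fit is maximum-likelihood logistic regression (binomial family,
logit link; IRLS, deviance tolerance 1e-8, 100 iterations). Perfect or
quasi-separation — detected by non-finite estimates, |coefficient|
above 30, or Wald SE above 1e3 — flags the model and substitutes a
ridge-stabilized refit (L2 penalty 1e-4), which carries no Wald
intervals.

AUC is the Mann–Whitney statistic (ties ½); its variance, 95% CI and
two-sided test against 0.5 use the DeLong placement method. The
optimal cutoff maximizes Youden's J over observed thresholds
(classification rule: positive iff score ≥ threshold; ties take the
lower threshold). Cross-validation is stratified k-fold (default 10)
with seeded shuffling; every training fold re-centers features on its
own patients so no held-out information leaks; Cohen's κ is computed
from pooled out-of-fold predictions thresholded at 0.5, with the κ at
the pooled Youden cutoff reported alongside. Train/test evaluation
does not require disjoint cohorts (pooled train = test is a supported
design) but logs any overlap prominently as an overfitting caveat.

## Survival

Kaplan–Meier product-limit curves per group and the log-rank test
(standard O−E chi-square, 1 df for two groups) compare DRFS between
score-high and score-low patients; membership is `probability ≥ cutoff`
(inclusive). Events precede censoring at tied times. Time units are
treated as opaque and consistent; hazard-ratio estimation and Cox
regression are out of scope.

## Correlation bridge

Peripheral score rows against external per-patient numeric annotations:
two-sided Pearson r and p per pair (patients matched by id, ≥ 3
required), flagged at numerical p < 0.05 with a BH-adjusted column
emitted additionally for rigor; zero-variance vectors give missing
(not 0) correlations.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with a known
truth record for every stage:

- **Counts**: gene × sample negative-binomial draws with mean
  `library × Σ_c fraction_{s,c} × profile_{g,c}` and shared dispersion
  0.1 (a typical gene-wise biological dispersion for human cohort bulk
  RNA-seq). Each of 11 cell types has a disjoint marker block
  (20 genes; 19 for the designated cytotoxic-effector block) elevated
  12-fold over a shared lognormal gene baseline — the order of
  specificity of canonical PBMC markers. Library sizes are Poisson
  around 1e5 (400 genes total, so per-gene depth matches a
  genome-wide library scaled down).
- **Composition**: latent fractions are Dirichlet (concentration 6 per
  type), with the subtype contrast multiplying B-cell concentration in
  HR+ and monocyte concentrations in TNBC by e^0.6.
- **Response effects** apply only in checkpoint-inhibitor arms, so the
  simulated chemotherapy-only arm is a built-in negative control: TNBC
  responders gain +0.10 effector fraction at early treatment; HR+
  responders lose 0.08 monocyte fraction (the chemotaxis program) and
  start with +0.06 effector fraction at baseline. Shifts are additive
  on the fraction scale with the remaining components rescaled to keep
  the simplex; infeasible extreme draws are clamped to 90% of the
  available room (a rare tail event at these defaults, so the mean
  shift equals the configured value).
- **Clonotypes**: 150 clones per sample, 3000 reads, proportions from a
  symmetric Dirichlet; responders' baseline log-concentration is
  shifted +1.0 (higher diversity) and TNBC responders' early-treatment
  concentration drops by e^1.5 (clonal expansion).
- **Survival**: exponential DRFS with log-hazard −0.8 per standard
  deviation of the true baseline T-cell fraction, administratively
  censored at 1825 days.
- **Gene sets** handed downstream are exactly the marker blocks (plus
  the monocyte-union chemotaxis program), so enrichment, deconvolution,
  clustering and the model are all verifiable by parameter recovery.

Effect-size magnitudes are not empirical estimates; they were fixed
once so that each downstream stage recovers its effect with high power
at the default cohort size (8 patients per subtype × arm × response
cell), and the deconvolution defaults sit at an operating point where
the 11-type NNLS recovery is well identified (per-type RMSE ≈ 0.03,
r ≈ 0.93 on designed mixtures). What the generator does **not**
emulate: batch/lane artifacts, gene–gene correlation beyond the
cell-type mixture, isoform structure, covariate-linked censoring,
dropout in clonotype capture, and any real marker-gene identity —
passing recovery tests demonstrates internal consistency of the
pipeline, not clinical validity of the signatures.

## Calibration and test scales

Null calibrations use: 500 replicates × 400 permutations for the GSEA
p-value uniformity check; 2000 (script) / 1000 (tests) null exponential
cohorts of 40 + 40 for the log-rank type-I error; 100 logistic
parameter-recovery replicates at n = 200. The null cross-validation
calibration uses cohorts of n = 400: 10-fold CV AUC of this
six-parameter model has a standard error of ≈ 0.057 at n = 200 and
≈ 0.043 at n = 400, so n = 400 is the scale at which the ±0.1
tolerance band spans ≈ 2.3 standard errors — at smaller n the band
narrows relative to intrinsic CV noise, a property of cross-validation
itself rather than of the model. Coefficient-recovery checks draw
feature tables from a known logistic truth (the only setting in which
"the CI covers the true coefficient" is well defined); pipeline-level
tests verify sign and AUC recovery from fully simulated cohorts.

## Known limitations

- The enrichment scorer is rank-based (single-sample GSEA family), not
  the kernel-CDF variant; scores from the two families correlate but
  are not interchangeable.
- The differential-expression ranking is t-based, not a count-model
  Wald test; genes with very low counts are less stably ranked than a
  dispersion-moderated statistic would give.
- Deconvolution accuracy degrades with collinear reference profiles;
  the condition number is reported and collinear pairs rejected, but
  closely related cell states (e.g. CD8 activation stages) remain the
  hardest to separate.
- The ridge fallback under separation yields point predictions but no
  valid Wald inference; small cohorts with strong features will often
  trigger it.
- Absolute-mode deconvolution coefficients are on an arbitrary scale
  (no external calibration constant is applied).
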