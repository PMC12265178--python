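# periscope

Peripheral-blood immune-signature analysis of neoadjuvant immunotherapy
response in breast cancer.

`periscope` is a reusable pipeline for longitudinal buffy-coat bulk
RNA-seq cohorts of patients with HER2-negative breast cancer treated
with chemotherapy ± an immune checkpoint inhibitor (anti-PD-1). From a
raw gene-count matrix, per-sample TCR clonotype tables and clinical
metadata it derives:

- **single-sample immune-cell enrichment scores** — a weighted
  running-sum (ssGSEA-style) statistic per gene set and sample;
- **PBMC immune-composition subtypes (PICS)** — hierarchical clustering
  of the immune-cell score vectors, cut to *k* (default 7) clusters,
  annotated by the elevated supertype (T cell / myeloid / B cell / NK),
  with a longitudinal composition-change statistic;
- **TCR repertoire diversity** — Shannon index
  H = −Σᵢ pᵢ ln pᵢ over CDR3 read proportions, with quality filters
  (H = 0 or < 10 clones excluded) and per-patient baseline → early-
  treatment deltas (a drop marks clonal expansion);
- **immune-cell deconvolution** — non-negative least squares against an
  11-type PBMC signature matrix (four CD8 states, CD4 T, B, two
  monocyte compartments, NK, cDC, pDC), absolute or relative mode;
- **composite scores** — a 19-gene cytotoxic/effector T-cell composite
  (mean of per-gene cohort z-scores over a panel such as *GZMB, PRF1,
  NKG7, KLRD1, TBX21*) and a leukocyte-chemotaxis enrichment score;
- **a subtype-conditional logistic response model** predicting
  pathological complete response (pCR):

  ```
  response ~ subtype + Δ T-cell composite |TNBC
           + baseline T-cell composite |HR+
           + baseline TCR Shannon
           + Δ chemotaxis score |HR+
  ```

  evaluated with Mann–Whitney AUC + DeLong 95% CI and test vs 0.5,
  Youden-J optimal cutoff, stratified 10-fold cross-validation with
  Cohen's κ, and cross-cohort train/test validation;
- **survival stratification** — Kaplan–Meier curves and log-rank
  comparison of distant recurrence-free survival (DRFS) between
  model-score-high and -low patients;
- **a synthetic-cohort generator** with known ground truth for every
  stage (negative-binomial counts driven by latent Dirichlet cell
  fractions with marker-block structure, power-law clonotype
  abundances, subtype- and response-linked effects, exponential DRFS).

Preranked GSEA (weighted Kolmogorov running sum, gene-label permutation
null, NES, BH adjustment, leading-edge extraction) and a 50× bootstrap
stability analysis for enrichment calls are included for differential
contrasts.

## Worked example

Simulate a cohort (64 patients × 2 timepoints, both arms), score it and
fit the response model on the checkpoint-inhibitor arm:

```python
from periscope.synthetic import SimulationConfig, simulate_cohort, CHEMOTAXIS_SET
from periscope.preprocess import filter_genes, normalize_transform
from periscope.scores import composite_score, chemotaxis_score
from periscope.tcr import diversity_records
from periscope.model import build_features, fit_model, predict_prob, roc_auc, cross_validate
from periscope.io_formats import SampleTable

counts, samples, clonotypes, sets, truth = simulate_cohort(SimulationConfig(seed=42))
values  = normalize_transform(filter_genes(counts))
tcell   = composite_score(values, truth.effector_panel)
chemo   = chemotaxis_score(values, sets, CHEMOTAXIS_SET)
records = diversity_records(clonotypes.values())

arm      = SampleTable(samples.select(arm="ChemoPembro"))
features = build_features(tcell, chemo, records, arm)
model    = fit_model(features)
probs    = predict_prob(model, features)
roc      = roc_auc(features.frame["response"], probs)
cv       = cross_validate(features, n_folds=10, seed=42)
print(f"n patients: {len(features)}")
print(f"AUC: {roc.auc:.3f}  (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
print(f"Youden cutoff: {roc.optimal_cutoff:.3f}")
print(f"10-fold CV kappa: {cv.kappa:.2f}")
```

prints

```
n patients: 32
AUC: 1.000  (95% CI 1.000-1.000)
Youden cutoff: 0.989
10-fold CV kappa: 0.94
```

The generator's default effect sizes are deliberately strong, so on the
checkpoint-inhibitor arm the pooled train-on-test AUC saturates at 1.0
(the fit is flagged as separable and ridge-stabilized) and the
cross-validated κ is high. The same model fitted on the simulated
chemotherapy-only arm — where the generator encodes no response-linked
signal — gives a CV κ near 0: the κ contrast between arms is the
model's built-in negative control. The Youden cutoff is the probability
threshold that maximizes sensitivity + specificity − 1; patients at or
above it are called immune-high for the DRFS comparison.

The same analysis runs end-to-end from a YAML config:

```bash
periscope run --config pipeline.yaml --out results/
# or, on simulated fixtures written to disk:
periscope simulate --seed 42 --out sim/
periscope validate sim/counts.tsv sim/samples.csv sim/gene_sets.gmt
```

Every run writes a `manifest.json` with config, seed and content hashes
of all inputs and outputs; reruns with the same config and seed are
byte-identical.

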