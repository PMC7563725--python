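# Methods

This note documents the models, numerical choices and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic study generator

The generator emulates a merged multi-batch case/control expression study on
the log2 scale. For gene *i* (module *m(i)*, loading `l_i`), sample *j*
(phenotype `y_j ∈ {0,1}`, batch `g(j)`):

```
x_ij = μ_i + l_i f_{m(i),j} + δ_i y_j + γ_ig + s_ig ε_ij
```

* `μ_i ~ U(5, 9)` — baseline log2 expression, the typical microarray range.
* `f_m` — the module's latent factor, standard normal across samples and
  shifted by `trait_effect` in cancer samples; all co-expression is
  factor-driven, which matches the working assumption of correlation-based
  module detection and gives the closed-form planted correlation
  `l_i l_j / sqrt((l_i²+σ²)(l_j²+σ²))` that the tests verify.
* Loadings `l_i ~ U(0.5, 1.0)`; designated hub genes get `1.0 + 0.3`, so the
  ground-truth hubs are the genes with the largest within-module
  connectivity — a recoverable target for the K.in ranking.
* `δ_i` — background trait effects: 5% of non-module genes receive
  |log2FC| ~ U(1.5, 3) with random sign, emulating DE genes outside the
  disease module.
* Batch effects: per-gene per-batch location `γ ~ N(0, 0.8²)` plus a
  multiplicative noise scale `s ~ U(0.8, 1.25)` — exactly the location/scale
  form the correction targets. At these values >95% of genes show a
  significant batch ANOVA before correction (verified in tests).
* Residual noise `ε ~ N(0, 0.6²)`.

The default desk-scale study is 2,000 genes, four batches of 45 samples
(~180 total, last batch held out), three modules of sizes 150/100/60 with the
first trait-associated (`trait_effect = 3.5`) and carrying 10 hubs. The trait
effect is calibrated so the planted hubs land in the regime reported for
strong cancer-vs-normal signatures — hub gene significance ≈ 0.8–0.85,
disease-module eigengene–trait correlation ≈ 0.93, hub |log2FC| ≈ 4.5 —
comfortably inside the GS > 0.5 / |MM| > 0.8 screening bounds rather than at
their edge.

What the generator does **not** emulate: probe-level intensities and
normalization artifacts, heavy-tailed or count noise, correlated batch-by-
phenotype confounding, overlapping modules, or module factors with
non-Gaussian dynamics. Passing tests therefore demonstrate correctness of the
computations and recoverability under a well-specified factor model, not
performance on any real cohort.

## Batch correction

Parametric empirical-Bayes location/scale adjustment. A per-gene linear
model with batch indicators and the phenotype is fitted by least squares;
data are standardized by the pooled **design-adjusted residual** standard
deviation (not the total per-gene sd — scaling by total sd would let the
per-batch scale step re-inflate residual noise of strong trait genes to the
total variance, which measurably degrades downstream class separation).
Per-batch locations are estimated from phenotype-adjusted residuals — the
biological contrast is protected — and scales from their within-batch
variance; both are shrunk by empirical Bayes (normal prior on locations,
inverse-gamma on scales, method-of-moments hyperparameters, the standard
iterative posterior solution, tolerance 1e-6). `no_eb` disables shrinkage and
`mean_only` disables the scale step; in that configuration a pure
location-shift design is inverted exactly (tested at 1e-10).

The fit/transform split (`BatchCorrector`) corrects a held-out batch with
the *fitted* standardization and phenotype effect; only the batch's own
location/scale come from its samples. Consequently nothing estimated from
training batches depends on held-out data — the property the no-leakage test
asserts. Correction of a new batch removes that batch's mean residual
profile; with very small or heavily imbalanced new batches the location
estimate is noisy, which is the usual limitation of batch correction applied
per batch.

## Differential expression

Hand-implemented moderated t-statistic. Pooled two-group residual variances
`s²_g` (d_g df) are modelled as scaled F draws around a prior `s₀²` with d₀
prior df; `(d₀, s₀²)` come from moment matching on `log s²_g` (digamma/
trigamma identities, Newton inversion of the trigamma function). When the
observed spread of log variances does not exceed chi-square sampling noise,
d₀ = ∞ and the prior scale is the mean variance; total df are capped at the
pooled residual df across genes. These conventions reproduce the reference
Bioconductor implementation to ≤ 5e-13 on the frozen oracle fixtures in
`tests/data/` (both the finite-d₀ and the infinite-d₀ branch). BH adjustment
is the five-line step-up, property-tested against brute-force enumeration
and cross-checked against statsmodels. Screens use strict inequalities
(adj. p < α, |log2FC| > threshold).

## Network construction and module detection

* **Scale-free fit**: connectivity is binned into 10 equal-width bins; the
  log10 frequency of non-empty bins is regressed on the log10 bin-mean
  connectivity; the fit index is R², reported with the slope and a truncated
  model (adds a linear k term). Equal-width binning is the conventional
  discretisation for this diagnostic; an equal-count variant (with density
  normalisation) lets R² cross the 0.85 bound at powers too small for module
  separation, so it is not used.
* **Power selection**: smallest candidate (grid 1–20) with R² > 0.85 and a
  negative slope; argmax fallback with a warning.
* **TOM**: standard unsigned form, vectorised as `A₀A₀` with a zeroed
  diagonal; brute-force oracle equivalence is property-tested.
* **Tree cut**: average-linkage clustering of `1 − TOM`; a module is a
  *maximal* dendrogram subtree with ≥ `min_size` (default 30) genes whose
  absorbing merge lies at least `min_gap` (default 0.002) of the dendrogram
  height range above the subtree's own top merge. Rationale: genuine
  co-expression branches complete well below the height at which they join
  anything else, while sub-branches of an unstructured background are
  absorbed almost immediately — on the default study the two populations of
  relative separation differ by ~2 orders of magnitude (≥ 0.008 vs ≤ 1e-4),
  so 0.002 splits them with wide margin at every network density. This
  replaces a fixed-height or height-quantile cut, both of which fail when
  TOM dissimilarity saturates near 1 (high powers) or when a large
  unstructured background agglomerates below the cut. The rule is fully
  deterministic; no per-dataset tuning is performed.
* **Eigengenes**: leading right-singular vector of the gene-standardized
  module submatrix (unit-norm sample scores), sign-oriented to correlate
  non-negatively with the module's mean standardized profile; explained
  variance is the leading squared singular value over the total.
* **Merging**: repeatedly merge the most-correlated eigengene pair while any
  pairwise correlation exceeds the threshold (default 0.8); the smaller
  module adopts the larger one's label; terminates in at most
  (initial module count − 1) iterations.
* **Module–trait**: Pearson r of each eigengene with the 0/1 phenotype;
  p from `t = r√(n−2)/√(1−r²)` on n−2 df. Key module = largest |r|, ties by
  smaller p then larger size.

On the default study the planted disease module is detected together with
the background DE genes — both are driven by the phenotype, so they genuinely
co-express; module-recovery ARI is therefore evaluated over planted-module
genes.

## Hub screen

GS is the absolute gene–phenotype correlation (downregulated genes score
positively); MM is the *signed* gene–eigengene correlation and the screen
uses its magnitude, since anti-correlated genes are equally central in an
unsigned network. K.in sums adjacencies within the gene's own module.
Candidate counts at each screening stage (GS/MM survivors, DE survivors) are
logged. Ties in the K.in ranking break by GS, then gene id, making the
screen independent of input row order.

## VAE

Pure-numpy MLP with explicit forward/backward passes: encoder
input→h1→h2→(μ, log σ²), mirrored decoder, ReLU hidden units, linear output.
Loss per sample = squared reconstruction error summed over genes +
`kl_weight` × KL(N(μ,σ²)‖N(0,I)) summed over latent dimensions, averaged
over the batch. Summing the reconstruction over genes (the Gaussian
log-likelihood scaling) keeps its balance against the KL term independent of
the input dimension; averaging it instead lets the KL dominate and collapses
the posterior, leaving latents without class signal. Optimiser: Adam
(0.9/0.999, ε 1e-8), learning rate 5e-4, batch size 20, 6 epochs, batches
shuffled per epoch from the run seed; He initialisation for ReLU layers,
zero biases. Reference geometry 584-100-10-100-584 at 1,159 inputs; hidden
widths scale proportionally with other input counts (floored at the latent
dimension). Inference uses latent means only. Analytic gradients are checked
against central finite differences at 1e-4 relative tolerance (the check
fixture nudges parameters off exact ReLU kinks, where the subgradient is
undefined). Training on CPU is single-threaded deterministic:
identical config + data give bit-identical histories.

## Classifier and evaluation

Features = hub-gene expression columns + latent columns, z-scaled with
training-split statistics (zero-sd guard). Linear soft-margin SVM, C = 1
(RBF available via config); AUC is the Mann–Whitney rank statistic on
decision scores with mid-ranked ties, property-tested against all-pairs
counting; confusion matrix rows are true class 0/1. A single-class test
split yields AUC = None rather than a fabricated number.

Estimation policy: the default is strict train-only estimation for every
model-side stage; `paper_mode` estimates DE and the network on all samples,
reflecting the common workflow in which feature discovery precedes the
train/test split. The held-out batch's correction optionally uses its
phenotype labels for location protection (mirroring joint correction
practice); labels enter only through batch-level means and cannot encode
per-sample information, and the trained model remains independent of the
held-out data either way.

## Pipeline, seeds, problem sizes

All thresholds live in `PipelineConfig` (defaults: DE α 0.05, |log2FC| 1,
scale-free R² 0.85, min module size 30, eigengene merge 0.8, GS 0.5, MM 0.8,
top 10 hubs, latent dim 10, lr 5e-4, batch 20, 6 epochs, linear SVM C 1).
One root seed is split per stage via `numpy.random.SeedSequence`. The test
suite and the acceptance script run everything at the default desk scale —
2,000 genes × 180 samples, five seeds where variability matters — which a
single CPU core completes in a few seconds per study; the statistics of
interest (module recovery, hub recovery, held-out accuracy) are stable
across seeds at this size.

## Known limitations

* The dynamic tree cut is the branch-separation simplification described
  above, not the full dynamic hybrid algorithm; very nested or overlapping
  module structures that the hybrid method resolves may be merged or dropped.
* Unsigned network only in the default path (signed adjacency behind a
  flag); signed TOM variants are not implemented.
* The moderated t supports a single two-group contrast — no multi-factor
  designs, paired samples or count-model weighting.
* Nonparametric batch-effect priors and surrogate-variable estimation are
  out of scope.
* The VAE has no annealing schedule, early stopping or hyperparameter
  search; with six epochs the latents are a coarse compression by design.
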