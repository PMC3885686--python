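# Methods

## Scope

The package compares covariate transformations for penalized-regression
gene-signature building on RNA-Seq data along two axes: identification
(does the model select the truly informative genes?) and prediction
(does the gene signature reduce the prediction error of a clinical-only
survival model?). All data are synthetic; the generator is a first-class
module whose job is to reproduce the statistical structure of bulk tumor
RNA-Seq cohorts, so that every downstream claim is testable end to end.

## Synthetic cohort generator

Counts for gene g in sample s are negative binomial with mean
μ_g · f_s and variance μ + α_g μ² (α_g = 0 degenerates to Poisson).

* Base means μ_g ~ LogNormal(2.5, 1.8): median normalized count ≈ 12
  with roughly four decades of dynamic range, as in gene-level counts
  from patient cohorts that include many lowly expressed genes.
* Dispersions α_g ~ LogNormal(log 0.4, 1.0): median 0.4 with a long
  right tail to α ≈ 3. Cross-patient tumor cohorts are far more
  dispersed than technical replicates; the long tail matters because the
  handful of very dispersed genes are exactly the ones whose raw and
  log scales behave differently, which is what separates the
  transformations.
* Library-size factors f_s ~ LogNormal(0, 0.25), so median-of-ratios
  normalization is a non-trivial step.
* Gene-gene correlation via a Gaussian copula: consecutive blocks of 50
  genes share a latent factor with within-block latent correlation 0.5.
* Extreme values: a fraction 0.001 of entries is multiplied by a factor
  uniform on [10, 50] — enough to reproduce the correlation-inflation
  phenomenon (pairs whose pre-truncation correlation exceeds the
  post-truncation one by more than 0.5).
* Gene lengths ~ LogNormal(log 2500, 0.8), used only for binning when
  informative genes are drawn.

What the generator does **not** emulate: read-level structure (no
FASTQ), isoform/splicing variation, GC or length bias in expression
levels, batch effects, and any dependence of dispersion on expression.
Passing tests therefore demonstrate the behavior of the methods under
NB-with-outliers structure, not under every pathology of real cohorts.

Binary outcomes: one informative gene is drawn uniformly from each of
n_informative gene-length bins (lengths sorted, near-equal contiguous
bins, remainder on the first bins). All informative genes share one
effect size b, calibrated by bisection so that the signal-to-noise ratio
SNR = Var(η) / mean(π(1−π)) hits its target (2.5 by default), where
η is the centered linear predictor and π = expit(η). The centering fixes
the population prevalence at one half; with all-positive covariates and
positive effects an uncentered η would place almost every subject in one
group (or separate the groups completely on the log scale). The SNR
definition — signal variance over mean Bernoulli conditional variance —
is recorded in every run manifest so it can be swapped. Effects enter
either linearly in the normalized counts or in log(x+1) ("logarithmic"
scenario); the two scenarios deliberately match and mismatch the scales
the transformations model.

Survival outcomes are proportional-hazards with an exponential baseline
(scale 0.1 by default); the fitters never see the baseline. Censoring is
uniform on [0, c] with c calibrated by bisection so the expected
censoring fraction matches the target (default 0.3), then verified
within ±0.05 empirically.

## Preprocessing

1. Genes whose maximum count over samples is ≤ 10 are removed (strict:
   a count of 11 anywhere retains the gene).
2. Median-of-ratios size factors: per-gene geometric means over samples
   (genes with any zero count excluded), per-sample median of
   count/reference.
3. Per-gene truncation at median + 3·IQR, with quartiles by linear
   interpolation between order statistics (the numpy default; the
   convention is recorded in the manifest since the bound depends on
   it).

Genes that end up constant after truncation (a gene with ≥ 75% zeros has
zero IQR and collapses onto its median) are dropped during cohort
preparation: they carry no covariate information and cannot be
standardized. In the resampling study the same rule is applied per
split to genes constant on the training part.

## Transformations

All parameters are estimated on training samples only and reused on
held-out samples — the discipline honest prediction-error estimation
requires, even though single-cohort analyses often ignore it.

* `log`: log(x+1).
* `vst`: the common dispersion α̂ is the least-squares slope (through
  the origin, clamped at 0) of s²_g − m_g on m²_g across genes; the
  transform w(x) = (2/√α̂)·asinh(√(α̂x)) is the closed-form integral of
  v(μ)^{−1/2} for v(μ) = μ + αμ², falling back to 2√x at α̂ = 0. This
  closed-form NB variance-stabilizer replaces dispersion-GLM machinery
  deliberately: it has one interpretable parameter and an exact inverse
  relationship to the generator's variance model.
* `boxcox`: per-gene λ from the grid −2 … 2 in steps of 0.25, applied
  to x+1 (consistent with the log's shift), maximizing the Pearson
  correlation of the sorted transformed values with standard-normal
  quantiles at Blom plotting positions. Correlations within 2·10⁻³ of
  the per-gene maximum are treated as tied and resolve toward λ = 1,
  then toward 0. The tolerance makes the tie rule operative: near the
  optimum the QQ-correlation criterion is flat to ~10⁻⁷, so under exact
  comparison sampling noise — not the data — would pick among
  equivalent candidates, and exactly normal genes would be assigned
  λ = 0.75 in a non-negligible fraction of draws.
* `standardize*`: per-gene mean 0, variance 1, SD with denominator
  n − 1 (recorded in the manifest).
* `ranks`: within-gene ranks 1..n. Ties are broken by seeded
  N(0, (10⁻⁴·(IQR+1))²) jitter, added only to genes that contain ties,
  before ranking; every gene then carries exactly the multiset
  {1, …, n}. Held-out values are scored by their midrank against the
  (jittered) training sample, so train and test live on one scale.
* `blom`: normal scores Φ⁻¹((r − c)/(n − 2c + 1)) with c = 3/8.

## Model fitting

Componentwise likelihood-based boosting starts at β = 0; each step
scores every penalized covariate by U_j²/(I_j + λ) at the current fit,
updates the winner by U_j/(I_j + λ), and refreshes the intercept and the
mandatory (clinical) block by one unpenalized Newton step. Ties break
toward the lowest index; paths are deterministic. The logistic
information is the raw weighted second moment x_jᵀWx_j of the candidate
one-parameter update (not the centered variance): candidates are pure
offsets on the current fit, which is also what makes the selection
scale-sensitive on uncentered covariates. The Cox version uses the
Breslow partial likelihood, whose score and information are
shift-invariant. The penalty comes from a shrinkage factor ν ∈ (0,1]:
λ = (1/ν − 1) × total null-model weight (n·p̄(1−p̄) logistic, number of
events Cox, n gaussian), so a standardized covariate's first update is
shrunk by ≈ ν; the default ν = 0.1 mirrors the usual gradient-boosting
step factor. A continuous-response (gaussian) family exists mainly as an
analytic bridge: on an orthonormal design with small ν the boosting path
coincides with the lasso's soft-thresholding path, which the tests
verify at matched L1 norms.

The lasso-Cox path is solved by the coordinate-descent solver in
scikit-survival (penalty factors 0 on the mandatory block); every
returned solution is verified against the KKT conditions of the
L1-penalized partial likelihood, with the stationarity tolerance scaled
by the penalty. Cross-validation folds are stratified (by y or the event
indicator) and seeded; the Cox out-of-fold criterion is the
full-minus-reduced partial log-likelihood; ties resolve toward the
smaller model. Fold fits for penalty ranking use a looser solver
tolerance than the final KKT-verified fit.

## Evaluation

* Selection curves walk the boosting path; at each step the non-zero
  penalized support gives an (FP, TP) pair, TP*(f) is the best TP with
  at most f false positives, and pAUC10 = mean of TP*(f) over
  f = 0..10. Tracing along the path is the only ordering the fit
  provides. Because the support never shrinks, paths may be truncated
  once the support exceeds n_informative + 11 without changing pAUC10.
* Brier curves are IPCW-weighted with a Kaplan–Meier censoring model
  fitted on training data (weights floored at 10⁻³); survival
  predictions use the Breslow baseline from the training fit. The
  no-information curve pairs every training prediction with every
  training outcome (computed in linear time via its moment expansion).
* 0.632+: R = (oob − apparent)/(noinf − apparent) clipped to [0,1]
  (R = 0 when noinf ≤ apparent), w = 0.632/(1 − 0.368R), estimate
  = (1−w)·apparent + w·min(oob, noinf).
* IPEC integrates the 0.632+ curve by the trapezoid rule on a grid up to
  the 95th percentile of observed times (the integration limit is a
  convention and is recorded in the manifest).
* Added value per split: Δ = 1 − IPEC_combined/IPEC_clinical — zero when
  the genes add nothing, negative when they hurt, and the fraction of
  clinical prediction error eliminated when positive. This is the
  unique form consistent with all three of those requirements.

## Study designs and problem sizes

The identification study holds one cohort fixed (2,000 genes × 200
samples by default) and redraws the informative set, effect calibration
and outcome per replicate (10 by default, 50 supported), fitting fixed
500-step boosting paths per transformation. The prediction study
resamples train/test splits without replacement (training fraction
0.632, matching the subsampling rationale of the 0.632+ estimator;
20–50 splits), fits CV-tuned boosting and lasso per transformation plus
a clinical-only Cox model per split, and an optional fixed-step
(default 200) boosting run collects selected-gene sets for the overlap
table. These sizes keep a full run in minutes on one CPU while
preserving every qualitative contrast; at several-fold larger cohorts
the same contrasts strengthen, since with 200 samples and SNR 2.5 only
one or two informative genes sit above the detection threshold in any
single replicate.

## Numerical choices and degenerate inputs

* Boosting refreshes of the unpenalized block carry a 10⁻¹⁰ ridge so
  near-separation does not make the Newton step singular.
* Cox machinery handles tied times by Breslow risk sets; the partial
  likelihood is computed with a max-shift for overflow safety.
* calibrate_effects brackets by doubling, checks monotonicity of SNR(b)
  on the bracket, then bisects to relative tolerance 10⁻⁶.
* Constant genes: Box-Cox flags them and returns λ = 1; standardization
  raises an error naming the gene; the rank transforms jitter them into
  a valid permutation.
* Zero-event folds in Cox CV trigger a reshuffle (up to 10 attempts)
  with a warning.

## Known limitations

* The VST uses a single common dispersion; per-gene or trended
  dispersions are not modeled (the standardized VST largely absorbs the
  difference).
* The no-information error and 0.632+ weighting follow the standard
  censored-data adaptation; alternative overfitting corrections are not
  implemented.
* Added value compares IPECs per split; no significance machinery
  beyond split-level summaries is provided.
* The generator's independence of dispersion and mean is a
  simplification; real cohorts show a decreasing dispersion trend.
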