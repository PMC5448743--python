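# Methods

This note documents the statistical procedures implemented in `mirisk`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Data model

Ct (cycle threshold) behaves as a negative log2 abundance: one cycle less ≈
twice the template. All log-scale computation therefore happens directly on
Ct (or −Ct where a "higher = more" orientation is needed); no further log
transformation is applied. The binary outcome codes the atherosclerotic
group as 1 (events) and the non-atherosclerotic group as 0 (nonevents)
throughout; fold changes are event-group mean over nonevent-group mean.

## QC and quantification

- **Hemolysis**: a serum is retained only if its 415-nm free-oxyhemoglobin
  absorbance is strictly below 0.2 (hemolysed red cells release abundant
  cellular miRNAs that contaminate the circulating signal). Samples with a
  missing absorbance cannot be certified and are excluded with a logged
  reason.
- **Undetermined wells**: replaced by the maximal cycle number (default 40).
  Detection flags survive imputation, so "detected in all samples" criteria
  see the original status.
- **ΔCt**: per sample, the reference Ct of a multi-member set is the
  unweighted arithmetic mean of the members' Ct — averaging on the log
  scale, i.e. geometric-mean normalization on the linear scale. The
  alternative (summing the members) changes the scale of ΔCt and is not
  scale-consistent between 1- and 2-member references, so the mean is used.
  Q_rel = 2^−ΔCt. Reference subtraction makes ΔCt invariant to any additive
  per-sample Ct offset, which is the property that justifies the whole
  construction.

## Reference selection

Candidates must (1) be detected in every serum, (2) show a mean fold change
within 0.9–1.1 and (3) no significant group difference (two-sided
equal-variance t-test, p > 0.05). Both the fold change and the test are
computed on **sample-centered Ct** (each sample's mean Ct over fully
detected miRNAs subtracted). Per-sample extraction offsets are common-mode:
on raw Ct, a chance imbalance of offsets between groups shifts *every*
miRNA's apparent fold change at once and can reject all genuinely stable
miRNAs together. Centering — standard global-mean normalization for array
cards — removes exactly that component. Zero-variance centered genes with
equal group means are treated as trivially non-different (p := 1).

Stability of the k candidates follows the two-group model-based (NormFinder
-type) estimator on log-scale expression (−Ct):

1. center each sample across the k candidates;
2. per gene × group, compute the raw interaction d̂_ig (group mean of the
   centered values minus the gene's unweighted two-group average; sums to
   zero over genes and over groups) and the within-group sample variance
   s²_ig;
3. bias-correct the variances for the centering step by solving
   E[s²_ig] = σ²_ig(1 − 2/k) + (1/k²)Σ_i′ σ²_i′g, which gives
   Σσ² = Σs²·k/(k−1) and σ̂²_ig = (s²_ig − Σσ²/k²)/(1 − 2/k); negative
   solutions are clamped to 0 (requires k ≥ 3);
4. shrink the interactions empirically: d̃ = d̂·γ²/(γ² + σ̂²/n_g) with
   γ² = max(0, Var_i(d̂_ig) − mean_i(σ̂²_ig/n_g)). The gene-wise mean of d̂
   is exactly 0 by construction, so Var_i is computed as the mean square;
5. stability ρ_i = mean over groups of |d̃_ig| + √(σ̂²_ig/n_g).

Pairs are scored as the pseudo-gene formed by averaging the two members'
centered values: its d̂ follows by linearity, its within-group variance is
measured empirically from the averaged values (so correlation between the
members is captured), and the singles' γ² is reused for shrinkage. No
k-dependent bias correction applies to the pseudo-gene because it does not
participate in the sample centering. The lowest-stability set (ties broken
lexicographically) is the reference. In the pipeline the pair search is
restricted to the 25 most stable singles, which bounds the O(k²) pair scan
while mirroring the shortlist size a practitioner would carry forward.

This estimator is this package's own implementation of the published
two-group model; exact numerical agreement with the original closed-source
add-in is not claimed (its internal constants are not public), but on
synthetic panels with known per-gene bias and variance the estimator ranks
the truly most stable gene first (see the reproducibility studies below).

## Marker discovery

The differential filter selects miRNAs with Q_rel fold change < 0.5 or
> 2.0 **and** two-sided equal-variance Student-t p < 0.05 (no
multiple-testing correction, matching common single-cohort screening
practice; the validation cohort provides the error control). miRNAs whose
nonevent mean Q_rel is zero have an undefined fold and are excluded with a
warning. The filter is label-symmetric: swapping the groups maps fold f to
1/f and preserves the outcome.

Stepwise discriminant analysis runs forward on the Q_rel candidate matrix:
with p variables entered and Wilks' Λ_p = det(W)/det(T), a candidate's
F-to-enter is F = (n − g − p)(Λ_p/Λ_{p+1} − 1)/(g − 1) on
(g − 1, n − g − p) degrees of freedom (g = 2 groups). The largest-F
candidate enters while its p-value is below α = 0.05. These df make the
single-candidate F equal exactly the squared two-sample t statistic, and
Wilks' Λ is invariant to per-variable affine rescaling, so standardized and
raw Q_rel select the same set. Variables producing a singular scatter
matrix (e.g. duplicates of an entered variable) are skipped with a warning.
Whether to run the discriminant step on Q_rel or ΔCt was genuinely open;
Q_rel was chosen because the filter thresholds are defined on that scale.

Validation re-tests the chosen markers in an independent cohort with the
same t-test; subgroup comparisons use a t-test for two categories and
one-way ANOVA for three or more (for two categories F = t² exactly).

## Risk modeling

Univariate comparisons: chi-squared without continuity correction on r × 2
contingency tables for categorical covariates (tables with a degenerate
margin or expected counts < 1 are flagged unreliable), two-sided
equal-variance t for continuous ones.

Forward logistic regression uses a likelihood-ratio entry test: each
excluded covariate is added in turn, 2·Δℓ is referred to χ²(1), and the
most significant enters while p < α = 0.05. The final model is refit by
maximum likelihood; Wald 95% CIs are exp(B ± 1.96·SE). A score-test entry
rule would behave nearly identically; LR was chosen as the conventional
forward-LR default. Complete separation is detected from the fitted
probabilities (all events above 1 − 10⁻⁴ and all nonevents below 10⁻⁴) or
optimizer non-convergence — not from coefficient magnitude, because a
covariate on a tiny scale (Q_rel values of order 10⁻²) carries a
legitimately enormous odds ratio. Newton fits fall back to BFGS/L-BFGS on
numerical failure.

LOOCV re-estimates coefficients for a *fixed* covariate list in each fold
and classifies the held-out patient at threshold 0.5; selection is not
re-run per fold (re-running selection inside folds estimates a different
quantity — the performance of the selection procedure — and is available by
simply calling the selector inside a user-written loop). Non-convergent
folds keep the last-iterate prediction and warn.

## Incremental value

AUC is computed from midranks (Mann–Whitney), identical to the trapezoidal
area under the empirical ROC; paired AUC differences use the DeLong
structural-component variance and a two-sided normal test. NRI is the
category-free version forced by the movement-indicator definition (+1 for
any probability increase among events, −1 for any decrease, 0 for ties);
threshold-based misclassification counts are reported separately and never
fed into NRI. IDI equals the change in discrimination slope. Both use
asymptotic z-tests; `bootstrap_reclassification` provides a seeded
percentile-bootstrap cross-check (2000 resamples). Percentages are reported
to 1 decimal and AUC/NRI/IDI to 4 decimals in the pipeline report.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: a 754 ×
2·n_per_group Ct matrix with 5 planted reference miRNAs (no group effect,
SD 0.15 cycles), 14 planted differential miRNAs (additive Ct shift of
−log2FC in the event group; default |log2FC| = 2 with alternating sign,
matching the 4-fold-and-beyond changes typical of discovery-stage screens),
noise miRNAs with per-miRNA baselines spread over the detectable range
(mean 30, SD 3.5 cycles; values beyond 40 cycles are emitted as
undetermined), per-sample additive offsets (SD 0.5 cycles) and per-well
noise (SD 1 cycle). Clinical covariates are drawn per group from the
configured means/SDs and prevalences — defaults reproduce the group
contrasts of an elderly ischemic-stroke cohort (e.g. HbA1c 5.7 ± 0.7 vs
6.4 ± 1.1%, HDL-C 45.1 ± 9.0 vs 40.3 ± 12.3 mg/dl, lipoprotein(a)
14.5 ± 10.4 vs 21.9 ± 15.7 mg/dl; diabetes prevalence 15% vs 56%) — with
physiological floors applied to non-negative quantities. A configurable
fraction of sera (default 5%) receives a hemolysis absorbance above the 0.2
cutoff. All draws come from a single seeded generator; identical parameters
and seed give bit-identical outputs.

Deliberately **not** modeled: correlation between clinical covariates
(draws are independent per covariate, so the joint multivariate group
separation is stronger than in real, collinear laboratory data — synthetic
in-sample accuracies and AUCs run high for that reason), panel-specific
chemistry, preamplification bias, batch effects beyond the per-sample
offset, and heavy-tailed Q_rel distributions. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure, not field performance on real sera.

## Reproducibility studies and problem sizes

`mirisk.studies` packages six seeded end-to-end checks (run by
`scripts/acceptance.py` and the test suite):

- **AUC oracle**: 2000 random score/label vectors, n ≤ 12, scores on a tied
  grid, compared to exhaustive pair enumeration (exact agreement expected).
- **NRI/IDI closed forms**: hand-enumerable movement patterns (NRI 2/3,
  maximal NRI 2.0, forced IDI 0.2).
- **Stability truth recovery**: 200 panels, k = 20 genes, 50 samples per
  group; one gene planted with zero bias and SD 0.3 among genes with
  |bias| ≥ 0.4 and SD 0.4–1.0. The planted biases are mean-centered
  because the stability model scores bias *relative to the panel average*;
  without that, fully random biases create frequent genuine near-ties in
  the truth ranking and top-1 agreement is not a meaningful check.
- **Forward-selection recovery**: 100 cohorts, n = 200, 15 standard-normal
  covariates, true log-OR 1.0 on two of them; measures the rate at which
  both planted covariates are selected and the Wald-CI coverage of the true
  odds ratio. Note that with α = 0.05 per entry step, a noise covariate is
  *expected* to slip in after the planted ones in ≈ 1 − 0.95¹³ ≈ 49% of
  runs — that is a property of forward selection at this α, not an error.
- **Null calibration**: 1000 null miRNAs (t-filter rejection ≈ 5%) and 1000
  null cohorts (forward selection picks ≥ 1 of 15 covariates in
  ≈ 1 − 0.95¹⁵ ≈ 54% of runs).
- **End-to-end**: the default 32-per-group synthetic cohort run twice;
  planted-marker recovery through the filter and discriminant stages and
  byte-identical reports.

These sizes keep the full suite and the acceptance script at roughly one to
two minutes each on a single CPU while holding Monte-Carlo standard errors
near one percentage point.

## Known limitations

- The stability estimator is validated against simulated truth, not against
  the original add-in's numeric output.
- Forward selection p-values are nominal per step; the package deliberately
  applies no multiple-testing correction anywhere, mirroring the screening
  style it implements, so selected-model inference is optimistic.
- The asymptotic NRI/IDI tests are anti-conservative in small cohorts; use
  the bootstrap cross-check below n ≈ 50.
- `CohortTable` expects complete data for modeled covariates; patients with
  missing values must be excluded (`dropna_covariates`) — no imputation.
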