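# Methods

This note documents the statistical procedures implemented in `pkdprog`,
the default parameters and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.

## Outcome: the annual eGFR slope

Serum creatinine (mg/dL) is converted to eGFR (mL/min/1.73 m²) with the
2009 CKD-EPI creatinine equation,

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female]

with κ = 0.7/0.9 and α = −0.329/−0.411 for women/men.  The race
coefficient is omitted by default (`CKDEPIParams.race_factor`, settable),
reflecting practice in European cohorts.  The closed-form inverse (used by
the generator) picks the branch from whether the requested eGFR lies above
or below the value at the knot Scr = κ; the map is strictly decreasing, so
the inverse is exact.

Measurements on or after a patient's earliest intervention (tolvaptan
start, dialysis, nephrectomy, transplant) are removed before fitting: an
intervention-day value is already treated as affected.  The per-patient
model `eGFR = α + β·day` is fitted by Huber M-estimation (tuning constant
1.345, ≤50 IRLS iterations, tolerance 1e-8; OLS fallback flagged
`converged=False`), and β is annualized by ×365.25.  Inclusion requires
≥3 measurements and −10 ≤ β ≤ +5 mL/min/1.73 m²/yr; the boundary values
are retained (removal applies strictly outside the band).  CKD stages use
the standard eGFR cut-points 90/60/30/15.

## Proteome preprocessing

Input is a long-format DIA protein-group report (Run, Protein.Group,
Genes, Q.Value, Intensity).  Steps, in order:

1. **q-value filter** — entries with identification q > 0.01 are set
   missing (not dropped as rows), so they enter the missing-value
   accounting exactly like undetected entries.
2. **Missingness filter** — proteins with strictly more than 80% missing
   entries are removed (exactly 80% is kept).
3. **Variance-stabilizing normalization** — the per-sample affine arsinh
   transform h(x) = arsinh(a_s + b_s·x), b_s > 0, is calibrated by
   maximizing the profile likelihood of the model h(x) = μ_protein + ε
   with the transform's log-Jacobian included (the Jacobian term is what
   prevents the degenerate b→0 collapse).  Calibration uses the 90%
   least-variable proteins; the fitted transform is then applied to all
   entries.  For large b_s·x, arsinh behaves as log, so a multiplicative
   sample shift becomes an additive offset on the transformed scale; the
   offset a_s absorbs additive background so low-intensity variance is
   stabilized rather than exploded (the property a plain log transform
   lacks).  Optimization is L-BFGS with analytic gradients; the
   residual-sum-of-squares is floored at 1e-12·N to keep the profile
   likelihood finite on degenerate (perfect-fit) inputs.
4. **Imputation** — missing entries are replaced by draws (with
   replacement, seeded) from the pool of observed transformed values at or
   below the dataset-wide 5th percentile.  The pool is dataset-wide, not
   per-protein: missingness in DIA serum data is dominated by left
   censoring at the detection limit, which is an intensity-level
   phenomenon.  An error is raised if the pool holds fewer than 10 values.
   The observation mask is preserved, so detection-indicator analyses can
   recover the original pattern.
5. **Outlier flagging** — samples are projected on the first two principal
   components of the centered/scaled matrix; each component is robustly
   standardized (median/MAD·1.4826) and samples with Euclidean robust
   distance > k_mad (default 5) are flagged.  The threshold is explicit
   because visual PCA inspection is not reproducible; flagged samples are
   reported and removal is a caller decision (the bundled pipeline removes
   them by default).
6. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment: per-protein standardization against the batch-size-weighted
   grand mean and pooled variance; per-batch per-protein additive (γ) and
   multiplicative (δ²) effects shrunk toward method-of-moments priors
   (normal for γ, inverse-gamma for δ²) by the standard iterative
   conditional solution; adjusted and back-transformed.  A single batch is
   a no-op; singleton batches are rejected.  Note that shrinkage
   deliberately leaves each protein's sampling deviation of batch means
   partially unadjusted — post-correction per-protein batch-mean
   differences scale as √(2/n_batch), not zero.

Every step appends a record to the matrix's provenance list; re-running
the pipeline on the same inputs with the same seeds reproduces the matrix
bit for bit.

## Univariate association

For each protein, abundance is regressed on the annual slope (single
covariate; the design is extensible).  Residual variances s²_g with d
degrees of freedom are shrunk toward a prior:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)

The prior (d₀, s₀²) is estimated by moment-matching the log residual
variances to a scaled F distribution (digamma/trigamma system; trigamma
inverse by Newton iteration).  When the observed spread of log-variances
is no larger than chi-square sampling noise the system has no finite
solution and d₀ = ∞ (full shrinkage, normal reference distribution).  The
moderated t = β/(s̃·SE-unit) is referred to t with d₀+d df, and p-values
are Benjamini–Hochberg adjusted.  A dedicated test verifies the
implementation against the Bioconductor limma implementation on a fixture
with heterogeneous variances (agreement to 1e-8).

eGFR-dependency of selected proteins is assessed by pairwise-complete
Pearson correlation with the t-distributed p-value, and concordance of
correlation signs across two cohorts is summarized over proteins
significant in both.  For heavily censored proteins, the binary detection
indicator is correlated with the slope (point-biserial).  Heatmap-style
structure uses average-linkage agglomerative clustering on 1−Pearson
distances; cluster characteristics are compared by pairwise Welch t-tests
with Bonferroni adjustment (continuous) and one-sample chi-square
proportion tests against the whole-cohort proportion, without continuity
correction (categorical).

## Multivariate selection

The weighted LASSO minimizes Σ w_i (y_i − b₀ − xᵀβ)²/Σw + λ‖β‖₁.  Weights
down-weight extreme outcome values: u_i = (y_i − median)/MAD_σ (MAD scaled
by 1.4826), w_i = 1 for |u| ≤ k, k/|u| beyond (k = 1.345); uniform and
user-supplied schemes are available.  The weighting scheme is the largest
interpretive choice in the package — the procedure it reimplements is
described only as mitigating the influence of extreme slope values — and
is therefore configurable.

λ runs over 100 log-spaced values from λ_max (smallest all-zero penalty)
down to 10⁻³·λ_max.  Stability selection draws 100 seeded 2:1 train/test
splits; within each training part predictors are z-scored and λ is chosen
to minimize the weighted 10-fold CV error (ties toward the larger,
sparser λ).  A protein's selection frequency is the fraction of replicates
with a nonzero coefficient; the selected set is frequency ≥ 0.75 (the
boundary is inclusive: 0.74 is out).  Test halves are not used for
selection.  No random-effect term for repeated patients is included; the
package takes one sample per patient by default.

## Progression models

Design matrices code proteins as z-scores (scaling stored for later
evaluation on the training scale), sex as male=1, Mayo imaging class as
dummies for 1C and pooled 1D–1E against the pooled 1A–1B reference, and
genotype as PKD1-truncating / PKD1-non-truncating against PKD2.  Fits are
OLS with Wald t confidence intervals and two-sided p-values; rank-deficient
designs are rejected with the collinear terms named (serum CST3 is the
canonical offender, being collinear with SERPINF1/CFHR1/GPX3).  Adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1).

The published screening-cohort coefficient sets (Proteome, Clinical,
Combined; n=212) ship as packaged data (`data/published_models.json`).
Their protein coefficients are assumed to apply to standardized abundances
— the coefficient magnitudes (0.3–0.7 on a slope scale, against age/eGFR
in natural units) are only consistent with z-scored protein inputs, and
`evaluate_published` rejects protein inputs with |z| > 10 as presumably
unscaled.  CIs are treated as Wald t-intervals.

The MIC comparator classifies patients by the theoretical yearly kidney
growth rate r = ln(htTKV/150 mL/m)/age with half-open class boundaries at
1.5/3/4.5/6 %/yr, and predicts the slope as the class mean in the fitting
cohort (OLS on class indicators).  A refit class-mean model was chosen
over transcribed external class equations so the comparator is trained on
the same cohort as the competing models; the choice is switchable by
supplying any other `FittedModel`.

Cross-validation draws seeded 2:1 train/test splits (default 100) and
reports the median test R² and mean test RMSE.

## Evaluation

RMSE is reported overall and within CKD-stage groups (default stage 1
versus stages 2–4).  Endpoint prediction projects baseline + slope·years
and reports ΔeGFR = observed − predicted (positive = overestimated loss).
Agreement between observed and predicted slopes is a Huber robust
regression line with case-resampling percentile bootstrap 95% CIs (1000
replicates, seeded).  Repeatability over sampling time points counts all
unordered within-patient prediction pairs within ±1 eGFR unit/yr.  The
rapid-progressor ROC labels patients with observed slope strictly below
−3 mL/min/1.73 m²/yr as rapid, scores by the negated predicted slope, and
reports the trapezoidal AUC (equal to the Mann–Whitney ranking
probability; ties are handled by counting all tied scores at one operating
point).  Cross-cohort marker comparisons (e.g. hemoglobin beta as a
hemolysis check) use Welch's t-test.

## Synthetic cohort generator

The generator emulates the statistical structure of a registry-based
ADPKD screening cohort; the defaults are the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| n_patients | 214 | screening-cohort scale |
| female fraction | 0.565 | cohort demographics |
| age | N(46, 12²) yr, clipped 18–80 | median ≈ 46 |
| baseline eGFR | U(30, 110) | median ≈ 66–70, CKD 1–4 |
| true slope | N(−2.7, 2.5²) mL/min/1.73m²/yr | typical ADPKD decline |
| creatinine noise | 5% log-normal CV | assay + biological variation |
| visits | 4/yr, jitter ±30 d | routine-care creatinine draws |
| follow-up | median 6.8 yr (log-normal, σ=0.25) | registry follow-up |
| tolvaptan/dialysis/nephrectomy/transplant | 15/1/2/1 % | intervention mix |
| proteins | 200; noise SD 0.5 (log) | desk-scale DIA panel |
| marker effects | ±1.0 noise-SD per slope-SD, signs of the published panel | see below |
| batch structure | 2 batches; shift SD 0.3, scale SD 0.2 (log) | lab batch effects |
| censoring | global detection-limit quantile 2%; RARRES2-like protein at its own 22.2% | left-censored MNAR |

Trajectories are linear with a physiologic floor at 5 mL/min/1.73 m²;
creatinine is the exact CKD-EPI inverse of the true eGFR at the exact age
(so the zero-noise pipeline round trip is exact for unfloored
trajectories).  Interventions are placed in the middle 30–90% of
follow-up and act only through censoring — no pharmacodynamics.

Protein log-intensities follow
`b_g + β_g·slope + γ_g·eGFR + batch shift + batch scale·ε`.  The marker
effect default of one residual-SD per slope-SD keeps the *realized*
standardized effect in the fully processed matrix at or above the
half-SD design point of a clearly detectable marker, after the ~30–40%
attenuation from batch scale jitter, arsinh compression and low-tail
imputation.  The visit rate matters for the same reason: per-patient
slope estimates are the regression outcome, and their reliability
(~0.98 at quarterly visits) bounds how much marker signal survives;
sparser sampling makes the six markers mutually redundant given the noisy
outcome and selection frequencies degrade.  Marker baselines (except the
designated high-missingness protein) are kept at or above the cohort mean
abundance — the panel proteins are abundant serum proteins — while the
RARRES2-like protein sits one baseline-SD low, near the detection limit,
and is censored at its own 22.2% quantile.  Left-censoring is applied
against a single global detection-limit threshold by default
(`censor_mode="per_protein"` is available), and simulated q-value failures
concentrate at low intensity; both choices keep missingness an
intensity-level phenomenon, which is what makes the dataset-wide
low-pool imputation coherent.  Outlier samples are displaced along a
shared sign-alternating protein pattern that no per-sample affine
recalibration can absorb.  An optional per-protein global offset
(`apply_cohort_shift`) emulates a cross-cohort matrix change such as EDTA
plasma versus serum.

What the generator does **not** emulate: nonlinear eGFR trajectories
(AKI episodes, tolvaptan pharmacodynamics), protein–protein correlation
beyond the shared slope/eGFR drivers, peptide-level quantification
artifacts, longitudinal drift within batches, and informative dropout.
Passing recovery tests therefore show that the pipeline's statistics
behave as designed under the stated generative model — not that the
published cohort-level numbers (R², AUC, protein sets) are reproduced;
those depend on non-public registry data.

## Numerical choices and degenerate inputs

- vsn calibration: L-BFGS-B, ≤5000 iterations, analytic gradients;
  convergence accepted at the optimizer's relative-reduction criterion or
  a gradient max below 1e-6·|objective|; failure raises with diagnostics.
- ComBat iteration: ≤100 conditional updates, tolerance 1e-6; δ² floored
  at machine epsilon.
- Trigamma inverse: Newton, ≤50 iterations, relative tolerance 1e-8.
- LASSO paths: coordinate descent with tolerance 1e-3 inside CV folds and
  the library default for the final per-replicate fit; nonzero means
  |β| > 1e-12.
- CV-λ tie-break: largest (sparsest) λ within 1e-12 of the minimum error.
- Dendrogram ties follow the linkage implementation's lowest-index
  convention; clustering is invariant to input order up to cluster labels.
- Half-open MIC class intervals: a growth rate exactly at a boundary goes
  to the higher class (1.5 %/yr → 1B).
- Agreement-line bootstrap resamples with degenerate (constant-predictor)
  draws are redrawn once, then recorded as NaN and excluded from the
  percentile if still degenerate.

## Known limitations

- The weighted-LASSO weight scheme is an interpretation (Huber on the
  outcome); alternative schemes may select different panels on real data.
- The vsn calibration is a reimplementation of the glog/arsinh idea, not
  a port; parameter values are not interchangeable with other tools, only
  the transformed scale's behaviour is.
- The MIC comparator is a class-mean refit, not the literature class
  equations; on cohorts very unlike the fitting cohort the two differ.
- Moderated tests assume one sample per patient; repeated samples need an
  explicit aggregation or mixed-model extension before testing.
- Adjusted R² comparisons against printed values inherit the rounding of
  the printed R² (three decimals), so agreement is asserted to the
  corresponding precision only.
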