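# Methods

This note documents the models, estimators and numerical choices behind
`tpdcnet`, in the spirit of the methods documentation that accompanies
packages such as statsmodels or msprime: what is computed, under which
assumptions, with which defaults, and what the synthetic benchmarks do and
do not demonstrate.

## Time-resolved partial directed coherence (TPDC)

### Model

Each multichannel hemodynamic recording is modelled as a time-varying
multivariate autoregressive (MVAR) process of order p over N channels:

    x(t) = sum_{r=1..p} A_r(t) x(t-r) + e(t),    e(t) ~ N(0, Sigma)

The Fourier transform of the lag coefficients,

    Abar(t, f) = I - sum_{r=1..p} A_r(t) exp(-i 2 pi f r / fs),

defines the squared partial directed coherence from channel j to channel i:

    |pi_{i<-j}(t, f)|^2 = |Abar_ij(t, f)|^2 / sum_{k=1..N} |Abar_kj(t, f)|^2.

The `I - A(f)` form is the standard PDC convention; it guarantees a non-zero
denominator for every stable model (the diagonal term of a null model is
exactly 1), whereas a denominator built from the raw coefficient transform
would vanish for uncoupled channels. Squared PDC lies in [0, 1] and each
source column sums to 1 over targets — an identity the test suite asserts to
1e-10 on every estimated spectrum.

Effective connectivity (EC) between two regions is the squared PDC averaged
over the hemodynamic band 0.009–0.08 Hz (closed interval, intersected with
the frequency grid; the number of in-band bins is recorded on the result)
and over all post-burn-in time points.

### Dual extended Kalman filter

Time-varying coefficients are tracked with a dual filter:

* a **state filter** over the stacked signal z(t) = [x(t) … x(t-p+1)] with
  companion-form dynamics built from the current coefficient estimate;
* a **weight filter** over the stacked coefficients (dimension p·N²) with
  random-walk dynamics, its measurement linearised around the current
  filtered state.

The two exchange estimates at every sample. Because the weight-filter
measurement noise is modelled as diagonal, the weight filter decouples into
N independent filters of dimension p·N, which is how it is implemented
(identical estimates at a fraction of the cost).

Tunable constants (all in `EKFConfig`, all logged at fit time):

| parameter | default | meaning |
|---|---|---|
| `weight_process_noise` | 1e-4 | random-walk variance per step; sets the tracking-speed / variance trade-off |
| `obs_noise_scale` | 1e-2 | state-filter measurement noise as a fraction of each channel's variance |
| `init_window` | max(5·p·N, 100) | leading samples for the least-squares initialisation of the weights |
| `burn_in` | max(50, 5·p·N), capped at T/4 | samples excluded from the valid range |
| `divergence_bound` | 1e3 | coefficient magnitude that aborts the filter with an error |

Initialising the weights at the stationary least-squares fit of the leading
window makes convergence fast and reproducible; starting from zeros would
lengthen the transient without changing the steady state. On
constant-coefficient data the time-averaged filter estimates agree with the
stationary least-squares oracle to well under 0.05 (n = 5000), and after a
mid-series step of 0.8 in one coefficient the last-quarter mean tracks the
new value to within 0.1 — both checked across seeds in the test suite.

The MVAR order is configurable; `select_order` offers AIC/BIC selection over
stationary fits (BIC is the default recommendation, capped at 10). The
frequency grid is 129 evenly spaced points on [0, fs/2].

### fNIRS walking stages

Motion-corrected delta optical density at two wavelengths is converted to
oxy-/deoxy-hemoglobin concentration changes by inverting the modified
Beer–Lambert system per probe, using packaged base-10 extinction
coefficients (Prahl/Cope compilation, cm⁻¹·µM⁻¹, overridable) and the
general wavelength- and age-dependent differential pathlength factor
equation of Scholkmann & Wolf (2013). The conversion is linear and exactly
invertible; the round-trip is verified to 1e-10.

Each walking trial (2 channels, left/right prefrontal, 10 Hz) passes through
the same TPDC chain; trials are averaged, and the two off-diagonal
directions are averaged into one bilateral prefrontal EC scalar per subject
and condition. HbO is the default chromophore (higher SNR in walking
fNIRS); HHb is available via `select_chromophore`.

## SVM model selection

Resting-state EC features (20 directed pairs among 5 ROIs) feed an RBF-SVM:
epsilon-SVR for predicting walking prefrontal EC, SVC for separating
patients from controls. Hyperparameters are fixed, not tuned:

* kernel width sigma by the median-distance heuristic on each training fold
  (implemented as the upper median of squared pairwise distances, a
  deterministic partition pick);
* regularisation constant C = 1;
* SVR epsilon tube IQR(y)/13.49 on each training fold — the scale-adaptive
  convention, so the tube width follows the response scale rather than
  assuming unit-scale targets.

Every non-empty feature subset (optionally capped by size) is scored by
k = 5 outer cross-validation; the inner k = 5 loop is retained in
`nested_cv_evaluate` as an honest score-estimation harness, but because no
hyperparameter depends on it, it cannot change the outer-fold scores and is
skipped inside the exhaustive enumeration, where it would multiply the cost
six-fold for no effect on the ranking. The optimal model maximises the mean
outer-fold score; ties within 1e-6 fall to the smaller standard error, then
the smaller subset, then lexicographic order — fully deterministic.

The enumeration engine works on precomputed per-feature squared-distance
matrices in per-fold permuted layout, accumulating subset distances
incrementally along the combination tree, and fits through the libsvm
binding directly; the test suite asserts exact agreement with the public
scikit-learn estimators and with the reference evaluator. A budget guard
refuses searches above a configurable evaluation count (default 200,000)
unless explicitly overridden: the full 2^20 space at nested-CV cost is an
hours-scale computation that should be a deliberate choice.

Classification metrics are accuracy, sensitivity and specificity in percent
with the patient group as the positive class; a fold missing one class
yields NaN for the affected metric, a warning, and exclusion from the
across-fold mean.

## Shapley attribution

Kernel SHAP is implemented in-package. The interventional value function
v(S) replaces features outside the coalition S with background rows (the
model's training fold) and averages the model output. For up to 12 features
all 2^m coalitions are enumerated, making local accuracy — base value plus
attributions equals the prediction — exact; the test suite also checks
agreement with an independent brute-force implementation of the Shapley
definition. Beyond 12 features a weighted-least-squares estimator with
sampled coalitions is used, with local accuracy enforced as an equality
constraint. Global explanations are the mean absolute Shapley value per
feature and group, averaged over outer folds, ranked descending by the
group average.

## Cohort statistics

* **dEC** is baseline minus follow-up, per subject and feature; subjects
  missing a session are excluded with a warning.
* The **nonparametric two-way ANOVA** for the 2x2 mixed design (group x
  condition) is, by default, a parametric mixed ANOVA on the pooled ranks
  (rank-transform procedure, via pingouin); the aligned-rank transform is
  available as `method='art'`. The variant choice is logged because the
  rank-based factorial ANOVA family has no single canonical member. Under a
  global null the per-effect type-I error is calibrated to 5% +/- 2%
  (checked over 1000 simulated datasets).
* **Wilcoxon signed-rank** (the paired-difference formulation), **Mann–
  Whitney U** and **paired t** use exact small-sample null distributions
  where feasible (scipy's exact methods), verified against brute-force
  enumeration of orderings/sign assignments on small examples.
* **Correlations**: Spearman on dEC pairs; for covariate correlations each
  variable failing Shapiro–Wilk at alpha = 0.05 is Box–Cox transformed at
  its maximum-likelihood lambda (non-positive values are shifted with a
  logged offset, or rejected in strict mode) before Pearson.
* **FDR**: Benjamini–Hochberg step-up, applied within each named battery
  (e.g. the 20 resting-state ECs), never across batteries. On a 20-feature
  global null, the fraction of replicates with any adjusted p < 0.05 stays
  at or below ~5%.

All tests are two-tailed at alpha = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator produces (a) stable time-varying MVAR series — 5-channel
"resting-state-like" series at 1/1.7 Hz and 2-channel "walking-trial-like"
series at 10 Hz — with known coefficient trajectories, Gaussian innovations,
a burn-in of max(200, 10p) samples discarded to remove initial-condition
transients, and an optional causal gamma-shaped smoothing kernel (off by
default) to probe robustness to hemodynamic smoothing without claiming an
HRF model; and (b) two-group (PD/HC, n = 19 per group by default), two-
session EC cohorts with 20 features in [0, 1] built from a clipped-Gaussian
subject-level model (baseline level 0.35, between-subject SD 0.12,
within-subject SD 0.05), planted group/session shifts, and a response that
is a known linear combination of a chosen feature subset plus Gaussian
noise.

These benchmarks validate the estimators against ground truth; they do not
establish performance on real recordings. Real hemodynamic signals carry
measurement noise, nonstationarity beyond the modelled coefficient drift,
hemodynamic convolution, and non-Gaussian EC distributions whose family the
clipped Gaussian only stands in for. Passing tests therefore demonstrate
correctness of the computation, calibration of the statistics under the
stated models, and recoverability of planted structure at realistic sample
sizes — not clinical validity.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run stationary/EKF checks at
n = 5000 (2 channels), spectrum identities at n = 1500, planted-truth
searches over all subsets of size <= 5 of the 20 features (21,699 models per
run, n = 100 rows), ANOVA calibration at 500–1000 replicates and the FDR
null battery at 1000 replicates. These sizes make every ground-truth effect
detectable while keeping a full run on one CPU comfortable.

## Known limitations

* No significance thresholding of PDC (surrogate or bootstrap nulls) and no
  alternative directed-connectivity estimators (DTF, coherence).
* The Kalman filter runs forward only; no backward smoothing pass.
* The published analyses this pipeline mirrors depend on unreported
  constants (MVAR order, filter noise settings); results on real data are
  therefore reproducible given a configuration, but not bit-exact against
  any external reference.
* Imaging-format ingestion (NIfTI, SNIRF) and fNIRS motion-artifact
  correction are out of scope; the contract starts at extracted,
  motion-corrected time series.
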