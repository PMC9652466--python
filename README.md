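# tpdcnet

Directed effective-connectivity analysis for hemodynamic brain signals:
time-resolved partial directed coherence (TPDC) from multichannel ROI time
series, RBF-SVM model selection over connectivity features, and the
accompanying cohort statistics. The package is aimed at researchers studying
intervention effects on brain networks — the motivating use case is
treadmill-training studies in Parkinson's disease, where resting-state fMRI
connectivity between five large-scale regions (prefrontal cortex, motor
cortex, brainstem, cerebellum, subcortical region) is linked to prefrontal
fNIRS activity measured during walking.

## What it computes

**TPDC.** Each recording is a time-varying MVAR process
x(t) = Σ_r A_r(t) x(t−r) + e(t), estimated per time point with a dual
extended Kalman filter (a state filter for the signal and a weight filter
for the coefficients, exchanging estimates every sample). The Fourier
transform Ā(t, f) = I − Σ_r A_r(t) e^(−i2πfr/fs) gives the squared PDC

    |π_{i←j}(f)|² = |Ā_ij(f)|² / Σ_k |Ā_kj(f)|² ,

column-normalised per source, averaged over the hemodynamic band
0.009–0.08 Hz and over time into one directed EC matrix. Five ROIs yield 20
directed features.

**Model selection.** An exhaustive feature search (all 2²⁰ = 1,048,576
subsets over 20 features; size-capped in practice) scores every subset with
an RBF-SVM under nested 5×5-fold cross-validation with fixed
hyperparameters (median-heuristic kernel width, C = 1), and selects the
model with the best mean outer-fold score and minimal standard error.
Feature contributions come from an in-package Kernel SHAP implementation
(exact coalition enumeration up to 12 features), summarised as mean
absolute Shapley values per group, averaged over folds.

**Statistics.** Rank-based two-way mixed ANOVA on walking prefrontal EC,
Wilcoxon/Mann–Whitney/paired-t contrasts on resting-state ECs, ΔEC
(baseline − follow-up) Spearman correlations, Shapiro–Wilk-gated Box–Cox +
Pearson covariate correlations, and Benjamini–Hochberg FDR within each
battery.

**Synthetic ground truth.** A first-class generator produces stable
(time-varying) MVAR signals and two-group, two-session EC cohorts with
planted effects and a response built from a known feature subset, so every
stage is testable without access to patient data.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import tpdcnet as t

# simulate a 2-channel series with unidirectional coupling 1 -> 2
A = np.array([[0.5, 0.0], [0.4, 0.5]])
spec = t.MVARSpec(n_channels=2, order=1, coeff_fn=t.constant_coeff_fn(A),
                  noise_cov=np.eye(2), sampling_rate=1.0, n_samples=2000)
ts = t.simulate_mvar(spec, seed=1)

# dual-EKF -> squared PDC -> band-averaged EC matrix
ec = t.tpdc(ts, order=1, band=(0.009, 0.08))
print(ec.round(3))
```

prints (rows = targets, columns = sources)

```
       ch1    ch2
ch1  0.640  0.011
ch2  0.360  0.989
```

The influence 1→2 (row ch2, column ch1: 0.360) clearly dominates the
reverse direction (0.011), matching the simulated coupling; each column
sums to 1 by the PDC normalisation. At f = 0 the closed-form squared PDC
for this model is 0.16/0.41 = 0.390; the band average sits below it because
the band lies away from DC.

Model selection on a synthetic cohort:

```python
cohort = t.simulate_cohort(t.CohortSpec(
    n_per_group=25, true_subset=("CB->SC", "MC->SC", "PFC->MC"),
    response_coeffs=(0.9, 0.7, 0.6), noise_sd=0.02, seed=0))
ranked = t.exhaustive_search(cohort, t.SVMConfig(), t.CVConfig(seed=0),
                             max_features=3)
best = t.select_optimal(ranked)
print(best.subset, round(best.mean_score, 3))
# ('PFC->MC', 'MC->SC', 'CB->SC') 0.939
```

The search recovers exactly the three planted features with a mean
outer-fold R² of 0.94.

A command-line interface mirrors the library
(`tpdcnet simulate | tpdc | beer-lambert | cohort | select-model | stats |
run`); `tpdcnet run --config cfg.yaml --out rundir` executes the configured
stages end to end and writes a manifest sufficient to reproduce the run.

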