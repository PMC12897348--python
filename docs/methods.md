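# Methods note

This note records the statistical model behind `tbscreen`, the fidelity
and limits of its synthetic data generator, and the numerical choices
that matter for reproducing its outputs. Empirical figures quoted here
are computed by the test suite or by `scripts/acceptance.py`; nothing
below asserts a number the repository does not itself compute.

## 1. Problem and labels

The package screens for obstructive sleep apnea (OSA) severity from
tracheal breathing sounds recorded during wakefulness, plus five
anthropometric variables. Severity classes follow the standard
apnea–hypopnea index (AHI, events/hour) cut-offs:

| class | AHI |
|---|---|
| non | < 5 |
| mild | 5 – < 15 |
| moderate | 15 – < 30 |
| severe | ≥ 30 |

Two label schemes are supported: the four classes above, and a
three-class scheme that merges moderate and severe into
`moderate_severe`.

## 2. Synthetic cohort generator

Because real clinical recordings cannot ship with the package, all data
are synthetic, generated by `tbscreen.cohort`.

**Anthropometrics.** Per class, age, BMI and neck circumference are
drawn from truncated normals with class-specific means and SDs; sex is
Bernoulli with class-specific male proportion; Mallampati score is
categorical. AHI is drawn from a truncated lognormal restricted to the
class's AHI interval, so labels and AHI are consistent by construction.
The default cohort has class sizes 74 / 35 / 50 / 40 (n = 199).

**Audio.** Each subject gets one nose-route and one mouth-route
recording at 16 kHz: five breath cycles of 1.2 s inspiration, 0.3 s gap,
1.6 s expiration (gain 0.6) and 0.4 s pause (17.5 s total). The carrier
is pink noise shaped by two resonances (IIR peak filters). Severity
enters only through the resonance center frequencies:
`f1 = 450 + 90·k·effect` and `f2 = 1300 + 180·k·effect` Hz, where `k` is
the class rank and `effect` is the configurable acoustic effect size
(mouth route shifts `f1` by +120 Hz).

**Fidelity and limits.** The generator reproduces the *structure* of
the problem — class-conditional anthropometric distributions, consistent
AHI labels, breath-phase morphology, a monotone class-separability knob —
not the acoustics of real tracheal sound. Its key falsifiable property,
exercised by the tests, is that at `effect = 0` the audio of all classes
is bit-identical for a fixed seed (so any downstream accuracy above
chance would indicate leakage), while at moderate effect sizes the
pipeline recovers the separability. Per-subject randomness uses
`np.random.SeedSequence(entropy=seed, spawn_key=(class_idx, i))`, so
results are reproducible and editing one class's size does not perturb
the other classes' subjects.

Feature-level cohorts (`generate_feature_cohort`) skip audio synthesis
and draw the 188 acoustic features directly from class-shifted
distributions; these are used for fast end-to-end trials and the
acceptance computations.

## 3. Signal preparation

Recordings are band-passed 75–3000 Hz with a zero-phase (forward–
backward) 4th-order Butterworth filter. The tests verify the measured
response against the closed form
`|H(f)|² = 1 / (1 + w^{2n})`, `w = (f² − f₀²)/(f·B)`,
`f₀ = √(75·3000)`; applied twice, the gain at each band edge is exactly
0.5. Breath phases are segmented with a log-variance profile (50 ms
windows, 50 % overlap, threshold at 0.25 of the dynamic range, minimum
segment 200 ms, short gaps merged), alternating inspiration/expiration.

## 4. Features

A frozen 188-name dictionary (version "1.0") covers, per route × phase:
spectral features (six octave-band powers and ratios over edges 75, 150,
300, 600, 1200, 2400, 3000 Hz; total power; centroid; spectral entropy),
higher-order statistics (bispectrum mean/max/entropy and mean
bicoherence on the principal triangle of a quarter-grid, nfft 256),
time-domain measures (Higuchi and Katz fractal dimensions, zero-crossing
rate, envelope-peak statistics), time–frequency measures (4-level `sym4`
DWT relative energies and log-energy entropies; constant-Q per-octave
means and SD), and nonlinear measures (recurrence quantification at a
10 % recurrence-rate target, dimension 3; Rosenstein largest Lyapunov
exponent). Per route, jitter and shimmer are computed from envelope
peaks. Each feature family is tested against an analytic or brute-force
oracle (e.g. bicoherence ≈ 1 for a phase-coupled triad, DWT relative
energies summing to 1, jitter of known inter-burst periods).

## 5. Tabular pipeline

1. **Imputation** – severity-stratified k-NN (k = 3) on z-standardized
   distances, with stratum-mean and global-mean fallbacks (each fallback
   warns).
2. **Adaptive normalization** – per column, the scheme (z-score, robust,
   mean-range, min-max) that maximizes plug-in mutual information with
   the label (10 quantile bins; ties resolved in that fixed order).
3. **Three-stage selection per one-vs-one task** – Welch t-test filter
   (α = 0.05), random-forest + sampling-permutation-Shapley ranking,
   then recursive feature elimination with an in-package RUSBoost
   classifier down to `target_k = 30` acoustic features. The five
   anthropometric columns are appended afterwards, giving a 35-column
   design matrix (acceptance quantity t11; deterministic).

## 6. Classification stack

Six canonical one-vs-one tasks are trained as bagged ensembles with
stored bootstrap indices, so out-of-bag (OOB) probabilities are exact.
Model family and hyperparameters come from a Gaussian-process
expected-improvement search (Matérn 2.5) over OOB balanced accuracy;
with a single candidate family and budget ≤ 1 the search is skipped. The
meta learner consumes the 12 OOB pairwise probability columns
(6 tasks × 2) and is a scheme-specific MLP — (16, 16), lr 7.06e-2 for
three classes; (16, 16, 8), lr 5.14e-3 for four — chosen by CV unless a
single candidate is given. Using OOB rather than in-sample base outputs
avoids the optimistic bias that would otherwise leak into the stack.

## 7. Conformal prediction

Split conformal with score `s = 1 − p(true class)`. The threshold is the
`⌈(1−α)(n+1)⌉`-th smallest of the calibration scores augmented with ∞
(∞ when the rank exceeds n). Calibration subjects are a class-stratified
20 % holdout of the training set (half-up per-class counts). Prediction
sets may be empty. Finite-sample marginal coverage ≥ 1 − α holds by
exchangeability; the acceptance computation t8 measures it empirically:
mean test coverage over 500 independent n = 120 cohorts at α = 0.05,
compared against 95 % within 3 Monte-Carlo standard errors.

## 8. Partitioning and evaluation

Subject-level splits are stratified 85/15 with half-up per-class test
counts ((74, 35, 50, 40) → (11, 5, 8, 6)), followed by a seeded
greedy-swap refinement that reduces the train/test discrepancy of
binarized clinical factors without changing class counts. K-fold
assignment is rarity-first greedy with per-class fold quotas within ±1.
Metrics are reported in percent. Paired comparisons use the exact
McNemar test (two-sided binomial, center not double-counted when tied),
paired t, Wilcoxon, Cohen's d_z and Cliff's δ, with Bonferroni
correction at 0.05/6 ≈ 0.00833 for the six pairwise comparisons.

## 9. Numerical choices

- All statistics use explicit `ddof`: sample SDs over folds are ddof = 1.
- Half-up rounding (`floor(x + 0.5)`) for per-class counts, so splits
  are platform-independent.
- Randomness flows from integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; derived seeds are drawn
  below 2³¹. No global RNG state is used.
- Zero-phase filtering uses `scipy.signal.filtfilt` with default
  padding; tests measure gains away from the edges.
- The bispectrum uses non-overlapping 256-sample segments (up to 64) so
  the phase-coupling oracle is exact in expectation.
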