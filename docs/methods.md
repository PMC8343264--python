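# Methods

This note documents the models, rules and numerical choices behind
`hypnorisk`, in the order data flows through the pipeline, together with
the design decisions that were genuinely open and the limitations a user
should know about.

## Epochs, labels and pruning

All staging operates on 30-s epochs labelled WAKE, N1, N2, N3, REM or
UNKNOWN. Quality control applies two rules before any analysis: an epoch
flagged artefactual or with more than 50% of its samples missing becomes
UNKNOWN, and a 24-h day whose UNKNOWN fraction exceeds 30% is excluded
from all downstream analyses. Both thresholds are configurable
(`PruningRules`); pruning is idempotent and never converts UNKNOWN back
to a stage.

Days run from noon to noon. The boundary is a package choice — the
alternative (midnight) splits the main sleep period across two days,
which corrupts per-day totals. A sleep period belongs to the day
containing its onset. Tests verify that shifting the boundary by ±2 h
changes per-patient mean total sleep by less than 5% on simulated data.

## Feature extraction (21 features per epoch)

Spectral estimates use Welch's method with 4-s Hann windows and 50%
overlap (0.25 Hz resolution), so integer band edges fall on bin edges.
Band membership is half-open `[low, high)` to avoid double-counting
shared edges at 3, 7, 12 and 15 Hz. The features are:

* mean dominant frequency — the mean over Welch sub-windows of each
  window's 1–25 Hz peak frequency (an epoch-level argmax was the other
  candidate; the sub-window mean is smoother and equally simple);
* spectral median frequency — the frequency splitting the 1–25 Hz Welch
  spectrum into equal power halves, interpolated bin-centred so a pure
  tone returns its own bin frequency;
* absolute and relative power in delta 1–3, theta 3–7, alpha 7–12,
  low beta 12–15 and high beta 15–20 Hz (relative to the total 1–25 Hz
  power);
* normalised spectral entropy (Shannon entropy of the within-band
  normalised spectrum divided by log of the bin count) in each of the
  five bands plus broadband 1–25 Hz;
* relative energies of three Daubechies-4 discrete-wavelet detail
  levels whose nominal bands are 8–16, 4–8 and 2–4 Hz, relative to the
  total coefficient energy.

The wavelet triplet is a reconstruction: the feature set this package
implements is specified only as spectral, entropy-based and wavelet
features totalling 21, of which the spectral and entropy features
account for 18 identifiable ones. Three wavelet relative energies
complete the set; they should not be assumed to match any particular
earlier implementation coefficient-for-coefficient.

Quantile normalisation rescales each feature by its 5th/95th quantiles,
`x' = (x − q05)/(q95 − q05)`, fitted per patient on non-missing epochs
(at least 20). Values are clipped to [−0.5, 1.5] to bound the influence
of energy outliers; the clipping range is a package choice, since
quantile scaling alone leaves extreme artefact epochs unbounded.
Constant features (q05 = q95) are flagged unusable rather than divided
by zero, and are excluded from feature selection. Both normalised and
raw features are kept, because classifier selection considers both.

A note on estimator limits encoded in the tests: under a Hann taper a
bin-centred pure tone occupies exactly three bins with weights
(1/6, 2/3, 1/6), so the spectral entropy of a tone has a small positive
floor rather than reaching 0; the exact 0 limit is only attained by a
single-line spectrum.

## Patient-specific staging

Training days: nine days at rounded-equidistant positions across the
usable days (first and last always included). On real data the labels
for those days come from manual scoring; on synthetic data from
generator ground truth.

Feature selection: greedy sequential forward selection of 8 of the 21
features, scored by stratified cross-validated macro recall with a
Gaussian Naive Bayes worker classifier. Ties break toward the lower
canonical feature index, making selection deterministic given the seed.

Model selection: a grid over {KNN with neighbour count k = 3..50,
Gaussian Naive Bayes} × {normalised, raw} features, evaluated by
stratified 5-fold cross-validation (folds shuffled with the run seed).
The "K = 3–50" range is interpreted as the KNN neighbour count tuned by
cross-validation. The selection metric is macro-averaged recall, which
protects the rare stages (N1, REM) from being swamped by WAKE/N2; plain
accuracy is reported alongside. Ties prefer Naive Bayes over KNN, then
smaller k, then the normalised variant. KNN cross-validation evaluates
all k values from a single neighbour search per fold, with majority
votes breaking ties toward the lowest class index.

Scoring proceeds in 24-h blocks; epochs with missing selected features
score UNKNOWN. Agreement metrics (accuracy, Cohen's kappa, per-class
recall, confusion matrix) exclude UNKNOWN epochs pairwise. N1 is known
to be the least reliable stage — it is electrographically close to wake
and rare — so no analysis in this package draws conclusions from N1
accuracy, and isolated N1 runs bordered by wake on both sides are
ignored entirely when detecting sleep periods.

## Sleep periods, naps and cycles

Sleep-period detection replaces manual onset/offset labelling with
explicit rules: maximal runs of sleep stages are merged across wake
gaps shorter than 30 min; a period must contain at least one sleep run
of 10 min; intra-period wake is WASO and counts toward total sleep
duration; periods shorter than 2 h (including WASO) are naps. The
30-min merge and 10-min seed are configurable tolerances chosen to keep
a night with ordinary arousals in one piece without bridging night and
morning nap.

Cycles follow the REM-anchored definition: REM runs separated by less
than 10 min form one REM period, cycle *i* spans from the start of REM
period *i* to the start of REM period *i+1*, and at most five cycles
per night are analysed. Note this differs from conventional AASM-style
cycle scoring, which would end a cycle at the end (not the start) of
its REM period; the REM-start-to-REM-start reading is used deliberately
and consistently, including in the simulator's ground truth, so
recovered trends are comparable. Nights with fewer than two REM periods
yield no cycles.

Circadian statistics use unit-vector averaging on the 24-h dial;
histograms are normalised to unit mass over 24 bins.

## Day categorisation, outcomes and the risk model

For each sleep variable (total sleep duration; WASO, N1, N2, N3, REM
proportions of total sleep) and each patient, the 25th and 75th
percentiles are computed over **seizure-free** days only, with linear
interpolation between order statistics (the numpy default; the
percentile definition was unspecified and this is the least surprising
choice). Baseline is inclusive on both endpoints; seizure days are
labelled `excluded` — they never shift thresholds and contribute no
predictor rows, but their seizures still serve as outcomes for earlier
days' windows. Each variable is categorised marginally, one model per
variable.

The outcome of a categorized day is whether any seizure onset falls in
`(day_end, day_end + 48 h]`, where `day_end` closes the day's own 24-h
window: the window is anchored at the end of the measurement day
(half-open at the start so the day's own seizures are not counted,
closed at +48 h). The anchor was an open choice; anchoring at the day
end keeps predictor and outcome temporally disjoint.

The risk model is a logistic regression with a patient-specific random
intercept, fitted by maximising the marginal likelihood with adaptive
Gauss–Hermite quadrature: each patient's integrand is centred at its
posterior mode (found by Newton iterations) and scaled by the local
curvature, then integrated with 15 Hermite nodes. The variance
parameter is optimised on the log scale. Start values come from a
ridge-stabilised ordinary logit. Inference is Wald-type from the
numerical Hessian at the optimum (matching the CI style such analyses
report); profile-likelihood intervals are not implemented. With the
random-intercept SD fixed at 0 the model reduces exactly to ordinary
logistic regression, which the tests exploit as a closed-form oracle
(2×2-table odds ratio, and statsmodels `Logit`). Complete separation in
binary predictors is detected and reported as a warning on the results
object. Two contrasts per model are tested at Bonferroni-corrected
α = 0.025.

## Post-seizure comparisons

Days are partitioned into control (seizure-free), wake-seizure and
sleep-seizure days; a day with both kinds is excluded, as is a day
whose only seizures fall in UNKNOWN epochs. A seizure in intra-period
wake (WASO) counts as a sleep seizure. For recovery analyses the label
can be shifted by one day (`label_days_after_seizure`) so each day is
classified by the preceding day's seizure status.

Per-patient condition means feed a one-way repeated-measures ANOVA.
Proportions are arcsine-square-root transformed first; sphericity is
not assumed and the Greenhouse–Geisser epsilon (computed from the
condition covariance matrix, clipped to [1/(k−1), 1]) corrects both
degrees of freedom. Dunnett many-to-one contrasts against control use
the two-sided equicorrelated (ρ = 0.5) multivariate-t distribution with
n−1 degrees of freedom, evaluated by quasi-Monte-Carlo rectangle
probabilities with a fixed internal seed (100 000 points, reproducible
to well below any decision threshold); with a single comparison this
reduces exactly to the paired t-test. Patients missing a condition are
dropped listwise; at least three complete patients are required.

Bootstrap mean-difference distributions resample within group with
replacement (default 10 000 resamples) and report the 2.5/97.5
percentile interval.

## The synthetic cohort generator

The generator emulates the structure of a long-term ambulatory cohort
so that every pipeline stage can be validated against known truth. Its
defaults describe the study conditions the package targets:

| Parameter | Default | Why |
|---|---|---|
| sleep onset clock time | 23:00 ± 0.75 h (SD) | typical adult schedule |
| night sleep duration | 9.5 ± 1.0 h | cohorts with refractory epilepsy sleep long (roughly 7.5–11.4 h/day) |
| naps per day | Poisson(0.6), 0.25–1.75 h | observed nap rates of 0.2–1.3/day; naps are < 2 h by definition |
| cycles per night | 5, first 1.9 h, ×0.85 per cycle | shortening cycles across the night |
| N3 share by cycle | 0.35 → 0.08 | deep sleep front-loaded |
| REM share by cycle | 0.10 → 0.32 | REM back-loaded |
| WASO fraction | 0.10 | arousal-interrupted sleep |
| dropout / artifact rate | 0.03 / 0.01 per epoch | telemetry gaps and artefacts |
| baseline log-odds | −0.85 | day-level seizure probability ≈ 0.30 for a high-burden cohort |
| random-intercept SD | 0.5 | marked between-patient heterogeneity |
| per-patient day counts | 224–709 days, 4340 total across 10 patients | the cohort scale the analyses target |

Nights are assembled from cycles laid out N1 | N2 | N3 | N2 | REM with
per-cycle stage shares from the trajectories above; WASO is inserted as
short (0.5–4 min) arousal runs into non-REM sleep so every cycle keeps
its REM period. Seizure days are drawn from the generating logistic
model on the day's sleep category; event times are placed into
sleep-wake states by configurable weights or, without a hypnogram, by a
two-component von Mises clock-time mixture anchored at typical sleep
onset and offset (an illustrative choice — no quantitative circadian
seizure-phase parameters were available to emulate). Post-seizure
effects are additive shifts on the next day's sleep: +0.7 h after a
wake-seizure day; +1.2 h, +0.04 WASO proportion and −0.04 REM
proportion after a sleep-seizure day.

Signals are synthesised in the frequency domain as coloured Gaussian
noise whose spectrum is piecewise-constant over the five scoring bands
(plus a 5% broadband floor), giving exact control of expected relative
band powers at any sampling rate. The default rate is 128 Hz — all
features live below 25 Hz, so nothing is gained by simulating faster.
Two fidelity levels exist: signal-level simulation for feature-extractor
and end-to-end tests, and a fast feature-level path
(`simulate_feature_matrix`) that draws per-state Gaussian feature
vectors with a fixed state-mean pattern scaled by a separation
parameter, for classifier tests.

What the generator does **not** emulate: real iEEG morphology
(spindles, K-complexes, epileptiform discharges), non-stationary drift,
medication/alcohol/stress covariates, multi-channel montages, weekly
rhythms, or seizure clustering beyond the day-level model. Passing
tests therefore demonstrate that the pipeline's rules and estimators
are correct and well calibrated under controlled conditions — not that
the stager would reach the same accuracy on clinical recordings.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed; identical seeds and
parameters reproduce byte-identical outputs. Parameter-recovery and
calibration studies run at 10 patients × 430 days with 25 replicates
(recovery) or 200 replicates (null calibration); the end-to-end staging
test uses 2 patients × 20 days of signal-level simulation. These sizes
were chosen so the Monte-Carlo error of a mean recovered odds ratio
(≈0.012) sits well inside the ±0.05 acceptance band while the whole
suite stays desk-scale.

## Known limitations

* Associations between sleep categories and subsequent seizures are
  correlational; nothing here supports causal claims, and reverse
  causality (pre-seizure states altering sleep) cannot be excluded by
  the design.
* The 21-feature set is a documented reconstruction (see above).
* Wald intervals can undercover when patients are few and the
  random-intercept variance is near zero.
* The Dunnett quantile uses an equicorrelation approximation rather
  than the exact correlation structure of the difference scores.
* The stager assumes a single representative channel; channel reduction
  from a montage is out of scope.
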