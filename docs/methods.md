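# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish about real data.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, not
the physiology. Background activity is Gaussian 1/f^α noise (default
α = 1, 10 µV RMS — typical of broadband scalp EEG), generated independently
per epoch and channel by spectral shaping, with the DC bin zeroed. Epochs
are 797 samples at 256 Hz (floor(3.11 s × 256) + 1), with the stimulus
onset placed exactly on sample index 285 so that t = 0 lies on the grid;
the axis spans [-1.113, 1.996] s. Continuous recordings place events at
the task's 3.11 s stimulus-onset asynchrony with a seeded shuffle of the
six emotion labels.

An effect specification is a frequency band ⊂ [4, 90] Hz, a post-stimulus
window ⊂ [0, 2] s, a channel subset, a signed dB change, and the
(emotion, load) cells it applies to. Effects are implemented
*multiplicatively*: the band-limited component (4th-order zero-phase
Butterworth) is rescaled by 10^(dB/20) inside the window under a Tukey
(α = 0.2) taper. Because the same realization's baseline is left untouched,
the realized window-to-baseline band-power ratio equals the requested dB by
construction — the contract the ERSP stage is tested against. A
down-scaling (negative dB) yields event-related desynchronization without
needing to "subtract" oscillations.

MOT behavior follows the study's success model with one target among `d`
discs: each trial is Bernoulli with p = (m_true + d/2)/d. As printed, this
model puts chance performance at 1/2 for d = 4 rather than at the guess
rate 1/d; the generator deliberately follows the printed form rather than
silently correcting it, and the capacity estimator inverts exactly the same
form, so estimator-recovery tests are internally consistent. Default
generating capacities (low-traits group: 1.58 / 2.60 effective targets for
the 4- and 8-disc tasks; high-traits group: 0.78 / 1.32) mirror the
reported group means on the m′ scale (0.79/0.65 vs 0.39/0.33).

Trait T-scores are multivariate normal, rounded to integers and clipped to
[20, 120], with a compound-symmetric inter-scale correlation of 0.95 by
default — strong enough that most of the 13 scales exceed VIF 10 in a
31-subject sample, which is the multicollinearity regime the ridge stage
exists for. Group means default to 45 (low) and 65 (high), SD 10.

What the generator does **not** emulate: eye/muscle artifacts, volume
conduction from a head model, non-Gaussian amplitude distributions,
cross-channel correlation of the background, trial-order effects, and
inter-subject variability beyond the seeded noise. A pipeline that passes
these tests is therefore shown to be *algorithmically* correct and
calibrated under exchangeable noise, not validated against physiological
recordings.

## Preprocessing

- Average re-reference and per-channel mean removal are exact arithmetic
  operations (idempotent to 1e-9).
- The bandpass is a 6th-order Butterworth (scipy `butter(3, band)`, which
  doubles the order for bandpass designs) applied forward–backward;
  zero-phase filtering is chosen to preserve ERSP latencies. A high cutoff
  at or above Nyquist is clipped to 0.95 × Nyquist with a logged warning.
- Line noise is removed by least-squares sine/cosine regression at 60 Hz
  and harmonics in 4 s windows with 50 % overlap, Hann-weighted
  overlap-add (constant-overlap-add, so stationary content is subtracted
  exactly and slow amplitude drifts are tracked). This approximates
  multitaper line-removal plug-ins without reimplementing them.
- Bad channels: (1) flatline (derivative < 1e-8 µV/sample) longer than
  5 s; (2) line-band (±1 Hz) to broadband Welch power ratio more than 4 SD
  above the channel population; (3) mean log-likelihood under a pooled
  Gaussian KDE (Silverman bandwidth; deterministic subsampling to a few
  thousand points) more than 5 SD below the population mean. The KDE is the
  package's estimator choice — only the statistic, not the estimator, is
  canonical.
- Interpolation is the spherical-spline method of order m = 4 with the
  Legendre expansion truncated at 7 terms (the named toolbox's "n = 7" is
  read as the term count; the alternative reading — a different
  parameterization — is not defined anywhere we could verify). The
  constant term makes spatially uniform fields exact.
- Amplitude-based epoch rejection (±150 µV default) stands in for
  transient-artifact removal; the synthetic data carries no physiological
  artifacts, so a subspace-reconstruction stage would have nothing to do.
- Resampling is polyphase (`resample_poly`) with the rational factor from
  a denominator-limited fraction; only downsampling is supported.

## ERSP

Wavelet power uses complex Morlet wavelets with a cycle count linear in
frequency: cycles(f) = 4 + 41·(f − 4)/86, i.e. 4 cycles at 4 Hz to 45 at
90 Hz. The default grid is 44 linear bins (2 Hz steps) and the time grid is
decimated by 13 samples (≈ 51 ms hops). Samples closer to an epoch edge
than the wavelet half-support (cycles/2f) are flagged invalid and excluded
from baseline means — never silently zeroed. The epoch geometry guarantees
the [0, 1.5] s statistics window is edge-valid down to 4 Hz.

ERSP is dB of the trial-mean power over the trial-and-time mean baseline
power ([-1.1, -0.1] s): log of the mean, not mean of single-trial logs,
which is biased at low SNR. Scaling the whole recording by a constant
leaves ERSP unchanged.

**Surrogate significance mask.** The naive surrogate scheme — resample one
baseline time point per epoch, average, and compare raw trial-mean power to
the surrogate quantiles — is badly anti-conservative on wavelet power
(~20 % false positives at α = 0.05 in our null simulations): the wavelet
correlates baseline samples within an epoch, and a surrogate's time draw
lies inside the very window that defines its own reference, deflating the
null spread. The package therefore uses a calibrated epoch-level bootstrap
of the *contrast*: each of the 200 surrogates is a mean over an epoch
resample (with replacement) of one random baseline time point per drawn
epoch, referenced to the baseline-window mean of an independent epoch
resample; the observed trial-mean power, referenced to the observed
baseline mean, is declared significant outside the two-sided α quantiles.
Measured null false-positive fraction: ~6 % at α = 0.05 (100-epoch runs).

A planted +6 dB, 0.6 s burst is recovered at ~5.4 dB at the window core
(central half in time, interior of the band); the full-window mean is
biased low (~4 dB for short bursts) purely by Morlet temporal/spectral
smoothing, so calibration statements in the tests are made at the core.

## Cluster-based permutation inference

Statistic maps are computed per (channel, frequency, time) sample:
repeated-measures one-way or fully-within two-way ANOVA F (each effect
against its subject-by-effect error term), paired T, or pooled-variance
independent T. The cluster-forming threshold is the parametric critical
value at p < 0.05 for the design's df (±t₀.₀₂₅ for T maps, with positive
and negative clusters formed separately). Clusters are connected components
over adjacent frequency bins, adjacent time bins, and neighboring sensors;
components spanning fewer than two distinct sensors are discarded (a
`min_sensors=0` variant covers resting-state-style controls). Cluster mass
is the sum of the statistic over members.

Sensor neighborhood is great-circle distance ≤ 0.85 rad on the unit
sphere. The threshold was set so that laterally adjacent 10-20 sites
(Cz–C3: 0.84 rad on the sphere-projected template) are neighbors and the
32-channel preset has median degree 7; note the template is slightly
asymmetric (Cz–C4 is 0.853 rad and just misses), which is a property of
the idealized coordinates, not of the algorithm.

The permutation null exchanges condition labels within subject (cell
labels jointly for the two-way design — exact interaction-only permutation
schemes do not exist, a documented limitation), signs of paired
differences (closed-form vectorization: the per-sample sum of squares is
flip-invariant, so all permutation T maps come from one matrix product),
or group membership for independent designs. The maximum cluster mass per
permutation forms the null; p = (1 + #{max ≥ |mass|})/(1 + n_perm), ties
counted as exceedances (conservative), so p ∈ [1/(n_perm+1), 1]. An exact
mode enumerates all 2^S sign assignments for small paired designs and then
reports the exact permutation p (#assignments ≥ observed / 2^S). Post-hoc
pairwise dependent-sample cluster tests multiply p by the number of pairs
(Bonferroni, capped at 1) and decide at 0.025 per tail.

## Behavior

Capacity: m = n(dp − d/2) ∈ [−d/2, d/2]; the printed rescaling formula has
ambiguous parenthesization, and is implemented as the affine map of
[−d/2, d/2] onto [−1, 1] — the only reading consistent with the printed
endpoint values (m = −2 → −1 for d = 4; m = 4 → 1 for d = 8).

The mixed (split-plot) two-way ANOVA is computed by explicit sums of
squares: group against subjects-within-groups, the repeated factor and the
interaction against the condition-by-subjects(group) term. Generalized eta
squared follows the Olejnik–Algina scheme with both factors manipulated:
SS_effect / (SS_effect + SS_subjects-within-groups + SS_within-error);
classical partial eta squared is emitted alongside. Mauchly's W and the
Greenhouse–Geisser ε come from the double-centered within-level
covariance; ε ≡ 1 (and W ≡ 1) with two within levels, and the
GG-corrected p is reported whenever Mauchly's p < 0.05. Residual normality
is Shapiro–Wilk on cell-mean + subject-deviation residuals. Post-hocs use
pairwise differences over the matching error term with studentized-range
p-values (Tukey's procedure) and a plain difference/SE z column. The
1.5 × IQR sensitivity rerun drops whole subjects contributing a flagged
value — removing single cells would unbalance the repeated design — and
reports whether any effect's p < 0.05 decision changes.

BF₀₁ uses the BIC (unit-information prior) approximation
exp((BIC₁ − BIC₀)/2) on nested OLS fits with subject dummies. This tracks,
but does not equal, default-prior Bayes factors from JZS-style analyses;
its values are used only for direction-of-evidence statements, never as
numerical reproduction targets.

## Trait regression

VIF is 1/(1 − R²) from regressing each predictor on the rest (perfect
collinearity → +∞ sentinel). Ridge solves the penalized least-squares
problem on internally standardized predictors via SVD; GCV(λ) =
N·RSS/(N − tr H)² is minimized over 50 log-spaced penalties in
[1e-4, 1e3]. Approximate inference uses the sandwich variance of the
linear ridge estimator with residual df N − tr H; these SE/T/p are
approximations (the provenance of such values in applied reports is
typically unstated) and are labelled as such in the API. Single-predictor
OLS goes through statsmodels with Durbin–Watson, Shapiro–Wilk and
Breusch–Pagan diagnostics and a Bonferroni column over the model family.

Bivariate outliers use a robust ellipse: coordinate-wise medians,
1.4826·MAD scales, a Gnanadesikan–Kettenring robust correlation, and a
χ²(2) 0.99 fence on the robust squared Mahalanobis distance — emulating the
~1 % outlier rate of bivariate-boxplot constructions, whose published
variants do not fix constants. The fence is affine-equivariant under axis
scaling.

## Problem sizes in the test suite

The statistical guarantees are exercised at desk scale, chosen once:
type-I calibration on 200 replicate null datasets (10 subjects, 2
conditions, 8 channels × 10 frequencies × 15 times, 250 permutations);
planted-effect recovery with 20 subjects, 12 channels, a +10 dB theta
burst over 5 neighboring channels and 300 permutations; ERSP calibration
with 102 epochs; estimator recovery with 1000 subjects × 40 trials. All
randomness is seeded; identical seeds give bit-identical outputs across
every generator and test.

## Known limitations

- The amplitude-threshold epoch gate is not a substitute for artifact
  subspace reconstruction or ICA-based component rejection on real data.
- The joint within-subject cell permutation tests full exchangeability;
  a significant interaction cluster can in principle reflect strong main
  effects under this null.
- Ridge SE/T/p are first-order approximations; for publication-grade
  inference a resampling scheme should be preferred.
- The EDF+ export path is not implemented; synthetic studies are written
  as BrainVision triplets only.
- BF₀₁ values are BIC approximations and not comparable in magnitude to
  default-prior Bayes factors.
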