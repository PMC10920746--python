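# Methods

This package re-implements, as a tested pipeline, a frequency-tagging EEG
analysis of face realness: steady-state visual evoked potential (SSVEP)
amplitude extraction, spatio-spectral decomposition (SSD), N170-like ERP
metrics, task-related component analysis (TRCA) decoding of realness
level, and a linear-versus-quadratic mixed-model comparison.  Because the
original recordings are only available on request, the package ships a
synthetic-data generator that emulates the study design; every analysis
stage is exercised and tested against it.

## Study design emulated by the generator

Thirty-six face images form a complete 6 (realness, R0 most cartoon-like
to R5 photographic, coded 1..6) x 2 (gender) x 3 (emotion) factorial.
Each session presents each image once in random order, one 10 s trial per
image, with a face shown every 200 ms for 100 ms followed by 100 ms of
scrambled background — a 5 Hz face presentation rate and a 10 Hz
face/background reversal rate.  Trials begin with a 200 ms gray screen;
the generator defines face onsets on the 5 Hz grid from trial start (50
onsets) and suppresses the evoked response during the gray lead, so the
analyzed [1 s, 9 s] window is unaffected.  The full study has 10 subjects
and 8 sessions; simulation studies in the tests and the acceptance script
use smaller subject/session counts, chosen so each study runs in seconds
to minutes while keeping the statistical behavior of interest.

## Generative model

Each face onset evokes a biphasic transient modeled as a sum of Gaussian
bumps: a positive peak (default +2 uV at 100 ms, width 15 ms) and an
N170-like trough (default -5 uV, width 15 ms) whose latency depends on
realness level (defaults 173.1, 176.9, 175.5, 178.9, 177.51, 177.38 ms
for levels 1..6, following the reported per-level latencies).  The
sum-of-Gaussians family was chosen because window means have a closed
form, giving exact oracles for the amplitude-measurement tests.

The trough is scaled by the realness amplitude profile

    a(r) = b0 + b1 r + b2 r^2,       r = 1..6,

plus a Gaussian subject random intercept (SD 0.3); the positive peak is
realness-independent, so classes differ both in trough latency and in the
ratio of the two components.  The default profile (b0, b1, b2) =
(1.2, -0.175, 0.025) is U-shaped with its vertex at r = 3.5.  Its
magnitude is an arbitrary choice — the study does not determine the true
effect size — calibrated analytically so that a 10-subject experiment
detects the quadratic term with roughly 90% likelihood-ratio power at the
default trial noise (SD 1.0 in amplitude units, averaged over 48
trials/condition), i.e. comfortably above 80% without saturating.

The evoked source projects to the scalp through a fixed Gaussian spatial
profile (width 0.05 m) centered midway between PO8 and O2, encoding the
occipito-parietal, right-lateralized topography, without a volume-
conduction head model.  Background activity is 1/f pink noise per channel
(default SD 1.0 uV, exponent 1) plus a 10 Hz alpha sinusoid with random
phase and a posterior spatial profile (default SD 0.5 uV at its peak).
The noise scale was set so that decoding difficulty is in the regime the
study reports (six-class accuracy a few times chance; the near-identical
pair hardest); real EEG has higher broadband noise but also richer
class-specific structure than a latency-and-ratio code, and the generator
trades one simplification against the other.

What the generator does *not* emulate: eye blinks and muscle artifacts,
channel-specific noise topographies, non-stationarities across sessions,
realistic volume conduction, or genuinely unknown class differences
(e.g., topography shifts across realness).  Passing tests therefore show
that the algorithms are correct and well-calibrated under the assumed
signal model, not that the reported effect sizes would replicate.

The stimulus table carries an eye-size confound: mean eye size decreases
by `confound_slope` (default -30 px) per realness level, except that the
two most realistic levels share one distribution, so an R4-vs-R5 contrast
is confound-free.  The realism rating increases linearly with realness;
luminosity has no systematic trend.  By default the confound affects only
stimulus attributes, not the EEG; an optional coupling flag
(`confound_drives_eeg`) exists for sensitivity analyses.

## Preprocessing

A zero-phase Butterworth band-pass (3-40 Hz) of order 3 per pass is
applied forward-backward, so the effective magnitude response is the
squared third-order response and the group delay is zero.  Trials are
trimmed to [1 s, 9 s] after the trial marker (dropping SSVEP ramp-up and
ramp-down), decimated to 250 Hz after an anti-alias low-pass at 0.4x the
target rate (the decimation method is otherwise unspecified; aliasing
must be prevented), and segmented into forty non-overlapping 200 ms
windows aligned to face onsets.  The recording reference is kept as-is.
All amplitudes are carried in microvolts; SSD/TRCA component signals are
arbitrary-unit.

## Amplitude measurement

Single-trial FFT amplitudes use a Hamming window and are normalized by
the window's coherent gain (sum of window / N), so a unit-amplitude
on-bin sinusoid reads exactly 1.0 uV; requested frequencies must be exact
FFT bins (8 s trials make 5, 10, 15 Hz exact).  Electrode-cluster values
are unweighted means over the nine parieto-occipital channels (Pz, PO3,
PO7, PO4, PO8, POz, O1, Oz, O2).  Welch spectra use 2 s Hamming windows
with 50% overlap (0.5 Hz resolution, separating 5 Hz from its flankers).

## SSD

Spatial filters maximize w'C_s w / w'C_n w where C_s is the covariance of
the data band-passed in [4, 6] Hz and C_n the summed covariance of the
[2, 3] and [7, 8] Hz flanking bands, each filtered with a 2nd-order
zero-phase Butterworth on the concatenated continuous data of one
participant.  C_n receives trace-scaled shrinkage (default 1e-6) against
rank deficiency.  Up to three components with eigenvalue > 0.7 are kept.
Patterns are reconstructed as A = C_s W (W'C_s W)^-1 and sign-
standardized to be non-negative at Oz.  Components are matched across
subjects by the absolute dot product of unit-normalized patterns; with
more than two subjects the mean pairwise similarity is used (the
aggregation is not otherwise pinned down).

## TRCA classification

For each class, S sums channel-by-channel cross-covariances of the
class's *session-mean* responses over all ordered pairs of distinct
sessions (sessions, not trials, index the repetitions: each image appears
once per session), and Q is the covariance of the session-averaged class
template.  The spatial filter is the leading generalized eigenvector of
(S, Q); one filter per class (no ensemble or filter-bank variant).  An
alternative Q — the summed within-session covariance — is available by
flag and yields the same filter up to scale, a property asserted in the
tests rather than assumed.  Covariances remove the per-window time mean.
An optional ridge on Q handles the rank-deficient noise-free limit.

A test trial is assigned to the class whose filtered template has the
largest Pearson correlation with the filtered test data; exact ties go to
the lowest class index (deterministically, with a warning).  Evaluation
is leave-one-session-out cross-validation with per-session class balance
enforced, accuracies averaged across folds and then subjects.  Decoding
windows (2 s or 8 s) are measured from the trimmed-trial start.

Significance uses a label-permutation test: realness labels are shuffled
among included trials within each subject x session (preserving the fold
structure; the shuffling scope is not otherwise specified), the full
fit + cross-validation is rerun, and p = #(permuted accuracy >
observed)/n_perm as printed, with an add-one variant by flag.  The
printed estimator is anti-conservative in the presence of ties (it can
return 0); the calibration test uses two subjects so the fold-averaged
accuracy takes a finer grid of values and ties are rare.

## Mixed-model comparison

Response amplitudes (5 Hz FFT amplitude, SSD component amplitude, or
N170 magnitude) are modeled as

    amplitude ~ 1 + realness + (1 | subject)
    amplitude ~ 1 + realness + I(realness^2) + (1 | subject)

with realness as a numeric 1..6 predictor and a subject random intercept
only.  Both models are fit by full maximum likelihood — REML likelihoods
are not comparable across different fixed effects — and compared by a
likelihood-ratio test (chi-square, 1 df) and AIC/BIC with k = fixed
effects + random-intercept variance + residual variance and n = number of
observations, so the information-criterion identities are exact.
Observations are session-averaged within subject x condition by default
(a trial-level option exists; the original observation level is not
stated).  Confound-adjusted variants add the covariate (eye size) to both
models.  The L-BFGS optimizer occasionally reports a spurious infinite
likelihood when the random-intercept variance hits the zero boundary; the
fit falls back to BFGS and then Powell and keeps the first finite
maximum.  A constant response is reported as a degenerate comparison with
chi-square 0 rather than an error.

Condition means are accompanied by 95% within-subject confidence
intervals: subject-mean centering with grand-mean restoration, condition
SEM scaled by the Morey factor sqrt(M/(M-1)) for M conditions, and a t
quantile with (n_subjects - 1) df.

The N170 amplitude is the signed mean of the averaged 200 ms response in
[150, 190) ms (window edges are sample-inclusive at the left, exclusive
at the right, a stated convention that makes tests exact); magnitudes are
the inverted values.  Latency is the waveform minimum within
[130, 200] ms.  The two-way repeated-measures latency ANOVA uses emotion
as the second factor (the only other within-trial factor crossing
realness); all 15 level pairs are compared post hoc with paired t-tests
and Bonferroni correction (p x 15, capped at 1).

Partial correlations are computed by residualizing both variables on the
covariate and correlating the residuals (t-based p, n-3 df); a covariate
identical to one of the variables returns 0 by convention rather than an
error.

## Numerical conventions and edge cases

- Seeds: every stochastic function takes or carries an explicit seed; the
  pipeline expands its global seed to per-stage seeds by a fixed counter
  scheme (`stage_seed = seed * 100 + stage_index`).
- Generalized eigenproblems are solved with `scipy.linalg.eigh`;
  condition numbers above 1e12 raise with a pointer to the
  regularization flag.
- The BrainVision writer stores multiplexed IEEE float 32 in microvolts;
  reading checks sidecar presence and that the binary size is a whole
  number of channel frames before parsing.
- Degenerate inputs (constant responses, zero-amplitude kernels, empty
  groups, unbalanced designs) either return defined values (t = 0,
  p = 1; chi-square 0) or raise with messages naming the violated
  requirement.

## Problem sizes

Defaults in the test-suite simulation studies: 1-2 subjects, 3-8
sessions, the nine-channel cluster or a four-channel posterior subset,
2 s windows at 250 Hz.  The acceptance script simulates 6 subjects x 8
sessions for decoding, 10 subjects at the amplitude level for the
mixed-model operating characteristics, 100 label-permuted datasets for
the chance level, and 200 permutations for the significance example.
These sizes are the package's own scaled-down choices; the emulated
study's full size (10 subjects x 8 sessions of 64-channel, 1 kHz EEG) is
supported by the same code paths.

## Known limitations

- The SSVEP/N170 class structure is a two-parameter code (trough latency
  and component ratio); decoding accuracies on synthetic data are
  comparable to the reported ones by construction of the noise scale,
  not evidence about real EEG.
- SSD component selection across subjects assumes comparable channel
  sets and at least one retained component per subject.
- The permutation test's printed estimator can return p = 0; use the
  add-one flag for publication-grade inference.
- No artifact rejection, re-referencing, or ICA is implemented; the
  pipeline assumes clean input.
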