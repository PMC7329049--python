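# Methods

This note documents the models and procedures implemented in `vocaffect`,
the design choices made where the design was genuinely open, and what the
synthetic data can and cannot establish.

## The analysis chain

The package reproduces a playback-experiment analysis in five stages:
corpus construction, acoustic measurement, feature screening, perceptual
statistics, and acoustic prediction models. All randomness flows from one
master seed; each stage draws a sub-seed derived from the seed and the
stage name (CRC32 of the name), so adding a stage never perturbs another
stage's stream, and re-running any stage against cached upstream tables is
byte-reproducible.

## Synthetic corpus and listener models

**What the generator emulates.** The corpus preset fixes the study design:
155 stimuli from 66 callers across 10 behavioural contexts with per-context
counts (19, 22, 11, 10, 12, 15, 16, 21, 16, 13), arousal marginals
62/71/22 (high/medium/low; the only low-arousal context is *eating low
value food*), and valence classes positive/negative/none (69/75/11 — the
per-context counts are the authoritative design quantity; marginal totals
are derived). Caller pools are disjoint across contexts (8, 9, 5, 4, 5, 6,
7, 9, 7, 6; each within 4–21 and at most the context's stimulus count),
and every caller contributes at least one stimulus.

Each stimulus is a call bout: N amplitude-enveloped calls separated by
silences. A call is a 12-harmonic stack on a sinusoidally modulated f₀
contour with a spectral tilt (dB/octave), mixed with Gaussian noise so the
noise carries a specified fraction of the power, with 10 ms Hann on/off
ramps. Context presets place calls on the acoustic axes the analysis
measures — grunts low-pitched, short and noisy; screams high-pitched, long
and tonal-to-harsh — so that negative/high-arousal contexts are
acoustically more extreme. These presets are design choices of the
simulator, not claims about chimpanzee vocal production.

Within the context means, each stimulus draws independent scatter in four
places: pitch-modulation depth (drawn in absolute Hz over a wide log-range,
3–160 Hz, capped at 30% of f₀), per-call noise fraction (a bout-level
shift plus within-bout spread, with occasional near-tonal calls inside
noisy bouts), per-call pitch (±4%), and spectral tilt (s.d. 2.5 dB/oct).
This heterogeneity mirrors real corpora, where bouts mix call qualities,
and it is what keeps the six modelling features from being deterministic
functions of one another: without it, f₀ s.d. is proportional to f₀ mean
and HNR max to HNR mean, and the variance inflation factors explode; with
it, all six features keep VIF < 5, the regime the analysis assumes.

Bouts are written as 16-bit mono PCM WAV at 44.1 kHz (configurable),
peak-normalized to 0.9 full scale — the normalization target is a
convention; only relative levels matter downstream.

**Listener models.** The experiments measured behaviour without specifying
a generative model, so the simulators use the simplest families that span
the observed phenomena, with all parameters exposed as configuration:

- *10-way choice*: the truth-aligned option carries a per-context log-odds
  weight against nine zero-logit alternatives; a lapse parameter mixes in
  uniform guessing. Lapse 1 is exact uniform responding; infinite weight
  is a perfect categorizer.
- *Ratings*: a latent Gaussian centred on an arousal-class gain (±1.1 for
  high/low) or a valence-class gain (±0.7) plus a constant valence bias
  (−0.35 rating points by default, encoding the tendency to judge calls as
  negative), discretized to 1–5.
- *Yes/no matching*: response "yes" follows a logistic in match status
  with a per-context sensitivity (log-odds) and a response bias; the
  implied ground-truth sensitivity is d′ = z(p_hit) − z(p_fa), available
  in closed form for tests.

The default preset gives negative contexts higher weights and sensitivities
than positive ones (1.2/1.1 vs 0.7/0.55), producing the qualitative
pattern of better accuracy for negative vocalizations; the null preset
(lapse 1, no bias) is the calibration condition.

## Acoustic measurement

Segmentation thresholds 10 ms RMS frames at 25 dB below the loudest frame,
merges gaps shorter than 50 ms and drops segments shorter than 30 ms.
Pitch analysis uses 40 ms frames at a 10 ms hop, normalized
autocorrelation computed by FFT with exact per-lag energy normalization,
search range 70–1800 Hz (the chimpanzee call range from low grunts to
screams). A frame is voiced iff its autocorrelation peak reaches 0.45, the
implied f₀ is in range, and the frame centre lies inside a call segment.

Two selection rules stabilize the tracker. A local maximum only counts as
a period candidate once the autocorrelation has dipped below half the
peak's height at shorter lags — for any band-limited signal r(τ) stays
high near τ=0, and noise decorates that plateau with spurious micro-peaks.
Among candidates, the strongest peak sets the period hypothesis, and a
nearly-as-strong candidate (≥0.9 of the best) at an integer fraction of
its lag takes precedence, suppressing octave-down errors without letting
noise-displaced neighbours of the true peak bias the estimate. A 5-frame
running median then removes isolated octave errors while leaving glides
intact. Frame HNR is 10·log₁₀(r/(1−r)) at the chosen lag, capped at 40 dB
so noiseless synthetic input stays finite. Jitter and shimmer come from
parabolic-refined waveform peaks at the tracked period within voiced
spans (local measures, in percent, needing ≥3 consecutive periods). SCoG
is the power-weighted mean frequency of the whole-bout spectrum; the peak
time is the centre of the strongest spectrogram frame, and its relative
position is scaled to the span from first segment start to last segment
end.

The feature vector has 15 parameters: n_calls, duration (summed call
durations; models use one value per stimulus), peak time and relative
position, % voiced, jitter, shimmer, SCoG, f₀ min/max/mean/s.d., and HNR
mean/max/s.d. Stimuli with undefined voiced features (e.g. fully noisy
bouts) carry NaNs and are dropped listwise, with counts logged, from any
model that uses those features.

Measured accuracy of the extractor on its own generator: f₀ recovery
within 2% for tones and bouts at 80–1500 Hz up to noise fraction 0.5;
call counts exact for constructed layouts; HNR 0 ± 1.5 dB at equal
harmonic/noise power; all features invariant to overall gain (relative
measures throughout) and to leading silence (except the peak time, which
shifts by exactly the pad).

## Perceptual statistics

Unbiased hit rates Hu_i = n_ii²/(row_i·col_i) correct forced-choice
accuracy for response bias; the matching individual chance level (Wagner)
is row_i·col_i/N². Both are arcsin√p transformed — the standard variance
stabilizer, and for Hu also a first-moment correction: conditional on the
response marginal, E[√Hu] equals √chance exactly under uniform guessing.
Per-category paired Wilcoxon signed-rank tests compare the transformed
scores (zeros dropped; exact null for n ≤ 25 when tie-free, else normal
approximation with continuity correction; all-zero differences give p = 1
by convention), Bonferroni-corrected by the number of categories.

Ratings are recoded to −2…+2 and scored per response: high arousal is
correct iff the value is positive, low iff negative, medium iff zero;
positive/negative valence analogously, with no-valence stimuli excluded.
For rating scales, Hu needs a stimulus-by-response table, so responses are
classed by rating sign (valence gains a third "neutral" response column);
this construction is ours — the original procedure is not fully specified.
A per-response reading of the correctness criteria is used throughout
(the group-level "significantly different from zero" phrasing cannot
produce per-participant Hu scores). The negativity-bias check tests
per-participant mean valence ratings against zero; the fatigue check
compares accuracy in the first and last 30 trials per judgment type.

For the matching task, d′ = z(hit) − z(false alarm) with rates 0 and 1
replaced by 0.5/n and (n−0.5)/n using the participant's own trial counts,
per-context one-sample t-tests against zero at α = 0.005, and a one-way
ANOVA on d′ for negative vs positive contexts. Outlier screening excludes
participants at or below mean − 3 s.d. of categorization accuracy,
computed once on the full sample.

Power analysis searches the smallest n whose one-sample t-test power —
noncentrality d·√n, critical value at α with n−1 df, via the noncentral t
distribution — reaches the target; one-tailed by default (the only
configuration consistent with both published sample sizes, 296 and 156).

**Calibration caveat.** The test suite includes a 200-replicate null
calibration at the study's design sizes. The d′ procedure is exactly
calibrated (rejection rate 0.005 at nominal 0.005). The signed-rank test
on arcsine-Hu versus arcsine-chance is anticonservative at 155 trials per
participant (≈0.03 at nominal 0.005): with ~15 trials per category the
per-participant Hu−chance differences are right-skewed, violating the
symmetry assumption; the effect disappears at ten times the trial count.
This is a finite-sample property of the published procedure itself, which
users applying it to comparably sized designs should know.

## Prediction models

Classifiers are maximum-likelihood multinomial (context 10-class, arousal
3-class) or binomial (valence) logits on the six z-scored features, so
coefficients are log-odds per SD. Per-predictor likelihood-ratio χ² tests
refit without the predictor (df = classes − 1); the overall test compares
the intercept-only model. Agreement is reported in-sample, as in the
original analysis; a k-fold cross-validated agreement is available behind
a flag and is the quantity that sits at 1/k under label permutation
(in-sample agreement is upward-biased by the 63 free context-model
parameters at n = 155). Quasi-separated fits fall back to a
ridge-stabilized likelihood with a warning — on well-separated synthetic
contexts this is the common path.

The accuracy GLMMs are binomial logistic models with crossed random
intercepts for participant and chimpanzee identity, estimated by Laplace
maximum likelihood: an inner Newton solve finds the joint conditional
mode of the random effects (spherical parameterization, so the objective
stays smooth as a variance approaches zero), and the participant block of
the penalized Hessian is diagonal, reducing each solve to the caller-sized
Schur complement; the outer optimizer is L-BFGS-B over fixed effects and
log-standard-deviations, with a Nelder-Mead retry on non-convergence.
Fixed-effect standard errors are Wald, conditional on the variance
estimates. On shared data the fitter matches lme4's `glmer` (also Laplace)
to ~1e-3 in coefficients, variances and AIC, and with variances fixed at
zero it reproduces a plain logit to 1e-4. AIC = −2ℓ + 2k counts both
variance parameters; AICc is used for model selection over the full
six-feature model and its six leave-one-feature-out reductions, choosing
the minimum with exact ties kept at the larger model, and flagging ΔAIC >
2 as a meaningful distinction.

## Problem sizes and defaults

Default design sizes are the study's: 310 participants (experiment 1) and
312 per context, 3120 total (experiment 2), with α = 0.005 for the context
and d′ tests and 0.05 elsewhere. The test suite exercises the full corpus
but scales listener counts to keep each check sharp and the whole suite
fast; the calibration and recovery suites state their replicate counts
(200 and 20) in the tests themselves.

## Limitations

- Synthetic calls are harmonic-stack caricatures; passing tests establish
  that the *procedures* are correct and calibrated on data with known
  structure, not that real chimpanzee vocalizations behave this way, and
  the published empirical values (test statistics, per-context d′,
  agreement percentages, variance shares) are not reproducible without
  the original recordings.
- The pitch tracker targets the stated 70–1800 Hz range with moderate
  noise; it is not a noise-robust tracker and is not bit-compatible with
  PRAAT's algorithm.
- Jitter/shimmer on strictly alternating period sequences measure the
  true period of the signal (the alternation's cycle), so controlled
  perturbation measurements should pass the nominal pulse rate explicitly.
- GLMM inference is conditional on the estimated variances, as in lme4;
  no profile or bootstrap intervals for variance components.
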