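# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `cardiogate`. It states no empirical result that the
test-suite or `scripts/acceptance.py` does not itself compute.

## Cardiac-gated scheduling model

The scheduler emulates online ECG-locked cue delivery. R-peaks arrive as a
strictly increasing event stream (detected from a sampled trace by upward
threshold crossing with a local-maximum rule and a 250 ms refractory period,
or supplied directly). Before each trial the stream is monitored from the end
of the inter-trial fixation (default 1000 ms); the first R-peak at or after
that point is the anchor R\*.

* **Systole** trials fire at R\* + 290 ms, near the peak of arterial
  baroreceptor firing. A forward offset is realizable reactively, so no
  prediction is involved and the scheduling error is identically zero
  whenever detection is exact.
* **Diastole** trials fire 10 ms before the *predicted* next R, where the
  prediction is R\* plus the median of the three preceding inter-beat
  intervals. A backward offset is only realizable through prediction; the
  per-trial error is exactly `median(prev 3 IBIs) − next IBI`, a quantity the
  simulator verifies trial by trial.

**Evaluation reference.** Achieved onsets are expressed relative to a
reference R-wave: the anchor for systole, the *targeted* R (the anchor's
successor) for diastole. An alternative reading — "the first R after the
onset" — was rejected: a cue landing 1 ms past its targeted R would then be
scored against the following beat and charged an error of a whole IBI, which
contradicts both the error identity above and the achievable precision of the
method. When anchors are unknown (external onset lists), the diastole
reference is the R nearest to `onset + 10 ms`. Offsets are histogrammed in
50 ms bins over [−400, +600) ms (edges at integer multiples of the bin width;
out-of-range values land in the end bins; bin edges are not prescribed by the
task, so this is a package convention), and the headline precision statistic
is the fraction of trials with |error| ≤ 200 ms.

At the default conditions (75 bpm, RMSSD 54 ms) the diastole error is the
difference between a median of three jittered IBIs and an independent IBI —
standard deviation ≈ 46 ms — so essentially all trials fall within the
200 ms tolerance; the fraction degrades monotonically as RR variability
grows (property-tested over a sweep).

## Synthetic cohort generator

The generator's defaults are the study conditions: 41 subjects; 400-trial
sessions of 200 Go / 66 NoGo / 134 Choose (Go and NoGo counts round, Choose
absorbs the remainder), half of each type per cardiac phase (odd counts give
a ±1 split, the side chosen by coin flip); 75 bpm with RMSSD 54 ms;
six heartbeat-counting trials of 25–50 s; ~1% Go omissions.

* **RR streams.** IBIs are `60000/bpm + N(0, RMSSD/√2)`, truncated to
  [300, 2000] ms. Independent Gaussian jitter makes the expected RMSSD equal
  the target exactly (successive differences of iid noise have twice the
  variance); autoregressive structure, respiratory arrhythmia, and drift are
  omitted because RMSSD is the only variability statistic consumed
  downstream. Per-subject heart rate is N(75, 10) bpm and RMSSD is lognormal
  with mean 54 and SD 29 ms, clipped to physiological ranges.
* **Latents.** Each subject carries a standardized metacognition latent
  (drives the accuracy–confidence coupling, clipped to [−0.9, 0.98]), a
  tracking-ability ratio (N(0.72, 0.16), with a 1-in-41 mixture component
  near 2.4 that produces substantial over-estimators), and a standardized
  impulsivity latent (drives NoGo commission probability and loads 0.6 on
  every questionnaire subscale). This latent structure is a stand-in for
  unobserved individual differences, not a mechanistic claim.
* **Tracking trials.** Real counts are beats of a generated RR stream in
  consecutive windows; reported counts are
  `round(ability · real + N(0, 2))`, floored at zero; confidence couples to
  standardized per-trial alternative accuracy with the subject's coupling
  strength, around a per-subject level N(4.7, 1.8), mapped into [0, 10].
* **Behaviour.** RTs are lognormal (right-skewed, as empirical RT
  distributions are), with subject-level Go means around 482 ms and
  Choose-Go means around 520 ms; a press slower than the 1000 ms cue
  duration is recorded as an omission, since the cue has already terminated.
* **Effect calibration.** The two injectable cohort effects (awareness ↔
  %Choose-Go, default −0.44; insight ↔ Choose-Go RT, default −0.40) are
  calibrated against the *realized* awareness/insight scores of the
  simulated subjects, cohort-z-scored, rather than against the raw latent.
  The six-trial awareness score is a noisy estimate of the coupling, and the
  attenuation it induces depends on the whole cohort's coupling
  distribution; driving behaviour from the realized score removes that
  unknown, leaving only binomial attenuation of %Choose-Go, which is
  corrected analytically: the propensity weight is
  `target / λ` with `λ = σ_p / √(σ_p² + p̄(1−p̄)/n_choose)` (σ_p = 0.11,
  p̄ = 0.605). Choose-Go RT attenuation is negligible (~80 presses per
  subject) and uses a fixed 0.99 correction.
* **Determinism.** A master seed spawns per-subject substreams through
  `SeedSequence(seed, spawn_key=(subject_index,))`; cohorts are reproducible
  file-for-file (checksums in the manifest) and insensitive to generation
  order.

What the generator does **not** emulate: real heartbeat-counting response
styles (time-estimation strategies, digit preferences), questionnaire item
structure, phase-dependent behaviour (none is injected by default), or any
coupling between heart-rate variability and behaviour. Passing
parameter-recovery tests therefore shows that the pipeline's estimators are
consistent under the generative model — not that the published effects hold
in real data.

## Interoception scoring

Both accuracy formulas use the absolute difference |real − reported| in the
numerator. The signed variant would make scores *larger* when participants
over-report, and is incompatible with the over-estimator heuristic and with
the observed ranges of the indices (standard accuracy bounded above by 1,
alternative accuracy in [−1, 1]); the absolute-difference reading follows
the established scoring tradition for this task.

* Standard accuracy: mean of `1 − |real − reported| / real`; reported only
  for subjects who do not report more than twice the real total across the
  six trials (totals, not per-trial, so one miscounted trial does not
  exclude a subject).
* Alternative accuracy: mean of `1 − |real − reported| / ((real+reported)/2)`
  (the symmetric-mean denominator).
* Insight: mean per-trial `standard accuracy − confidence/10`, **signed** —
  0 is optimal, negative marks confident-but-inaccurate subjects. The
  per-trial difference is averaged, not the difference of the two means.
* Awareness: within-subject Pearson r between per-trial alternative accuracy
  and confidence; undefined (missing, not zero) when either sequence has no
  variance, and propagated as missing into cohort statistics.
* TIPE: cohort-z-scored sensibility minus cohort-z-scored alternative
  accuracy, with the n−1 sample SD; the cohort mean is 0 by construction.

## Statistics

Frequentist machinery delegates to scipy/statsmodels: paired t with the 95%
CI of the mean difference; Wilcoxon signed rank reporting W⁺ (sum of
positive ranks, ties mid-ranked, zeros dropped; exact p for n ≤ 25 without
ties, else a tie-corrected normal approximation, with the z value recorded
alongside); Pearson correlations with pairwise deletion and per-cell
effective n; simultaneous-entry OLS with the omnibus F on (k, n−k−1)
degrees of freedom. No multiple-comparison correction is applied anywhere —
a fidelity choice, not an endorsement.

The default-prior Bayes factors are authored here and are the package's
reproducible numbers:

* **t-test**: `BF₁₀ = ∫ T_{n−1}(t | δ√n) Cauchy(δ; 0, 0.707) dδ /
  T_{n−1}(t | 0)`, adaptive quadrature over the real line.
* **Correlation**: stretched-beta prior on ρ with width κ (κ = 1 is the
  uniform special case, the default); the marginal likelihood integrates the
  exact sampling density of the observed r (hypergeometric form) over the
  prior. The quadrature agrees with the analytic closed-form solution of
  this test to 10⁻⁸ (cross-checked in the suite).
* **Regression**: Zellner–Siow mixture-of-g prior with scale √2/4 — the
  "medium" continuous-covariate default of the reference Bayesian-regression
  implementations; R² is recovered from F and the Bayes factor is a 1-D
  integral over g, mapped to (0, 1) via g = u/(1−u).

All three use `scipy.integrate.quad` at relative tolerance 10⁻⁹; an
independent fixed-grid trapezoid oracle (10⁵ points, explicit changes of
variables) checks each family to 10⁻⁴ relative error in the tests, and
pingouin's analytic values provide a second, fully independent cross-check.
Reproduction of printed three-decimal Bayes factors from printed summary
statistics is limited by the three-decimal rounding of the inputs
themselves, which perturbs the Bayes factor by up to about 1%; tests assert
at that precision. Summary-statistic entry points `(t, n)`, `(r, n)`,
`(F, n, k)` are first-class and bit-identical to the raw-column paths.

Degenerate inputs: zero-variance differences, |r| = 1 (reported as infinite
evidence), rank-deficient designs, and insufficient history for the IBI
predictor all raise typed errors rather than returning silent values.

## Exclusion rule

Subjects whose pooled NoGo commission-error rate exceeds the cohort mean
plus two sample SDs are excluded before any analysis. The rule is single
pass (no re-computation after removal) and one-sided; with fewer than three
subjects it is not applied.

## Problem sizes

The test-suite runs cohorts of 5–8 subjects for pipeline mechanics, two
200-subject cohorts for effect/null recovery, 10⁴ vectorized null
simulations for type-I calibration, and 400 Bayes factors for the H₀
sanity property. `scripts/acceptance.py` averages the diastole precision
over 20 independent 400-trial sessions. These sizes were chosen to give
stable statistics at interactive runtimes.

## Known limitations

* The latent model links interoception and behaviour through two pairwise
  channels only; it cannot reproduce an arbitrary joint correlation matrix.
* The artifact screen is a range check on IBIs, a crude surrogate for
  visual inspection of a raw trace.
* The Bayesian counterpart of the Wilcoxon test is deliberately absent: the
  rank-based sampling method behind it is not identifiable from summary
  descriptions, and guessing it would produce unverifiable numbers.
* The generator's questionnaire model preserves marginal ranges and a
  single shared factor, not the full inter-scale correlation structure.
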