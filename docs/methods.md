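# Methods

`seegspeed` implements a trial-by-trial decoder of movement speed from
intracranial (SEEG) local field potentials, exercised end to end on a
synthetic session generator because no patient recordings are distributed
with it.  This note documents the model, the numerical conventions, the
generator's design, and what the package's tests do and do not establish.

## Decoding model

For subject *n*, the normalized speed on trial *t* is modeled as Gaussian
with mean linear in a feature vector of band-averaged spectral power:

E[yₙ(t) | xₙ(t)] = β₀ + Σⱼ βⱼ·xₙⱼ(t)

where yₙ(t) is the z-score of the natural log of the trial's speed ratio
(trial speed ÷ calibration speed, clipped to [0, 1]) over all completed,
unperturbed trials of the session, and each feature xₙⱼ is the mean
z-scored log power of one electrode contact over one frequency band during
the movement window (MoveOnset → HitTarget).

Feature selection is by LASSO in Lagrangian form,
(1/2N)·Σ(y − β₀ − Xβ)² + λ·‖β‖₁, with predictors standardised to unit
sample standard deviation, the response centred, and the intercept
unpenalised; coefficients are reported on the original scale.  λ is chosen
by 10-fold cross-validation on the training 80% of trials over a grid of
100 geometrically spaced values from λ_max (the smallest λ whose solution
is all-zero) down to 10⁻⁴·λ_max; λ̂ minimises the mean validation MSE,
with ties resolved toward the largest (sparsest) λ.  The final model is an
unpenalised least-squares refit on the features with nonzero coefficients
at λ̂ (the shrunken coefficients are persisted alongside for audit; a flag
on the model switches prediction to them).  Performance is reported as
Pearson R and MSE on the held-out 20%, plus a categorical accuracy: each
prediction is mapped back to the ratio scale and classified against the
trial's instructed-speed window — 66.7 ± 13.3% of calibration for fast
trials, 33.3 ± 13.3% for slow, endpoints inclusive (the convention matters
only on a measure-zero set) — and compared with the actual outcome.

Stability of the selection is assessed by repeating the cross-validation
100 times (25 per session in the 20-session benchmarks) with re-randomised
fold partitions of the *fixed* training set, keeping the test set fixed.
A feature's selection fraction is the number of fold fits giving it a
nonzero coefficient at that iteration's λ̂, divided by the number of fold
fits in which it was a candidate (folds × iterations).  We read "repeated
for different splits of the training set" as re-partitioning the training
set into folds; the alternative reading (fresh 80/20 splits) would
contradict the fixed test set and is rejected.

## Spectral preprocessing

1. **Notch**: second-order biquad with unit-circle zeros at 60 Hz; the pole
   radius is solved numerically (Brent) so the −1 dB points sit at
   60 ± 1.5 Hz; gain normalised to unit peak passband response; applied
   forward-backward (zero phase).
2. **CWT**: complex Morlet, ω₀ = 6, on a log grid of 12 voices/octave from
   1 to 200 Hz (92 frequencies).  Scale↔frequency uses the
   admissibility-corrected (Torrence–Compo) map
   f = (ω₀ + √(2+ω₀²))/(4πs), about 1.4% off the naive ω₀/(2πs) at ω₀ = 6.
   The analytic filter is applied in the FFT domain with support truncated
   where the Gaussian response falls below e^(−21) of peak.
3. **Binning**: mean power over trailing 100 ms windows every 50 ms (50%
   overlap); a bin is labelled by the time of its last sample, and bins are
   emitted only once a full window exists.
4. **Normalization**: z-score of the natural-log power per frequency over
   all session bins, using the population standard deviation (N).  The
   behavioural speed normalization instead uses the sample standard
   deviation (N−1); both conventions are fixed here and covered by tests.

Two CWT routes exist.  `cwt_power` is the full-rate reference (one value
per sample per frequency).  The pipeline uses `binned_cwt_power`: because
the truncated analytic filter makes each frequency's transform — hence its
power envelope — strictly band-limited, the transform can be evaluated on a
decimated grid (stride a divisor of the bin step, sample rate at least 2.5×
the envelope bandwidth) and the exact full-rate window mean applied in the
decimated frequency domain via the window's Dirichlet response.  The two
routes agree to ~1e−4 relative (the fast path uses single-precision
spectral arithmetic) and the reference route is oracle-tested against
direct time-domain convolution with sampled Morlet kernels.

Edge handling: no cone-of-influence masking.  Sessions are long relative
to the wavelet support, the generator pads 3 s at both ends, and the
frequencies below 4 Hz — where support is longest — are computed but not
used by any band feature.

Bands are half-open, [4,8) theta, [8,15) alpha, [15,30) beta, [30,60) low
gamma, [60,100) high gamma, [100,200) hyper gamma, so each shared printed
edge belongs to the upper band and the bands tile [4, 200) exactly.

## Synthetic session generator

The generator emulates one recording session of the instructed-speed
reaching task: 2 kHz multichannel signal, channel metadata (region label
from a small fixed vocabulary, hemisphere, artifact flag), and a trial
table with instruction, perturbation flag (20% of trials), completion flag
(95%), calibration speed, target distance and the MoveOnset/HitTarget
epochs.  Speed ratios are drawn log-normal (log-mean −0.7, log-sd 0.5) and
clipped at 1; movement time follows from the drawn speed (clipped to
0.4–2.5 s); the instruction is "fast" when the ratio is at or above the
distribution median.  Inter-trial gaps are compressed to 0.9–1.3 s — the
real task spends several seconds per trial on instruction, fixation and
feedback epochs, which carry no modelled signal and would only inflate
compute.

**Signal model.**  Each of the channels × 6 bands pairs carries an
independent Gaussian carrier, spectrally flat over the central portion of
its band (inset 15% of the band's log-width per side, so wavelets centred
in one band respond only weakly to neighbouring bands' carriers), at
carrier-to-noise power ratio 400 over the broadband white noise floor.
The carrier's log amplitude follows a piecewise envelope z(t): i.i.d.
normal values over 200 ms rest segments between movements, and one value
per trial during the movement window (extended 100 ms before MoveOnset so
every spectrogram bin labelled inside the window is fully covered; a 20 ms
smoothing removes step discontinuities).  Instantaneous carrier power is
∝ exp(γ·z) with modulation depth γ = 1.2 ln-power units.

For an *informative* pair the movement value is y_t + jitter, where y_t is
the trial's normalized speed and the jitter (sd 1.85) is the trial-level
power variability not explained by speed.  Non-informative pairs have no
trial-locked envelope at all: their segment process runs through the whole
session at matching variance.  This is deliberate: log power has a small
convexity bias near amplitude steps (a spectrogram bin close to a step
mixes two power levels, and the log of the mixture exceeds the mixture of
the logs), so a trial-locked envelope makes that bias proportional to the
density of window boundaries — which is higher for short trials, and
movement duration is deterministically tied to speed.  Locking every
pair's envelope to the trials would therefore give all features, including
null ones, a weak duration-mediated correlation with speed.  With the
continuous envelope the step density is uniform in time and null features
are genuinely uninformative, which the null benchmark verifies against
the behaviour of ideal Gaussian features.  Because the spectrogram z-scores
log power per frequency over the session, the slope of the z-power feature
against y equals γ divided by the session standard deviation of γ·z; the
generator therefore solves the rest-segment variance so that the session
variance of z equals 1/effect², realizing a configured effect size in
z-power units per unit normalized speed.  Configurations whose effect size
admits no nonnegative rest variance (too large an effect for the session's
movement fraction and jitter) are rejected.

Two second-order corrections are applied or documented:

* **Band calibration.**  Spectral-estimation noise and residual cross-band
  leakage inflate the z-score denominator and attenuate the realized slope
  by a band-dependent factor (0.70–0.93 under default parameters).  These
  factors were estimated by regressing realized slopes over repeated
  200-trial sessions and are compiled into the generator, which divides
  the design effect by them.  The compensation is verified by the
  effect-recovery test (realized slope within two standard errors of the
  configured effect at 200 trials) and holds near the default envelope
  parameters; far from them the contract degrades gracefully.
* The clipping of speed ratios at 1 and of movement durations at their
  range bounds makes the realized speed distribution a censored
  log-normal, exactly as the behavioural pipeline assumes.

**What the generator does not emulate**: 1/f spectral shape, line-noise
harmonics beyond the injected 60 Hz-free noise, autocorrelated artifacts,
perturbation dynamics (perturbed trials differ only by their exclusion
flag), volume conduction between channels, and any anatomical realism in
the region labels.  Passing benchmarks therefore certify the statistical
machinery — spectral estimation, selection, stability, evaluation — under
the assumed signal model, not decoding performance on real LFP.

## Standard benchmarks

* **Recovery** (20 sessions): 40 channels × 6 bands = 240 candidate
  features, 100 task trials (≈76 modeled after removing perturbed and
  incomplete trials), five informative pairs on distinct channels spanning
  theta–high gamma, effect size 0.45 each with jitter chosen so that OLS
  on the five ground-truth columns gives in-sample R² ≈ 0.6.  Reported:
  median test R, the fraction of sessions recovering ≥4 of 5 pairs in the
  final selection, the median number of true pairs within the top-8
  selection-fraction ranks of a 25-iteration stability analysis, and the
  median ground-truth R² (the generator's own check).
* **Null** (20 sessions): identical generator with no informative pairs.
  Reported: median |test R| (0 when nothing is selected and R is
  undefined), median selected-feature count, and decoded accuracy relative
  to the intercept-only floor (the floor is the base rate of the majority
  predicted outcome, not 0.5, because an intercept-only decoder predicts
  the same outcome for every trial of a given instruction).

Runtime: each session costs ~20 s on one CPU (generation ~5 s, CWT of 40
channels ~10 s, 26 cross-validation runs ~5 s), so each benchmark sweep
stays within a quarter hour.  The stability loop uses 25 iterations per
benchmark session (100 is the single-session default).

## Numerical choices and degenerate inputs

* LASSO solves use scikit-learn's coordinate descent: solver tolerance
  1e−4 for the many cross-validation path fits, 1e−12 for certified single
  fits, which brings KKT residuals below 1e−8 on standardised data.
  λ = 0 falls back to a least-squares solve.
* Zero-variance feature columns are dropped from LASSO fits with a warning
  (coefficient 0); rank-deficient final refits drop dependent columns via
  pivoted QR with a warning.
* Duplicated columns: coordinate descent assigns the shared weight to one
  of the duplicates; the objective is invariant to the split and the tie
  policy is covered by a test.
* Cross-validation ties at the minimum mean MSE resolve to the largest λ.
  Folds are random, not stratified by instruction, and seeded.
* Intercept-only models have undefined Pearson R; it is reported as NaN
  with a warning and mapped to |R| = 0 in the null benchmark summary.
* Speed ratios of exactly 0 cannot be log-transformed; such trials are
  dropped with a warning (completed trials imply positive speed).
* All randomness flows from explicit seeds (`numpy` Generator /
  SeedSequence); every pipeline stage is bit-reproducible under a fixed
  master seed, and reports are written with round-trip float formatting.

## Known limitations

* The effect-size contract is calibrated at the default envelope
  parameters; strongly different γ, jitter, carrier SNR or movement
  fractions change the attenuation factors.
* The stability report counts features as (channel, band) pairs; region
  labels are metadata only, and the region-level roll-up of the original
  feature maps (atlas matching, MRI rendering) is replaced by plain-text
  band and hemisphere summaries.
* The held-out test set of a 100-trial session has ~15 trials, so
  per-session test R is noisy by construction; benchmark criteria use
  medians over 20 sessions.
* A "best model over iterations" summary (the highest R across the 100
  stability refits) is a post-hoc selection; per-iteration metrics are
  exposed so such a summary can be formed, but no best-model value is
  endorsed as an unbiased estimate.
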