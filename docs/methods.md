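# Methods

This note records the models, parameter choices and numerical conventions
behind `primemeg`, and what the synthetic validation does and does not
establish.

## The synthetic study

`SimConfig` holds the design constants of the simulated experiment.  Timing
follows the modeled paradigm: prime→target SOA 0.2 s, tones 0.05 s and
1.15 s after the button press, 0.1 s tone duration, 600 Hz sampling.  Epochs
are prime-locked and span −0.5 s to `SOA + rt_max + tone2_delay + 0.3 s`
(with `rt_max = 1.2` s, the response deadline), so the second tone is always
inside the epoch and all datasets share one time axis.

**Reaction times** are shifted log-normal (location shift 0.15 s, trial SD
0.06 s), mean 0.357 s in the incompatible condition and +0.046 s on
compatible trials — the negative compatibility effect at study scale.
Target errors occur with probability 0.07 (compatible) vs 0.035
(incompatible); error or late trials carry no tone, no loudness judgment and
no epoch, mirroring the exclusion of incorrect/no-response trials from all
analyses.

**Loudness judgments** come from an equal-variance SDT observer.  With the
second tone physically softer the decision variable is N(+d′/2, 1),
otherwise N(−d′/2, 1); the observer answers "first louder" (= second softer)
when the variable exceeds the condition's criterion.  Defaults d′ = 2.25,
criterion 0.2 (compatible) vs 0.0 (incompatible).  Closed forms
P(first_louder | tone2 softer) = Φ(d′/2 − c) and
P(first_louder | tone2 louder) = Φ(−d′/2 − c) make the generator its own
oracle: the analysis-side estimators recover d′ and c without bias.  The
simulator fixes discriminability through d′ directly rather than through
sound-pressure levels, since the adaptive staircase that would set physical
levels is not part of the model.

**Prime recognition** (the awareness control task) is a separate
forced-choice simulation: 200 trials per subject, chance performance
(d′ = 0) except for deliberately "aware" subjects (default d′ = 0.8, for
whom the resampling test's detection power is ≈1 at 200 trials; at 100
trials it was only ≈0.85, which is why 200 is the default).

**Sensor array and forward model** are deliberately simple plumbing.
Sensors sit quasi-uniformly (Fibonacci lattice, ~2 mm jitter) on a spherical
cap of radius 110 mm covering the upper ~120°; sensors are neighbors when
closer than 1.4× the median nearest-neighbor distance (every sensor is
guaranteed one neighbor).  The lead field is the scalar kernel
`gain(s,q) = 1/(δ² + ‖p_s − p_q‖²)` with softening δ = 30 mm — smooth,
monotone in distance, full rank in practice, and orientation-free (dipole
orientation enters the pipeline only through the ROI sign-flip mechanism).
The source grid is a mirror-symmetric *cortical shell*: 20-mm grid points
kept 45–70 mm from a point just above the head origin, plus four labeled
sources (left/right auditory at (±55, −38, 11) mm and left/right hand knob
at (±33, −18, 60) mm).  The shell matters: with a solid-ball grid the group
localizer t/F statistic of a bilateral symmetric auditory response peaks at
deep midline sources, because their minimum-norm spatial filters match the
*summed* bilateral field better than either true source's own filter.  Real
forward models avoid this for the same reason this one now does — the
source space is a sheet with no deep midline dipoles.

**Source activity.**  Both auditory sources receive a biphasic M100-like
template (Gaussian peak at +100 ms minus a weaker Gaussian at +190 ms,
amplitude 10) at each tone onset.  Compatible trials additionally receive a
Hann-windowed transient (amplitude 6) in the *left* auditory source inside
`auditory_effect_window` = 387–477 ms after prime onset.  Motor activity is
a lateralization variable u(t) ∈ [−1, 1] (+1 = left hand prepared): a
prime-driven Hann bump in phase 1 (0.25–0.45 s), its reversal in phase 2
(0.45–0.60 s), and a smooth ramp that converges on the executed hand at the
press and decays 0.25 s later; the hand-knob source contralateral to the
prepared hand is active (±amplitude/2, default 6).  This reproduces the
qualitative two-phase pattern: compatible traces lateralize first toward,
then away from, then back to the executed response; incompatible traces
mirror the first two phases.

**Noise** is Gaussian, white in time, spatially correlated through the
symmetric square root of a Gaussian distance-decay covariance whose length
scale is set so nearest-neighbor sensors correlate at
`spatial_noise_correlation` (default 0.6); per-sensor SD is `noise_sd`.  An
optional 50-Hz line component (random per-trial phase, fixed per-sensor
coupling) exercises the notch filter; it is off by default, and the
pipeline applies the notch exactly when it is on.  Temporal whiteness is
accepted because cluster inference is permutation-based and needs no
temporal noise model.

**Effect scale.**  `noise_sd = 0.008` with effect amplitude 6 (≈60% of the
M100) puts the per-bin across-subject t of the ROI effect near 3.5 under
the default 15 subjects × 192 trials — a clearly significant cluster of the
kind the modeled design is built around, while single-trial data remain
noise-dominated.  Between-subject amplitude variability is not modeled;
subject-level variance comes from finite-trial sampling alone, so group t
statistics for the large behavioral effects (e.g. the RT contrast) are
higher than empirical data would give.  Calibration of the *null* tests is
unaffected.

## Analysis conventions

- **SDT scoring**: signal class = "second tone physically softer"; hit =
  response "first louder".  Criterion `c = −(z(H)+z(FA))/2` is then already
  positive for a bias to report the first tone softer; no extra sign flip is
  needed.  Rates are corrected with the 0.5 log-linear adjustment *only*
  when a cell would give a rate of 0 or 1, keeping interior estimates exactly
  at `k/n` (an unconditional adjustment would bias, e.g., H = 42/50 and
  FA = 8/50 from d′ = 1.989 down to 1.935).
- **Awareness test**: resampled responses are drawn independently of trial
  identity, so the null hit and false-alarm counts are binomial with the
  subject's marginal response probability; the implementation draws those
  binomials directly, which is equivalent to and much faster than per-trial
  resampling.  Ties count as exceedance, so a constant responder gets p = 1
  rather than p = 0.  Default 10⁵ resamples, reducible for tests.
- **Paired one-tailed t-tests** return t = ±∞ with p ∈ {0, 1} (plus a
  warning) on zero-variance differences, and t = 0, p = 0.5 when all
  differences vanish.
- **Artifact rejection** replaces an interactive visual step by a
  deterministic rule: per-trial summary = mean over sensors of per-sensor
  temporal variance; rejected if above 5× the median across trials.  The
  rule never sees condition labels.  The threshold is global rather than
  per sensor type — the synthetic array has a single sensor type.
- **Notch filter**: 4th-order Butterworth band-stop 48.5–51.5 Hz applied
  forward and backward (`filtfilt`, odd-reflection padding).  Synthetic
  epochs carry ≥0.5 s of margin in place of the long context segments a
  continuous recording would provide.
- **Planar gradient** (visualization only): per sensor, a least-squares
  linear fit of the topography over the sensor and its neighbors in local
  tangent-plane coordinates; output is the norm of the fitted slope.  It is
  a neighbor-based first-derivative estimate, not a reimplementation of any
  particular toolbox's interpolation; accuracy degrades at the cap rim where
  neighborhoods are one-sided.
- **Minimum-norm inverse**: `W = Lᵀ(LLᵀ + λI)⁻¹`, identity prior.  Default
  `λ = trace(LLᵀ)/(n_sensors · SNR²)` with SNR = 3 — a standard heuristic;
  λ = 0 is allowed only when the sensor Gram matrix is invertible, otherwise
  the error message advises regularizing.
- **Localizer and ROI**: the localizer is the tone-2-locked response 50–150
  ms after tone onset minus a 50-ms pre-tone baseline, summarized per
  subject and source, tested with a one-sample t (F = t²; zero-variance
  sources get t = 0 with a warning — F maps are kept finite rather than
  inventing significance).  Per hemisphere (masks x < 0 and x > 0), the ROI
  is the largest contiguous component — Euclidean adjacency at 1.5× the
  grid's median nearest-neighbor distance — of the ≤150 highest-F points
  within 25 mm of the hemisphere's F peak; ties with the 150th F value are
  all included so the rule is order-independent, and equal-size components
  are broken by peak membership, then summed F.  ROI time courses average
  members after multiplying each by the sign of its localizer t.
- **Cluster permutation test**: first-level threshold = two-tailed critical
  t at p < .05; spatiotemporal connectivity = sensor adjacency at the same
  bin or the same sensor at consecutive bins (no gap bridging).  The
  permutation scheme flips each subject's condition pair independently —
  the standard realization of within-subject reassignment; when
  2^n_subjects ≤ n_permutations the whole flip space is enumerated and p is
  exact.  Positive and negative clusters are tested against the max-mass
  distribution of their own sign and called significant at α/2 = .025, the
  two-tailed reading of a 5% family-wise level.  Ties count as exceedance
  and p is floored at 1/n_permutations.  All permutation t maps are computed
  with a single sign-matrix multiplication per block (squares are
  flip-invariant, so only means need recomputation).
- **Topography correlation**: per-subject Pearson r across sensors between
  the compatibility-effect topography (averaged over the significant
  cluster's time window; the full interest window if none) and the
  localizer topography, Fisher z-transformed, tested against zero
  two-tailed.  |r| = 1 is clamped to 1 − 10⁻¹² with a warning.
- **Lateralized time courses**: the subtraction order of the two hemispheric
  difference signals is fixed as left-hemisphere minus right-hemisphere, and
  the result is flipped, if necessary, so that its mean within ±50 ms of the
  mean response time is negative (executed-response lateralization negative).
  Traces are smoothed with a 20-ms square kernel; even sample counts use the
  classic centered form (half-weight end taps), which passes linear trends
  unchanged.  Landmarks are operationalizations, not measured quantities of
  any real dataset: phase-1 peak = first local extremum after target onset
  with the prime-consistent sign and at least 20% of the trace's absolute
  maximum (the floor suppresses noise wiggles); reversal = next zero
  crossing (linear interpolation); final convergence = last zero crossing
  before the mean response time.  Missing landmarks are reported as absent,
  and the latency-ordering verdict compares the ROI cluster onset *strictly*
  against the compatible trace's final convergence.
- **RT matching** operates on correct-response trials per subject: greedy
  extraction of globally minimal |ΔRT| pairs without replacement (ties
  broken lexicographically after sorting by RT then index), then the largest
  distinct-Δ cutoff whose retained pairs give an independent-samples t-test
  with p ≥ .05.  Cutoffs retaining fewer than two pairs are not valid
  candidates; if no cutoff works the error reports the best achievable p.
  Cutoffs are scanned per subject.  A degenerate post-test (zero variance in
  both groups, e.g. identical lists) is defined as p = 1.

## Pipeline

`run_pipeline` chains simulate → awareness exclusion → behavioral contrasts
→ per-subject epoch generation and preprocessing → sensor-level cluster test
→ source localizer and per-hemisphere ROIs → left-ROI cluster test →
topography correlation → lateralized motor time courses and latency ordering
→ RT-matched ROI re-analysis.  The interest window for all cluster tests is
300 ms after prime onset (100 ms after target) up to the mean tone-1 onset,
computed once from the behavioral table.  Every stochastic step is seeded
from the run config; two runs with the same config are identical, and every
output file carries the config hash.  Epoch data inside the pipeline are
float32 (the per-subject arrays are ~100 MB at study scale); all statistics
are computed in float64.

## What the validation shows — and what it does not

The test suite and `scripts/acceptance.py` establish that, on data with
exactly the generator's statistical structure: the cluster test's
family-wise false-positive rate is nominal (200 null datasets of 12 subjects,
30 sensors × 100 bins); permutation p-values match exhaustive enumeration;
the inverse equals the ridge solution to 10⁻⁸; SDT estimators recover the
criterion effect without a spurious d′ effect and their null tests are
calibrated; the awareness test is valid and conservative; RT matching
abolishes the 46-ms shift for every subject; and ≥90% of seeded replicates
recover a significant left-ROI cluster overlapping the injected window, a
positive topography correlation, and the auditory-before-final-motor-reversal
ordering.  Problem sizes in the suite (e.g. 200 null replicates, 20 recovery
replicates) are the package's chosen simulation scales.

The generator does *not* emulate: between-subject amplitude or latency
variability, temporally correlated (1/f) noise, eye/muscle artifacts beyond
a variance scaling, realistic dipolar field geometry, head-position
differences between subjects, or oscillatory activity.  Passing these tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not performance claims about real MEG recordings.
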