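# Methods

## The decoding problem

A user wearing a shoulder–elbow exoskeleton reaches from a central home
position toward one of eight targets equally spaced on a 25 cm-radius
circle (E, NE, N, NW, W, SW, S, SE, i.e. 45° apart). The goal is to infer
the intended direction from surface EMG of six upper-limb muscles (biceps
brachii, triceps brachii, anterior/medial/posterior deltoid, upper
trapezius) *before* the limb has moved appreciably, exploiting the
electromechanical delay between muscle excitation and movement, and to use
the estimate to assist the reach with an attractive force field.

## Signal chain

Raw EMG at 1 kHz passes a causal chain: 4th-order Butterworth band-pass
20–400 Hz, 2nd-order IIR notch at 50 Hz (Q = 30), full-wave rectification,
and a 2nd-order Butterworth low-pass at 4 Hz. The output (the *linear
envelope*) is clamped at zero (the final low-pass can overshoot slightly
negative) and decimated by plain sample-picking to the 100 Hz control
rate; the 4 Hz envelope bandwidth makes picking alias-free. All filters
are single-pass so offline results equal what a real-time loop would
compute. Orders are our choice — the chain's corner frequencies are the
specification, the orders are not; low orders keep group delay small.

**Onset detection.** The six envelopes are summed and compared against an
adaptive threshold `T(n) = mean + h·std` of the summed envelope in a 150 ms
window ending at sample `n−1`. The window trails and excludes the tested
sample so a rising signal cannot inflate its own threshold. The default
gain `h = 9` is fixed empirically by a false-positive suite: with a
15-sample window the normalized excursion behaves like a heavy-tailed
t(14) statistic, and `h = 9` is the smallest integer gain producing zero
false onsets over 1000 seeded five-second baseline trials while a
realistic burst onset (20× the summed baseline noise) still trips within
one control sample on every step trial.
One onset per trial is reported (each trial contains a single reach).
A consequence of the adaptive window worth knowing: the window's standard
deviation grows with the signal's own slope, so a *slow smooth* ramp never
crosses `mean + 8·std`; detection relies on the abruptness of real EMG
bursts. Onset detection runs at the 100 Hz control rate by default
(15-sample window); 1 kHz operation is available through configuration.

## Synergy model

With envelopes `E` [6 × T], muscle synergies are the non-negative
factorization `E ≈ W H` (`W` [6 × 4], `H` [4 × T]). Four synergies are the
model order throughout. Extraction uses multiplicative (Lee–Seung)
updates of the Frobenius objective, which never increase the RMS residual;
the per-iteration residual history is stored so tests can audit the
guarantee. Ten seeded random restarts are run and the best kept; a run
stops when the relative RMSE change falls below 1e-6 or after 1000
iterations. Afterwards each column of `W` is rescaled to unit norm with
the inverse scale folded into `H`, removing the scale indeterminacy so
training coefficients and online estimates live on the same scale. The
training matrix concatenates, per trial, the envelope segment from the
detected onset through the 0.6 s accumulation window (60 samples at
100 Hz). Envelopes are deliberately *not* MVC-normalized anywhere in the
decoder path; MVC enters only the iEMG effort metric.

Online, for each control sample `e_k`, the activation vector is
`argmin_{c≥0} ‖e_k − W c‖₂`, solved exactly by Lawson–Hanson active-set
NNLS (deterministic; KKT conditions are asserted in tests against an
exhaustive-support oracle).

## Direction classifier

For every direction `d` a Gaussian mixture with three full-covariance
components is fitted by EM on that direction's training activation
vectors, with seeded k-means initialization. Covariances are regularized
by adding 1e-6 times the mean per-feature variance to the diagonal —
NNLS features contain exact zeros, so unregularized fits can go
degenerate.

At run time, each activation sample is scored in the log domain under all
eight mixtures; the eight densities are normalized to a probability
vector (uniform prior — targets appear in randomized order). Evidence
accumulation is the recursive Bayesian product: the cumulative vector is
multiplied element-wise by the new likelihood vector and renormalized each
step. Renormalizing every step keeps the recursion in floating range
(densities over 60 steps would otherwise underflow); if all eight
densities underflow anyway, the step returns the uniform vector, and if
the product vanishes the previous cumulative vector is kept. The running
estimate is the argmax of the cumulative vector, ties broken toward the
lowest direction index (E first); after the 0.6 s accumulation time the
estimate is frozen.

## Assistance model

The active chain is a generic 4-DOF serial arm: three intersecting
shoulder axes (abduction/adduction about x, flexion/extension about y,
internal/external rotation about the humeral axis) and one elbow flexion
axis; segment lengths default to 0.30 m (upper arm) and 0.33 m
(forearm+hand). The device-specific passive chain and scapulohumeral
rhythm are not modeled; the shoulder mounting is a fixed rigid transform.

The virtual-stiffness law computes `F = K ∘ R(x_target − x_hand)` (per-axis
gains applied in the shoulder frame) and maps it to joint torques by
statics, `τ = Jᵀ F`, with a geometric positional Jacobian validated
against central finite differences. Gravity compensation treats the two
segments as point masses at configurable centers. The printed reference
gains [0.01, 0.03, 0.01] N/m produce ~10⁻³ N forces over this workspace —
implausibly small for visible assistance — so the closed-loop simulator
applies a separate gain multiplier (default 1000, i.e. reading the values
per millimeter) while preserving the printed numbers verbatim in the
configuration. The simulator integrates
`x_{k+1} = x_k + (v_intent + admittance·F)·dt`, which is stable for
`admittance·k_eff·dt < 2`.

Manipulability defaults to the inverse condition number of the Jacobian,
`√(λ_min/λ_max)` of `JJᵀ`: exactly 0 at singular configurations, 1 for an
isotropic velocity ellipsoid, and bounded in [0, 1] everywhere — the two
properties the index must satisfy. A Yoshikawa-style measure
(`√det(JJᵀ)` normalized by its sampled workspace maximum) is selectable.
Per-movement values are means along the time-normalized trajectory, with
joint angles recovered by damped-least-squares inverse kinematics
(damping 1e-3, joint-limit clamping).

## Evaluation battery

Errors are classified by circular index distance between true and
estimated targets: 1 step (45°) is type 1, 2 steps type 2, 3 steps type
3, 4 steps (opposite) type 4. Percentages are computed over non-excluded
trials, so accuracy + type 1..4 = 100 exactly; *modified accuracy* is
accuracy + type 1 (adjacent confusion treated as acceptable for
assistance). Polar repeatability errors Δρ, Δθ are absolute differences
between an assisted end point and the transparent centroid for the same
target, with angles wrapped to ≤ 180°. iEMG integrates the MVC-normalized
envelope over movement-normalized time (constant envelope at MVC level →
100). Movement end is non-causal: the first sample after the displacement
peak at which it decays to 20% of the peak. The kinematics benchmark
assigns each hand sample to the nearest 45° target angle; samples within
1 cm of home (our choice; angle is meaningless at the origin) inherit the
previous estimate, starting from E. Time-resolved curves report modified
accuracy at every control step from 0.05 s after the detected onset.

The adjusted chance level is the upper bound of the two-sided 95%
binomial interval around random guessing: the smallest count `k` with
`CDF(k; n, 1/8) ≥ 0.975`, reported as `100·k/n`. For the reference
protocol size (8 targets × 20 repetitions = 160 trials) this gives
29/160 = 18.1%.

## Synthetic sessions

The generator produces the structure the decoder assumes, at envelope
level (the decoder never consumes raw EMG; a raw mode — envelope-modulated
wide-band noise — exists to exercise the filter chain):

- **Synergy basis `W_true`** [6 × 4], unit-norm columns: two
  flexor-dominant synergies (biceps + anterior deltoid) and two
  extensor-dominant ones (triceps + posterior deltoid).
- **Cosine direction tuning** with preferred angles 45°, 135°, 225°, 315°
  and exponent 1: each diagonal target recruits exactly one synergy and
  each cardinal target an equal blend of two. The cone generated by the
  eight activation patterns then has the four synergies as its extreme
  rays, which makes the basis identifiable for NMF — noise-free recovery
  is a meaningful test, not luck. Exponent 0 removes all direction
  contrast (the chance-floor construction).
- **Temporal profile**: a Gaussian bell peaking at 50% of the 1 s movement
  (width 0.45 of the duration) truncated at the EMG onset. The truncation
  produces the abrupt envelope rise of real ballistic bursts — about a
  quarter of peak within one control sample — which is what the adaptive
  onset detector keys on; a symmetric untruncated bell would rise too
  slowly to ever cross an 8σ adaptive threshold.
- **Trial-to-trial motor variability**: the muscle pattern of each trial
  is tuned to the instructed angle plus Gaussian jitter (default σ = 10°),
  and a small fraction of trials (default 8%) are "lapses" tuned to an
  unrelated angle, while the hand still reaches the instructed target
  under visual guidance. This is the mechanism that produces realistic
  adjacent-direction confusion: with purely i.i.d. sample noise the
  60-step evidence accumulator is essentially perfect at any SNR high
  enough for onset detection, which no real session resembles.
- **Noise**: i.i.d. Gaussian per sample, clipped at zero, with standard
  deviation = (peak noiseless envelope)/SNR (default SNR 20), plus a small
  tonic baseline. Real envelopes are smoother than white noise; see
  limitations.
- **Kinematics**: minimum-jerk path from home to the target starting one
  electromechanical delay (default 0.1 s — free-movement literature values
  of 0.04–0.07 s lengthened by exoskeleton coupling) after the EMG onset,
  then a hold. Transparent reaches end exactly on the target, so the
  transparent centroid used by the repeatability metrics is the target
  itself.
- **MVC**: 1.2× each muscle's largest noiseless envelope (reaching is
  submaximal).

Sessions (default 10 training + 20 test trials per direction, randomized
order) are fully reproducible from one seed, in memory or as plain-text
CSV trials with a JSON manifest and a ground-truth sidecar.

## Problem sizes used by the tests and the reproduction script

The reference study runs the default session (80 training, 160 test
trials). The chance-floor run uses 50 test trials per direction (400
decoded trials); synergy-recovery runs use 6 training trials per
direction; the decoder-vs-benchmark time-course comparison uses ten
replicate sessions of 5 training + 8 test trials per direction. These are
the package's chosen desk-scale sizes; they keep every seeded run in the
minutes range on one CPU while leaving the statistical conclusions stable
across seeds.

## What passing tests do and do not show

The generator satisfies the decoder's own assumptions (exact low-rank
synergy structure, conditionally independent noise given the trial
pattern, stationary mixtures). Passing the end-to-end checks therefore
shows the pipeline is implemented correctly and behaves sensibly under its
model class — it does not certify performance on real EMG, where
crosstalk, impedance drift, fatigue, non-stationary synergies and
label-free rest periods all violate the model. Absolute synthetic
accuracies are optimistic compared to the human-subject numbers; the
qualitative relationships (above-chance decoding, adjacent-error
dominance, early EMG advantage over kinematics and the late reversal) are
the meaningful outcomes.

## Known limitations

- Envelope-level synthesis with white (sample-independent) noise; real
  envelope noise is low-pass and partially correlated across muscles.
- The 4-DOF arm is a stand-in: no passive-chain kinematics, no dynamics,
  no series elasticity; gravity uses two point masses.
- The decoder assumes exactly one reach per trial and a detectable onset;
  trials without one are excluded, mirroring the study protocol.
- Mixture training uses a fixed three-component order; no model selection.
- No rejection/veto logic: the decoder always commits to a direction.
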