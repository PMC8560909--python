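# Methods

This document describes the statistical and modelling choices implemented in
`bistableflow`: the Granger-causality (GC) engine, the permutation and
cluster statistics, the heartbeat-artifact removal, the synthetic-data
generator, and the hierarchical predictive-coding model, together with the
numerical decisions behind them and their known limitations. Every
quantitative statement here is computed by the test suite
(`tests/`) or by `scripts/acceptance.py`.

## 1. Granger causality engine (`bistableflow.varfit`)

For a channel pair (x, y) and model order `p`, each demeaned trial
contributes rows `w_t = [x_{t-1..t-p}, y_{t-1..t-p}, x_t, y_t]` to a
(2p+2)×(2p+2) moment matrix `M = Σ w w'`. Full- and reduced-model
least-squares solutions, and hence innovation variances, are obtained from
sub-blocks of `M` alone; time-domain GC in each direction is

```
GC = ln(σ²_reduced / σ²_full),  clipped at 0.
```

Working in moment space has two payoffs:

- **Permutation nulls are re-summations.** Swapping the electrode labels of
  a trial corresponds to a fixed index permutation of its moment matrix, and
  shuffling trial labels between two conditions is a masked re-summation of
  per-trial moments. Both nulls therefore reuse the per-trial moments and
  cost a small matrix solve per permutation instead of a refit from raw
  data.
- **Exact agreement with ordinary least squares.** On 20 random stable
  bivariate VAR(2) systems the engine matches an independent two-regression
  `lstsq` oracle to ~1e-13 relative error (criterion: < 1%).

**Model order** is selected per recording as the median (half-up rounding)
of per-pair BIC-optimal orders over a candidate range. The worked
conversion used throughout: an order of 14 samples at 256 Hz corresponds to
14/256 s ≈ 54.7 ms of history.

**Spectral GC** uses the Geweke decomposition of the fitted VAR transfer
function and innovation covariance on an evenly spaced grid from 0 to
Nyquist (default 0.5 Hz for single pairs, 2 Hz in group analyses). The mean
of spectral GC over the grid recovers time-domain GC.

*Numerical choice — fit order for the identity check.* The Geweke identity
is validated on VAR(2) data but with both estimators fitted at order 6. The
marginal process of one channel of a bivariate VAR(2) is ARMA, so the
reduced autoregression in time-domain GC is misspecified at order 2 and
carries a few-percent truncation bias that does not vanish with more data;
it decays rapidly with fit order (sub-1% by order 6, measured 0.2–0.4% max
relative error over seeds). The identity is also checked as a *relative*
error, which is ill-conditioned when a direction's GC is near zero, so the
validation systems couple both directions non-trivially.

## 2. Permutation tests and calls (`bistableflow.granger`)

All calls are two-sided at α = 0.05: the observed statistic must exceed the
97.5th or fall below the 2.5th percentile of its permutation null
(strict inequalities).

- **Feedforward/feedback asymmetry** (`asymmetry_test`): statistic
  `GC_ff − GC_fb`; null from per-trial electrode-label swaps (each trial's
  labels flipped independently).
- **Percept dependence** (`percept_difference_test`): per-direction GC
  difference between preferred and non-preferred trials; null from trial
  labels shuffled between the (count-equalized) conditions. Counts are
  equalized by dropping equally spaced trials from the larger set.
- **Lobe-level direction bias** (`group_bias` / `sign_test`): significant
  pair-level calls per lobe pair are aggregated with a two-sided sign test —
  exact binomial tails for n < 20, otherwise a continuity-corrected normal
  approximation whose error on the two-sided p is below 0.01 for n ≥ 20
  (measured 0.0028 at k = 15, n = 20, exact p ≈ 0.0414).
- **Frequency clusters** (`spectral_cluster_test`): per frequency bin, a
  sign-test z over pairs' significant directional calls; clusters are
  maximal runs of same-sign significant bins scored by |Σz|, compared
  against the per-permutation maximum cluster across the pair-wise
  permutation spectra.

**Calibration.** Empirical type-I error of the asymmetry, percept and
channel-classification tests, and family-wise error (FWER) of the cluster
correction, are all within [0.02, 0.09] at nominal α = 0.05 over 200
Monte-Carlo runs with 200 permutations. The cluster FWER is calibrated
under *direction exchangeability*: every pair is strongly coupled but in an
independently random direction. A fully symmetric no-coupling null is
degenerate for this discrete statistic — without individually significant
connections no bin can reach group significance, which forces FWER toward 0
and would not probe the correction at all.

**Power.** Planted unidirectional coupling (gain 0.5, 80 trials of 64
samples) is detected in ≥ 90% of runs; condition-dependent coupling is
recovered in ≥ 85%; band-limited coupling (30–50 Hz) yields a corrected
cluster overlapping the true band in ≥ 90% (all measured at 100%).

## 3. Preprocessing (`bistableflow.preprocess`)

Stages: per-block linear detrend → zero-phase notch at the line frequency
and harmonics → heartbeat template subtraction → common-average reference →
log₁₀ high-gamma (50–120 Hz) Hilbert envelope, demeaned per block → 50 Hz
anti-alias low-pass and downsampling to 256 Hz for GC analysis.

**Heartbeat detection** thresholds the ECG at 60% of its 99th-percentile
amplitude with a 300 ms refractory window.

**Heartbeat template subtraction.** Per channel, epochs of length twice the
median inter-beat interval (IBI), centered on each beat, are averaged; the
average is low-passed below 5 Hz (zero-phase 3rd-order Butterworth) and
tapered with a 10% Tukey window; the template is then subtracted at every
beat time. Two implementation decisions matter:

- *Overlap-add normalization.* Template placements at successive beats
  overlap by about one IBI. Summing them would subtract each beat's
  artifact roughly twice (the template itself contains attenuated
  neighbor-beat copies). Placements are therefore blended by taper-weighted
  averaging so that every sample is corrected exactly once, with the weight
  sum clamped at 1 so sparse coverage degrades smoothly to a single tapered
  placement and no discontinuities are introduced between beats.
- *No demeaning of the template.* A beat-locked waveform with nonzero
  integral repeating every IBI contributes a genuine DC component to the
  artifact train; subtracting the template's mean would leave that DC in
  place as a constant beat-locked residual. Recordings are detrended before
  this stage, so the epoch-average mean is artifact, not signal.

Measured on generator ground truth: beat-locked average power of the
residual artifact is reduced by ≈ 99% (criterion ≥ 90%), while a
non-beat-locked 10 Hz probe changes by < 0.2% in amplitude (criterion
< 2%); the probe sits above the 5 Hz template low-pass.

## 4. Behavior and classification

Percept streams are segmented into dominance periods between button
presses; "unsure" reports and period fragments outside presentations are
excluded. Individual bias uses the exact two-sided sign test over
presentations; group bias uses the Wilcoxon signed-rank test (verified
against full 2ⁿ enumeration for small n). Cross-session reliability is the
one-way intraclass correlation ICC(1,1) = (MSB − MSW)/(MSB + (k−1)MSW),
which matches a brute-force ANOVA computation to 1e-10 and equals 1 when
within-subject variance is zero.

Switch periods are windows around percept transitions; maintain periods are
the interiors of dominance periods at a safety margin from any transition.
A channel is labelled switch- or maintain-preferring by a paired comparison
of its high-gamma envelope between matched period pairs; label overlap
across the two ambiguous images is tested with a χ² contingency statistic,
and the dorsoventral distribution of switch channels with a rank-sum test
on electrode coordinates.

## 5. Synthetic data generator (`bistableflow.synthetic`)

No raw patient ECoG can be redistributed, so the generator emulates every
property the pipeline consumes, with ground truth retained for testing:

- **Percept schedules**: gamma-distributed dominance durations with
  different means for preferred (8 s) and non-preferred (5 s) percepts,
  optional "unsure" reports and reaction-time jitter.
- **Recordings**: stable multichannel VAR processes whose directed
  inter-group coupling gains switch with the current percept condition
  (e.g. feedback-dominant during one percept, feedforward-dominant during
  the other); band-limited coupling is available through FIR-shaped
  cross-coefficients.
- **Event-locked high gamma**: envelope boosts at percept switches (or
  sustained during maintain periods) on designated channels.
- **Artifacts**: sinusoidal line noise and a beat-locked low-frequency
  waveform (a Gaussian-windowed 1.5 Hz cosine, ±0.3 s) placed at beat times
  with ~3% IBI jitter around 70 bpm, plus a clean simultaneous ECG channel
  with sharp R-waves.

Generator defaults are the study conditions; tests treat them as fixed
ground truth rather than tunable knobs.

## 6. Hierarchical predictive-coding model (`bistableflow.hpc`)

Six rate populations: {prior P, concept C, sensory S} × {preferred PP,
non-preferred NPP}. Each rate follows

```
τ dr/dt = −r + F(drive),    F(y) = 1 / (1 + exp((θ − y)/k))
```

with θ = 0.2, k = 0.1, integrated by Euler–Maruyama at dt = 1 ms. The
drive combines: spike-frequency adaptation (−φ·a, τ_a = 2000 ms), an
Ornstein–Uhlenbeck noise process (τ_n = 100 ms, scale σ), rectified
bottom-up prediction errors `max(0, δ·(r_below − r))`, top-down predictions
`η·r_above`, mutual inhibition between the two concept populations
(−β·r_other), external sensory input to both sensory populations, and — in
the prior layer only — a constant `±Bias` (excitatory to PP, suppressive to
NPP) modelling the long-term prior.

### Parameters (calibrated defaults)

| Parameter | Default | Units | Role / why this value |
|---|---|---|---|
| τ_p, τ_c, τ_s | 10 | ms | rate time constants; fast relative to alternation |
| τ_a | 2000 | ms | adaptation; sets seconds-scale dominance durations |
| τ_n | 100 | ms | OU noise correlation time |
| σ | 0.03 | — | noise scale; enough to trigger switches without washing out bias effects |
| φ | 0.2 | — | adaptation gain; with σ produces spontaneous alternation |
| β | 1.5 | — | concept-layer mutual inhibition; enforces bistability |
| δ_p, δ_c, δ_s | 1.0 | — | prediction-error gains (unit reference scale) |
| η_p, η_c | 0.7 | — | prediction gains; strong enough for top-down stabilization |
| Bias | 0.08 | — | long-term prior drive; source of all asymmetries |
| i_pp, i_npp | 0.8 | — | equal sensory input (the image is ambiguous) |
| θ, k | 0.2, 0.1 | — | sigmoid threshold/slope |

The defaults were calibrated by (1) finding an alternating regime of the
noise-free adaptation–inhibition skeleton, (2) adding noise at the smallest
scale giving robust alternation, and (3) setting `Bias` to the smallest
value producing a clear duration asymmetry. On a 2×10⁶-step simulation the
model yields ~700 completed episodes, median preferred dominance ≈ 3.5 s vs
non-preferred ≈ 2.0 s (rank-sum p < 1e-80), and all four directed-flow
inequalities: predictions P→C and C→S are stronger during the preferred
percept (+0.021, +0.013), prediction errors S→C and C→P stronger during the
non-preferred percept (−0.008, −0.067). With `Bias = 0` both effects
vanish (rank-sum p ≫ 0.05; |asymmetry| < 0.004).

**Percept labelling** uses the concept-layer rate difference with
hysteresis and a debounce window; first and last episodes are censored from
duration statistics. **Flow asymmetries** are means of the corresponding
prediction/error signals during preferred minus non-preferred samples.

*Numerical notes.* The simulation kernel is numba-jitted; results are
bit-reproducible for a given seed. Deterministic fixed points of the
noise-free system are validated with damped fixed-point iteration — the
rectified errors make the vector field non-smooth, which defeats Newton-type
root finders but not a contraction on the reduced 6-dimensional map.

### Robustness and limitations

- The sign pattern of the four flow asymmetries is preserved under every
  one-at-a-time ±25% perturbation of the gain parameters (16/16). Under
  *joint* random ±25% perturbations of all gains it is preserved in most
  but not all draws; one failing corner (adaptation gain near −19% with
  prediction gains near +25%) locks the network into a single attractor and
  stops alternating. The calibrated operating point is not globally
  structurally stable.
- The Geweke identity check degrades for directions whose GC is near zero
  (relative error on a near-zero quantity); this is a property of the
  error metric, not of the estimator.
- The normal-approximate sign test is only used for n ≥ 20, where its
  documented error on the two-sided p is < 0.01; smaller n use exact tails.
- The generator's VAR recordings are stationary within a percept condition
  and switch coefficients instantaneously at reported percept changes;
  real recordings have transition dynamics the pipeline never sees.
- Heartbeat removal assumes a usable ECG channel; with no detected beats
  the recording passes through unchanged (with a warning) rather than
  guessing beat times from the ECoG itself.
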