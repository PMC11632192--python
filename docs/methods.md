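# Methods

## The latent model

One MWT trial is modeled by a latent sleepiness process on the fine
(15-s) epoch grid anchored at lights-off:

    S(t) = clip( exp(a + b·t + ε_t), 10⁻³, 1 ),   ε_t ~ N(0, σ²) iid,

with `a` the log-sleepiness at lights-off (`exp(a) ≤ 1`), `b` the growth
rate in 1/min, and σ the per-epoch log-scale noise. The process is
*exactly* log-linear until clipping, so the downstream log-linear
trajectory fit is the correctly specified estimator and
parameter-recovery tests are sharp. The clip floor 10⁻³ is shared with
the metrics module's log floor so that "sleepiness ≈ 0" epochs transform
to a finite constant rather than −∞.

Everything else about a session derives from S(t):

- **Hypnodensity.** Each fine epoch's stage-probability 5-vector has
  non-wake mass exactly S; N1 receives the fraction `min(1, 2(1−S))` of
  that mass and N2 the remainder, N3/REM stay 0 (MWT naps rarely reach
  them). Reconstructing sleepiness as `1 − p_W` returns S exactly, so
  the hypnodensity→score path is testable to machine precision.
- **Hypnogram.** Each 30-s epoch is staged by its mean fine-epoch
  sleepiness: N2 above θ_N2 (default 0.9), N1 above θ_N1 (default 0.5),
  else wake. Both clauses of the sleep-onset rule are thereby exercised.
- **SOL.** Scored from the hypnogram: earliest epoch starting three
  consecutive N1 epochs, or a single N2/N3/REM epoch; `SOL = 0.5·e` min,
  censored at the 40-min maximum. The noise-free crossing time is
  `(ln θ_N1 − a)/b`, giving the analytic ground truth `1/SOL ∝ b` that
  the slope/inverse-SOL correlation checks rest on.
- **Trial end.** The session is truncated one stage epoch after the
  onset rule fires, mimicking a technician ending the trial at
  unambiguous sleep onset. (Real trial-end handling varies; this is a
  fixed convention here.)
- **Microsleeps.** An inhomogeneous Poisson process with intensity
  `base_rate · S(t)` (events/min; base rate default 1/min at S = 1)
  restricted to wake stage-epochs, sampled by thinning; durations
  uniform on [3, 15) s; overlapping candidates are redrawn up to 100
  times then dropped, so events never overlap.
- **EEG.** One or more channels at 256 Hz: pink (1/f) background noise
  (5 µV RMS) plus a 10 Hz alpha oscillation with amplitude
  `40 µV · (1 − S)` and a 6 Hz theta oscillation with amplitude
  `40 µV · S`; during microsleep events theta is boosted 3× and alpha
  suppressed to 0.25×. This is a deliberately minimal stand-in that
  carries the alpha→theta drowsiness shift and nothing else — no
  spindles, K-complexes, eye movements or EMG, no realistic spectral
  shape above 12 Hz. Tests passing on it show the qEEG chain recovers a
  known band-power trajectory; they do not show robustness to real EEG
  morphology or artifacts beyond the injected classes.

## Study-level generative model

A study is a set of arms (label, n, base slope per day), days
(baseline/day 1/day 7) and four daily sessions (10:00–16:00). The
session slope is

    b = base(arm, day) + siesta_bump·1[14:00] + participant offset,

with participant intercept offsets N(0, 0.3²) applied to `a` (clamped so
`exp(a) ≤ 1`) and participant slope offsets N(0, 0.02²); per-epoch noise
σ = 0.2. Treatment effects are *reduced slopes* on post-baseline days,
matching the observation that treatment changes how fast sleepiness
builds, not its starting level. The default design mirrors a two-cohort
narcolepsy trial (13 + 14 participants across six arms); untreated
slopes (~0.1–0.12/min, SOL ≈ 10 min) versus high-dose slopes
(~0.02/min, censored at 40 min) reproduce the qualitative ceiling
pattern. KSS self-ratings are generated every 2 h from 09:00 as
`1 + 8·(mean day sleepiness)` plus N(0, 0.7) noise, rounded and clamped
to [1, 9].

All randomness flows from one study seed through
`SeedSequence(seed, participant index, day index, session index)`, so
any single session can be regenerated in isolation and whole runs are
byte-reproducible.

## qEEG chain

- **Filtering.** Zero-phase (forward-backward) band-pass 0.1–55 Hz.
  The low edge is a 4th-order Butterworth high-pass. The high edge is an
  8th-order Chebyshev-II low-pass whose 30 dB stopband starts at the
  corner: a Butterworth of practical order cannot meaningfully attenuate
  60 Hz line noise against a 55 Hz corner (≈9.5 dB at 4th order even
  zero-phase), while Chebyshev-II buys a sharp stopband at the price of
  a slightly early passband roll-off — irrelevant here because every
  feature lives below 12 Hz. Notches are 2nd-order IIR, 1 Hz bandwidth,
  config-driven; a helper flags spectral peaks >10 dB above the local
  median floor as notch candidates but never applies them.
- **Artifact rejection** on 2-s windows, any rule on any channel:
  non-finite samples or a ≥0.5-s flat run (missing); ≥10 consecutive
  samples within one least-significant quantum of the channel extremes
  (saturation — checked before the flat rule, since a rail-pinned run
  fires both); sample-to-sample steps above 50 µV/sample at 256 Hz
  (scaled as a constant µV/s limit at other rates); peak-to-peak above
  500 µV. The thresholds are documented conventions, not values taken
  from any particular lab.
- **Spectra.** Non-overlapping 2-s windows, DPSS tapers with NW = 2 and
  3 tapers, eigenvalue-weighted, one-sided PSD in µV²/Hz on the 0.5 Hz
  grid the 2-s window implies. The 2-s window is the minimal length
  achieving that resolution; taper parameters are standard conventions
  and exposed in config.
- **θ/α epochs.** Windows are assigned to 15-s epochs by start time;
  surviving spectra averaged; θ = Σ bins in [4, 8) Hz, α = [8, 12) Hz
  (half-open so the shared 8 Hz bin counts once). An epoch needs ≥4
  surviving windows (of 7–8) and positive α power, else it is invalid —
  an invented quorum, config-exposed.

## Endpoints

The trajectory fit clips at 10⁻³, logs, and regresses on epoch-center
time over `[0, SOL)` (whole session when censored — and the window
question for the "average" endpoint is resolved the same way, with a
`window="full"` switch). A fit needs ≥4 valid epochs (1 min), echoing
the SOL > 1 min eligibility filter used for slope analyses. The
microsleep-rate denominator is the number of complete 30-s epochs of the
whole session, with a pre-SOL alternative behind a switch. Inverse SOL
is computed for censored sessions too (1/40 per min) and flagged rather
than dropped. `isSiesta` compares scheduled slot labels, not wall-clock
minutes. KSS interpolation is linear in clock time with no
extrapolation.

## Statistics

The endpoint model is Gaussian: response ~ day + treatment +
day×treatment + isSiesta, random intercept per participant, REML. Wald
(normal) inference; change-from-baseline contrasts are the `day[d]`
coefficient plus, for non-reference arms, the `day[d]:treatment[g]`
interaction, with the contrast vector emitted for audit. Microsleep
endpoints use the same Gaussian response (count likelihoods are out of
scope; the shrinkage prior is what rescues degenerate cells).

The Bayesian variant places N(0, t²) priors on non-intercept fixed
effects (t is a *standard deviation* by default; a `t_is_variance`
switch covers the other reading of "N(0,t)"), an effectively flat prior
on the intercept, and weak inverse-gamma (0.01, 0.01) hyperpriors on
both variances. The Gibbs sampler draws the fixed-effect block from its
conditional with the random intercepts integrated out (per-group
Woodbury inversion of `σ²I + τ²J`), which decorrelates the β and u
blocks; chains mix to R-hat ≈ 1.00 where the naive two-block scheme
sat at 1.15+. Defaults 4 chains × 2000 iterations, first half burn-in;
R-hat > 1.1 flags the fit unreliable. WAIC and PSIS-LOO are computed
from per-observation conditional log-likelihood draws (arviz); points
with Pareto k > 0.7 fall back to an exact leave-one-out refit in which
the held-out subject's intercept is marginalized. The sweep selects t*
at the maximum discrete second difference of LOO on the log-t grid,
flagging a "weak inflection" when the curvature is below the LOO
Monte-Carlo error.

rmcorr is the subject-adjusted ANCOVA: within-subject centering of both
variables, common slope by OLS,
`r = sign(slope)·√(SS_x/(SS_x+SS_err))`, df = N − k − 1, p from the t
distribution. Subjects with fewer than two paired observations are
dropped with a warning.

## Numerical and design notes

- Per-coordinate shrinkage paths are **not** monotone in t under the
  correlated day×treatment design (the day main effect absorbs signal
  from a strongly shrunk interaction); the L2 norm of the coefficient
  vector is, and is what the shrinkage-monotonicity test asserts,
  alongside the orthogonal isSiesta coordinate.
- Per-session slope endpoints are estimates whose error variance grows
  roughly like 1/SOL³, so the endpoint table is heteroscedastic in a way
  the Gaussian mixed model ignores. Consequences: (i) a small
  attenuation of siesta/treatment effects from truncation conditioning,
  within ±10% under default noise; (ii) model-based standard errors
  understate the uncertainty of contrasts that load on short sessions,
  so full-pipeline CI coverage runs below nominal. The SOL > 1 min
  eligibility filter trims the extreme of this; CI calibration itself is
  verified on data generated from the model's own assumptions. A
  measurement-error-weighted model would address it and is future work.
- LMM fitting retries lbfgs → powell → cg on linear-algebra failures;
  boundary fits (participant variance 0) are legitimate and flagged
  converged.
- Sessions at the scoring-grid scale: the scorer agrees with the
  analytic crossing to within one 30-s epoch only when the N1 band is
  wide enough for the triple-N1 rule to complete, i.e.
  `(ln θ_N2 − ln θ_N1)/b` comfortably above 1.5 min; steeper sessions
  legitimately trigger via the N2 clause.
- Problem sizes in the test suite and acceptance script (200-replicate
  calibration runs, 50-study model-selection runs, 12–24 participant
  designs) were chosen as the smallest sizes at which the Monte-Carlo
  bands stated for each check are meaningful.

## Limitations

- The simulator's EEG is schematic (two oscillators plus pink noise);
  artifact-detector operating characteristics are measured against
  injected faults of the four modeled classes only.
- Hypnodensities are consumed or simulated, never produced from EEG: no
  sleep-staging network is included, and no automated microsleep
  detection is attempted (events are inputs).
- No count-data likelihood for microsleep endpoints (Hurdle-type models
  are an explicit non-goal); the Gaussian-plus-shrinkage route is what
  is implemented and tested.
- EDF files are read (via mne, optional) but not written; the native
  signal format is the documented columnar CSV.
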