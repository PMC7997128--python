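# Methods

## Stimulation protocol

Commanded thermode temperature is piecewise linear with every ramp at
5 °C/s. Phase boundaries are fixed at the nominal 6.5 / 12 / 33 s, with
each ramp placed at the start of its destination phase: the trace ramps
from the 38 °C baseline to T1 at t = 0, steps to T1 + ΔT at 6.5 s, returns
to T1 at 12 s, and ramps back to baseline at 33 s, followed by 10 s of
post-stimulus recording. For T1 ≈ 47 °C this leaves ≈ 4.7 s of plateau
inside T1 and ≥ 4.8 s inside T2, close to the intended ≈ 5 s dwell times;
per-subject boundary adjustment to the exact ramp durations is deliberately
not attempted, so all subjects share one grid and windowed statistics align
across conditions. Traces are sampled at 10 Hz by default — enough to
resolve the shortest ramp (0.2 s at ΔT = 1 °C) while keeping a trial at
~450 samples; the builder rejects sampling intervals longer than the
shortest ramp. Within the numerical construction the T3 plateau equals T1
*exactly* (the grid values are interpolated between exact knots), which the
protocol tests exploit with zero-tolerance assertions.

Condition order is a uniform random permutation of the five conditions per
participant, reproducible from a seed; each trial is followed by a 50-s
baseline interval (the interval matters only for metadata here, since
carry-over effects are not modelled).

## Calibration

The T1 temperature targets NRS 5. Graded 5-s stimuli on a 38–50 °C grid in
2 °C steps seed an ordinary least-squares line of peak rating on
temperature; the line is inverted at NRS 5, clamped to [38, 50] °C and
rounded to 0.1 °C. A 15-s verification stimulus follows: a peak rating in
the closed band [4, 6] accepts the temperature, otherwise the temperature
steps by ±0.5 °C, up to a configurable iteration budget (default 10), and
failure is returned with the full iteration log. A line is the simplest
monotone model consistent with the up/down adjustment semantics; sigmoidal
psychometric fits are out of scope.

One wrinkle: ratings pinned at the scale floor or ceiling (0 or 10) carry
no slope information and would bias the line, so `calibrate_subject` drops
them before fitting whenever at least two distinct interior temperatures
remain. `fit_calibration_curve` itself uses whatever it is given — a
two-point data set with a floor rating is still fittable.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
thermophysiology. Per subject, the latent model is

    rating(t) = clip( 5 + k·(T_eff(t) − t50) + m(t) + ε(t), 0, 10 )

* **Transduction** — static slope k (NRS/°C) around the subject's NRS-5
  temperature t50. Population: t50 ~ N(47.1, 1.4²) °C matching the reported
  calibrated-temperature distribution; k ~ N(1.0, 0.15²), floored at 0.05.
* **Perceptual lag** — `T_eff` is the commanded temperature passed through
  a first-order low-pass (exact zero-order-hold discretization of
  dy/dt = (x−y)/τ), τ = lag_tau ~ N(1.0, 0.2²) s. Time constants below one
  sample pass the input through unchanged.
* **Modulation** — the paradigm-defining term, triggered at the T2→T3
  return (12 s): zero before it, rising with time constant
  mod_tau ~ N(2.0, 0.3²) s to a sustained level of −gain_oa·|ΔT| for OA
  (downward return step) and +gain_oh·|ΔT| for OH (upward return step).
  The T1→T2 step's perceptual impact is carried implicitly by the
  transduction term. Modulation is sustained through T3 by default; an
  optional decay constant is exposed per subject. Gains are drawn jointly
  bivariate normal — defaults gain_oa ~ mean 0.75, gain_oh ~ mean 0.4
  (hyperalgesia weaker than hypoalgesia, matching the paradigm's observed
  asymmetry), both SD 0.5 (individual subjects may show reversed
  responses), correlation ρ = 0.27 echoing the reported weak offset–onset
  association. Female subjects receive an additive +0.3 shift on gain_oh,
  giving the exploratory sex contrast something to find.
* **Noise** — white Gaussian smoothed by the same low-pass filter
  (trackball traces are smooth), analytically rescaled so its stationary SD
  is noise_sd = 0.5 NRS. The noise level is *homogeneous* across subjects
  by default (`noise_sd_sd = 0`): the subtracted effect is an extremum
  statistic, so a subject-level noise scale would bias the offset and onset
  effects of the same subject together and manufacture offset–onset
  correlation that the gains do not carry. The heterogeneity field remains
  available for users who want to study exactly that artifact.

Calibration inside the simulator uses each subject's noise-free steady-state
response (stimulus durations ≥ 5 s are long against the ~1 s lag, so the
peak rating sits at the static fixed point). In the rare case a subject's
t50 is so extreme that no admissible temperature reaches the acceptance
band, the last attempted (clamped) temperature is used.

What the generator does *not* emulate: the transient overshoot ("dip")
beyond the sustained hypoalgesic level visible in empirical offset traces,
carry-over between trials, habituation/sensitization across the session,
scale-use idiosyncrasies, or any biophysics of skin heating. Passing tests
therefore validate the pipeline's arithmetic and inferential calibration on
data with the assumed structure — not the physiological claims themselves.

## Effect extraction

Window means use the half-open window [20, 33) s (last 13 s of
stimulation); at 10 Hz that is exactly 130 samples, and the shared 20-s
boundary sample belongs to T3 everywhere, never double-counted. Difference
traces are control-subtracted per subject on a common grid (mismatched
grids are rejected, not resampled); OA differences are sign-inverted so the
canonical response is positive in both paradigms. The subtracted effect is
max(T3 window) − min(T2 window) with the T2 window widened to [9, 20) s to
absorb the perceptual lag. The published verbal definition ("difference
between the minimum during T2 and the maximum during T3") leaves the sign
convention open; we fix the positive-going order — magnitudes are
identical either way — and the statistic is invariant to adding a constant
to the whole trace.

## Inference

All procedures are implemented from their definitions, with only the
distribution functions taken from scipy:

* **rm-ANOVA** — classical within-subject SS decomposition (see README),
  df = (k−1, (k−1)(n−1)), no sphericity correction (noted in the run
  metadata). Zero error variance is reported as F = ∞, p = 0 and flagged
  degenerate rather than raising.
* **Paired t** — t = mean(d)/(sd(d)/√n), df = n−1, two-sided. A
  two-condition rm-ANOVA equals its squared paired t, which the tests
  assert.
* **Two-sample t** — pooled-variance Student form by default (Welch
  available by flag). The sex analysis uses control-subtracted window means
  per experimental condition, excludes unreported-sex subjects, and reports
  raw p per condition.
* **Pearson r** — two-sided p via t = r·√(df/(1−r²)), df = n−2.
* **Benjamini–Hochberg** — step-up, p_(i)·m/i with a downward cumulative
  minimum, capped at 1, input order preserved. The post-hoc family is the
  three pairwise comparisons within one ANOVA model, each model corrected
  separately; post-hocs run only when their ANOVA's raw p < α = 0.05.
* **Within-subject SEM** — subject-centering (subtract the subject mean,
  add the grand mean), per-condition SD of centered values over √n, times
  the √(k/(k−1)) small-sample correction; invariant to per-subject offsets.

An independent brute-force oracle (nested dummy-coded GLMs fit by least
squares) pins the ANOVA to 1e-8 relative error on random tables, and
statsmodels' `AnovaRM` / `multipletests` serve as external cross-checks in
the test suite only — the pipeline never calls them.

## Numerical and design notes

* Filter initialization: the low-pass starts at the first sample's value,
  so pre-trial baseline is an exact fixed point.
* With zero gains and zero noise, condition differences in the analysis
  window are not *exactly* zero: the lag filter carries a decaying memory
  of the T2 excursion (≈ 1e-4–1e-3 NRS at window start). Disabling the lag
  makes the cancellation exact; tests assert both.
* Latent-vs-recovered symmetry: because the subtracted effect adds
  extremum noise and a shared transduction span k·|ΔT|, the recoverable
  offset–onset correlation is attenuated below the latent gain correlation
  at the default noise level (≈ 0.0–0.2 across ranges at ρ = 0.27).
  Recovery checks therefore use the two clean regimes — a noise-free
  mirror generator (ρ = 1, equal gains), which yields r ≈ 1, and an
  independent-gain generator at n = 500, which yields |r| < 0.1.
* Simulation-study problem sizes: replicated checks run the generator's
  fast path (window means only, identical subject-level seeding) — 2000
  cohorts of n = 21 for the null-calibration check and 500 cohorts of
  n = 41 for the range-ordering check, sizes chosen to give stable rates
  while keeping the default suite quick.
* Determinism: a run is a pure function of config + seed; per-subject
  streams derive from `numpy` `SeedSequence` spawning, and result files are
  byte-identical across repeated runs.

## Limitations

The simulator's sustained-step modulation is a deliberate simplification of
empirical offset dynamics; absolute effect sizes produced under default
settings are plausible but not fitted to any data set, so simulated F and
t statistics exceed the published ones in magnitude. Real rating data must
arrive on a common time grid per subject (resample upstream if needed).
The pipeline implements the paradigm's fixed analysis windows; data-driven
window selection is out of scope.
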