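# Methods

## Scope and data model

`pupilkit` analyses continuous pupil-diameter recordings from binocular
light-reflex examinations: 3 s of darkness followed by a 10 s white-light
stimulus at 4 lux (mesopic) or 300 lux (photopic), five repeats per
condition per session. The native export format of the acquisition device
is proprietary, so the package defines a long-format trace CSV (one row per
sample: timestamps, diameter in mm, a device-validity flag, stimulus
metadata) as its interchange format. Timestamps are seconds from recording
start with stimulus onset at 3.0 s by protocol; all window arithmetic is
relative to the per-trace `stimulus_onset` field, never hard-coded.
Sampling defaults to 30 Hz — consistent with a 0.5 mm per-sample step
corresponding to roughly 15 mm/s — but is a per-trace field. Missing
diameters (lost tracking) and `device_valid = 0` are distinct states; both
are discarded by the reading algorithm but accounted separately in quality
scores. Both eyes are modelled; analyses default to the right eye.

## Automated reading

Per trace and eye:

1. **Hampel-style outlier removal.** For each present-diameter sample, the
   median `m` and MAD-based scale `S = 1.4826·median(|x_j − m|)` are taken
   over the 1.4 s window of present-diameter samples centred on it
   (truncated at the edges; a trailing window is available by config). The
   sample is *removed* (not median-substituted) when `|x − m| > 1.5 mm` or
   `|x − m| > 3·S` — the OR of the absolute cap and the scaled rule, so the
   effective threshold is `min(1.5, 3·S)`. If `S = 0` (constant window)
   only the absolute cap applies, which prevents flat segments from
   removing themselves. A single-sample window is always retained.
2. **Validity rules.** Device-invalid samples, missing diameters, values
   outside [2, 9] mm, and samples stepping more than 0.5 mm from the most
   recent *retained* sample are discarded. Anchoring the step rule on the
   last retained point stops one spike from cascading into removals of the
   recovered signal; comparing against the previous raw sample is available
   via `step_anchor="raw"`.
3. **Window summary.** In the half-open interval [onset + 2 s, onset + 4 s)
   — chosen to capture maximum constriction while excluding pupillary
   escape and latent constrictions — the retained diameters give the median
   and 10th percentile (linear-interpolation definition), the quality score
   `q = retained / total window samples` (device-invalid and missing
   samples count in the denominator), and the weight `w = q·e^(−2d)` with
   `d = |median − p10|`.
4. **Session estimate.** Repeats with `q > 0.5` (strict) contribute
   `p̄ = Σ wᵢ·p10ᵢ / Σ wᵢ`. When none qualifies the session reports *no*
   value (never zero or NaN) so the failure propagates as a reduced N, not
   as a corrupt number.

The **emulated human-assisted reading** is the minimum present diameter
over the full stimulus after removing device-invalid samples and values
outside [2, 9] mm, averaged over repeats. The GUI procedure it emulates is
not algorithmically specified anywhere; the emulation is deliberately a
single-data-point reading so that the two methods diverge through the
documented mechanisms (10% percentile vs minimum — about 200 ms of data vs
one sample on a fully valid window — plus window exclusion of escape and
latent constrictions). Outputs are labelled as emulated.

## Agreement analysis

Paired readings are compared the Bland–Altman way on the difference scale
(`v = a − b`) and, when proportional bias is detected, on the ratio scale
(`v = a/b`). Orientation: differences and ratios are taken as automated
minus/over human (and screening vs baseline for visit comparisons); the
orientation is recorded in each result's labels.

* bias = mean(v); SD uses the n−1 sample estimator; LOA = bias ± 1.96·SD;
  the agreement (over time) or inter-method repeatability (between
  methods) coefficient is 1.96·SD.
* SE(bias) = √(SD²/n) and SE(LOA) = √(3·SD²/n); 95% CIs use the two-sided
  t quantile with n−1 df. The 1.96 normal quantile appears only inside the
  LOA definition itself, never in the CIs.
* Outliers beyond 3·SD of the all-data bias are removed in a *single* pass
  and everything recomputed; both the all-data and reduced results are
  reported. No iteration.
* Proportional bias is screened by Pearson correlation of values against
  averages (two-sided, t distribution with n−2 df). The ratio analysis is
  triggered when the outlier-excluded difference-scale correlation has
  p < α (default 0.05). An undefined correlation (zero variance, detected
  with a relative tolerance guard so floating-point jitter cannot
  manufacture a correlation) is treated as non-significant and flagged.
* The ratio scale requires strictly positive values and is equivalent to a
  log-transformed difference analysis (log(a/b) = log a − log b);
  `log_ratio_equivalence_check` exposes the identity as a self-test.
* Q–Q plot data pair sample order statistics (standardized by sample
  mean/SD) with standard-normal quantiles at (i − 0.5)/n; the package emits
  plot data only and makes no automatic normality decision.
* Subjects missing either member of a pair are dropped pairwise per
  comparison (each comparison keeps its own N) rather than listwise.
* `loa_ci_from_summary` applies the identical interval arithmetic to
  printed summaries (bias, coefficient, n), which is how published
  agreement tables can be checked without raw data.

Report JSON carries full precision; the rendered tables round to 2 decimals
on the mm scale and 3 on the ratio scale.

## Synthetic generator

The trace model is phenomenological, chosen as the simplest shape that
reproduces the qualitative PLR: flat dark baseline; cubic-smoothstep phasic
constriction from `baseline` to exactly `phasic_min` at
onset + `time_to_min`; an optional plateau (`escape_delay`); exponential
escape toward `phasic_min + escape_amplitude` with time constant
`escape_tau`; optionally a Gaussian-shaped latent constriction reaching
`depth_mm` at `time_s` (σ = 0.25 s), emulating near-fixation/cognitive
re-constriction late in the stimulus. Measurement noise is stationary AR(1)
(marginal SD `noise_sd`, default 0.01 mm; correlation time 0.1 s). Blinks
arrive as a Poisson process (default 0.1/s), each replacing ~0.15 s of
samples with missing/invalid values flanked by sub-2 mm spikes, so both the
validity and the range filters are exercised. Trajectories leaving
(0, 10) mm raise a parameter error. Everything is deterministic given
(params, seed).

Cohort defaults encode the targeted study conditions:

| parameter | mesopic | photopic | rationale |
|---|---|---|---|
| subject mean (SD) size, mm | 4.12 (0.70) | 2.73 (0.29) | descriptive table of the target study |
| between-visit difference SD, mm | 0.454 | 0.122 | coefficient/1.96 for 0.89 / 0.24 mm |
| method bias (automated/human) | 1.023 | 1.0 | observed 2.3% ratio; see below |
| within-session repeat SD, mm | 0.12 | 0.05 | small vs the 1.0 mm tolerability range |
| latent-constriction probability | 0.05 | 0 | occasional, mesopic-only events |

Design choices made where the design was genuinely open:

* **Visit structure.** Each visit's true size is the subject truth plus an
  independent Normal(0, between_visit_sd/√2) perturbation. This preserves
  the visit-difference SD while keeping differences uncorrelated with
  averages; an asymmetric "visit 2 = visit 1 + drift" model would correlate
  them by construction (cov = −Var(drift)/2) and spuriously trigger the
  ratio analysis for visit comparisons.
* **Method bias mechanism.** The session template puts the phasic trough at
  onset + 1.2 s with a fast escape (τ = 0.3 s), so the 2–4 s window sits on
  the sustained plateau; the in-window escape amplitude is
  (method_bias − 1)·phasic_min. The emergent automated/human ratio then
  tracks the configured multiplicative factor. `escape_amplitude` here is
  the *in-window* escape component, not the full physiological escape
  (which can be much larger when the trough falls inside the window, as in
  the single-trace presets).
* **Photopic method bias = 1.0.** The photopic automated-vs-human offset
  (~0.02 mm) emerges from the minimum-vs-10th-percentile mechanism alone,
  which is size-independent — consistent with the photopic comparisons
  showing no significant proportional bias. A multiplicative photopic
  component at the generator's low photopic noise would make the
  difference-vs-average correlation significant and wrongly trigger the
  ratio analysis.
* **Tolerability range.** Sessions redraw all five repeat minima (cap 100)
  until their spread fits 1.0 mm, emulating the device's acceptance rule,
  whose actual mechanism is unknown.
* `simulate_method_pairs` generates paired readings directly
  (b = subject size, a = b·Normal(ratio, 0.006)) for power and CI-coverage
  checks of the ratio machinery; the ratio SD is set so the 2.3% bias is
  detected by the proportional-bias screen with high power at n = 43.

What the generator does **not** emulate: mechanistic autonomic dynamics,
constriction latency/velocity structure, real device noise spectra and
blink signatures, dark-adaptation state, or accommodation. Passing recovery
tests therefore demonstrate correctness of the *analysis chain* under the
assumed statistical structure, not validity of that structure for any
particular instrument.

## Numerical conventions

* Percentiles: NumPy linear interpolation between order statistics.
* Window endpoints are half-open [onset+2, onset+4); the Hampel window is
  closed on both sides.
* Weighted-mean estimates are bounded by the contributing 10th percentiles
  (a property test enforces this).
* A zero-SD difference set yields a degenerate result (zero-width LOA and
  CIs) flagged `degenerate`, not an error.
* CSV round trips are bit-identical: floats are written in shortest-repr
  form and parsed with round-trip precision.
* Cohort RNG streams are spawned per subject from a root `SeedSequence`, so
  results are independent of subject evaluation order.

## Problem sizes

Tests run compact versions of every scenario: a 10-subject cohort for
pipeline structure, one 43-subject right-eye cohort (shared fixture) for
parameter recovery, and 200 paired-level replicates for CI coverage. The
acceptance script averages 6 replicate 43-subject cohorts — the coefficient
estimate at n = 43 has a sampling SD of ~11%, and 6 replicates bring the
reported mean within a few percent of the generating value — plus 200
ratio-coverage replicates.

## Known limitations

* The human-assisted reading is an emulation of an interactive procedure;
  its exact in-GUI sanity rules are unknown.
* Whether the original algorithm's Hampel window was centred or trailing is
  unstated; centred is the default, trailing a config switch.
* Published LOA confidence intervals recomputed from 2-dp rounded summary
  rows can land half an ulp from the published print (which was computed on
  unrounded data); the bias CIs and the mesopic rows reproduce exactly.
* Dynamic pupillometry parameters (baseline diameter, constriction latency
  and velocity) are out of scope.
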