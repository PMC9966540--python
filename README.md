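# pupilkit

Automated reading of pupillary-light-reflex (PLR) recordings and
Bland–Altman reproducibility analysis, for pupillometry studies that track
minimal pupil size over time — for example as a safety measure in
atropine-based myopia-control trials in children.

A dedicated pupillometer records the pupil diameter of both eyes
continuously through 3 s of darkness and a 10 s light stimulus, under
mesopic (4 lux) and photopic (300 lux) conditions, five repeats per
condition (with a 1.0 mm tolerability range across repeats). Human-assisted
reading — an operator marking the minimum in a GUI — is slow and sensitive
to blink artifacts. `pupilkit` provides:

* **an automated reading algorithm** that converts raw traces into one
  robust minimal-pupil-size estimate per session;
* **agreement statistics** in the Bland–Altman framework, with exact
  confidence intervals, an outlier policy, a proportional-bias screen and a
  ratio-scale fallback;
* **a synthetic PLR generator** emulating the examination protocol (phasic
  constriction, pupillary escape, latent constrictions, blinks), used for
  validation and as a stand-in for proprietary device exports;
* **a CLI** (`pupilkit simulate | read | agree | run | report`) gluing the
  stages into one reproducible pipeline.

## The reading algorithm

For each 13 s trace and eye separately:

1. A Hampel-style filter over a rolling 1.4 s window removes samples whose
   deviation from the window median exceeds 1.5 mm or `3·S`, where
   `S = 1.4826 · MAD` is the robust scale of the window. Samples are
   removed, never replaced.
2. Device-invalid samples, missing samples, diameters outside [2, 9] mm and
   samples more than 0.5 mm from the previous retained point (≈15 mm/s)
   are also discarded.
3. In the light interval 2–4 s after stimulus onset the median and 10th
   percentile (`p_med`, `p10`) of the retained diameters are computed, with
   a quality score `q` (retained / total window samples) and a weight
   `w = q · e^(−2d)`, `d = |p_med − p10|`.
4. The session estimate is the weighted mean over repeats with `q > 0.5`:
   `p̄ = Σ wᵢ p10ᵢ / Σ wᵢ`. If no repeat qualifies, the session is flagged
   below the quality threshold (no value, reduced N downstream).

The emulated human-assisted reading is the minimum single sample over the
whole 10 s stimulus (after a [2, 9] mm blink-spike guard), averaged over
repeats — so it sees pupillary escape and late "latent" constrictions that
the 2–4 s window deliberately excludes.

## Agreement statistics

For paired readings (visit A vs B, or automated vs human), per-subject
differences `v = a − b` (or ratios `a / b`) are summarised as:

* bias = mean(v); LOA = bias ± 1.96·SD(v); coefficient = 1.96·SD(v);
* SE(bias) = √(SD²/n), SE(LOA) = √(3·SD²/n), 95% CIs = estimate ±
  t₀.₉₇₅,ₙ₋₁ · SE;
* outliers beyond 3·SD removed in a single pass (both results reported);
* Pearson correlation of v against averages screens for proportional bias;
  when significant, the analysis is repeated on ratios (equivalent to a log
  transform, since log(a/b) = log a − log b).

## Worked example

The bundled `figure2` preset is a noise-free mesopic trace that constricts
to 4.7 mm, escapes, and latently re-constricts to 4.1 mm at 10.5 s:

```bash
$ pupilkit simulate --preset figure2 --seed 1 --out sim
wrote 1 trace (390 samples) to sim/traces.csv
$ pupilkit read sim/traces.csv --out readings.csv
wrote 2 readings to readings.csv
$ cat readings.csv
subject_id,visit,eye,condition,method,pupil_mm,n_repeats_used,quality_flags
figure2,screening,right,mesopic,automated,4.7,1,automated; 1:q=1.00
figure2,screening,right,mesopic,human,4.1,1,emulated human-assisted reading (whole-stimulus minimum)
```

The windowed automated reading reports the 4.7 mm plateau; the
whole-stimulus human-style reading registers the 4.1 mm latent
constriction — the mechanism behind the systematic automated-vs-human bias.

At cohort scale (43 subjects, two visits, both light conditions):

```python
from pupilkit import CohortParams, RunConfig, run_pipeline, simulate_cohort

cohort = simulate_cohort(CohortParams(n_subjects=43, eyes=("right",), seed=1))
bundle = run_pipeline(cohort.traces, RunConfig(seed=1))
res = bundle.report["comparisons"]["visits_human:mesopic"]["difference"]["all"]
print(f"mesopic visits: n={res['n']} bias={res['bias']:.2f} mm "
      f"LOA=({res['loa_lower']:.2f}, {res['loa_upper']:.2f}) "
      f"coefficient={res['coefficient']:.2f} mm")
ratio = bundle.report["comparisons"]["methods_screening:mesopic"]["ratio"]["all"]
print(f"mesopic methods (ratio scale): mean ratio={ratio['bias']:.3f} "
      f"(95% CI {ratio['ci_bias'][0]:.3f} to {ratio['ci_bias'][1]:.3f})")
```

prints

```
mesopic visits: n=43 bias=0.06 mm LOA=(-0.75, 0.87) coefficient=0.81 mm
mesopic methods (ratio scale): mean ratio=1.022 (95% CI 1.019 to 1.024)
```

i.e. a mesopic over-time agreement coefficient near the generator's 0.89 mm
target, and an automated reading measuring ≈2.2% larger than the emulated
human reading — recovered from the traces alone, with the generating value
(1.023) inside the CI. The same run is available as
`pupilkit run --seed 1 --out outdir`, which writes `report.json`
(unrounded), rounded agreement tables, readings, and Bland–Altman / Q–Q
plot-data CSVs.

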