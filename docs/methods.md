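# Methods

This note documents the models, the defaults and why they were chosen,
the synthetic-data generators and their limits, and the numerical
choices that shape the results.

## Brain pilocarpine pharmacokinetics

A single intraperitoneal pilocarpine dose is modelled with Bateman
kinetics — first-order absorption into, and first-order elimination
from, a single brain compartment.  We use the unit-peak parameterisation

    C(t) = α · D · u(t),
    u(t) = [e^(−t/τ_dec) − e^(−t/τ_abs)] / [e^(−t*/τ_dec) − e^(−t*/τ_abs)],
    t*   = (τ_abs τ_dec / (τ_dec − τ_abs)) ln(τ_dec / τ_abs),

so that u peaks at exactly 1 and α (µg/mL per mg/kg) is directly the
peak concentration per unit dose.  This decouples curve *shape*
(τ_abs, τ_dec) from *scale* (α).

Parameter conventions and defaults:

* **τ_abs = 6.9 min, τ_dec = 100 min.**  The published shape constants
  for brain pilocarpine are read as *time constants in minutes*.  Read
  as rates they would put elimination ~14× faster than absorption,
  which contradicts the observed fast rise (~20 min to peak) and slow
  decline.  Both are configurable.
* **α = 1.0 µg/mL per (mg/kg)** is a calibration convention, not a
  measured value: no absolute dose-to-concentration scale is available
  for this preparation.  Under it, the standard induction scheme
  (166 mg/kg at t = 0 plus a half-dose booster at 45 min) peaks at
  ≈ 200 µg/mL — inside the 170–230 µg/mL window in which SE is
  triggered — while a single 166 mg/kg dose peaks at exactly
  166 µg/mL, just short of the window.  That reproduces the qualitative
  logic of the protocol (a booster is needed) without claiming a
  measured amplitude.
* **Linearity.**  Doses superpose additively with no saturation; only
  pilocarpine events enter the sum (scopolamine and diazepam in a
  schedule are protocol metadata).
* Degenerate parameter pairs (|τ_abs − τ_dec| < 1e−6 min) are rejected
  rather than switched to the t·e^(−t/τ) limit form; the limit is a
  measure-zero case with no practical use here.

**Protocol metrics** (peak, window entry, minutes-in-window, overshoot)
are computed on a uniform 0.1-min grid, so reported times are accurate
to grid resolution.

**Fitting** (`BatemanPK.fit`) is bounded trust-region least squares over
(τ_abs, τ_dec, α) started from a fixed 3×3×3 grid around data-driven
heuristics (time of the sample maximum; log-linear tail slope for
τ_dec; maximum value over cumulative dose for α).  The multi-start grid
is fixed, so the result is deterministic for given data.  τ_abs < τ_dec
is enforced by relabelling after the fit (the Bateman curve is invariant
under exchanging the constants up to sign).  Fewer than 4 samples raises
an insufficient-data error.  Under the generator's study conditions
(cv = 5% lognormal noise, 24 samples over 180 min) the median relative
parameter error over 50 replicates is well under 10%; noise-free data
are recovered to optimizer tolerance.

## Electrographic seizure and SE detection

The detector operationalises rater criteria: spike-wave discharges
repeating at > 2 Hz, at least 3× baseline amplitude, lasting > 10 s.

1. **Baseline scale** — 1.4826 × median absolute deviation of a quiet
   epoch (default the first 60 s), a robust standard-deviation
   equivalent.  A flat epoch is a degenerate-baseline error.
2. **Spike extraction** — local extrema of |signal − running median|
   (0.5-s median window, removing DC and slow drift) above
   amp_ratio × baseline scale, with a 50 ms refractory.  This is the
   simplest operator adequate for spike-wave morphology at 100–2000 Hz
   sampling; it is *not* a morphology classifier.
3. **Rate segmentation** — centered sliding-window spike rate (2-s
   window, half-open); maximal supra-2-Hz intervals merged across gaps
   < 5 s, trimmed to their first/last spike, kept iff duration > 10 s,
   mean spike rate > 2 Hz and median spike amplitude ≥ 3× baseline.
   Intervals are half-open [start, end) seconds.
4. **SE bounds** — onset is the start of the first event ≥ 300 s (an
   operational convention; behavioral onset is not modelled).  Offset is
   the earliest time t after onset at which the windowed rate is below
   1 Hz *and* the mean spike rate over the following 120 s is below
   1 Hz.  The averaged second condition, rather than requiring every
   2-s reading below threshold, is deliberate: thresholding at 3× a
   MAD-scale admits sparse extreme-value peaks from any stochastic
   background (≈ 0.5–0.6 per second for Gaussian noise at 200 Hz), and
   a literal every-reading rule would almost never terminate SE on such
   data.  If the quiet interval does not complete before the trace
   ends, the offset is open (the animal is censored in SE).
   The "decrease in amplitude" part of the offset criterion is folded
   into the rate criterion: sub-threshold spikes drop out of the train.
5. **"Evolving"** discharges (frequency/amplitude evolution within an
   event) are not operationalised; nothing in the pipeline enforces or
   measures evolution.

Consequences to keep in mind: spike-level output on noisy data contains
sparse supra-threshold background peaks by construction; the event-level
screen (rate × duration × amplitude) is what carries specificity, and on
hour-long background-only synthetic traces it yields zero events.
Detections are invariant to DC offset and to joint rescaling of trace
and baseline.

The power spectrogram is a boxcar short-time periodogram normalised so
per-segment total power equals the segment's time-domain mean square
(Parseval); it is a display/QC tool, not part of detection.

## Diary statistics

* **Span convention.**  "Days from the first seizure to the end of the
  recording" is inclusive of both endpoints, so a diary whose only
  seizures fall on the last day has span 1 (and frequency equal to that
  day's count).  This avoids zero divisions and matches day-counting
  language.  Seizure-free percentage uses the same span; it can never
  reach 100% because the first-seizure day itself has a seizure.
* **High days / clusters.**  "More than 7" is strict (8 flags, 7 does
  not).  A cluster requires the ≥ 5 following seizure-free days to be
  fully in-record (no extrapolation).  Runs of consecutive high days
  collapse into one cluster anchored at the run's last day, otherwise a
  day-wise reading double-counts a single burst.
* **Epilepsy rule.**  ≥ 2 spontaneous seizures; single-seizure diaries
  are classified non-epileptic and excluded from frequency comparisons.
* **Progression** is operationalised by the Mann–Kendall trend test on
  daily counts with tie-corrected variance and continuity correction, at
  α = 0.05 (the criterion is otherwise only verbal).  The test size was
  verified by permutation (≈ 5% rejections under the null).
* **Weekly binning** anchors at the first seizure day by default
  (configurable to the SE day) and drops a partial final week.
* **Remission model selection.**  Candidates: one-phase decay
  (Y0, plateau, k ≥ 0), straight line, horizontal line, optional
  Gaussian transient.  Nonlinear candidates use bounded multi-start
  least squares.  `RemissionResults.best` is the lowest AICc (residual
  variance counted as a parameter), ties to fewer parameters; every
  non-horizontal candidate also carries an extra-sum-of-squares F-test
  p-value against the horizontal line.  At 8 weekly bins AICc recovers
  the generating model in ≥ 80% of Poisson replicates at the
  study effect sizes (constant 14/week vs decay 30→5, k = 0.8/week) and
  exactly in the noise-free limit.
* **Pattern classification** precedence: non-epileptic → remitting →
  progressive → clustering → regular.  *Remitting* requires a declining
  candidate (decay with Y0 > plateau, or negative-slope line) to beat
  the horizontal line at p < 0.05 **and** the final week below 25% of
  the peak week.  The F-test, not AICc, gates this step: at 6 weekly
  bins (a 42-day record) the AICc small-sample correction penalises the
  3-parameter decay so heavily that it is effectively unselectable even
  on noise-free remitting trajectories, while the F-test retains power;
  the 25%-of-peak guard keeps rising trajectories (which a decay with
  Y0 < plateau can also fit) out of the remitting class.
* **Dose-to-SE survival** uses the standard product-limit estimator
  (via lifelines) over cumulative pilocarpine dose, right-censoring
  animals that never reached SE at their last cumulative dose.  At tied
  doses, events precede censorings (the standard convention).

## Synthetic data

Generators are pure functions of (spec, seed) — bit-reproducible — and
their defaults are the study conditions used throughout the tests.

* **PK samples**: model concentrations at n = 24 times spread over
  (0, 180] min, multiplied by lognormal noise with mean 1 and
  coefficient of variation cv (default 5%); cv = 0 reproduces the model
  exactly.  Multiplicative lognormal noise keeps concentrations
  positive.
* **EEG**: Gaussian background (σ = noise_scale, default 20 µV at
  200 Hz) plus embedded periodic biphasic spike-wave complexes (sharp
  10-ms positive spike, slower 60-ms negative wave, 70 ms total) whose
  positive peak is amplitude_ratio × noise_scale.  For Gaussian
  background the MAD-based baseline scale ≈ noise_scale, so
  amplitude_ratio is the amplitude criterion's multiple by
  construction.  Only rate/amplitude/duration are emulated — no 1/f
  spectrum, no artifacts, no circadian structure — so detector tests
  certify the operational criteria, not performance on real mouse EEG.
* **Diaries**: daily counts are negative-binomial around a
  pattern-specific rate trajectory (var = µ + a·µ², default a = 0.3;
  a = 0 degenerates to Poisson — overdispersion is the norm in seizure
  diaries).  Patterns: regular (constant base rate, default 2/day over
  42 days), clustered (deterministic alternation of cluster_dwell days
  at cluster_rate = 12/day with quiescent_dwell = 6 zero days — a
  two-state alternation rather than a hidden Markov chain, so cluster
  ground truth is exact), progressive (linear ramp), remitting
  (exponential rate decay).  Deterministic dwell times make
  cluster-detection truth unambiguous at the cost of realism.
* **Weekly totals**: Poisson draws around a given weekly mean
  trajectory, for model-selection tests.

## Numerical and interface choices

* All event intervals and epochs are half-open [start, end); diary days
  are integer indices (day 0 = recording start), calendar dates are
  deliberately unsupported.
* Protocol grids: 0.1 min; EEG rate grids: 0.5 s (and ≤ rate_window/4).
* The CLI derives per-stage seeds from the single `--seed` by fixed
  offsets; reruns are byte-identical.
* EDF input is read through mne when installed; there is no EDF writer
  in the toolkit, so the EEG text format of record is the CSV dialect
  (`# sampling_rate_hz=` header).  Diary/dose CSVs round-trip losslessly
  through their writers.
* Problem sizes in the test-suite and acceptance script (50 PK
  replicates, 10 one-hour traces, 100–200 diaries, 100 weekly-selection
  replicates) were chosen as the smallest sizes at which the binomial /
  median statistics quoted above are stable to a few percent.

## Known limitations

* The PK model is one-compartment with an assumed concentration scale;
  it cannot predict absolute brain concentrations without an external
  calibration of α, and no plasma/brain partitioning or metabolite
  kinetics are modelled.
* The detector mirrors rater thresholds, not rater judgment: it does
  not enforce discharge evolution, reject artifacts beyond the robust
  baseline, or use spectral features; two-observer manual scoring
  cannot be fully reproduced.
* Diary pattern classes are mutually exclusive by precedence although
  real animals mix them (e.g. progressive with clusters); the
  classifier reports the first matching class.
* Kaplan–Meier curves here describe dose-to-event data from a protocol
  with shared dosing steps; with very few animals the estimator's steps
  are coarse and confidence bands (available via lifelines) should be
  consulted.
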