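# pilotle

Computational toolkit for the **pilocarpine mouse model of temporal lobe
epilepsy (TLE)**: pharmacokinetically guided pilocarpine dosing,
operational detection of electrographic seizures and status epilepticus
(SE) in single-channel EEG, and statistics of chronic-epilepsy seizure
diaries (frequency, seizure-free days, clusters, progression, remission,
dose-to-SE survival).  It is aimed at labs running chemoconvulsant TLE
models who need reproducible, scriptable versions of the criteria they
apply by hand, and at methodologists who want to exercise those criteria
on synthetic data with known ground truth.

## The models

**Brain pilocarpine kinetics.** After an intraperitoneal dose *D* (mg/kg),
brain concentration follows Bateman (first-order absorption/elimination)
kinetics, written here in unit-peak form

```
C(t) = α · D · u(t),    u(t) = [exp(−t/τ_dec) − exp(−t/τ_abs)] / [exp(−t*/τ_dec) − exp(−t*/τ_abs)]
t*   = τ_abs τ_dec / (τ_dec − τ_abs) · ln(τ_dec/τ_abs)
```

with defaults τ_abs = 6.9 min, τ_dec = 100 min (peak ≈ 20 min after
injection) and α = 1 µg/mL per mg/kg (a calibration convention; see
`docs/methods.md`).  Repeated doses superpose linearly.  Protocols are
evaluated against the 170–230 µg/mL brain-concentration window in which
SE is triggered.  `BatemanPK(samples, schedule).fit()` recovers
(τ_abs, τ_dec, α) from concentration–time samples by bounded multi-start
least squares.

**Electrographic seizures.** A seizure is a run of spike-wave discharges
repeating at > 2 Hz, at least 3× the robust (MAD-based) baseline
amplitude, lasting > 10 s.  SE onset is a detected event ≥ 300 s; SE
offset is a sustained (120 s) slowing of the discharge rate below 1 Hz.

**Seizure diaries.** Daily seizure counts per animal.  Frequency =
total seizures / days from first seizure to recording end (inclusive);
% seizure-free days over the same span; a *cluster* is a day with > 7
seizures followed by ≥ 5 seizure-free days; ≥ 2 spontaneous seizures
define epilepsy.  Weekly totals are compared across one-phase decay
`Y(t) = plateau + (Y0 − plateau)e^(−kt)`, straight line, horizontal line
(and optionally a Gaussian transient) by AICc, with extra-sum-of-squares
F-tests against the horizontal line (`RemissionTrajectory(weekly).fit()`).
The dose required to trigger SE is summarised by a Kaplan–Meier curve
over cumulative dose with right-censoring of non-responders.

## Worked example

```python
import pilotle as p

params   = p.PKParams(tau_abs=6.9, tau_decay=100.0, alpha=1.0)
protocol = p.make_protocol(initial_dose=166.0, n_boosters=1, booster_interval=45.0)
ev = p.evaluate_protocol(protocol, p.TargetWindow(170.0, 230.0), params)
print(f"peak {ev.peak_concentration:.1f} ug/mL at {ev.peak_time:.1f} min; "
      f"in window for {ev.minutes_in_window:.1f} min; overshoot: {ev.exceeded_high}")

samples, _ = p.gen_pk_samples(params, protocol, cv=0.05, n=24, horizon=180.0, seed=1)
print(p.fit_pk(samples, protocol).summary())

d, _ = p.gen_diary(p.DiarySpec(pattern="remitting", base_rate=4.0, decay_k=0.1, seed=3))
print(f"frequency: {p.seizure_frequency(d):.2f} Sz/day; "
      f"seizure-free days: {p.pct_seizure_free_days(d):.1f}%; "
      f"pattern: {p.classify_pattern(d).value}")
```

prints

```
peak 200.7 ug/mL at 58.7 min; in window for 34.1 min; overshoot: False
Bateman PK fit
==============================================
n observations                              24
tau_abs (min)                            6.741
tau_decay (min)                           99.4
alpha (ug/mL per mg/kg)                   1.01
peak time (min)                          19.46
RSS                                      386.3
R^2                                     0.9905
frequency: 1.00 Sz/day; seizure-free days: 57.1%; pattern: remitting
```

The first line says the standard induction scheme (166 mg/kg plus an
83 mg/kg booster at 45 min, scopolamine pretreatment) drives the modelled
brain concentration into the SE-triggering window for half an hour
without overshooting it — whereas a single 166 mg/kg dose peaks at
166 µg/mL and never reaches the window.  The fit block shows the model
parameters recovered from 24 noisy samples (truth 6.9 / 100 / 1.0), and
the diary line classifies a synthetic animal whose seizure rate decays
with time as remitting.

## Command line

A single console script `pilo` exposes the pipeline:

```sh
pilo simulate-pk --dose 166 --n-boosters 1 --booster-interval 45 --out series.csv
pilo plan-protocol --initial 166 --window 170:230
pilo simulate-data diary --seed 0 --out sim/
pilo detect-seizures --in trace.csv --baseline 0:60 --out events.csv
pilo analyze-diary --in diary.csv --out stats.json --raster raster.csv
pilo run-all --seed 0 --out-dir out/
```

All stochastic commands take an explicit `--seed`; repeated runs with the
same seed are byte-identical.

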