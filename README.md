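# actispiro

Functional data analysis linking accelerometer-assessed physical activity to
spirometry-measured lung function in older adults, with effect modification
by smoking history.

Conventional accelerometer studies collapse a week of wrist-worn recordings
into minutes per day spent below 0.03 g (sedentary), between 0.03 and
0.10 g (light activity) and at or above 0.10 g (moderate-to-vigorous
activity, MVPA), and regress lung function on those minutes.  The cut-points
are laboratory conventions; whatever dose-response structure lies along the
intensity continuum is lost.  This package implements, end to end, the
functional alternative:

* each participant's waking 5-second epoch accelerations *a* are
  transformed to *x* = log(1 + *a*) and summarized by a kernel density
  *f<sub>i</sub>* (Gaussian kernel, two-stage direct plug-in bandwidth); the
  diurnal activity distribution is **A<sub>i</sub>(x) = T<sub>i</sub> ·
  f<sub>i</sub>(x)**, where *T<sub>i</sub>* is daily waking time in minutes,
  so the mass of *A<sub>i</sub>* over any intensity range is the daily
  minutes spent there;
* each participant's expired-air volume-time curve *y(t)* is rebuilt from
  routine spirometry summaries — PEF, FEF25/50/75, FVC — by fitting the
  flow-volume curve *F(v)* with a penalized cubic spline and solving the
  autonomous ODE **dy/dt = F(y)** anchored at **y(1 s) = FEV1**;
* the two functions meet in a penalized function-on-function regression

  *y<sub>i</sub>(t) = α(t) + ∫ β<sub>g(i)</sub>(x, t) A<sub>i</sub>(x) dx +
  Z<sub>i</sub> γ(t) + ε<sub>i</sub>(t)*

  with a group-specific coefficient surface β<sub>g</sub>(x, t) per smoking
  history group (current / recent ex / long-term ex / never), tensor-product
  B-spline bases, second-difference penalties and GCV smoothing; pointwise
  Wald inference yields significance masks, and the smallest intensity with
  an unbroken significant-positive run to the top of the group's occupied
  range defines a group-specific **activity-intensity threshold**, whose
  time-above exposure feeds a per-10-minutes effect estimate.

Cohort data of this kind are access-controlled, so the package ships a
first-class synthetic cohort generator (`synthetic_cohort`) that emulates
the study design — nine 24-h days of 5-s epochs with a sleep log, wear gaps
and validity failures, five spirometry attempts per participant drawn from
parametric flow-volume templates, and a covariate table — with every planted
effect serialized next to the data, so each pipeline stage can be validated
against known ground truth.

## Worked example

A synthetic cohort of 300 current and never smokers with planted
thresholds (0.054 g at 3.5 ml per minute above it in current smokers;
0.161 g at 3.0 ml per minute in never smokers), using 60-second epochs to
keep the example quick:

```python
import numpy as np
from actispiro import (CohortConfig, generate_cohort, process_participants,
                       cohort_densities, select_best_blow, reconstruct_cohort,
                       make_design, fit_fof, threshold_table)
from actispiro.scalar_models import ModelSpec, fit_activity_model
from actispiro.synthetic_cohort import PlantedEffect

cfg = CohortConfig(
    n_participants=300, seed=1, epoch_seconds=60.0,
    group_proportions=(0.5, 0.0, 0.0, 0.5),
    planted_surface={"current": PlantedEffect(0.054, 3.5),
                     "recent_ex": PlantedEffect(0.10, 0.0),
                     "longterm_ex": PlantedEffect(0.10, 0.0),
                     "never": PlantedEffect(0.161, 3.0)},
)
cohort = generate_cohort(cfg)

acc = process_participants(cohort.epoch_table, cohort.sleep_log, n_days=cfg.n_days)
dens = cohort_densities(acc["waking"], acc["summary"])
best, excluded = select_best_blow(cohort.spirometry_trials)
vt = reconstruct_cohort(best)

tab = cohort.covariates.merge(acc["summary"], on="participant_id").merge(
    best[["participant_id", "fvc", "fev1"]], on="participant_id")
for e in fit_activity_model(tab, ModelSpec("fvc", "mvpa", "model1",
                                           interaction_with_smoking=True)):
    print(f"FVC per +10 min MVPA, {e.group:12s}: {e.beta_per_10min:6.1f} ml "
          f"[{e.ci_low:6.1f}, {e.ci_high:6.1f}]")

design = make_design(dens, vt, cohort.covariates)
fit = fit_fof(design)
print(threshold_table(fit, dens, cohort.covariates, outcome_times=(5.0,)).to_string(index=False))
```

Output:

```
FVC per +10 min MVPA, current     :   37.9 ml [  21.2,   54.6]
FVC per +10 min MVPA, never       :   23.7 ml [   5.0,   42.4]
  group  outcome_time  threshold_g  delta_per_10min    ci_low    ci_high   n
  never           5.0     0.260774        74.080449 25.845794 122.315103 135
current           5.0     0.050545        33.944692 22.834253  45.055130 137
```

Reading: the conventional analysis sees a stronger MVPA association in
current smokers.  The functional analysis localizes where on the intensity
axis the association lives: in current smokers the significant-positive
region starts at 0.051 g — just below the light/MVPA boundary and close to
the planted 0.054 g — with 33.9 ml of FVC per 10 daily minutes above it
(planted: 35 ml).  In never smokers benefit only appears well above the
conventional 0.10 g MVPA cut-point, though with half as many informative
participants the threshold and effect are imprecise at this sample size.
The thresholds are ordered as planted: current < never.

The same stages are scriptable from a shell:

```bash
actispiro simulate --n 200 --seed 1 --out data/
actispiro process   --data data/ --out results/
actispiro density   --data data/ --results results/
actispiro spirometry --data data/ --results results/
actispiro fit-scalar --data data/ --results results/
actispiro fit-fof    --data data/ --results results/
actispiro thresholds --data data/ --results results/
actispiro report     --results results/
```

## Layout

| module | role |
| --- | --- |
| `synthetic_cohort` | cohort generator with planted, recoverable structure |
| `accelerometry` | waking-window extraction, validity rules, nonwear imputation, 5:2-reweighted summaries |
| `activity_density` | plug-in-bandwidth KDE of log(1+a), diurnal A_i(x) on a shared grid |
| `spirometry_curves` | best-blow selection, penalized-spline F(v), volume-time ODE |
| `scalar_models` | per-level linear models with smoking-history interactions |
| `fof_regression` | penalized function-on-function regression, surfaces, masks, slices |
| `threshold_analysis` | intensity thresholds and per-10-min effects above them |
| `cli` | one subcommand per stage |
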