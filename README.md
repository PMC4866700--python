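# eidermoult

Analysis pipeline for the remigial (wing) moult of sea ducks held on
warm (18 °C) and cold (8 °C) water in a crossover design.  During wing
moult, ducks shed all flight feathers at once and are flightless until
the new feathers regrow; the package quantifies how water temperature
shapes the timing and energetics of that period.  It is written for
avian ecophysiologists and quantitative ecologists who want the full
chain — growth-curve fitting through thermal energetics — as tested,
scriptable components rather than one-off analysis code.

## What it computes

**Feather growth.**  Each feather's regrowth is a Gompertz curve

    y(t) = A·exp(−exp(μe/A·(λ−t)+1))

with asymptotic length `A` (mm), maximum growth rate `μ` (mm day⁻¹,
attained where y = A/e) and lag phase `λ` (days), fitted to twice-weekly
triplicate caliper measurements by nonlinear least squares
(`GompertzModel.fit()` → `GompertzResults` with estimates, standard
errors, diagnostics and a `summary()` table).

**Moult phenology.**  Event dates are analytic threshold crossings of the
fitted curve: shedding at 1.5 % of A, emergence at 5 %, regained flight
at 88 %; flightless duration is the 1.5 %→88 % interval and the mean
growth rate is taken over the 5–90 % window (analytically,
rate = 0.6902·μ).

**Thermal energetics.**  Wet conductance of a floating bird,
C_w = H·M/((T_b−T_w)·A) with plumage area A = 0.097·M^(2/3), body
temperature 40.2 °C, and heat production H = 3.83 W kg⁻¹ in the
thermoneutral band (16–25 °C) or 5.48 − 0.09·T_w below it.

**Body-mass dynamics.**  Weekly masses aligned to each bird's moult at
six time points (±1 month, ±1 week, shedding and flight-regain dates),
with group means ± SE, anticipatory gains and post-moult contrasts.

**Time budgets.**  In/out-of-water scan samples summarised per session
and compared across treatments with a from-scratch Mann–Whitney U test
(exact enumeration for small samples, tie-corrected normal approximation
otherwise).

**Synthetic cohorts.**  A seeded generator (`simulate_cohort`) emulates
the 13-bird crossover with all of the above structure, so the entire
pipeline is testable end to end without field data.

## Worked example

```sh
eidermoult run --seed 1 --outdir out
```

prints

```
eidermoult pipeline report (seed=1, config=687d7c02bf25)

fits: 68 curves, 68 converged
P9 emergence warm-minus-cold (pooled): +7.15 days
P9 mean flightless duration: 41.4 days

wet conductance (W m^-2 degC^-1):
  cold (8 degC): 1.904
  warm (18 degC): 2.185
  warm vs cold: +14.7%

time budget (% in water):
  cold: 28.2% in, 71.8% out (4 sessions)
  warm: 23.8% in, 76.2% out (5 sessions)
  Mann-Whitney U = 0.0, p = 0.020 (normal)
```

Reading the report: all 68 simulated bird-year-feather curves were fitted
successfully; warm-water birds started growing their ninth primary about
7 days later than cold-water birds (the generator imposes a +7-day lag
shift, recovered here from the fits), while the flightless period itself
(≈41 days) does not differ because growth *rate* is unaffected by
treatment.  The conductance block evaluates the energetic trade-off: the
warm group's lower shedding-date mass gives it ≈15 % higher wet thermal
conductance than the heavier cold group.  The time-budget block shows
both groups spending roughly a quarter of their time on the water, with
per-session proportions compared by the rank test.  The same stages are
available individually (`simulate`, `fit`, `phenology`, `thermo`, `mass`,
`timebudget`) and as library calls; outputs are CSVs stamped with the
seed and configuration hash, so re-running a seed reproduces every file
byte for byte.

From Python, the core object is statsmodels-flavoured:

```python
import numpy as np
from eidermoult import GompertzModel, GompertzParams, gompertz_length, derive_phenology

p = GompertzParams(A=167, mu=5.0, lam=20.0)
t = np.repeat(np.arange(0, 80, 3.5), 3)
y = gompertz_length(t, p) + np.random.default_rng(0).normal(0, 1, t.size)
res = GompertzModel(t, y.clip(0)).fit()
print(res.summary())
print(derive_phenology(res))   # shed/emergence/regain dates, rates
```

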