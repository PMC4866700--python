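# Methods

## Scope and model

`eidermoult` re-implements, as a reusable tested pipeline, the analysis
chain of a captive-eider remigial-moult experiment: sea ducks in a
water-temperature crossover (pools held at 18 °C "warm" and 8 °C "cold",
treatments swapped between years) were measured twice weekly during wing
moult, and the analysis derives feather-growth curves, moult phenology,
thermal conductance, moult-aligned body-mass dynamics and in/out-of-water
time budgets.

### Feather growth

Feather regrowth is modelled with the Gompertz sigmoid in the
growth-curve parameterization

    y(t) = A · exp(−exp(μe/A · (λ − t) + 1)),

where `A` (mm) is the asymptotic feather length, `μ` (mm day⁻¹) the
maximum growth rate (the slope at the inflection, where y = A/e), and `λ`
(days) the lag phase (t-intercept of the inflection tangent).  The model
is fitted per bird-year-feather by nonlinear least squares
(`scipy.optimize.least_squares` with an analytic Jacobian).  Triplicate
caliper readings enter as independent observations by default
(switchable), since averaging them first changes only the weighting, not
the estimate, under iid noise.

Numerical choices:

* **Initialization** — A₀ = 1.05 × max observed length; μ₀ = steepest
  secant between session means; λ₀ = tangent intercept at that secant.
  This is parameter-free and robust on sigmoid data.
* **Bounds** — A ∈ [0.8 × max length, 3 × max length], μ ∈ (0, 10 μ₀],
  λ unbounded.  The asymptote's lower bound deliberately sits *below* the
  largest observation: with ≈1 mm caliper noise the sample maximum
  routinely exceeds the true plateau, and a bound at the maximum would pin
  roughly a third of estimates and falsely flag them.
* **Convergence** — relative cost-change tolerance 1e−10.  A solution on
  a bound or at the iteration cap is reported with `converged=False`;
  phenology derivation refuses such fits rather than propagating them.
* **Degenerate inputs** — fewer than 5 distinct time points, all-equal
  lengths, or negative lengths are rejected with diagnostics.

### Phenology

Moult events are threshold crossings of the fitted curve, as fractions of
Â: shedding of the old feather at 1.5 %, emergence (first measurable
millimetres of the new feather) at 5 %, regained flight at 88 %; the
flightless duration is the 1.5 %→88 % interval, and the mean growth rate
is computed over the 5–90 % window.  Because crossings are analytic,

    t_f = λ + (A/(μe)) · (1 − ln(−ln f)),

two identities hold and are enforced as tests: the 5–90 % rate equals
0.6902·μ for *any* parameters, and the flightless duration is independent
of λ.

The field convention of reading the 5–90 % rate off raw measurement pairs
gives systematically higher values than the curve-based rate (observed
mean-rate/max-rate ratios near 0.76 rather than 0.690), because the
nearest observations rarely sit exactly on the thresholds.  Both variants
are provided — `analytic` (default, curve-based) and `empirical`
(nearest session means to 5 % and 90 % of Â) — and are never conflated;
likewise the curve-based emergence date and the observed first-detection
date are separate quantities.

### Thermal conductance

Wet conductance of a floating bird is

    C_w = H·M / ((T_b − T_w)·A),   A = 0.097·M^(2/3),   T_b = 40.2 °C,

with mass-specific heat production piecewise in water temperature:
H = 3.83 W kg⁻¹ within the 16–25 °C thermoneutral band and
H = 5.48 − 0.09·T_w below it.  The two branches disagree by 0.21 W kg⁻¹
at 16 °C; the discontinuity is inherent to the source calorimetry and is
surfaced, not smoothed (the boundary itself uses the thermoneutral
branch).  Temperatures outside 0–25 °C are refused rather than
extrapolated.  Group mass for the headline conductances is the unweighted
mean of the two sex-specific shedding-date means — the pooling rule is
not dictated by the equations, but it is the convention under which the
grams-level inputs and the reported conductances (1.9 and 2.17
W m⁻² °C⁻¹, a 14 % contrast) are mutually consistent, and it is applied
uniformly.  On the cold branch conductance *falls* as the water cools
(the widening body–water gradient outpaces the H increase); this
direction is asserted numerically rather than assumed.

### Body-mass dynamics

Weekly masses are aligned per bird to six moult-anchored time points
(shed −30, −7, 0; regain 0, +7, +30 days), taking the nearest observation
within ±4 days (half the weekly spacing plus margin) and reporting gaps
as missing — never interpolating.  Group summaries use between-bird SE
(sd over birds / √n).  Two denominator conventions are fixed because they
are the only ones under which the grams and percentages of the reference
summaries agree: anticipatory gain percent uses the shedding-date (Start)
mass as denominator, and the post-moult cold-minus-warm contrast percent
uses the warm-group mass.  (A "percent of initial mass" reading with the
1MB denominator is inconsistent with the same tables by ≈3 percentage
points; the arithmetic, not the wording, is followed.)

### Time budgets

Sessions are 5-minute scan samples of birds in/out of the water; a
session's in-water proportion pools its counts.  Treatments are compared
with a from-scratch Mann–Whitney U: midranks for ties,
U = min(U_x, U_y), exact enumeration of the rank-assignment null when the
total sample is below 8 and otherwise the tie-corrected normal
approximation with continuity correction; two-sided p doubles the
one-sided tail, capped at 1.  The sampling unit is the session.  Note the
exact branch's p-values are discrete — with 3 vs 4 sessions the smallest
achievable two-sided p is 2/35 ≈ 0.057 — so calibration is tested at the
attainable level rather than at a nominal 0.05 that the discrete null can
never reach.

## Synthetic cohort

The generator emulates the study conditions so that every stage is
testable without the (undeposited) field data: 13 birds (8 from the first
cohort with three moult years, 5 from the second with two), treatments
alternating year over year; twice-weekly triplicate measurements with
1 mm Gaussian caliper noise truncated at zero, emitted only once the true
curve passes a 2 mm field-detection threshold and never before the old
feather's shed date; weekly masses from a piecewise-linear moult-aligned
trajectory (sex-specific baseline, treatment × sex anticipatory gains of
307/158/167/110 g, a 50 g drawdown over the moult, treatment-separated
recovery, 80 g between-bird spread, 25 g weighing noise); and binomial
scan counts at in-water probabilities 0.275 (cold) and 0.242 (warm) with
roughly 940 and 1300 recorded minutes respectively.

True parameters are drawn per bird-year from normals truncated at zero.
The warm treatment adds +7 days to λ and nothing to μ.  Defaults:
μ(P9) ~ N(5.05, 0.25²), μ(S1) ~ N(4.60, 0.25²) mm day⁻¹ — within the
range of reported group means — and λ ~ N(20, 4²) days on the run's
continuous axis.  No asymptotic feather lengths are reported for this
population, so `A` is a calibration choice: A(P9) = 167 mm is fixed by
internal consistency, since the flightless duration
(A/(μe))·(ln(−ln 0.015) − ln(−ln 0.88)) with μ ≈ 5.05 then reproduces the
reported ≈42-day durations (a 230 mm asymptote would imply ≈58 flightless
days, contradicting the phenology it must emulate); A(S1) = 150 mm.  All
of these are configurable.

What the generator does **not** emulate: attrition (cohort sizes are
specified directly, post-attrition), any energetic mechanism linking
temperature to onset (the λ shift is imposed), age structure, seasonal
calendar effects, or within-day measurement structure.  Passing tests
therefore demonstrate that the *analysis* recovers what the generative
model puts in under realistic noise — not that the biological claims hold
in the field.

## Problem sizes and determinism

Default analyses run a 13-bird cohort (68 curves, ≈4200 measurements,
<1 s end-to-end).  The parameter-recovery study uses 200 simulated birds
(one moult year each, P9 only) — large enough that the Monte-Carlo error
on a 7-day group contrast (SE ≈ 0.6 days) sits well inside the 1-day
check.  Every random draw flows from one `numpy` `default_rng` seed;
identical seed and configuration give byte-identical output tables, and
all CSVs embed the seed and a configuration hash.

## Known limitations

* Mixed-effects significance tests (bird as random effect) are out of
  scope; group contrasts are descriptive.
* The empirical 5–90 % rate depends on the measurement schedule, so its
  gap to the analytic rate varies with the sampling design.
* The conductance model inherits its constants from winter-acclimatized
  reference birds; only the two printed heat-production regimes are
  implemented, with no dry-air counterpart.
* Nearest-observation mass alignment biases the measured anticipatory
  gain slightly toward zero (the −30 day target typically lands on a −28
  day weighing); the same bias affects any weekly field schedule.
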