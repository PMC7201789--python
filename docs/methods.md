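# Methods

This note documents the models, parameter choices and numerical decisions
behind `safeloop`, and what its simulations can and cannot show.

## Control stack

### Inner loop

The PD controller acts on the *conditioned* reference `G_rf`:
`u_pd = Kp[(G − G_rf) + Td·Ġ]`. The sign convention is the one under which
the safety layer functions: glucose above the reference increases insulin,
so raising `G_rf` cuts insulin. `Kp` defaults to the TDI/2250 heuristic in
U/min per mg/dl and `Td` to 90 min. The CGM derivative is a backward
difference over one 5-min sample; an optional 3-point moving-average
smoother (`smooth_derivative`) is off by default because the surrogate CGM
is noiseless by default.

Insulin feedback subtracts `γ·Îp` from the action, with `Îp` the estimated
plasma-insulin deviation from basal. The estimator is a two-compartment
linear chain with the same rate constant as the IOB estimator, driven by
`(u_d − u_basal)` with boluses as impulses; it is zero at basal steady state
and signed during suspensions. γ = 0.42 is applied as a dimensionless gain
on the chain total (in U). The published tuning gives γ in L/min against an
unspecified pharmacokinetic model; since that model is not recoverable, the
gain, the chain rate (`k_ifb`) and γ itself are configurable, and the
qualitative property that matters — delivery is suppressed one-for-one with
estimated excess plasma insulin — is preserved and tested.

Meal boluses (announced meals only) are
`M_CHO/I2C + (G − G_r)/CF + ∫ u_basal over the next M_CHO minutes`, clamped
at zero. The correction term applies only at boluses, never between meals.

### IOB estimation

Two compartments with a single elimination constant `K_DIA = 0.013 min⁻¹`
(not individualized; configurable). Integration backends:

* `heun` (default): fixed-step explicit trapezoidal update at a 1-min
  internal step, matching pump resolution. Its accumulated error against
  the exact solution over a 24-h bolus trace is below 0.1% of the trace
  maximum (forward Euler would not meet this, which is why Heun is the
  default explicit scheme).
* `exact`: the closed-form zero-order-hold solution of the linear system,
  used as the numerical oracle in tests and for the offline constraint.

The offline **fixed constraint** reproduces the clinically validated
procedure for a 60-g meal: from the basal steady state, inject the
augmented bolus (60 g / I2C plus the next hour of basal) and read the IOB
estimate 90 min later with delivery at zero. One value per therapy; the
"fixed" arm holds it for the whole simulation (computed at 12:00; with the
generated flat profiles the clock time is immaterial).

### SAFE layer

`σ = (ÎOB − IOB̄) + τ(dÎOB/dt − dIOB̄/dt)` with τ = 10 min, switching
amplitude W = 350 mg/dl, filter rate λ = 0.1 min⁻¹ (the published table
prints "0.1 min"; the filter equation requires a rate). Discrete-time
details:

* derivatives are backward differences at the 5-min controller period;
* the limit is piecewise constant in every arm (profile segments, day/night
  gain switches, DRB raises/releases are all step changes), so its
  derivative term is zeroed at jumps — effectively always;
* the switching law runs at the controller period; the reference filter is
  advanced with the exact first-order update under held ω, so relaxation
  toward `G_r` is exactly exponential at rate λ regardless of step size.

### DRB tuner

Fasting baseline `IOB̄_bl(t) = K_IOB(t)·2·u_basal(t)/(60·K_DIA)`, i.e.
K_IOB times the steady-state IOB the basal rate would produce. K_IOB = 1
therefore means "never hold more IOB than open-loop therapy would"; the
defaults allow 30% more by day (06:00–23:00) and 10% by night. The switch is
a step by local clock, unsmoothed.

Postprandial rules, evaluated once per controller sample:

1. a meal announcement opens a window and sets `T_IOB = 1.5·M_CHO` min
   (announced grams — the controller cannot know the true ones); a new
   announcement during an active window resets it to the new meal;
2. before `meal_time + T_IOB` the limit stays at baseline (the bolus itself
   violates it and the SAFE layer suspends delivery);
3. from `T_IOB` on (inclusive), the first sample with G > 150 mg/dl raises
   the limit to `max(ÎOB(t−1), IOB̄_bl)` — once per meal;
4. the raised limit holds while G > 140 mg/dl; at G ≤ 140 the window closes
   and the limit returns to baseline. If G never exceeds 150, the window
   closes at the first G ≤ 140 after `T_IOB`; in the degenerate case where
   G sits in (140, 150] indefinitely the window stays open with the limit
   at baseline, which is harmless.

## Surrogate virtual patient

A Bergman-type minimal model with one gut compartment and a two-compartment
subcutaneous insulin chain (states and equations in `safeloop.patient`).
It is public and well-characterized, and it exercises every controller
pathway: meals raise glucose with a realistic lag, insulin lowers it through
a remote-action compartment, basal delivery holds a fasting steady state.
It does **not** reproduce the numerics of the licensed FDA-accepted
simulator platform or its adult cohort, so absolute outcome levels here are
not comparable to published cohort tables; only within-simulator,
between-arm comparisons are meaningful. That is also why the cohort-level
acceptance checks are directional (arm orderings under paired seeds) rather
than numeric reproductions.

Parameter ranges (uniform draws, rates in 1/min): glucose effectiveness
p1 ∈ [0.0035, 0.005]; remote-insulin equilibration p2 ∈ [0.015, 0.03];
plasma insulin elimination k_e ∈ [0.10, 0.16]; subcutaneous absorption
k_sc ∈ [0.020, 0.033] (absorption peak ≈ 1–1.5 h, rapid-analog-like); gut
absorption k_abs ∈ [0.010, 0.020] (mixed-meal absorption stretching over
2–4 h); distribution volume V_g ∈ [115, 155] dl; carb availability 1.0;
insulin-free equilibrium G_end ∈ [280, 340] mg/dl; fasting target
g_b ∈ [110, 130] mg/dl; TDI ∈ [30, 60] U. The k_abs and V_g ranges were
calibrated once so that a therapy-consistent bolus under-covers the meal
peak at nominal sensitivity (the clinical norm — correction is the
controller's job) rather than over-covering it, which would make late
post-bolus hypoglycemia the dominant outcome and is not how tuned therapies
behave.

Therapy is derived from physiology, not sampled independently: CF =
1700/TDI, I2C = 450/TDI, insulin sensitivity `S_I = CF·k_e/g_b` (so one
unit produces ≈ CF of lowering exposure), and the flat basal rate
`u_b = p1(G_end − g_b)/CF` places the fasting equilibrium exactly at g_b.
Draws whose basal fraction of TDI falls outside [0.2, 0.7] or that fail a
24-h basal steady-state simulation check (±10 mg/dl) are rejected and
resampled. Profiles are flat; multi-segment profiles are supported
throughout and exercised in tests.

Variability: insulin sensitivity carries a 24-h sinusoid of ±30% amplitude
with one uniform phase drawn per patient per simulation — because the model
uses absolute (not deviation) insulin states, this genuinely shifts the
basal insulin requirement over the day. At each meal, k_abs and k_sc are
re-drawn uniformly within ±30% of nominal (non-compounding) and held until
the next meal. CGM noise is off by default (the reference evaluation does
not state a CGM error model) and configurable as additive Gaussian.

## Scenarios and arms

* **A** 7 days, one 60-g meal/day uniform in 10:00–16:00 (DRB vs fixed).
* **B** 45 days, one meal/day of 40–120 g (uniform — the sampling law is a
  package choice) in 08:00–19:00.
* **C** 14 days, meals 07:30/45 g, 13:00/90 g, 18:30/50 g, each announced
  with a ±15% uniform carb-counting error; four arms (DRB, fixed, fasting
  baseline only, unconstrained).

Each patient's streams (meal schedule, circadian phase, meal perturbations,
CGM noise) derive from `SeedSequence([master_seed, patient_index])` and are
identical across arms, so arm comparisons are paired. The plant advances at
1-min Heun steps inside 5-min controller intervals with delivery held.
Meal times are snapped to the 5-min grid. Plant divergence (non-finite
state) is recorded as a per-run failure, not silently dropped.

The **unconstrained** arm is deliberately kept identical to the others
except for the absent limit. Under this plant the TDI/2250 proportional
gain over-delivers dramatically without the SAFE layer, so that arm shows
severe hypoglycemia; it demonstrates the magnitude of controller
overreaction the layer absorbs, not a clinically plausible deployment.

## Metrics

Time in 70–140 and 70–180 mg/dl as closed intervals; <70, <54 and >180
strict (boundary conventions are package choices). Hypoglycemic event:
a maximal run of consecutive samples strictly below 70 mg/dl spanning
≥15 min (3 samples at the 5-min period; boundary inclusive); events are
attributed to the day/night window containing their start. Glycemic
excursion: max BG in the 4-h postprandial window minus the premeal value.
Postprandial controller insulin: Σ u_d·Ts over the 4 h after (excluding)
the bolus sample. GMI(%) = 3.31 + 0.02392·mean glucose. Day/night split:
06:00–23:00 / 23:00–06:00. Cohort summaries are medians with 25th–75th
percentiles; event counts are summed.

CVGA uses the standard 9-region grid: minimum-BG axis clamped to [50, 110]
with lines at 90 and 70, maximum-BG axis clamped to [110, 400] with lines
at 180 and 300; the zone letter is the sum of the two axis category indices
(A best, E worst). Values beyond the plot edges are clamped, so e.g. a
day with min < 50 and max ≤ 180 reads as C rather than E — a known
limitation of the clamped-grid formulation.

## Problem sizes and limitations

The directional cohort checks run 10 surrogate patients × 14 days × 4 arms
× 5 seeds (≈ 2,800 simulated patient-days, about half a minute on one CPU);
scenario B's 45 days and larger cohorts run the same way, just longer.
Passing tests show that the control stack has the designed safety
mechanics on this surrogate cohort; they do not show performance on the
licensed simulator cohort or in patients. Known limitations: no CGM error
model by default, flat generated basal profiles, no rescue carbohydrates,
no exercise handling, single-insulin pharmacokinetics, and an IFB estimator
that preserves the published behaviour but not the original (unpublished)
model's units.
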