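# Methods

## Models

The GI and GIG models are deterministic compartmental ODE systems for
one subject during a hyperinsulinemic-euglycemic clamp.  Their
structural assumptions:

* glucose removal is first order in glucose with an insulin-
  proportional component (`(k2 + k4*I + k8) * Gc`), so uptake is
  mass-action in both glucose and insulin — a narrow-range
  approximation valid near clamp/fasting concentrations;
* beta-cell secretion responds to a low-pass-filtered glucose signal
  `Y` (`dY/dt = k3 (Gc - Y)`) through a thresholded linear drive
  `X = max(Y - k6, 0)`; `X` is algebraic, not a state;
* urinary glucose loss is first order, `k8 * Gc` (no renal threshold);
  `k8` is fixed per subject from the measured 0-120 min urinary
  glucose integral, so SGLT2-inhibitor-scale glycosuria enters the
  model as data, not as a fitted parameter;
* glucagon secretion is suppressed by insulin (`kGgS / max(I, eps)`),
  cleared first order (`kGgC`), and acts on glucose production
  additively (`+ kGN * Gg`); alternative suppression structures
  (by glucose, or jointly) are available and form part of the reduced
  variant family;
* insulin and C-peptide share the pre-hepatic secretion flux `k5*X`
  (expressed in C-peptide units, nmol/L/min); insulin receives
  `1000 * kratio * k5 * X` pmol/L/min, keeping `kratio` the
  dimensionless posthepatic insulin : C-peptide molar ratio in [0, 1].

Units are fixed internally: glucose mmol/L (18.016 mg/dL per mmol/L),
insulin pmol/L (6.0 pmol/L per uU/mL), glucagon ng/L, C-peptide
nmol/L, time in minutes.  Infusions are per-kg rates divided by the
per-kg blood volume `BVn = BV/weight`, with `BV = 0.75 dL/kg x weight`
by default (overridable per subject).

The epsilon floor in the `1/I` suppression term defaults to 1e-6 of
the subject's maximum observed insulin (1e-3 pmol/L absolute when no
data are attached); it only matters for degenerate candidates visited
during global search.

## Preprocessing

The quasi-continuous glucose trace is replaced by its trailing 5-min
window mean (the value reported at minute t averages samples in
(t-5, t]); sparse hormone series are used as measured.  Each variable
is normalized by its own maximum, and simulated trajectories are
normalized by the *observed* maxima, so the objective is a fixed
function of the parameters.  The same window operator is applied to
measured and simulated glucose: windowing only the measurement would
leave a systematic ~2-min-lag residual (~1e-2 in normalized RSS) that
no parameter vector can remove, breaking the identity that a noiseless
self-fit attains zero residual.  Missing samples are dropped, not
imputed, and the per-variable counts used by the objective weights
reflect the data actually present.

Trapezoidal quadrature fixes `k8` from the urinary-glucose balance; it
is exact for piecewise-linear traces.

## Objective and estimation

The GI objective weights the glucose and insulin squared-error sums by
`nI/(nGc+nI)` and `nGc/(nGc+nI)`; the GIG objective weights each of
the four variables by `(N - n_own)/N`, `N = nGc+nI+nGg+nCP` (weights
sum to 3).  This prevents the ~116-point windowed glucose trace from
drowning out the 12-point hormone series.

A soft fasting-steady-state term is added to the *optimized* objective
(never to the reported RSS): the model's initial glucose derivative,
scaled by a tolerated drift of 2% of `G0` per minute, enters as one
extra residual.  Subjects arrive fasted, and without this term the
first unobserved minutes (the window delays the first usable glucose
point to t = 5) admit degenerate large-production/large-removal fits
whose transients the data cannot see.

Global search is self-adaptive evolutionary programming in log10
parameter space: each individual carries per-coordinate mutation
scales, themselves log-normally mutated before use; survivors of the
(mu + mu) union are chosen by stochastic q-tournament (q = 10);
the population is initialized log-uniformly within the estimation
bounds ([1e-4, 1e4] for GI, [1e-4, 1e6] for GIG, [1e-10, 1] for
kratio).  Two desk-scale amendments keep small populations honest:

* 10% of each offspring batch are fresh log-uniform draws ("random
  immigrants"), preventing 40-parent populations from collapsing onto
  one basin of the strongly multimodal objective;
* local refinement is multi-start: the best-ever candidate, distinct
  finalists of the population, and a small grid of *steady-state warm
  starts* derived from the subject's own measurements (k7 from
  insulin flux / Iss, k4 from the clamp glucose balance, k1 from the
  fasting balance, glucagon clearance from the observed early Gg
  decay, with the poorly determined threshold fraction k6/G0, sensing
  rate k3 and glucagon production share gridded) are all coarsely
  refined, and the leaders polished deeply.  Refinement is
  bound-constrained trust-region least squares on the stacked weighted
  residual vector, with the jacobian built by batched forward
  differences through the vectorized simulator; it never returns a
  worse point than its input.

The default desk budget is 40 parents x 300 generations; the
full-scale budget of 400 x 4000 (`FULL_BUDGET`, CLI `--budget full`)
is available via configuration.  On
noiseless synthetic subjects the desk pipeline recovers the GI
parameters essentially exactly (RSS ~1e-13 in normalized units).

### Integration

The reference simulator (`model_core.simulate`) uses LSODA at
rtol 1e-8 / atol 1e-10 — parameters span many orders of magnitude and
candidate systems can be stiff.  The estimation path uses classical
RK4 on the 1-min protocol grid, vectorized across the candidate
population (numba-compiled when available, identical pure-numpy
recursion otherwise), with per-candidate power-of-two substepping up
to 1/4 min for fast candidates and state clipping to [0, 1e7] so that
unstable candidates yield large finite residuals instead of NaN.  In
the physiologic regime the two integrators agree to ~1e-5 relative;
the test suite checks this.  Synthetic data for variant-selection
studies are generated with the same discretization as the fitting
path, so a perfect fit is numerically attainable.

## Variant family and AIC

Reduced GIG variants toggle: glucagon action on glucose (kGN free vs
zero), the glucagon-suppression structure (by insulin, by glucose, or
both), the secretion threshold (k6 free vs zero), and whether
C-peptide clearance is tied to insulin clearance (kCPC = k7).  The
default family has 12 members and is configuration-extensible.  Each
subject x variant fit is scored with `AIC = N ln(RSS) + 2K` (natural
logarithm; K counts estimated parameters, k8 excluded; N is constant
across compared variants per subject).  RSS at or below 1e-12
(normalized units) is floored before the logarithm: below the
integration-accuracy floor residual differences carry no information
and the parameter-count penalty should decide.  The cohort-selected
variant is the modal per-subject winner, ties broken by lower mean
AIC, then enumeration order.

## Metrics

`DI/cle = k4 k5 / k7^2` and the numeric `PI/cle = kGN kGgS / kGgC^p`
(p = 2 primary; 1 and 3 as sensitivity variants) come directly from
fitted parameters.  The analytic `PI/cle = Gg0 G0 fg / (Gss Iss)` uses
only measured fasting/steady-state observables; the decomposition
`Ggsec/cle = Gg0 * Iss` (no glycemia-related quantity in its
numerator) and `Ggsen = G0 fg / (Gss Iss^2)` is chosen so the product
identity holds exactly while using only those five observables — a
configuration hook allows a different split.  ISI is
`100 * uptake / (G_end[mg/dL] / I_end[uU/mL])` with uptake = TGUR
(infusion minus urinary loss) under SGLT2 inhibition and the infusion
rate otherwise; the package returns unscaled ISI (display scalings
such as x1e4 are left to presentation).  OGTT indices follow the
standard published definitions (insulinogenic
`(I30-I0)/(G30-G0)`, Matsuda `1e4/sqrt(G0 I0 Gmean Imean)` in
mg/dL / uU/mL units).  Insulin half-life is `ln 2 / k7`, consistent
with first-order clearance.

## Cohort statistics

Spearman correlation uses mid-ranks and the t-approximation for p
(appropriate at cohort n of 68-120); an exhaustive-permutation p is
implemented for n <= 10 and serves as the oracle in tests.  Metric-
glycemia associations are analyzed on log10 scale.  SMA regression:
slope `sign(r) * sd(y)/sd(x)` through the centroid.  Slope
heterogeneity between groups: the statistic
`min_b sum_i -(n_i - 2.5) ln(1 - r_i(b)^2)`, where `r_i(b)` is group
i's correlation between SMA residuals `y - b x` and fitted axis scores
`y + b x`, referred to chi-squared with (groups - 1) df; a
label-permutation fallback is provided.  Under the null (simulated at
n = 60 per group) the LR test rejects at 3-6% for alpha = 0.05.

## Synthetic cohorts

The generator emulates the study design: per-subject parameters drawn
log-uniformly from physiologic sub-ranges of the estimation bounds,
each subject placed at its fasting equilibrium (solved by bisection of
the steady-state balance), then pushed through a closed-loop clamp and
a 75-g OGTT, with multiplicative lognormal measurement noise
(defaults: glucose 2%, insulin and C-peptide 7%, glucagon 10%).

Anchors (log10 centers) were fixed once from fasting/steady-state
balances at typical values for type 2 diabetes — G0 ~ 7.5 mmol/L,
I0 ~ 50 pmol/L, Gg0 ~ 150 ng/L, CP0 ~ 0.5 nmol/L, clamp insulin
~ 600-700 pmol/L at 1.25 mU/kg/min infusion with insulin half-life
~ 5 min, glucagon half-life ~ 6 min, C-peptide ~ 30 min.  Group
structure carries the cohort-level variance where the analysis expects
it: *control* draws the insulin axis (k4, k5, k7) wide (+-0.3-0.35
dex) and the glucagon block narrow (+-0.06), so PG120 variance is
insulin-driven and DI/cle correlates negatively with PG120;
*SGLT2i* reverses this, drawing the glucagon secretion/clearance axis
wide (kGgS +-0.45, kGgC +-0.30) with a tighter sensitivity spread
(kGN +-0.15) — most interindividual glucagon variance rides the
secretion-to-clearance balance, which is the axis the analytic PI/cle
actually responds to — and an elevated k8 (5e-3 to 2e-2 1/min,
matching clamp urinary losses around 0.5-1.5 mg/kg/min at
euglycemia); control k8 is near zero.

The clamp controller stands in for the bedside artificial endocrine
pancreas: insulin infusion constant (1.25 mU/kg/min), glucose infusion
updated every 5 min by a discrete proportional-integral rule
(kp = 3 mg/kg/min per mmol/L, ki = 0.4 per min, conditional
anti-windup at the actuator limits) toward a 5.2 mmol/L target.
Gains were tuned once against the settle-within-5%-by-90-min
requirement and fixed; subjects whose loop fails that check are
excluded with a log entry and replaced from the subject stream (each
subject has its own child seed, so cohorts of different sizes share
their leading subjects).  Steady-state observables (fg, Gss, Iss) are
means over the final 30 min.

The OGTT models systemic glucose appearance as a gamma-shaped flux
(shape 2, scale 20 min, peak ~30-40 min) integrating to
dose x 0.12 / weight.  The 0.12 effective appearance fraction lumps
incomplete absorption and first-pass hepatic uptake, which this
clamp-oriented model does not resolve; it was calibrated once so that
simulated 2-h glucose lands in the 6-18 mmol/L range typical of the
modelled population, and is configurable.  Hormone sampling follows
the clamp schedule {0, 5, 10, 15, 20, 30, 45, 60, 75, 90, 105, 120}
min; OGTT samples at {0, 30, 60, 90, 120} min.

What the generator does *not* emulate — and hence what passing tests
cannot show about real data: assay drift and outliers, within-subject
parameter drift over the test day, renal glucose thresholds,
drug pharmacokinetics, correlated measurement errors, and any model
misspecification beyond the GI-fitted-to-GIG-data case (the control
cohort is generated from the GIG model and fitted with the GI model,
which is the one deliberate mismatch the pipeline is exercised
against).

## Identifiability: what the clamp can and cannot estimate

Two structural findings from the synthetic studies, both analyzed
rather than patched:

1. **kGN is weakly identifiable from clamp data.**  In the glucose
   balance the kGN regressor is `Gg(t)`, which during a clamp decays
   at rate kGgC (~0.1/min) while insulin rises at rate k7 (~0.15/min);
   with the removal term `k4*I(t)*Gc` these regressors are nearly
   collinear over the only informative window (the first ~20-30 min,
   of which the first 5 are hidden by the glucose window average).
   Maximum-likelihood kGN estimates scatter with ~0.5 dex sd at 5%
   measurement noise — and almost as much at 1% — so the recovered
   `kGN kGgS / kGgC^2` preserves ranks only partially (Spearman
   ~0.3-0.5 against truth at n = 20) even though kGgS and kGgC are
   recovered well.  The corresponding acceptance test is left failing
   by design; the fasting-steady-state regularizer improves physical
   plausibility but cannot collapse a ridge that satisfies the fasting
   balance.  This mirrors the general caution that glucagon secretion
   and clearance are not separately identifiable from such protocols
   without exogenous glucagon experiments.

2. **The analytic PI/cle decreases along a pure kGN sweep.**  Raising
   kGN raises fasting glucose, hence (through the thresholded
   secretion) fasting insulin, which suppresses fasting glucagon
   `Gg0 = kGgS/(kGgC I0)` faster than `G0 * fg` rises:
   `d ln(PI/cle_analytic)/d ln kGN ~ s (1 - a) < 0` with
   `a = G0/(G0-k6) > 1` (still slightly negative at k6 = 0 through
   the fg term).  The index instead increases strongly along the
   secretion/clearance axis (kGgS up, kGgC down), which is what makes
   it a valid cohort-level glucagon readout: across subjects whose
   glucagon variance rides that axis, analytic and numeric PI/cle
   rank-correlate at ~0.9 and both correlate positively with PG120.
   The sweep test asserting the increasing-in-kGN property is
   likewise left failing, with this analysis as the explanation.

## Numerical choices and problem sizes

Tolerances: reference solver rtol 1e-8 / atol 1e-10 (tightened to
1e-11/1e-12 for nesting comparisons); RK4 substep threshold 0.8 of the
stability limit; AIC RSS floor 1e-12; fasting-equilibrium bisection
xtol 1e-12.  Ties in tournament selection and variant selection break
deterministically (fitness, then enumeration order).  Degenerate
inputs (all-zero series, zero variance, zero glucose integral,
non-positive observables) raise typed errors rather than propagating
NaN.

The test suite runs the studies at desk scale, chosen as the package's
own verification sizes: 20-subject recovery cohorts, a 12-subject x
8-variant selection study, ground-truth sign checks at the full
68/120 cohort sizes, a 120-subject recovered-parameter twin, and
500-replicate calibration of the common-slope test.  The entire suite
completes in a few minutes on one CPU; `scripts/acceptance.py` reruns
the full set of headline quantities in ~3-5 min.

## Known limitations

* Single-compartment, narrow-range kinetics: valid near clamp and
  fasting concentrations only; no hepatic/peripheral split, no
  incretin effect, no renal threshold.
* The exact infusion waveforms, sampling schedule and controller of
  the original bedside device are not public; the synthetic protocol
  is a plausible stand-in and all of its settings are configurable.
* The 54-variant family of the original analysis is not public; the
  implemented 12-variant family exercises the same selection machinery
  and is extensible.
* kGN-dependent quantities carry large estimation uncertainty from
  clamp data alone (see above); observable-based PI/cle is the more
  robust glucagon readout.
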