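# Methods

## Scope and data model

The package analyses single-dose crossover PK studies of an evening-dosed
delayed-release/extended-release (DR/ER) methylphenidate formulation and an
immediate-release (IR) comparator. Data are long-format observation tables
(subject, sequence, period, treatment, time post-dose in hours, plasma
concentration in ng/mL). Clock times never enter computation; the predose
sample (drawn minutes before dosing) is recorded at time 0. Concentrations
below the assay's lower limit of quantitation (LLOQ, 0.02 ng/mL) are
replaced by exactly 0 before analysis and the raw value is not retained —
the substitution is idempotent and applied on read. No support is provided
for urine data, metabolites, or enantiomer-specific concentrations.

## Noncompartmental analysis

AUC<sub>0–t</sub> uses the linear trapezoidal rule up to the last positive
concentration, with linear interpolation at non-sampled window boundaries
for partial AUCs. AUC<sub>0–∞</sub> = AUC<sub>0–t</sub> + C_t/λ_z, defined
only when C_t > 0 and λ_z exists. λ_z is minus the slope of the
least-squares regression of ln C on t over a terminal window of at least 3
positive points strictly after T_max. Because terminal-window selection is
rarely reported, the default policy is the WinNonlin-equivalent "best fit":
every suffix window is scored by adjusted R², the best wins, and ties
within 10⁻⁴ go to the longer window; a manual per-profile window override
is available. Interior zeros stay in the trapezoids (the piecewise-linear
interpolant is well defined) but are excluded from the log regression.
T_max ties break to the earliest time. Arm summaries report the arithmetic
mean, CV% with the sample (n−1) SD, median, range, and geometric mean;
summaries are computed per subject and then averaged, so the reported mean
t<sub>1/2</sub> is *not* ln 2 / (mean λ_z) and no such identity is enforced.

The early-exposure fraction — the share of total exposure accrued in the
first 10 h, which for an 8–9 PM dose is the overnight window — uses
AUC<sub>0–t</sub> as denominator rather than AUC<sub>0–∞</sub>:
AUC<sub>0–t</sub> is always defined, and the extrapolated share of AUC is a
few percent for these profiles, so the distinction is immaterial. Both the
window end and the denominator are configurable.

## Average bioequivalence

Exposure metrics are ln-transformed and modelled with sequence, period and
treatment as fixed effects and subject as a random effect, following the
FDA average-bioequivalence convention. For complete data (every subject has
every treatment) the model is estimated as the fixed-subject-effects OLS
crossover ANOVA — numerically identical to the REML mixed model in that
case, with sequence absorbed by the subject effects. Residual degrees of
freedom are n−2 for the 2×2 and 2n−4 for the six-sequence 3×3 Latin square.
Incomplete data fall back to REML (statsmodels MixedLM) with a containment
df rule, N_obs − n_subjects − (n_periods−1) − (n_treatments−1), which
reproduces the balanced-case df exactly; Satterthwaite approximations are
not implemented. Geometric LS means are back-transformed equal-weight
averages over factor levels; the 90% CI is exp(Δ ± t₀.₉₅,df·SE(Δ)); the
intrasubject CV is 100·√(exp(σ²_within) − 1) from the residual variance.
All pairwise contrasts of a three-treatment study come from one model fit,
with no multiplicity adjustment (the convention for 90% CI equivalence
testing). Equivalence limits 0.8–1.25 are inclusive. Dose-normalization
(for dose-proportionality and relative-bioavailability questions) happens
before the ln-transform. Everything is carried at full precision; rounding
to 3 decimals happens only in rendered tables. Replicate-design scaled
average bioequivalence and nonparametric T_max comparisons are out of
scope.

## One-compartment lag-time model

C(t) = scale·D·k_a/(k_a − k_e)·(e^(−k_e·(t−t_lag)) − e^(−k_a·(t−t_lag)))
for t > t_lag and 0 before, with scale = F/V in (ng/mL)/mg. Within a
relative tolerance of 10⁻⁸ of the diagonal k_a = k_e the limit form
scale·D·k_a·(t−t_lag)·e^(−k_a·(t−t_lag)) is used (continuity verified to
<10⁻⁵ in tests). Fitting a mean profile minimizes the unweighted sum of
squared concentration residuals — the appropriate objective when the target
is a single arithmetic-mean curve rather than subject-level data (no
population/mixed-effects estimation, by design). Optimization is
multi-start (k_a grid {0.2, 0.5, 1, 2}/h plus the flip-flop mirror of each
start; k_e started at the terminal slope; t_lag at the last all-zero
sampling time, bounded by the first positive one; scale from C_max) in
log-parameter space with tight tolerances, so the result is deterministic.
Because the biexponential is symmetric under k_a ↔ k_e, the reported
solution is the best-RSS minimizer whose k_e is closest to the NCA terminal
slope; the opposite ordering is exposed in the fit diagnostics rather than
discarded.

Multiple dosing uses superposition (linear kinetics): doses every τ hours,
C(t) = Σ_d C₁(t − (d−1)τ). Within-interval C_max is read from a 0.05-h grid
with local quadratic refinement (grid-converged well below 0.1% for these
rate constants); the trough C_min of dose n is the concentration exactly
τ = 24 h after that dose, evaluated analytically as Σ_{k≤n} C₁(kτ). When τ
vastly exceeds the washout time, each interval is evaluated only over its
numerically non-zero support. The closed-form steady state
scale·D·k_a/(k_a−k_e)·[e^(−k_e u)/(1−e^(−k_e τ)) − e^(−k_a u)/(1−e^(−k_a τ))]
with u = (t − t_lag) mod τ handles the pre-lag carry-over of the previous
dose automatically, and is proven equivalent to long-run superposition in
the tests (<10⁻⁶ ng/mL). Steady state is declared at the first dose whose
trough is within 1% of the closed-form trough. Accumulation ratios divide
the steady-state metric by the single-dose metric.

## Synthetic-study generator

The generator emulates the data-generating structure the analyses assume;
it is the package's test bed, not a record of any real dataset. Population
parameters (chosen once, to place the noiseless curves at the documented
landmarks):

| arm | k_a (1/h) | k_e (1/h) | t_lag (h) | scale ((ng/mL)/mg) |
|---|---|---|---|---|
| DR/ER (fasted/sprinkled) | 0.42 | 0.1192 | 10.0 | 0.203 |
| DR/ER fed | 0.285 | 0.1192 | 12.5 | 0.203 |
| DR/ER (vs-IR study) | 0.42 | 0.1192 | 10.0 | 0.1411 |
| IR | 1.6 | 0.191 | 0.0 | 0.306 |

These put the DR/ER peak at 14 h on the dense sampling grid (0, 2, 4, 6, 8,
8.5, …, 24, 36, 48 h) with terminal slope ≈ 0.119/h, C_max ≈ 12 ng/mL and
AUC<sub>∞</sub> ≈ 170 ng·h/mL at 100 mg, zero exposure before 10 h, and the
IR peak at 1.5 h on its own grid (0, 0.25, …, 24 h). The fed modifier adds
2.5 h of lag and reduces k_a so the model C_max drops ≈12% while AUC
(= scale·D/k_e) is exactly unchanged — a scale reduction would wrongly cut
AUC too. In the comparative-bioavailability configuration the DR/ER scale
is set so the true dose-normalized AUC ratio versus IR is 0.739 (colonic
delivery absorbs only ~74% of the released dose); because the two
formulations have different terminal rate constants this is a constraint on
scale/k_e ratios, not on scale alone.

Between-subject variability is lognormal on k_a/k_e/scale (default CVs
30/25/30%, drawn once per subject and shared across periods — subject is
the random effect; no subject-by-treatment interaction), with median equal
to the population value so geometric-mean contrasts are preserved exactly.
t_lag gets a truncated-normal jitter (SD 0.5 h, floor 8 h): the release
delay is the formulation's most tightly controlled feature, and these
defaults reproduce the low between-subject T_max CVs (≈6–14%) such
formulations show. Residual assay error is proportional (CV 10%) plus
additive (SD 0.02 ng/mL = LLOQ), applied only to samples that contain drug
— a sample with zero true concentration reads back sub-LLOQ and hence
exactly 0 — then clamped at zero and LLOQ-substituted. An optional
occasion-level lognormal multiplier on scale creates within-subject
variability of a configured CV; with it the 2×2 log-scale model is exactly
correct, which is what makes the `generate_true_ratio_study` harness a
clean calibration target (the test arm's population curve is the reference
curve times the requested ratio, sharing regimen, schedule and subject
draws, so the true geometric-mean ratio of every scale-linear metric is
exact). Draw order is fixed (subject parameters first, then per-period
occasion and residual draws), so studies are bit-reproducible from the
seed.

What the generator does *not* emulate: enantiomer kinetics, circadian
elimination, drop-out, sampling-time deviations, or any real
between-study differences — so passing tests demonstrate correctness of
the analysis machinery under the assumed model, not agreement with any
particular clinical dataset.

## Numerical and design choices

* Trapezoid windows outside the observed range raise; degenerate inputs
  (all-zero profiles, flat tails, <3 terminal points) yield "metric
  missing" rather than numbers.
* λ_z recovery on noiseless fast-absorption curves is within 1% of k_e;
  with slow absorption (flip-flop regime) the terminal slope reflects
  absorption, which is why the DR/ER parameterization keeps k_a > k_e.
* CI coverage of the bioequivalence machinery is checked by simulation
  (500 seeded replicates at true ratio 0.9, intrasubject CV 20%, n = 18;
  nominal 90%).
* Problem sizes throughout (20/18/12 subjects, 500 calibration replicates,
  0.05-h simulation grids) match the emulated designs and keep every
  check deterministic and fast on one CPU.
* The acceptance script derives independent sub-seeds from one user seed
  via `numpy.random.SeedSequence`, so all reported quantities are
  recomputed from scratch at run time.

## Known limitations

* The REML fallback's df rule is containment-style, not Satterthwaite;
  for severely unbalanced designs the CI may be slightly conservative or
  liberal.
* The linear trapezoidal rule overestimates AUC on convex decline
  (log-down trapezoids are not implemented in v1); the bias is immaterial
  at the dense sampling schedules used.
* Fitting the arithmetic-mean profile pools subjects with different lags
  and rates; the fitted parameters describe the mean curve, not any
  subject, and with noisy small-n means the k_a/k_e split can drift toward
  the degenerate k_a ≈ k_e ridge while still describing the curve well.
* No replicate-design bioequivalence, no two-compartment or
  transit-absorption models, no plotting beyond the data needed to make
  one.
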