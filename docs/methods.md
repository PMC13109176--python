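# Methods

This note documents the models, estimation procedures, generator design
and numerical choices behind `betasens`, in enough detail to reproduce or
audit any stage.

## C-peptide kinetics

C-peptide is cleared with two-compartment kinetics, so plasma C-peptide is
the convolution of pancreatic secretion with a two-exponential impulse
response

```
h(t) = A1 e^{−λ1 t} + A2 e^{−λ2 t},      λ1 > λ2 > 0,
```

with `∫ h dt = A1/λ1 + A2/λ2` available in closed form (used as the
quadrature oracle in tests). `CPeptideKinetics.population(age, bsa)`
builds per-participant parameters from the standard population estimates:
fast half-life 4.95 min carrying fraction 0.76 of a bolus, slow half-life
`0.14·age + 29.2` min, distribution volume `1.11·BSA + 2.04` litres. A 1
pmol bolus therefore peaks at `10⁻³/V` nmol/l. Fixed user-supplied
constants are accepted through the same type; every forward and inverse
computation in the package uses the same kinetics object, so round-trip
validation does not depend on the particular constants.

Units throughout: glucose mmol/l, C-peptide nmol/l, ISR pmol min⁻¹ m⁻²
(per m² of body surface area, supplied per participant), total output
nmol m⁻², βGS pmol min⁻¹ m⁻² per mmol/l, rate sensitivity pmol m⁻² per
mmol/l.

## Deconvolution

`deconvolve` reconstructs ISR on a 5-min grid by nonnegativity-constrained
regularized least squares:

```
min ‖C − H s‖² + w ‖D₂ s‖²   subject to s ≥ 0,
```

where `H` convolves a piecewise-linear secretion profile with `h`
(trapezoid rule on a 1-min grid) and `D₂` is the non-uniform
second-difference operator (exactly zero on affine profiles). The profile
is held at its t = 0 value for all earlier times — the pre-test steady
state — which is what makes the steady-state identity
`ISR = C/(A1/λ1 + A2/λ2)` exact for constant inputs. The smoothing weight
defaults to 0.1 with the penalty scaled by the kernel area so it lives on
the C-peptide residual scale. A step profile whose rise spans one grid
interval is recovered within a few percent from densely sampled noise-free
data; a true discontinuity is not representable in the piecewise-linear
class and rings at the jump, which is a resolution statement, not an
estimation failure.

## Beta cell model fit

The model is `ISR(t) = p(t)·f(G(t)) + k·max(dG/dt, 0)`:

* `f` — piecewise linear in glucose with knots at the observed-range
  quantiles (3 interior knots), node values ≥ 0;
* `p` — piecewise linear in time on nodes (0, T/2, T), nonnegative,
  time-average over the test constrained to 1;
* `k` — rate sensitivity on the positive part of dG/dt, computed by
  central differences on the sample grid and interpolated to the fine
  grid.

Model C-peptide is the model ISR convolved with `h` (1-min grid, pre-test
steady state as above) times BSA. Observations are weighted ∝ 1/C
(normalized to mean 1): assay noise is multiplicative, so relative
weighting is the appropriate likelihood.

**Identification.** A standard 6-sample MMTT under-determines a free joint
fit: many exact-fit decompositions of the curve into dose–response,
potentiation and rate components exist, and plain alternation from p ≡ 1
stalls in one of them (typically rate → 0 and a flattened potentiation).
Estimation therefore proceeds by profiling the affine component of the
potentiation factor: for each candidate tilt φ on a deterministic grid
(step 0.05 over ±0.8, refined at 0.005 around the optimum), the remaining
parameters (f nodes, k) solve a single NNLS problem with a curvature
penalty on `f` (weight 30, scaled by kernel area × BSA so it is on the
C-peptide residual scale; zero for affine f, so a linear truth is never
penalized). The final estimate is the quadrature-weighted posterior mean
over all evaluated tilts, with a Gaussian likelihood whose temperature is
the minimum residual divided by 2 degrees of freedom: at zero noise the
posterior collapses onto the exact tilt (recovery of βGS, rate
sensitivity and potentiation ratio is then exact to ≲ 2%), while under
noise the averaging suppresses the variance of the flat directions of the
profile objective. One further pass then allows smoothness-penalized
curvature in `p` (weight 1.0 on the second difference per unit of
*normalized* test time — measured per minute² the penalty would be
numerically inert). Finally `p` is rescaled so its time integral over the
test equals T exactly (`p ← p/mean(p)`, `f ← f·mean(p)`; the ISR product
is unchanged), which enforces the mean-1 convention to 10⁻⁶.

βGS is `(f(G_max) − f(G_min))/(G_max − G_min)`. AUC_Cp and its
incremental variant use the trapezium rule directly on the samples,
independent of the fit. If the observed glucose span is below 0.5 mmol/l
the slope is unidentifiable: the fit is flagged, βGS is NaN, and basal
ISR falls back to the steady-state deconvolution value.

**Quality control.** A test is flagged when the fit R² is below 0.7 or
the Spearman correlation between the glucose and C-peptide series is
below −0.5 (a strongly inverted excursion indicates measurement or
labelling error). On synthetic cohorts corrupted at the default 3.7%
rate, flagging catches essentially all inverted-excursion corruptions and
the flagged fraction tracks the injected rate.

**Accuracy at the validation sizes.** On 200 forward-simulated tests:
noise-free, ≥ 95% of βGS estimates fall within 5% of truth (in practice
all of them, max ≈ 0.05%); at a 5% CV C-peptide assay the cohort median
relative error is ≈ 8.5%, stable across seeds. Adding the generator's 2%
glucose assay CV on top raises the median to ≈ 10–11% — an
errors-in-variables effect on the dose–response abscissa that no amount
of C-peptide fitting can remove; analyses of noisy cohorts should expect
per-test βGS noise of that order, which is why normalized-trajectory and
survival analyses pool across participants.

## Synthetic cohort generator

The generator produces the three trial tables (participants, visits,
MMTT samples) plus a ground-truth table that downstream stages never
read. What it emulates:

* **Enrolment** at clinical onset in three age strata (children 3.5–11.9,
  adolescents 12–17.9, adults 18–45) with mix 0.22/0.40/0.38, matching
  the relative sizes reported for pooled stage 3 cohorts; sex balanced;
  BMI and BSA drawn per stratum.
* **βGS decline**: baseline βGS lognormal (median 35, σ_log 0.4, same in
  every arm), declining exponentially at stratum rates 0.65/0.50/0.32
  per year (children fastest) with lognormal individual frailty
  (σ_log 0.15). A trial's drug multiplies the decline rate by
  `treatment_effect` while its effect window is active; 1.0 is a null
  drug, 0 halts the decline. Normalized βGS is exactly 1 at baseline and
  available in closed form (`true_nbgs`), which is the trajectory oracle
  used in tests.
* **Glycaemia coupling (deliberate AUC confounding).** The dose–response
  is anchored at an absolute 4 mmol/l glucose threshold; fasting glucose
  is `4 + 70/βGS` and the meal excursion `157.5/βGS` (both clipped to
  physiologic ranges), so basal and meal-stimulated secretion *output*
  are largely preserved while βGS falls: the hyperglycaemia of a failing
  beta cell drives the remaining cells harder. This is what makes
  AUC_Cp a lagging endpoint in the generated data — normalized AUC_Cp
  separates treated from placebo arms much later (or never, at modest
  sample sizes) than normalized βGS, the central contrast the pipeline
  is designed to expose. Rate sensitivity (lognormal, median 300) and
  the potentiation tilt (uniform over ratios 1–1.9) are constant per
  participant and do not decline, further diluting AUC contrast.
* **MMTT curves**: parametric glucose (gamma-like rise to a peak at
  60–90 min, partial return by 120 min) sampled at 0/15/30/60/90/120 min;
  C-peptide by forward convolution of the model ISR with the population
  kinetics, pre-test steady state included; multiplicative assay noise
  (5% CV C-peptide, 2% glucose by default). The rate component uses
  central differences on the sampling grid, i.e. the generator encodes
  the information content actually available to the fit.
* **Clinical trajectories**: HbA1c is a logistic-shaped decreasing
  function of true βGS (`44 + 26/(1+exp((βGS−12)/5))` mmol/mol) plus
  noise, with an elevated pre-management baseline (N(58, 6)); insulin
  dose increases as βGS falls. The couplings are chosen so that roughly
  half the cohort can hold HbA1c < 53 mmol/mol at 12 months and a
  baseline model has real signal to find — test-harness choices, not
  physiology claims.
* **Schedules**: visits clustered at 0/3/6/12/18/24(/30) months with
  ±0.4 month jitter (baseline exactly 0); optional uniform dropout,
  default none.
* **Discordant tests**: a configurable fraction (default 0.037) of tests
  is corrupted — C-peptide excursion inverted about its baseline, or one
  mid-test sample turned into a gross outlier — with truth labels
  returned for QC sensitivity analysis.

What it does **not** emulate: immune markers, mechanistic
glucose–insulin feedback, pharmacokinetics beyond the effect window,
missing visits beyond simple dropout, assay drift, or between-trial
differences in procedures. Passing tests on these cohorts demonstrates
that the pipeline recovers known structure under realistic noise and
confounding; it does not validate the physiologic model against real
trial data.

Everything is driven by one `numpy` Generator seeded from the config;
identical configs give byte-identical tables.

## Endpoints

Flagged tests are dropped before normalization; a participant whose
baseline test is flagged is excluded entirely (with a logged reason), as
is one lacking a positive baseline βGS and AUC_Cp. nβGS and nAUC_Cp are
ratios to the participant's own month-0 value (exactly 1 at baseline).
Events are recorded at the first post-baseline visit crossing the
threshold — no interpolation between visits, since endpoints are only
observable at MMTT visits — otherwise censoring at the last visit.
HbA1c is canonically mmol/mol; percent values are detected (< 20) and
converted by the NGSP–IFCC relation `% = 0.09148·(mmol/mol) + 2.152`
(53 mmol/mol ↔ 7.0%). Follow-up intervals are binned right-closed at
6/12/18/24/30 months with an open-ended final interval; month 0 is its
own "baseline" label.

## Survival analysis

Each treatment arm is compared against the *pooled* placebo (all trials'
placebo arms). Cox models use Efron tie handling — visit-month clustering
makes heavy ties the norm — with covariates coded as sex (male vs
female), age per 10 years, and BMI per SD of the analysis cohort
(treatment arm + pooled placebo; the SD used is reported in the output
for transparency). Time-to-endpoint analyses at a horizon recode later
events as censored at the horizon. Kaplan–Meier CIs are log-log
(exponential Greenwood). The proportional-hazards diagnostic compares
log cumulative hazard (Nelson–Aalen) curves between groups on a grid of
event-time quantiles and reports the maximum deviation of their offset
from its median; parallel curves give small deviations, crossing hazards
large ones. All p-values are two-sided. Estimation is delegated to
`lifelines`; tests verify it against a hand product-limit fixture, a
hand log-rank computation, and an independently coded Efron
partial-likelihood maximization.

## Prediction of 1-year HbA1c response

The outcome is an HbA1c decrease of ≥ 5.5 mmol/mol (0.5%) from baseline
to the visit nearest 12 months within (6, 18] (boundary inclusive).
Predictors are baseline age, insulin dose, HbA1c and natural-log βGS,
each standardized to unit SD on the complete-case analysis sample, so
odds ratios are per-SD; multivariate and univariate ORs are reported with
Wald CIs. Discrimination is the in-sample ROC AUC (trapezoid over the
tie-grouped empirical ROC, equal to the midrank Mann–Whitney concordance)
with no optimism correction. Separation or singular information flags the
result rather than raising.

## Positive-vs-negative time course

Trial outcome labels (positive/negative) are configuration inputs. Only
drug-treated participants enter; per interval and metric the earliest
in-interval value per participant is used (one value per participant, no
pseudo-replication), compared by two-sided Mann–Whitney with medians and
IQRs reported. Intervals with an empty group are reported as missing.

## Validation problem sizes

The heavy suite checks run at: 200 forward-simulated tests per noise
regime (round trip); 400 replicates for Cox CI coverage at n = 500/arm,
true HR 0.5; 500 null replicates each for log-rank and Mann–Whitney
type-I error; 200 replicates of a one-trial 25-per-arm cohort through
simulate → fit → endpoints → Cox for the null-bias check (|mean log HR| <
0.05); 10 replicates at 150/group for the 3-month early-detection power
contrast (using a decline-halting positive-trial effect, which is what
positive immunotherapy trials look like early on). The full suite runs in
about five minutes on one CPU.

## Known limitations

* The potentiation factor is low-resolution (3 time nodes): a 6-point
  MMTT cannot support more structure. Its ratio is well recovered at low
  noise but is the noisiest output at 5% CV.
* Rate sensitivity is weakly identified when glucose rises slowly; its
  per-test error at realistic noise is large, and analyses should treat
  it as a cohort-level quantity.
* Per-record (repeated-MMTT) Cox risk sets are not implemented; all
  survival analyses are participant-level first-crossing. The event-count
  bookkeeping reflects that construction.
* The generator's couplings are calibrated for qualitative realism
  (confounded AUC, age gradient, attainable responder fractions), not
  fitted to any dataset; absolute effect sizes in the demo analyses are
  illustrative.
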