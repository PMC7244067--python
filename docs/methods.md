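# Methods

## The estimation problem

Red cells import creatine while young: the membrane creatine transporter
keeps the intracellular concentration tens of times above plasma, and —
because the mature erythrocyte has no nucleus — lost transporters are never
replaced, so the gradient decays over the cell's life. The erythrocyte
creatine concentration (EC) of a blood sample is therefore an age signal: a
population rich in young cells (hemolysis) shows high EC. rbcage turns that
signal into an estimate of the mean erythrocyte age *M*<sub>RBC</sub>.

## Calibration and inverse prediction

The calibration regresses ln EC (response) on *M*<sub>RBC</sub> (predictor):

    ln EC = a·M_RBC + b,    a = −0.04379 /day,  b = 2.882,

fitted on 21 hemolytic-anemia subjects whose *M*<sub>RBC</sub> came from
⁵¹Cr half-lives (below). The estimator is the **algebraic inverse**

    M_RBC = (1/a)·ln EC + (−b/a),

not a re-regression of *M*<sub>RBC</sub> on ln EC — the two differ, and only
the algebraic inverse is consistent with the forward fit. `published_model`
carries the reference constants exactly as printed (inverse −22.84 and
65.83); because those were inverted from unrounded coefficients, they differ
in the third decimal from inverting the printed forward pair (−22.8363,
65.814). `invert_model` implements the algebra; both are exposed and tested
against their own source.

Fit strength: Pearson *r* between *M*<sub>RBC</sub> and ln EC, t = |r|·√df /
√(1 − r²) with df = n − 2, and a two-sided p from the central t distribution
(the standard correlation test). Estimates outside the calibrated EC range
1.45–11.76 μmol/g Hb are returned but flagged `extrapolated` — including
the standard value 1.4, which sits just below the range minimum — and
non-positive ages (EC > e^b ≈ 17.8) are flagged `implausible` rather than
suppressed, so batch users keep the full information. The quoted lifespan is
2·*M*<sub>RBC</sub>, valid only under the uniform-age model below.

## Units

EC in mg/dL of packed red cells converts to μmol/g Hb by dividing by
MW × MCHC / 1000 = 131.15 × 33 / 1000 = 4.32795 (displayed as 4.328).
Internals always use the unrounded divisor to avoid compounding rounding
error. MCHC (default 33 g/dL) is configurable globally and per subject,
since it falls in iron-deficiency anemia.

## ⁵¹Cr survival and the ×2.61 rule

Red-cell death is age-determined, not memoryless, so a labelled cohort does
not decay exponentially: with a common lifespan L and steady production,
cell ages are uniform on [0, L], the surviving labelled fraction is
1 − t/L, and the mean age is L/2. Label elution from intact cells
multiplies survival by e^(−λ_e t), shortening the *apparent* half-life below
L/2. The working rule *M*<sub>RBC</sub> ≈ 2.61 × half-life (2.61 being the
printed rounding of 60/23; the exact ratio is selectable) compensates: with
L = 120 d and λ_e calibrated so the apparent half-life is the normal 23 d
(λ_e = 0.020885/d, closed form −ln(0.5/(1 − t/L))/t), the rule returns
60.03 d, within 0.1 d of the true mean age. The simulator observes the
*uncorrected* apparent half-life — the quantity the calibration was built
on — and also exposes the elution-corrected one (exactly L/2) for
comparison. The apparent half-life is located by bisection (tolerance
10⁻⁹ d); a test confirms it inverts the closed-form calibration to 10⁻⁶.

The anchor target of 23 d (rather than 25 or 27, the rest of the normal
range) is chosen because the 2.61 factor is itself built from 23.

## Creatine kinetics

Single-cell model — the minimal ODE consistent with a transporter influx
decaying as B·e^(−λ₂t) (transporters are lost randomly and never replaced)
and a first-order diffusive leak with rate constant λ₁:

    dC/dt = B·e^(−λ₂t) − λ₁·(C − C_p),   C(0) = C₀,

with closed-form bi-exponential solution, switching to the degenerate limit
C_p + (C₀ − C_p)e^(−λt) + B·t·e^(−λt) when |λ₁ − λ₂| < 10⁻¹⁰·max(λ₁, λ₂) to
avoid catastrophic cancellation. C_p defaults to 0 (plasma creatine is
second-order against the intracellular level). A subject's mean EC is the
uniform-age average (1/L)∫₀^L C(t) dt, in closed form (verified against
adaptive quadrature to 10⁻⁸ relative over random parameter sweeps).

**Which wing carries the observed slope is unidentifiable** — it may be λ₁
(diffusion) or λ₂ (transporter decline); the module exposes both and decides
nothing.

### The anchored preset, and a saturation effect worth knowing about

The "anchored" preset is the mono-exponential wing (B = 0) with
λ₁ = 0.04379/d — the calibration slope read as the **cell-level** rate
constant, which is the identification the calibration itself rests on — and
C₀ = 7.3953 μmol/g Hb so the population mean EC at *M*<sub>RBC</sub> = 60 d
is the standard 1.4 μmol/g Hb.

Uniform-age averaging flattens the population curve relative to the cell
curve: mean EC ∝ (1 − e^(−2λm))/(2λm) decays asymptotically like 1/m, so the
least-squares log-slope over *M*<sub>RBC</sub> ∈ [15, 60] d is bounded in
magnitude by ≈ 0.0291/d *for every* λ₁. Two consequences are documented in
the tests rather than papered over:

* `fit_rate_to_slope` (root-finding λ₁ so the population log-slope matches a
  target) correctly reports *no solution* for targets steeper than the
  bound, including −0.04379 on [15, 60];
* the anchored preset's population curve is close to, but not above,
  r² = 0.99 on [15, 60] (it evaluates to 0.9899): under this model the
  observed slope lives at the cell level, and the population-averaged curve
  is slightly more curved than a perfect exponential. The package treats
  this as a property of the reconstruction, not a tunable: choosing
  λ₁ ≤ 0.031 would push r² above 0.99 but would sever the preset's anchor to
  the calibration slope, so it is not done.

## Synthetic cohorts

The 21-patient reference table is not redistributable, so the generator
emulates its structure; results on synthetic cohorts demonstrate internal
consistency of the pipeline, not clinical validity on real patients.

* **Empirical mode** (the default study conditions): n = 21,
  *M*<sub>RBC</sub> uniform on [10, 60] d (the range implied by inverting
  EC 1.45–11.76; the true patient values are unpublished), ln EC on the
  calibration line plus Gaussian noise. The noise SD is closed-form
  calibrated to a target |r|: σ = |a|·sd(M)·√(1/r² − 1) = 0.2133 for
  |r| = 0.9475 — so the fitted model's residual assumptions hold exactly.
  The ⁵¹Cr axis is treated as the reference (noise off by default; optional
  Gaussian SD for sensitivity studies). Severity groups split at the range
  midpoint, mimicking the severe/mild structure without inventing clinical
  criteria.
* **Mechanistic mode**: lifespans uniform on [20, 120] d; EC from the
  kinetic population mean with multiplicative Gaussian noise (default CV 5%,
  a typical analytic CV for colorimetric creatine assays; redrawn while
  non-positive), and the half-life from the elution survival model with a
  shared λ_e (default anchored to 23 d at L = 120). Log-linearity here
  *emerges* from the mechanism (r² > 0.98 against the Cr-derived age axis).

Both modes are deterministic given a seed (identical seeds give
byte-identical CSV). What the generator does **not** emulate: disease-
specific EC biology (thalassemia, spherocytosis), assay-chemistry
differences, reticulocyte creatine loading, per-subject MCHC variation in
the historical cohort, or non-uniform true age distributions — so passing
tests certify the statistical machinery, not those aspects of real data.

### Group comparison

`compare_group_fits` reproduces the severe/mild contrast: on a linear EC
scale the two groups show clearly different regression lines, on the log
scale they (nearly) unify. "Unified" is defined as the pooled log-scale r²
exceeding the pooled linear-scale r². For mechanistic cohorts the group
log-slopes still differ noticeably (the population curve is genuinely
curved, so the steep/shallow halves have different local slopes); the tests
assert the robust qualitative ordering — log-scale disagreement far smaller
than linear-scale — rather than a fixed percentage.

## Numerical choices

* Printed constants (2.61, 4.328, −22.84/65.83) are used for display and
  reference-model anchors; internal arithmetic is unrounded.
* Root finding: Brent/bisection with 10⁻⁹–10⁻¹² tolerances; the λ₁ search
  bracket is [10⁻⁵, 1] per day.
* Exact fits (|r| = 1) return t = ∞, p = 0 instead of failing the
  correlation test.
* Degenerate inputs raise typed exceptions (`RBCAgeError` subclasses), with
  row numbers or subject ids where tabular input is at fault.

## Problem sizes

Simulation-based checks use 1000 replicates of n = 21 (slope and
correlation recovery), single cohorts of n = 2000–10000 (noise-calibration
closure), and 100-point random parameter sweeps for the quadrature
cross-check; the full suite runs in a few seconds.

## Known limitations

* Built entirely on the structure of a 21-patient historical dataset; no
  confidence or prediction intervals are provided for the inverse
  prediction, matching the source calibration.
* The kinetic ODE is a modelling assumption; the initial condition C₀ and
  the plasma term are not identifiable from calibration data.
* The uniform-age, common-lifespan population model is an idealization;
  lifespan = 2·mean age inherits it.
* Two normal anchors coexist (60 d textbook vs 58.14 d from the calibration
  at EC 1.4); both are reported, neither privileged.
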