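# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `viscowin`, in the spirit of a model
description a maintainer can audit.

## Constitutive model

HA in the joint space is treated as a linear viscoelastic,
shear-thinning fluid in the small-strain regime of ordinary gait. The
film is a single Kelvin–Voigt element — a spring (storage modulus G′)
in parallel with a dashpot whose viscosity follows the Carreau–Yasuda
law

η(γ̇) = η∞ + (η₀ − η∞)·[1 + (λγ̇)ᵃ]^((n−1)/a),

restricted to 0 < n ≤ 1 (shear-thinning or Newtonian; thickening is out
of scope). The stress under a strain waveform is
σ(t) = G′γ(t) + η(|γ̇(t)|)γ̇(t); the absolute shear rate makes the
dashpot direction-independent, so σ is odd under (γ, γ̇) → (−γ, −γ̇).

Products are tabulated by a single rheometric point (G′, η, tan δ at
37 °C and 10 s⁻¹), which under-determines the thinning profile. The
default calibration fixes a typical HA profile — a = 2, n = 0.5,
η∞ = 0, η₀ = 2·η_ref — and solves λ analytically so that
η(10 s⁻¹) = η_ref exactly. Every parameter is user-overridable; the
only datum the defaults pin is the tabulated point itself. Temperature
is fixed at 37 °C; no temperature model is included.

### Loss-modulus conventions

The tabulated loss tangents are not numerically consistent with
η·ω/G′ at any single oscillation frequency across the reference
products (the implied ω ranges roughly 0.5–1.0 rad/s), which simply
reflects that viscometric and oscillatory measurements are independent.
The simulator therefore exposes both conventions for the reported
per-cycle energy: the default anchors to the oscillatory measurement
(W = π γ₀² G″ with G″ = tan δ·G′); the alternative (`"eta_omega"`)
reports the time-integrated hysteresis loop of the Kelvin–Voigt
element, which for constant viscosity equals π γ₀² η ω. No attempt is
made to reconcile the two.

## Joint and loading model

The joint is a zero-dimensional (lumped) cavity: synovial volume,
injected volume, body weight and an (accepted but currently unused)
capsular compliance. This is a deliberate replacement of 3-D
finite-element contact simulation: no meshes, geometries or cartilage
material constants are available to reproduce such models, and every
quantity consumed downstream (energy, residence, coverage class) is a
lumped scalar. Spatial outputs — pressure maps, distribution fields,
an "effective lubrication area" — are therefore out of scope; coverage
is reported only as the categorical class below.

Gait is strain-controlled and sinusoidal by default (a haversine pulse
train is available behind a flag): γ(t) = γ₀ sin(2πft) with f in
[0.5, 2.0] Hz (30–120 steps/min, one loading cycle per step). Loading
magnitude is specified in body-weight multiples (1–3× BW), but no
load-to-strain constant is available for a lumped film, so the default
maps γ₀ = 0.25 × (BW multiple), i.e. γ₀ = 0.5 at a typical 2× BW. This
keeps peak shear rates of gait (≈0.3–6 s⁻¹) inside the 0.1–100 s⁻¹
band over which the thinning law is parameterised; γ₀ is directly
configurable.

Injection-volume tolerance: the knee accepts the full 1–4 mL range.
Hip and shoulder accept ≤ 2 mL; 2–3 mL is borderline (efflux fraction
0.25) and ≥ 3 mL causes overdistension (efflux fraction 0.5). The two
fractions are plausible placeholders — the underlying observation is
qualitative — and are exposed as arguments.

## Simulation outputs

* **Energy per cycle**: trapezoidal loop area ∮σ dγ, averaged over the
  last ⌈n/2⌉ of the n cycles (the linear element has no transient; the
  averaging window guards waveform variants). With dt ≤ 10⁻³/f the
  integration matches the analytic ellipse area within 0.5 %.
* **Peak stress**: max |σ(t)|.
* **Residence half-life**: log-linear in molecular weight with anchors
  t½(0.5 MDa) = 18 h and t½(2.0 MDa) = 60 h — midpoints of the
  qualitative bounds "< 24 h" and "48–72 h" — capped at 72 h for
  heavier products, multiplied by 0.67 in KL III–IV joints (elevated
  synovial turnover; the factor is a configurable model constant) and
  by (1 − efflux fraction). Clearance is first-order (k = ln 2 / t½).
* **Coverage class**: `under_resistant` if G′ < 100 Pa or η < 30 Pa·s,
  `focal_pooling` if G′ > 250 Pa, else `conformal`. Inequalities are
  strict, so exact-threshold inputs are conformal.

## Window and alignment

Window boundaries (G′ 120–220 Pa, η 50–120 Pa·s, tan δ 0.4–0.6) are
closed intervals — the source ranges carry no strictness — while the
patient/joint modifiers use strict inequalities
(conc ≥ 20 mg/mL and G′ > 160 Pa for KL III–IV; volume ≤ 2 mL,
G′ > 180 Pa and η ∈ [60, 100] Pa·s for hip and shoulder, which share
one rule set). Alignment implies window membership by construction.
Of the four packaged reference products exactly HA-B and HA-C are
in-window.

## Synthetic cohort

The generator emulates the retrospective validation study's
*statistical structure*, not its patients:

* n = 126 (default), ages uniform on [45, 78], sexes balanced, BMI
  uniform on [22, 36] (restricted per stratum), daily step counts
  log-normal with median 5 500 and log-sd 0.45 (sedentary to > 8 000
  steps/day), gait frequency uniform on [0.5, 2.0] Hz, knee joints with
  synovial volume uniform on [5, 8] mL and a standard 3 mL injection.
* Arms and strata: aligned with probability 0.5; within the aligned arm
  strata A1 (KL II–III, BMI < 30), A2 (KL II–III, BMI ≥ 30), A3 (KL IV)
  with weights (0.40, 0.30, 0.30). The weights are chosen so the
  aligned-arm mixture responder rate, Σwᵢpᵢ ≈ 0.634, reproduces the
  reported alignment odds ratio (≈ 2.19 against the non-aligned rate
  0.441); they are configurable. The non-aligned arm spans KL I–IV.
  (The study text describes a KL I–III cohort while its subgroup table
  contains a KL IV stratum; the generator follows the table.)
* Formulation assignment is consistent with the alignment classifier:
  aligned KL II patients receive HA-B or HA-C, aligned KL III–IV
  patients HA-C, non-aligned patients HA-A or HA-D. A regression test
  re-derives the aligned flag through `alignment_label` for every
  generated patient.
* Outcome: womac = μ_s + β·z + ε with ε ~ N(0, σ_eps), z the patient's
  standard-normal activity score (the log-scale step-count deviation —
  the continuous, learnable component of benefit: active patients with
  a matched depot gain more), and
  μ_s = 30 + σ_tot·Φ⁻¹(p_s), σ_tot = √(β² + σ_eps²), clipped to
  [−100, 100]. By construction P(womac ≥ 30) = p_s per stratum, with
  p = (0.784, 0.652, 0.415, 0.441) for (A1, A2, A3, N). Age and sex are
  independent of outcome so crude and age/sex-adjusted odds ratios
  coincide asymptotically; BMI affects outcome only through stratum
  membership, which is why BMI is *not* in the default adjustment set
  (adjusting for a stratum determinant changes the estimand through
  non-collapsibility; the BMI-adjusted variant is available
  explicitly).

### Noise calibration

σ_eps and β are not free: `calibrate_noise` fixes them so that the mean
leave-one-out R² and RMSE of the default 2-component PLSR over
calibration cohorts (seeds 1–100, 24 used per evaluation) hit the
targets 0.61 ± 0.03 and 7.8 ± 0.5. The search is a nested bisection —
inner on β (R² is monotone in the signal scale at fixed noise), outer
on σ_eps (RMSE is monotone in the residual noise along the
R²-constrained path). The frozen result, σ_eps = 5.2068 and β = 10.0,
is the package default; verification on disjoint seeds (201–400) gives
mean R² ≈ 0.60 and RMSE ≈ 7.60. A target of R² = 1 is structurally
infeasible (the Bernoulli stratum structure and LOOCV estimation error
impose a noise floor) and raises a calibration error, as does an RMSE
below the floor.

Percentages are carried on the 0–100 scale throughout, so the RMSE is
in WOMAC percentage points.

### What the generator does not emulate

Real WOMAC subscales, longitudinal trajectories, inflammatory
covariates, site or injector effects, and any true mechanistic link
from the simulated mechanics to outcome — the feature signal is a
statistical stand-in whose strength was calibrated, not measured.
Passing validation tests therefore demonstrates that the statistical
machinery is correct and calibrated, not that the clinical effect would
replicate prospectively.

## Validation statistics

* **PLSR** is implemented as single-response NIPALS on internally
  standardised predictors (constant columns dropped with a warning),
  with the regression vector B = W(PᵀW)⁻¹q mapped back to the original
  scale. With all components it reproduces ordinary least squares to
  1e−8; scikit-learn's `PLSRegression` serves as an independent
  cross-check in the test suite, never as the implementation. The
  default of 2 components minimises mean LOOCV RMSE over calibration
  cohorts. Predictors: G′, η, tan δ, molecular weight, concentration,
  joint volume, loading frequency, BMI, KL grade, steps/day. The
  regression predicts the *continuous* WOMAC change (R²/RMSE are
  continuous-scale metrics); the binary endpoint is analysed
  separately.
* **LOOCV**: R² = 1 − Σ(yᵢ − ŷ₋ᵢ)²/Σ(yᵢ − ȳ)², RMSE in outcome units.
* **Odds ratios**: maximum-likelihood logistic regression
  (statsmodels; Newton/IRLS) of responder status on the alignment flag
  plus covariates, 95 % Wald intervals. With no covariates this equals
  the closed-form 2×2 ratio ad/bc to 1e−8, which the tests verify on
  random tables. Non-convergence (e.g. complete separation) raises a
  dedicated error.
* **Subgroup table**: per-stratum n, responder %, and crude OR against
  the pooled non-aligned arm. Adjusted per-stratum odds ratios are
  deliberately not produced: at the stratum level no adjustment set is
  defined that would not condition on a stratum determinant, so only
  the crude 2×2 ratios are reported.

## Numerical choices and degenerate inputs

* Time step dt ≤ 1/(100f) is enforced; the default 10⁻³/f gives 0.5 %
  loop-area accuracy. Trapezoidal integration throughout.
* λ-calibration is an exact analytic inversion; infeasible targets
  (η_ref outside the plateau interval, Newtonian n = 1) raise errors
  rather than returning boundary values.
* σ_eps = 0 makes the threshold construction degenerate and is
  rejected; probabilities must lie strictly inside (0, 1).
* Empty strata are reported as missing rows, not errors; an
  all-responder stratum reports an infinite crude OR.
* All generation is vectorised over one `numpy` Generator seeded from
  the config; the activity score is recomputed from the *stored*
  (rounded) step count so a persisted cohort file fully determines its
  outcomes.

## Problem sizes

The shipped verification and acceptance runs use 200 cohorts of n = 126
for the LOOCV metrics, 50 000 patients for the adjusted odds ratio and
200 000 per stratum for the responder rates — sizes at which the
Monte-Carlo error is comfortably below the comparison tolerances while
a full run stays in the seconds-to-minutes range on one core.

## Known limitations

* Single-point rheometry under-determines the thinning curve; two
  formulations with equal η(10 s⁻¹) but different true λ/n are
  indistinguishable to the calibrated defaults.
* The lumped joint cannot express varus/valgus asymmetry, pooling
  geometry or contact-pressure fields.
* The 0.67 turnover factor and the efflux fractions are plausible
  constants, not fitted quantities.
* Linear viscoelasticity only: large-amplitude (LAOS) behaviour,
  thixotropy and enzymatic degradation chemistry are out of scope.
* Multi-injection regimens and non-knee clinical validation are not
  modelled.
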