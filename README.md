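# viscowin

Viscoelastic-window modelling for intra-articular hyaluronic-acid (HA)
viscosupplementation in osteoarthritis.

Clinical response to HA injections is heterogeneous, and part of that
heterogeneity is mechanical: a formulation only protects a joint if its
viscoelastic profile matches the joint's loading environment. `viscowin`
is a toolkit for orthopaedic biomechanics and formulation researchers
that

1. **simulates** the in-joint behaviour of an HA depot under gait-cycle
   loading with a Kelvin–Voigt element whose dashpot follows a
   Carreau–Yasuda shear-thinning law,
2. **classifies** formulations against an *optimal viscoelastic window*
   (G′ ∈ [120, 220] Pa, η ∈ [50, 120] Pa·s, tan δ ∈ [0.4, 0.6] at 37 °C
   and γ̇ = 10 s⁻¹) with disease-severity (Kellgren–Lawrence) and
   joint-specific alignment modifiers, and
3. **validates** the alignment → outcome link statistically on synthetic
   knee-OA cohorts: partial least squares regression (NIPALS) of WOMAC
   improvement with leave-one-out cross-validation, covariate-adjusted
   logistic odds ratios and subgroup responder tables.

## Model

The stress in the HA film under a strain-controlled gait waveform
γ(t) = γ₀ sin(2πft) is

σ(t) = G′·γ(t) + η(|γ̇(t)|)·γ̇(t),

with the Carreau–Yasuda viscosity

η(γ̇) = η∞ + (η₀ − η∞)·[1 + (λγ̇)ᵃ]^((n−1)/a).

Per-cycle dissipated energy (damping) is the hysteresis-loop area
∮σ dγ, which for constant viscosity reduces to the analytic
W = π γ₀² η ω used as the simulator's oracle. Intra-articular residence
is a first-order clearance whose half-life is log-linear in molecular
weight (18 h at 0.5 MDa → 60 h at 2.0 MDa, capped at 72 h), shortened in
KL III–IV joints and by capsular efflux in over-filled hip/shoulder
cavities.

Because no patient-level data ships with the package, a synthetic-cohort
generator reproduces the validation study's structure: n = 126 knee-OA
patients, an aligned and a non-aligned arm, stratum responder
probabilities (78.4 %, 65.2 %, 41.5 %, 44.1 %) and a continuous WOMAC
improvement whose noise scale is frozen by an explicit calibration step.

## Worked example

```bash
viscowin cohort --n 126 --seed 42 --out cohort.csv
viscowin validate --cohort cohort.csv
```

prints (abridged):

```json
{
  "r2_loocv": 0.6693367402917136,
  "rmse_loocv": 7.043308517719386,
  "or_adjusted": 2.0668146485399883,
  "or_ci_95": [1.004989571085966, 4.250514546935607],
  "p_value": 0.04843938696757845,
  "n_components": 2
}
```

For this single 126-patient draw the 2-component PLSR explains 67 % of
the WOMAC-improvement variance under leave-one-out cross-validation with
a 7.0-point RMSE, and aligned patients have 2.07 times the odds of a
≥30 % WOMAC improvement after adjusting for age and sex (95 % CI just
excluding 1). Individual cohorts of this size scatter around the
population values; averaging over many seeds recovers them (see below).

Classification against the window, here for a KL III knee:

```bash
viscowin classify --kl III
```

```json
{"classification": [
  {"formulation": "HA-A", "in_window": false, "aligned": false},
  {"formulation": "HA-B", "in_window": true,  "aligned": false},
  {"formulation": "HA-C", "in_window": true,  "aligned": true},
  {"formulation": "HA-D", "in_window": false, "aligned": false}
]}
```

HA-B sits inside the window but fails the KL III modifiers
(concentration ≥ 20 mg/mL and G′ > 160 Pa); only HA-C is aligned for
this patient.

## Package layout

| module | contents |
| --- | --- |
| `viscowin.rheology` | Carreau–Yasuda law, Kelvin–Voigt stress, moduli, closed-form dissipation |
| `viscowin.loading` | joint specs, gait waveforms, injection admissibility |
| `viscowin.hasim` | cyclic simulation, residence half-life, coverage class |
| `viscowin.window` | viscoelastic window and alignment rules |
| `viscowin.cohort` | synthetic cohort generator and noise calibration |
| `viscowin.validation` | NIPALS PLSR, LOOCV, odds ratios, subgroup tables |
| `viscowin.io` / `viscowin.cli` | formats, run configuration, pipeline, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
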