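# Methods

## Model

Steady-state C3 leaf photosynthesis is modelled as the minimum of three
candidate net assimilation rates at chloroplast CO2 partial pressure C_c
(Pa), all sharing one day-respiration term R_L (assumed identical across
limitation states):

```
A_c = Vcmax (Cc − Γ*) / (Cc + Kc(1 + O/Ko)) − R_L          rubisco
A_j = J (Cc − Γ*) / (4 Cc + 8 Γ*(1 + 2 α_G + α_S)) − R_L   RuBP regeneration
A_p = 3 TPU (Cc − Γ*) / (Cc − Γ*(1 + 3 α_G + 4 α_S)) − R_L TPU
```

α_G and α_S (unitless, α_G + α_S ≤ 1) are the fractions of photorespiratory
glycolate carbon exported from the cycle as glycine and serine. With both
zero, A_j reduces to the classical electron-transport form and A_p to the
flat line 3·TPU − R_L; positive export tilts the TPU line downward in C_c
(reverse CO2 sensitivity). A_p has a pole at C_c = Γ*(1 + 3α_G + 4α_S);
below it TPU cannot be the operative limitation and the candidate is
treated as absent (a NOT_LIMITING sentinel), never as a numerical value.

C_c is tied to the measured intercellular CO2 by the mesophyll diffusion
constraint C_c = C_i − A/g_m. Because every candidate is a degree-1 rational
function of C_c, substituting the constraint yields a quadratic in A per
candidate, solved in closed form; the smaller root is the physical branch
(it is the one that remains finite as g_m → ∞), subject to C_c > 0 and the
candidate's own admissibility. A point's operative limitation is the
candidate with the smallest self-consistent A; exact ties resolve in the
fixed order rubisco < RuBP regeneration < TPU, matching the convention that
the lower-CO2 process dominates first. The closed form is verified in the
test suite against an independent bracketed-bisection root finder to 1e−6
on 1,000 random admissible parameter draws, and continuity in g_m is checked
against the g_m = ∞ limit.

Kinetic constants default to Bernacchi-style C_c-basis values at 25 °C
(Γ* = 4.275 Pa, Kc = 40.49 Pa, Ko = 27.84 kPa, O = 21 kPa) scaled to leaf
temperature by one-parameter Arrhenius responses
(Ha = 37.83 / 79.43 / 36.38 kJ mol⁻¹ for Γ*/Kc/Ko). All are overridable via
a flat key=value config. Each measurement's own O2 enters the effective
Michaelis constant Kc(1 + O/Ko); Γ* is not re-scaled for O2, a deliberate
simplification acceptable over the usual 1.5–21 kPa range of practice.
Fitted rates (Vcmax, J, TPU, R_L) are reported at measurement temperature;
a post-hoc 25 °C normalisation helper exists but is off by default.

## Estimation

The latent per-point limitation states make the likelihood piecewise. The
fitter alternates:

1. bounded nonlinear least squares (scipy `least_squares`, trf) on
   Σ(A_obs − A_model)², each point modelled by its currently assigned
   limitation solved self-consistently with the g_m constraint;
2. reassignment of every point by the minimum rule under the updated
   parameters;

until the assignment is unchanged (default cap 50 iterations; period-2
assignment cycles are broken by keeping the lower-SSR iterate). The
objective has local minima, so 10 seeded multistarts jitter the heuristic
initial guess (log-uniform ×/÷ up to 2 on rates, additive up to +0.15 on the
alphas) and the lowest-SSR result is returned. Default bounds:
Vcmax, J ∈ [0, 1000]; TPU ∈ [0, 200]; g_m ∈ [0.05, 100] μmol m⁻² s⁻¹ Pa⁻¹
(or fixed at infinity); R_L ∈ [0, 10]; α_G, α_S ∈ [0, 1] with the simplex
constraint α_G + α_S ≤ 1 enforced by a penalty residual (10³ × excess).
During optimisation a point whose assigned candidate becomes inadmissible
falls back to the minimum over the remaining candidates, keeping the
objective finite.

Any parameter may be fixed (never jittered, excluded from the free vector).
`include_tpu=False` removes TPU and both alphas from the model, giving the
nested two-limitation variant; `compare_fits` reports ΔSSR, the percent
reduction 100(1 − SSR_with/SSR_without), and an F statistic
(ΔSSR/Δp)/(SSR_with/(n − p_with)) with its degrees of freedom. The F value
is reported, not thresholded: residuals of a segmented model only
approximately satisfy the classical nested-regression assumptions. If fewer
than two points are assigned to a limitation, its exclusive parameters
(Vcmax / J / TPU+alphas) are flagged `*_underdetermined` — e.g. J is only a
minimum estimate when no points are RuBP-regeneration-limited.
Uncertainties come from a residual bootstrap (resample fitted-point
residuals, refit from the point estimate, percentile intervals),
deterministic under a fixed seed.

Curves are re-sorted ascending in C_i before fitting (the model is
order-free and split-order measurement protocols add noise); the original
row order is kept in curve metadata. Observed A may be negative
(sub-compensation points are legal data).

## Fluorescence diagnostic

PhiII (PSII quantum yield) tracks the electron-transport requirement:
rising with CO2 under rubisco limitation, flat under RuBP-regeneration
limitation, declining under TPU. `classify_phi_trend` computes rolling
least-squares slopes of PhiII against log(C_i) (windows of 5 points,
full-width at the edges; log because measurement grids are geometric),
classifies each point as increasing/flat/decreasing against a threshold of
0.12 × range(PhiII) per unit log(C_i), merges contiguous runs into
segments, and raises `tpu_evidence` when the highest-CO2 segment is
declining with ≥ 2 points. The relative threshold makes the classification
invariant to uniform rescaling of PhiII. The 0.12 default was calibrated
once on generator output against a ≤ 5% false-positive target at PhiII
noise σ = 0.005; the acceptance checks re-measure both rates (≈ 98%
true positives on TPU-transition curves, ≈ 0–1% false positives on TPU-free
curves, 100 seeds each). Fluorescence-based electron transport is the standard product
J_f = PhiII · Q_in · absorptance · β with defaults 0.85 and 0.5.

## Synthetic data

The generator simulates the measurement structure of a stepped CO2-response
protocol: a geometric C_i grid (default 5–150 Pa, 15 points), the forward
model for true A and C_c, homoscedastic Gaussian noise on A (default
σ = 0.3 μmol m⁻² s⁻¹) matching the unweighted SSR objective, and C_i
treated as an error-free regressor. PhiII is built by electron-demand
inversion — J_required = (A + R_L)(4C_c + 8Γ*(1+2α_G+α_S))/(C_c − Γ*),
capped at J, divided by Q_in·absorptance·β — plus Gaussian noise (default
σ = 0.005), which guarantees the gas-exchange and fluorescence channels are
internally consistent and reproduces the rising/flat/declining PhiII
signature by regime. Presets: `classic_three_regime`, `tpu_transition`
(Vcmax 120, J 160, TPU 11, g_m 8, R_L 1.2, alphas 0 — the reference
recovery scenario), `no_j_segment` (rubisco hands over directly to TPU, so
J is underdetermined), `subsaturating_light` (J low enough that TPU never
limits), and `no_tpu`.

What the generator does *not* emulate: CO2-leak and matching artifacts,
split-order measurement noise, slow induction/deactivation transients,
oscillations under TPU limitation, heteroscedastic or autocorrelated noise,
and biological drift within a curve. Passing recovery tests therefore
demonstrates correctness of the estimator under the stated error model, not
robustness to instrument pathology.

## Known limitations

- **g_m is weakly identified on single saturating-light curves, and Vcmax
  inherits that uncertainty.** The SSR profile along g_m is nearly flat
  above the true value (differences well below the noise variance), so the
  least-squares minimum frequently sits at large g_m with Vcmax biased low
  by ~5–15% at σ_A = 0.3, even though noiseless curves are recovered
  exactly. This is a property of the estimation problem, not the optimizer:
  profiling SSR over fixed g_m shows the free-fit optimum is the true
  global minimum. J and TPU are pinned by their own curve segments (median
  errors ~1%). The practical remedy, supported directly by the API, is to
  measure g_m and R_L independently and fix them — doing so restores ≤ 1%
  noiseless and ~1% noisy median recovery of the remaining parameters.
  Measuring at high-but-subsaturating light, which enlarges the J-limited
  segment that carries the g_m information, helps for the same reason.
- The with/without-TPU F statistic is approximate (segmented model,
  data-dependent assignment); treat it as descriptive.
- Temperature responses are simple Arrhenius (no peaked deactivation for
  J or TPU); fits spanning wide leaf-temperature ranges should supply their
  own constants.
- C4 photosynthesis, stomatal models, non-steady-state records and
  multi-curve co-fitting are out of scope.
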