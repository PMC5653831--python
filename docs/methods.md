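# Methods

This note records the scientific model implemented by `coralcf`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions.

## The proxy chain

The package reconstructs the carbonate chemistry of the coral calcifying
fluid from two skeletal measurements per sample.

**pH_cf from δ¹¹B.** Aragonite incorporates the borate ion, whose abundance
and isotopic composition follow the pH-dependent boric-acid speciation.
With seawater composition δ¹¹B_sw and fractionation factor α_B,

pH_cf = pK_B − log₁₀[(δ¹¹B_sw − δ¹¹B_carb) / (α_B·δ¹¹B_carb − δ¹¹B_sw + 1000(α_B − 1))].

Defaults: δ¹¹B_sw = 39.61 ‰ (modern mean seawater; configurable) and
α_B = 1.0272 (aqueous boric-acid/borate fractionation). The proxy is
undefined for skeletal values at or above seawater and below ≈12.1 ‰
(where the fractionation denominator vanishes); both are hard domain
errors, annotated with colony/period identity in pipeline use.

**[CO₃²⁻]_cf from B/Ca.** The empirical molar distribution coefficient

K_D = 0.00297 · exp(−0.0202 · [H⁺]_cf),  [H⁺]_cf in **nmol/kg**,

links the skeletal B/Ca ratio to the fluid borate/carbonate-ion ratio:
[CO₃²⁻]_cf = [B(OH)₄⁻]_cf·K_D/[B/Ca]. The nmol/kg unit of the exponential
is a deliberate interpretation: it is the only unit under which K_D varies
by only a few percent (≈2.5 % half-range) across the pH_cf 8.3–8.6 band in
which coral fluids sit; in mol/kg the exponential is indistinguishable
from 1 and in µmol/kg nearly so, contradicting the documented sensitivity
of the coefficient. The unit is asserted by a dedicated test.

**DIC_cf and Ω_cf.** DIC follows in closed form from pH and CO₃ through
the carbonic-acid equilibria, DIC = CO₃·(1 + [H⁺]/K₂ + [H⁺]²/(K₁K₂)), and
Ω_cf = [Ca²⁺][CO₃²⁻]/K*sp. Two modelling assumptions are inherited from
the proxy systematics: the fluid carries ambient-seawater total boron and
calcium (both conservative in salinity), and the seawater equilibrium
constants evaluated at ambient (T, S) are applied to the fluid without
ionic-strength correction.

## Equilibrium constants

All constants are on the total hydrogen-ion pH scale at surface pressure.

| quantity | default formulation | alternative |
| --- | --- | --- |
| pK_B | Dickson (1990) | — |
| K₁, K₂ | Lueker et al. (2000) | Dickson & Millero (1987) refit |
| K*sp (aragonite) | Mucci (1983) | — |
| B_T | Uppström-type, 0.1284 mg kg⁻¹ psu⁻¹ | Lee-type, 0.1336 |
| Ca | 10280·S/35 µmol/kg | — |

The K₁/K₂ and B_T choices are configuration keys (`constants.k1k2`,
`constants.boron`) because the source study does not name its
formulations; the B_T alternatives differ by ~4 % and propagate linearly
into CO₃_cf, while the K₁/K₂ alternatives differ by well under 1 % at
study conditions. Default salinity where an input lacks it is 35.5
(`seawater.default_salinity`), typical shelf water for the study region;
the induced pK_B uncertainty over S 35–36 is < 0.01. Constants are
recomputed per call — nothing is cached across conditions. Tests anchor
every formulation against published check values at 25 °C / S = 35 and an
independently coded speciation route.

## Thermometry and chronology

Skeletal Li/Mg and Sr/Ca decrease linearly with growth temperature. The
package fits ordinary least squares calibrations (slope, intercept, r²,
two-sided slope p from the t distribution, no multiple-testing
correction), inverts them, and runs a chronology check: each proxy is
regressed on the period-mean temperature of the window the sample is
paired with, and passes when r² ≥ 0.5 **and** the slope is negative. The
0.5 threshold is a package choice — the underlying claim is qualitative —
and is configurable (`thermometry.chronology_r2`). Calibrations are fit on
colony-level points by default (period means remain available through the
aggregation stage).

Period matching: each sample's growth window is its period midpoint ± half
the sampling interval (window edges halfway to neighbouring collections),
and environmental drivers are averaged over that window. This centred
convention is applied identically by the analysis pipeline and the
synthetic generator, which is what makes a zero-noise synthetic study
round-trip exactly.

## Precipitation kinetics and the scenarios

Modelled abiotic aragonite precipitation follows G = k(T)·(Ω_cf − 1)^n(T),
k in µmol m⁻² h⁻¹. The default parameterisation anchors on the abiotic
seawater precipitation calibration points (5 °C: k = 21.8, n = 0.9;
25 °C: k = 45.2, n = 1.9; 37 °C: k = 64.9, n = 2.4), with n linear in T
and ln k linear in 1/T; a piecewise-linear alternative is provided. The
reaction order increasing with temperature is the load-bearing property —
it is what makes temperature-coupled scenarios strongly pro-cyclical. All
model/data comparisons are made on the percent-of-mean scale (each series
normalised to its own mean ≡ 100 %), which removes the absolute scale of
k and the unit mismatch with measured rates (mg cm⁻² d⁻¹) entirely;
swapping parameterisations moves the percent-of-mean series by well under
5 % RMS. Undersaturated fluid (Ω < 1) yields G = 0 with a dissolution
flag: the power law is undefined for a negative base with fractional
order, and dissolution kinetics are out of scope.

Three seasonal scenarios are compared by RMSE between modelled and
measured percent-of-mean series (RMSE = √mean(squared difference), on the
percent scale):

1. seasonal T and proxy-derived seasonal Ω_cf;
2. seasonal T and seasonal DIC_cf, but pH_cf slaved to seawater pH via the
   muted aquaria response pH_cf = 0.51·pH_sw + 4.28, with Ω_cf recomputed
   from that pH and the seasonal DIC_cf;
3. seasonal Ω_cf at a fixed annual-mean temperature of 21.7 °C
   (configurable), removing the kinetic temperature response.

On data generated with counter-cyclical regulation, the ranking is
scenario 3 < 1 < 2: fluid-chemistry control fits the near-aseasonal
measured rates best, and seawater-pH-slaved pH_cf worst.

## The synthetic generator

The generator emulates a sub-tropical seasonal monitoring study and is the
package's test bed; its defaults are the study conditions themselves.

- **Environment**: daily sinusoids phase-locked to the austral cycle
  (maxima mid-February). Monthly-mean temperature spans 19.3–23.7 °C — the
  extremes are monthly-mean facts, so the daily amplitude is inflated by
  the one-month boxcar attenuation factor (≈1.1 %) — PAR spans 15–48
  mol m⁻² d⁻¹ and pH_sw 8.03–8.10 directly.
- **Fluid regulation**: true pH_cf runs 8.60 (winter) to 8.38 (summer) and
  DIC_cf 3620 to 4520 µmol/kg, each linear in period-mean temperature:
  counter-cyclical by construction. CO₃_cf and Ω_cf are always *derived*
  through the constants module, never set freely, so the truth is
  internally consistent and exactly recoverable.
- **Regulation noise**: period-scale deviations enter as a DIC supply
  anomaly (σ = 450 µmol/kg) of which half is compensated by pH along the
  seasonal counter-regulation slope, plus an independent pH residual
  (σ = 0.015). Deviations therefore move the fluid largely *along* the
  regulation line — this is what reproduces a weak DIC_cf–temperature
  correlation (r² ≈ 0.4) while preserving the emergent winter > summer
  Ω_cf ordering. A side effect is that the generator's DIC_cf–pH_cf
  coupling (r² ≈ 0.85) is tighter than observed in real colonies (≈0.64).
- **Observables**: per colony per period, δ¹¹B and B/Ca are exact forward
  inversions of the proxy chain at the true state; Li/Mg and Sr/Ca follow
  the species calibration lines. Gaussian analytical noise per observable
  (σ_δ¹¹B = 0.15 ‰, σ_B/Ca = 0.012 mmol/mol, trace-element σ sized for
  calibration r² ≈ 0.8) plus constant per-colony offsets on the boron
  observables model between-colony scatter. Measured rates are generated
  from the temperature-independent scenario (3) at a base rate of
  1.6 mg cm⁻² d⁻¹ with 8 % observation noise.
- **Problem sizes**: 4 colonies × 10 collection periods of 45 days
  (~15 months), matching the structure of the field record; Monte-Carlo
  recovery tests use 200 replicates.

What the generator does **not** emulate: the real 2013–2015 calendar and
its weather (forcing is a clean sinusoid), marine heat waves, nutrient
dynamics, autocorrelated colony physiology, or analytical drift. Passing
recovery tests therefore demonstrates that the *estimation chain* is
unbiased and internally consistent under the assumed noise structure, not
that field data of this kind will match the assumed structure.

## Numerical conventions and degenerate inputs

- (pH, CO₃) ↔ DIC and δ¹¹B ↔ pH_cf conversions are closed-form exact
  inverses (round-trip residuals < 1e-9 relative and < 1e-10 pH).
- Percent-of-mean requires a strictly positive series mean; RMSE requires
  aligned equal-length series (misaligned period labels are reported by
  name).
- Reconstructed pH_cf outside 7.5–9.5 is flagged, not rejected.
- Aggregation uses SE = sd(ddof=1)/√n; a single colony yields an undefined
  (NaN) SE; missing values reduce n.
- Season assignment: winter Apr-16–Oct-15, summer Nov-16–Apr-15; the
  unassigned mid-Oct–mid-Nov gap goes to the nearer boundary, logged.
- Seasonal percent differences use the smaller season as denominator and
  are emitted both on season means and on extreme period means (the two
  conventions differ and both are in circulation).
- All pipeline outputs are deterministic given inputs + configuration +
  seed; the generator requires an explicit seed.

## Known limitations

- The proxy chain applies seawater equilibrium constants to a fluid whose
  ionic strength the coral may modify; no correction is attempted.
- No propagation of δ¹¹B/B-Ca analytical uncertainty into CfState fields;
  colony scatter is the only uncertainty surfaced (as SE across colonies).
- Absolute modelled rates G are not convertible to mg cm⁻² d⁻¹ without a
  reactive-surface-area model, which is out of scope; only percent-of-mean
  comparisons are meaningful.
- The kinetics anchor values are a transcription of a published abiotic
  calibration; their absolute scale is untested by design (it cancels in
  percent-of-mean), and the temperature dependence of n is the only
  property the conclusions rest on.
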