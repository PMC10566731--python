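# Methods

`kelpcarb` models how marine macrophytes (sugar kelp *Saccharina latissima*,
sea lettuce *Ulva lactuca*, eelgrass *Zostera marina*, bladderwrack *Fucus
vesiculosus*) change the seawater CO₂ system through photosynthesis, and
predicts the resulting local amelioration of ocean acidification as a
function of biomass density, irradiance and water residence time. This note
documents the models, the fixed numerical choices, and what the synthetic
generators do and do not emulate.

## Carbonate system

All acid–base chemistry is solved on the **total pH scale** at surface
pressure with a fixed set of stoichiometric constants: K1/K2 from Lueker,
Dickson & Keeling (2000); KB Dickson (1990b); KW Millero (1995); KS Dickson
(1990a, free scale); KF Perez & Fraga (1987); K0 Weiss (1974); aragonite
Ksp Mucci (1983); boron/sulfate/fluoride/calcium totals scaled from salinity
(Uppström 1974; Morris & Riley 1966; Riley 1965; Riley & Tongudai 1967).
This is the common default set of the CO2SYS/seacarb family for total-scale
work; the formulations are validated in the test suite against their
published check values at S = 35, T = 25 °C.

The alkalinity model is

    TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_free − [HSO₄⁻] − [HF]

Phosphate, silicate and ammonia terms are omitted — those nutrients are not
measured in the tank and chamber experiments this package serves — and no
pressure correction or air–sea exchange is applied (closed chambers and
lidded flow-through tanks).

Numerical choices:

* `solve_from_pH_TA` is algebraic (no iteration).
* `solve_from_DIC_TA` and `solve_from_pCO2_TA` bracket pH on [3, 12] and
  use Brent's method to an xtol of 10⁻¹² pH; an absent sign change raises
  `InfeasibleStateError` rather than clamping.
* pCO₂ includes the Weiss (1974) virial fugacity correction (≈0.3% at
  experimental temperatures); `fco2` is also reported.
* Volumetric ↔ gravimetric conversion uses a fixed 1.024 kg L⁻¹, not a
  density equation — this is the factor the downstream worked example is
  defined with, and over the habitat T–S range the error is < 0.2%.

**Known discrepancy.** For the kelp-habitat background parcel
(DIC 2200, TA 2100 µmol kg⁻¹, S 30, T 11 °C) the solver returns pH 7.208,
while the figure quoted alongside those inputs in the source material is
7.15. The two printed numbers are mutually inconsistent: pH 7.15 at TA 2100
implies DIC ≈ 2222 µmol kg⁻¹ (2200 is that value rounded), and no
CO2SYS-family constant choice changes pH by 0.06 at fixed inputs. The
post-drawdown state is reproduced exactly (22.5 µmol L⁻¹ removed at
constant TA → pH 7.271 ≈ 7.27), as are the Monte-Carlo uncertainty
percentages, so the solver itself is sound; the acceptance test asserts the
pair as published and the initial-pH half fails by construction.

## Monte-Carlo error propagation

Measured pH (±0.01, electrode/spectrophotometric precision) and TA
(±5 µmol kg⁻¹, titration precision) are perturbed with independent Gaussian
noise, each draw re-solved, and one standard deviation of derived DIC, pCO₂
and Ω reported, absolute and as % of the central value. Default 100 draws
(the original analysis size) — raise `n_sims` for stable assertions; an
infeasible perturbed state is excluded and counted, never clamped, so the
SD is taken over valid states only. At representative conditions
(pH 7.5–8.1, TA 2100–2200 µmol kg⁻¹) the relative DIC SD is ≈0.28–0.29%,
essentially the TA error expressed in DIC units, and the pCO₂ SD ≈2.5%,
shrinking as pCO₂ rises. The Ω SD is reported without a hard-coded
expectation — Ω is strongly pH-sensitive, and our propagation makes its
relative SD ≈2%, not the hundredth-of-a-percent sometimes quoted.

## Photosynthesis–irradiance curves

The saturating, photoinhibition-free response used for every Δ variable is
the hyperbolic tangent P(E) = Pmax·tanh(αE/Pmax), with Ek = Pmax/α always
derived, never independently stored. Fitting is least squares by
Nelder–Mead simplex (statsmodels-style `LightCurveModel.fit()` →
`LightCurveResults`):

* start values Pmax₀ = max(P), α₀ = slope of the two lowest positive-light
  points — robust for saturating curves;
* the simplex is restarted once from its own solution (xatol 10⁻⁷/10⁻⁸,
  fatol 10⁻¹⁰/10⁻¹²), which removes premature collapse and recovers
  noiseless parameters to ~10⁻⁹ relative;
* the dark step (E = 0) is excluded by default: the model forces P(0) = 0
  while observed dark deltas reflect respiration. An optional net model
  P(E) − R_d fits a dark offset and keeps the dark step, for threshold
  work;
* Pmax is capped at 50× the largest |response|: data that never approach
  saturation leave Pmax on an unbounded ridge (Pmax → ∞ at fixed initial
  slope), and the cap keeps such fits finite without touching any
  identifiable optimum. Downstream, a fitted Pmax above 2× the largest
  observed response is flagged as a failed (unidentified) fit and excluded
  from treatment summaries, mirroring how replicate counts below the design
  size arise in practice.

With five usable light levels and noise at 10% of Pmax, the median relative
error of fitted Pmax is ≈16% — an identifiability limit, not an optimizer
limit: an independent gradient-based least-squares fit lands on the same
optimum to ~10⁻⁶ RSS. Tests assert the equivalence and a bounded error
rather than an unachievable precision.

Treatment comparisons use Welch's unequal-variance t-test with
Satterthwaite fractional degrees of freedom, computable from raw samples or
from published mean/SE/n summaries; both routes agree by construction, and
the sample route matches `scipy.stats.ttest_ind(equal_var=False)`.

## Chamber experiment (species × pCO₂)

Per sealed 1 L chamber (1.5 h): DIC and Ω at both time points come from the
carbonate solver; deltas are final−initial for DO/pH/Ω and
initial−final (**uptake-positive**) for DIC, DIC converted to µmol L⁻¹ with
the 1.024 factor; macrophyte chambers normalised by g DW × h, controls by
h only. Species effects: OLS `Δ ~ C(species) * pCO₂` with sequential
(Type-I) ANOVA in the order species, pCO₂, interaction — the default of the
R environment such analyses are usually run in — and per-species slopes
(with SEs and 95% CIs) from the interaction contrasts. Species-level TA
joined onto chambers is supported by passing the same TA to all chambers of
a species × level cell; a per-chamber TA column always takes precedence
because it is simply the column the pipeline reads.

## Amelioration predictor

From treatment-mean P-I parameters (scenario × flow × variable, defaults
from the flow-through experiment: e.g. DIC/future/0.5 L min⁻¹ Pmax = 25.79,
α = 0.17, with 150 g FW in 30 L), the per-biomass-density rate is

    rate(E, f) = P(E; Pmax_f, α_f) · v/B   [µmol L⁻¹ per (g FW L⁻¹)]

interpolated **linearly in flow** (the axis on which linearity was assumed;
residence time v/f is provided as a labelled conversion only) between the
fitted endpoints 0.5 and 1.4 L min⁻¹, exact at the endpoints, clamped with
a warning (or a hard error in strict mode) outside. The printed composite
normalisation "/B·v" is dimensionally ambiguous; the interpretation
rate = P̄·v/B is fixed here because it is the only one that closes the
worked example (4.5 µmol L⁻¹ g⁻¹ × 5 g FW L⁻¹ = 22.5 µmol L⁻¹).
Interpolation is point-wise on the two tanh curves, not on their
parameters; the two differ slightly between endpoints and the point-wise
choice preserves endpoint exactness trivially.

Bulk change = rate × stand biomass density; a DIC change is translated to
pH/Ω by removing it from a background parcel at constant TA (photosynthetic
CO₂ uptake leaves alkalinity unchanged) and re-solving both states. The
amelioration threshold E* is the smallest irradiance with non-negative net
rate given a dark (respiration) offset, found by bisection to 10⁻³; the
default offset is 0 because no fitted value is published — supply one, or
fit the net model to dark-step data. FW↔DW conversion:
DW = 0.1187·FW − 0.0086 (floored at 0).

Out of scope, deliberately: self-shading, depth attenuation of light,
biofouling, night-time respiration dynamics, and air–water CO₂ exchange.

## Synthetic generators

The generators produce the two experimental designs with the statistical
structure the pipeline assumes — they are the package's test bed, not a
hydrodynamic simulation.

**Chamber generator** (`generate_chamber_experiment`): 6 pCO₂ levels
(280–1120 µatm) × 4 species × 5 replicates + 1 control per level (126
chambers). Initial states solve a jittered target pCO₂ with TA
2150 ± 5 µmol kg⁻¹ at 14–16 °C, S 31; true per-species DO and DIC rates are
linear in pCO₂ (log-normal chamber-to-chamber variation, CV 0.15), applied
over biomass (0.5–1.5 g DW) × 1.5 h at constant TA; final pH/Ω follow from
the solver; measurement noise 0.01 pH, 5 µmol kg⁻¹ TA, 2 µmol L⁻¹ DO on
both time points. Because only the DO/DIC truths are applied, the generated
pH and Ω responses are *implied* by carbonate chemistry — with the reported
DIC slopes as truth, the implied kelp pH slope is ≈0.0006 per µatm, about
half the independently reported pH slope; the two printed slopes are not
mutually consistent through any carbonate model. The delta-level simulator
(`generate_chamber_deltas`) therefore carries all four reported slope sets
directly as truth with homoscedastic noise (SD = 10% of the design-mean
response, matching the constant-variance check the source analysis states),
and is the generator used for slope-recovery calibration: 95% CIs cover the
generating slopes in ≈95% of simulated experiments.

**Tank generator** (`generate_tank_experiment`): 2 scenarios (ambient
400–600 µatm/11 °C; future 1500–1700 µatm/13 °C) × 2 flows × 5 kelp tanks
(~150 g FW, 30 L) + 1 control, 6 light steps (0–100% of
260 µmol photons m⁻² s⁻¹). Per-tank P-I parameters are log-normal around
the treatment truth with CV = SE·√5/mean from the reported summaries, and
with the Pmax–α correlation back-computed from the reported Ek SEs
(independent draws would over-disperse Ek). Light steps carry the P-I
signal; the dark step carries a per-tank respiration offset (DO drawdown,
DIC release). Outflow DIC is drawn down at constant TA and outflow pH
solved, so all four deltas are mutually consistent. Measurement noise:
0.005 pH (spectrophotometric), 5 µmol kg⁻¹ TA, 1 µmol L⁻¹ DO — sensor
*repeatability*, since systematic accuracy cancels in paired inflow/outflow
readings from the same meter.

**What passing tests show, and don't.** Noiseless generation is exactly
invertible (refits recover Pmax 32.44 to 10⁻³; delta arithmetic is exact),
so pipeline algebra is verified end-to-end. At realistic noise the Welch
flow contrast in ambient DO Pmax is detected in roughly half of replicate
experiments; the ideal power of that design — 5 draws per group taken
straight from the summary distributions with no fitting error — is only
≈0.69, so moderate power is the faithful outcome, not a defect. None of
this validates the generators against raw field data: they encode the
*reported* means, slopes and dispersions, and real chambers/tanks add
drift, TA variation from calcifying epibionts, and non-steady-state
transients that are deliberately not modelled.

## Problem sizes in the shipped checks

Deterministic anchors run at n = 1; stochastic checks use 10,000 Monte-Carlo
draws for the uncertainty band, 200 simulated chamber experiments for CI
coverage, 120 replicate tank experiments for the power check, and a
90-state × 2,000-draw grid in the acceptance script — sizes at which every
asserted quantity is stable to well inside its tolerance.
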