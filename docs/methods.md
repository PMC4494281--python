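# Methods

`cowcalf` simulates a beef cow-calf grazing system on a one-hectare,
four-paddock unit at a daily time step, and converts the system's feed
flows and soil nitrogen fluxes into CO₂-equivalent emissions per hectare
and per kg of calf live weight at weaning. This note records the model
equations, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic inputs do and do not represent.

## Scope and intent

The package is a reduced-order surrogate of a full biophysical whole-farm
model, built for desk-scale experimentation: the pasture/soil component
keeps the limiting-factor structure of such models (temperature, water and
nitrogen can each cap growth) without their multi-layer soil physics, plant
phenology or species competition. The intended use is comparative — site
orderings, management contrasts (pasture-only vs supplemented), and
emission-source structure — not site-accurate prediction of any particular
year.

## Weather synthesis

Daily inputs are Tmin/Tmax (°C), rainfall (mm), solar radiation (MJ/m²) and
vapour pressure (kPa). The generator draws from a monthly climatology:

- **Rainfall occurrence**: first-order two-state chain. With stationary
  wet-day probability π_m for month m and persistence ρ (default 0.3),
  P(wet|wet) = π + ρ(1−π) and P(wet|dry) = π(1−ρ); the stationary
  distribution of the chain is exactly π. Wet-day amounts are exponential
  with mean (monthly total)/(expected wet days), so monthly and annual
  totals are unbiased. Annual totals inherit a realistic coefficient of
  variation (~17%), which is why long-run mean checks are made on
  replicate-averaged series.
- **Temperature**: mid-month means are linearly interpolated onto a 365-day
  year and perturbed by a shared Gaussian anomaly (σ default 2–2.8 °C by
  site); rain days run slightly cooler with a compressed diurnal range, and
  Tmax is floored at Tmin + 3 °C.
- **Radiation**: extraterrestrial radiation for the site latitude times a
  transmissivity of 0.70 (dry days) or 0.40 (rain days).
- **Vapour pressure**: saturation (Tetens) at Tmin, a dew-point proxy.

Calendar convention: southern-hemisphere seasonality, 365-day years with no
February 29 (the reader treats Feb 28 → Mar 1 as consecutive in leap
years). This simplifies annual bookkeeping; a real archive year can still be
supplied as CSV.

What the generator does **not** emulate: multi-year droughts beyond what the
occurrence chain produces, within-month spell structure, heat waves
correlated across weeks, or trends. Conclusions that hinge on interannual
persistence should not lean on synthetic weather.

## Soil water

A single bucket of plant-available capacity C (mm, 70–120 by site).
Potential ET is a Makkink-type radiation–temperature form; actual ET is
scaled down linearly once the bucket is below half full (`et_fill_frac`).
Drainage is the overflow above C, so the daily balance
`Δwater = rain − ET − drainage` closes identically. Water-filled pore space
is proxied as (water/C)·`wfps_at_capacity`, the latter a drainage-class
parameter (0.85 for the freely draining sands, up to 0.97 for the heavier
chromosols) controlling how often soils cross the anaerobic threshold.

## Pasture growth and quality

Growth (kg DM/ha/d) is

    growth = RUE · R_s · 10 · (1 − exp(−green/0.9)) · min(f_T, f_W, f_N)

capped at `max_growth`. RUE (0.5–0.6 g DM/MJ of total incident solar at
full cover) is an *effective* efficiency absorbing respiration and
partitioning; f_T is a hat function on the cardinal temperatures
(phalaris-type C3: 3.5/17/33 °C; kikuyu sward: 5/22/40 °C — the base is
lower than a pure C4 because the sward includes winter-active subclover,
while the warmer optimum preserves the C4 contrast); f_W is linear in
bucket fill up to 45% of capacity; f_N = N_min/(N_min + 6) is a
Michaelis-type mineral-N sufficiency.

The sward holds green and dead pools. New growth enters at
`digestibility_new` (67% kikuyu, 73% phalaris); standing green decays
0.1 percentage points/d toward a floor (48/52%); senescence moves 2%/d of
green to dead (fixed 45% digestibility), and dead decays to litter at
1.5%/d. Grazing prefers green over dead 1 : 0.3 by mass on offer, which is
what makes the kikuyu system's consumed diet a few digestibility points
poorer than the phalaris systems'. Energy content follows the affine map
ME = D/6 − 0.3 MJ/kg DM, anchored at (60%, 9.7) and (63%, 10.2).

## Soil and sward nitrogen

Pools: soil mineral N, soil organic N, green-herbage N, dead-herbage N
(kg N/ha). Daily fluxes:

- **Fixation** = legume_fraction × growth × 0.04 kg N/kg legume DM,
  credited to the sward with the day's growth. Legume fractions (0.21
  kikuyu/subclover, 0.07–0.08 phalaris systems) were calibrated so annual
  fixation sits near 60 kg N/ha at the kikuyu site and 20–30 kg N/ha at the
  phalaris sites.
- **Plant uptake** from mineral N covers the growth N demand (3% of new DM)
  not met by fixation, bounded by the pool.
- **Mineralisation**: first-order, 1.5×10⁻³/d of organic N. Deliberately
  fast (pool turnover ~2 years) so the coupled N cycle reaches a stationary
  state within the 10-year spin-up; slower turnover made supplemented
  systems (which import feed N every year) drift for decades.
- **Excreta**: animals retain 10% of intake N; of the excreted remainder,
  60% is urine (10% of it volatilised at deposition, the rest to mineral N)
  and 40% dung (to organic N). Excreta land on the currently grazed paddock.
- **Leaching**: mineral N × leach_eff × drainage/capacity on drainage days;
  leach_eff is a small site calibration constant (free-draining sites
  higher).
- **Denitrification**: k_denit × mineral N × f_wfps × f_temp, with f_wfps
  linear above the anaerobic threshold (0.6) and zero below, f_temp linear
  from 2 to 25 °C.

All pools are clamped non-negative and the system balance
(fixation + feed N in − retention − cut export − leach − volat − denit =
Δpools) closes to numerical precision; the test suite asserts closure below
0.1% of throughput.

## Herd energetics

Maintenance = 0.58·LW^0.75 MJ ME/d, plus 10% for grazing activity
(67.5 MJ/d at the 500 kg steer reference). The cow+calf unit adds:

- **Pregnancy**: linear ramp to 30 MJ/d over the final 90 days before the
  July 1 calving.
- **Lactation**: 74 MJ/d after a 15-day ramp, while the calf (born 28 kg) is
  at foot.
- **Calf**: its own maintenance plus 0.6 kg/d × 15 MJ/kg growth demand.
- **Recovery**: up to 0.5 kg/d of regain (40 MJ/kg) while the cow is below
  her 500 kg target.

The lactation and pregnancy shapes are declared surrogates; their scale is
set by one constraint — the annualised unrestricted requirement of the
reference unit equals 1.5× the steer reference (~101 MJ/d) — which the test
suite checks by direct 365-day evaluation.

Intake per head is min(requirement/ME, 16.9 kg DM, herbage on offer above
the residual). Energy is allocated hierarchically: cow maintenance (funded
by live-weight mobilisation at 28 MJ/kg if intake falls short), then
pregnancy, then calf keep (lactation + calf maintenance), then calf gain,
then cow recovery (stored at 40 MJ/kg). Unfunded lactation dries off rather
than drawing on reserves, so a maintenance-only ration leaves both cow
weight and calf weight unchanged. The daily identity
`intake = allocated + stored − mobilised` holds exactly and is asserted.

In supplemented runs a substitution rule applies: if the requirement cannot
be met inside the DMI cap on pasture alone and the supplement is more
energy-dense, pasture intake backs off just far enough that supplement fed
into the remaining gut fill closes the gap. Without this, gut fill blocks
supplementation exactly when it is needed (late lactation on poor pasture).

## Management

Four equal paddocks; the herd stays on its paddock until biomass reaches
the species residual (0.5 t DM/ha phalaris, 1.0 kikuyu — the kikuyu
residual is higher to protect its stoloniferous base), then moves to the
paddock with most biomass above the residual. Grazing can never take a
paddock below the residual; drought decay can.

Cutting (supplemented mode only, matching the study design in which
pasture-only systems conserved nothing): a paddock at 2.5 t DM/ha is
flagged, cut on reaching 3.5 t DM/ha back to 2.0 t DM/ha (the flag-to-cut
gap lets spring flushes be captured at higher yield). The cut, less 10%
wastage, becomes a silage lot. Lots expire 12 months after harvest; feeding
draws oldest lots first. Silage and grain share one fixed quality per site
(10.5 MJ/kg DM and 2.5% N at the phalaris sites; 10.0 and 2.0% at the
kikuyu site) — the model does not predict conserved-forage quality, so cut
herbage leaves the N ledger at its actual sward N and fed supplement enters
as external feed N at the fixed quality. Supplement is fed whenever pasture
leaves an ME deficit or the cow is below the 450 kg floor. In pasture-only
runs, days with no grazable pasture remove the herd from the system (no
intake, no excreta, no enteric emissions that day), and the removal days are
reported.

**Carrying capacity** is estimated in a separate steer mode: a
continuous-valued number of 500 kg reference steers grazes a one-hectare
paddock each day, sized to consume exactly the biomass above the residual;
the run-average steers/ha over the retained years, divided by 1.5 (the
cow+calf : steer requirement ratio) and rounded to 0.1, is the capacity in
cows/ha. Because grazing pins biomass near the residual, site capacity
differences emerge from growth seasonality, residual level, diet quality
and senescence losses.

## Emissions accounting

- **Enteric CH₄**: %GEI = 1.30 + 0.112·D + L·(2.37 − 0.050·D), with D the
  intake-weighted diet digestibility and L the feeding level (ME intake /
  cow maintenance with activity, floored at 1). Note the algebraic pivot at
  D = 47.4%: above it, higher feeding level lowers the percentage loss.
  Gross energy is 18.4 MJ/kg DM; CH₄ energy density 55.22 MJ/kg. These two
  standard constants make 7.4 %GEI at 60.2% digestibility correspond to
  ~40.6 g CH₄/kg digestible DM, which the tests assert.
- **Manure CH₄**: 1.9 g CH₄ per kg faecal DM (faecal DM = intake × (1−D)).
- **Soil N₂O**: indirect factors 0.0125 (leached N) and 0.010 (volatilised
  N) kg N₂O-N per kg N; direct denitrification emits 1.5% of denitrified N
  as N₂O-N (the remainder leaves as N₂); all × 44/28.
- **Feed production**: 14, 45 and 60 kg CO₂-eq per t DM of grazed pasture,
  silage and grain respectively — calibration constants chosen so the
  feed-production share of intensity sits in the few-percent range typical
  of low-input systems.
- **Aggregation**: GWP₁₀₀ of 21 (CH₄) and 310 (N₂O). Intensity = total
  CO₂-eq / calf live weight weaned per ha; undefined (not infinite) when
  nothing weans.

Replacement animals, soil carbon change, and machinery/fuel are outside the
boundary.

## Runs, spin-up and reporting

A run covers `total_years` of daily steps; the first `discard_years`
(default 10) are discarded so the soil organic pool and sward state reach
their stationary regime. Annual summaries are calendar years (the July
calving and its November weaning fall inside one summary year); statistics
are arithmetic means with sample (n−1) SDs. Seeded runs are bit-reproducible
and the CSV writers are deterministic. Problem sizes used by the shipped
tests — 25-year runs (8 discarded) and 20-year capacity runs (5 discarded)
on the four sites — were chosen as the smallest that give stable annual
statistics for band and ordering checks; the analysis scripts use the full
40-year/10-discard protocol.

## Calibration posture

About a dozen per-site species/soil constants (RUE, cardinal temperatures,
senescence and decay rates, legume fraction, leaching efficiency, k_denit)
were calibrated once so that long-run outputs land in the published
plausibility bands for these systems: capacities 0.6–0.9 cows/ha with the
kikuyu site lowest; kikuyu diet digestibility a few points below the
phalaris diets; ~60 kg N/ha/yr fixed at the kikuyu site versus 20–30
elsewhere; denitrification > volatilisation > leaching in CO₂-eq;
enteric share 0.75–0.93 and feed-production share 0.02–0.06 of intensity.
The calibration targets are encoded as tests, not baked into outputs.

## Known limitations

- The pasture surrogate has no species competition, phenology or multi-layer
  hydrology; absolute growth at any one site-year is not trustworthy, only
  the structure of responses.
- Pasture-only cow live weight equilibrates lower than field experience
  suggests at these stocking rates, because unsupplemented winters run a
  chronic energy deficit in the surrogate; supplemented runs, where the
  acceptance constraints bind, hold the 450 kg floor.
- Fixed stocking: cow numbers do not adapt within a run; the capacity
  estimator is the only place animal numbers respond to feed.
- Single-quality supplement and fixed-quality silage; no market or economic
  layer.
- Enteric coefficients apply to mixed temperate diets (digestibility
  40–85%); the code refuses diets outside that range rather than
  extrapolating.
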