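# Methods

`hydrogap` simulates the coupled water and carbon balance of an evergreen
temperate rainforest stand: a stochastic daily weather generator drives a
canopy-interception and bucket soil-moisture model, and the resulting
water supply throttles the annual biomass production of individual trees
competing for light on a 20 × 20 m patch mosaic. The default
parameterization describes a North Patagonian rainforest site on northern
Chiloé Island, Chile (41.85°S; wet-temperate, ~2 000 mm rain per year).

## Weather generator

Rainfall is a marked point process. Intervals between events are
exponential with seasonal mean 1/λ (days) and each event carries an
exponential depth with seasonal mean η (mm). Because exponential
inter-arrivals make the event process Poisson, the production code draws
each day's event count N ~ Poisson(λ) and the daily total as
Gamma(N, η) — exactly the same process, fully vectorized. An explicit
event-level simulator (used in diagnostics and the event fixture) keeps
the τ/h representation available; recovering 1/λ and η from its output
is a standing property test.

Daily mean temperature is Gaussian per season. Daily global radiation
(µmol photons m⁻² s⁻¹, interpreted as the daylight-hours mean) is
Gaussian with parameters conditioned on season and on whether the day is
wet (P_d ≥ 1 mm; the boundary value counts as wet), truncated at zero.

A generator run with the seasonal event statistics alone overestimates
rainfall (the winter value 1/λ = 0.29 d implies rain on ~97 % of days),
so each season's daily values are rescaled by a single analytic factor,
prescribed seasonal sum / expected raw sum. Normalizing in expectation —
rather than forcing each simulated season to the prescribed sum exactly —
preserves the interannual variability that the site climatology reports.
The calendar is a fixed 365-day year; seasons follow calendar months
(Dec–Feb = DJF, etc.), austral convention, with no leap years.

Drought scenarios multiply η by 0.5–1.0 and 1/λ by 1.0–1.5 in the growing
season (DJF and SON) only; prescribed sums are rescaled by
η-factor/λ-factor so normalization transmits, rather than silently
undoes, the drought signal. The warming scenario adds seasonal offsets
(+4.0, +3.0, +2.0, +2.0 °C for DJF/MAM/JJA/SON) to the temperature means
with rainfall untouched.

## Canopy interception

Canopy storage follows S(LAI) = S_max·(1 − exp(−f_h·LAI/LAI_max)) with
f_h = 3 and LAI_max = 5.5; S_max ≈ 5.243 mm is fixed by the field
calibration anchor S(5.0) = 4.9 mm. Daily interception follows a
Rutter-type saturating curve Ec = S·(1 − exp(−α_h·P/S)) with initial
slope α_h = 0.7 and asymptote S, capped at the day's rainfall.

In the coupled daily loop interception is additionally limited by the
evaporative energy available that day (see the budget ordering below).
Without that limit, near-daily winter rain would evaporate ~900 mm yr⁻¹
from the canopy — far beyond both the energy supply and observed
interception fractions (~20 % of rainfall) for this forest type.

## Soil moisture bucket

Normalized soil moisture s ∈ [0, 1] of a single stand-level root-zone
bucket of capacity n·z = 0.757 × 520 mm ≈ 393.6 mm is the central state
variable. The explicit daily update is

    n·z·Δs = Pnet − Tr − Q,   Q(s) = k_sat·s^c,

with saturated conductivity k_sat = 4 mm d⁻¹, percolation exponent c = 2
(the empirical percolation law is a power law; the exponent is exposed in
config), and post-step clipping: moisture above saturation leaves as
runoff, and a would-be negative store first reduces transpiration, then
drainage. The balance P = Ec + Tr + Q + runoff + n·z·Δs closes to
round-off on every step, and the suite asserts annual closure below
10⁻⁶ mm. Soil evaporation and lateral flow are neglected (closed-canopy,
flat, rain-saturated terrain).

The water-stress factor ω(s) is 0 at the wilting point θ_wp = 0.125, 1 at
the moist-soil threshold θ_msw, and linear between. θ_msw is
parameterized as θ_wp + f·(θ_fc − θ_wp) with f configurable; the default
f = 1 anchors θ_msw at field capacity θ_fc = 0.3 — production is
unstressed only when the soil is at or above field capacity, which is the
standard bucket-model convention and lets stress engage at realistic
summer moisture levels. Thresholds are read on the normalized-s scale by
default, with a config switch for the volumetric interpretation.

## Potential evapotranspiration

PET is Priestley–Taylor: PET = α_PT·(Δ/(Δ+γ))·Rn/L, with the
psychrometric constant γ = 65 Pa K⁻¹, latent heat L = 2.56×10⁶ J kg⁻¹,
and Δ(T) the standard saturation-vapor-pressure slope. Net radiation
converts the daylight-mean photon flux to energy with the PAR photon
energy (0.2174 J µmol⁻¹), the PAR fraction of global shortwave (0.5) and
the astronomical daylength at the site latitude, reduced by albedo 0.17;
net longwave loss is the LPJ-style (0.2 + 0.8·n_i)(107 − T) W m⁻² with
sunshine fraction n_i = clip(Rg/Rg_clear, 0, 1), Rg_clear = 1800
µmol m⁻² s⁻¹. Both flux terms integrate over daylength: PET is treated
as a daylight process (nighttime net radiation is negative and PET is
floored at zero anyway). Every constant here is a named config value.

α_PT (default 1.041) was calibrated once so that the long-run mean annual
PET under the generated current climate reproduces the regional estimate
of 769 mm yr⁻¹; the value sits below the classic 1.26 but within the
range reported for forest canopies, whose stomatal control lowers the
effective coefficient. The 24-hour longwave convention was rejected
because it collapses winter PET (~19 mm per season) and with it winter
interception, which is energy-limited here.

## Transpiration and the carbon–water coupling

Water-use efficiency links the two budgets: annual transpiration demand
is Tr = PB/WUE with WUE = 9 g CO₂ per kg H₂O, so a potential gross
production of 2 664 g CO₂ m⁻² yr⁻¹ poses a 296 mm yr⁻¹ demand. The
demand is prorated over the active photosynthetic period (365 days,
evergreen canopy) by each day's share of annual PET: transpiration
follows the evaporative environment within the year, and the proration
reduces to uniform under a flat PET climate while preserving the annual
Tr = PB/WUE proportionality. (Uniform proration against this site's
strongly seasonal PET would strand most wet-season demand and make
realized production *rise* under drought through freed evaporative
budget — the opposite of the production–moisture coupling the model
exists to represent.)

Each day the posed demand is reduced by ω(s) and capped at PET_d;
transpiration has first call on the evaporative budget, and interception
evaporates from the remainder, so daily ET = min(Tr + Ec_raw, PET) and
both ET ≤ PET and Tr ≤ PET − Ec hold by construction. The realized
fraction of the annual demand, ω_year = ΣTr/Σdemand, scales every tree's
realized production before the demographic step — conserving the WUE
proportionality between realized transpiration and realized production.

A unit caveat: published stand calibrations for this forest type pair
Tr = 296 mm yr⁻¹ with PB = 32.9 tC ha⁻¹ at WUE = 9, which is not
reachable with the physical C→CO₂ conversion (44.01/12.01; that PB would
demand ~1 340 mm). The conversion factor is exposed as a named constant
(`forest.CO2_PER_C`) with the physical default; absolute stand-level
production values in tC therefore sit below those published numbers, and
are treated as illustrative throughout.

## Demography core

Stand dynamics are individual-based on a default 5 × 5 grid of 20 × 20 m
patches (1 ha, torus boundary). Within a patch, leaf area accumulates in
0.5 m height layers (each crown spreads its leaf area uniformly over its
crown depth) and irradiance declines downward as exp(−k·LAI above), with
a stand-level extinction coefficient k = 0.5.

A tree's gross production integrates the saturating single-leaf light
response P(I) = pmax·αkI/(αkI + pmax(1−m)) analytically over its own leaf
area index (self-shading), multiplied by crown area and the active
period; a brute-force quadrature oracle pins the closed form to 10⁻⁶
relative. Maintenance respiration (fraction of biomass per year) and
growth respiration (fraction of net assimilate) are subtracted, a size
factor 1 − (dbh/dbh_max)² shuts growth down toward the species maximum
diameter, and the net biomass increment — floored at zero, trees do not
shrink — is inverted through the allometry (safeguarded Newton on the
strictly increasing B(dbh)) to update diameter, height, crown and leaf
area. Allometry: saturating height h_max·dbh/(dbh + h_half), crown
diameter proportional to dbh, leaf area = crown area × species LAI
factor, biomass = stem volume × form factor × wood density × 0.5 carbon
fraction.

Mortality combines (a) a background rate, (b) an elevated rate when the
annual diameter increment falls below a species threshold, (c)
deterministic self-thinning — smallest trees first, a reproducibility
choice — whenever a patch's summed crown area exceeds the patch area, and
(d) gap formation: dying trees of dbh ≥ 45 cm fall with probability 0.3
onto one of the four torus neighbors, killing trees there with
probability proportional to the faller's crown area. Recruitment enters
at dbh = 1 cm at a species maximum rate per patch, reduced linearly with
floor light below a species threshold (Poisson counts).

The shipped three-species table is an illustrative, synthetic
parameterization (a shade-tolerant conifer, a mid-tolerant broadleaf and
a light-demanding pioneer) with magnitudes chosen once so that bare-ground
succession reaches a basal area of ~55–66 m² ha⁻¹ and LAI ~4.5 at age
60 — the scale observed in young secondary stands of this forest type.
It is not a published calibration, and stand-structure outputs under it
are qualitative.

## Coupling order and protocols

Each simulated year: stand LAI → potential production per tree from the
year's mean radiation → PET-prorated daily demand → 365-step daily water
loop (interception, PET, stress, caps, drainage, storage, runoff) →
ω_year → one demographic step (growth, mortality, recruitment). One
shared soil bucket serves the stand; interception uses stand LAI. With
hydrology disabled, ω_year ≡ 1 and the run reproduces the pure
demographic core exactly (a regression identity in the suite).

Two initialization protocols mirror the field comparisons: YS (bare
ground, reported after 60 years of succession) and OG (inventory
initialized, run to dynamic equilibrium; 1000 years in the full
protocol). Replicates derive child seeds from the master seed via
`SeedSequence` spawning, with separate weather and demography streams, so
scenario cells run under common random numbers.

## Scenario engine

The drought design is the full 6 × 6 factor grid (36 cells, baseline
included), 30 replicates per cell in the full protocol; summaries report
pooled replicate means at the reporting year and percent change
(scenario − baseline)/baseline × 100, so the baseline cell is 0 by
construction. The warming run and the monotone η sweep (event depth from
100 % to 0 % of current) reuse the same machinery. Response surfaces are
emitted as data, not figures.

## What the defaults do and do not show

The weather generator emulates the site's seasonal rainfall event
statistics, temperature and radiation climatology, including the
wet/dry-day radiation contrast; it does not represent multi-day storm
persistence, spatial weather fields, sub-daily structure, or long-term
trends in the baseline. Passing tests therefore demonstrate the coupled
model's internal consistency and its sensitivity structure under this
climatology — not predictive skill for any particular year or for stands
whose species parameters differ from the illustrative set.

## Numerical choices and problem sizes

Explicit forward Euler at Δt = 1 day with post-step clipping for the
bucket; analytic canopy integrals (no per-layer quadrature in
production); Newton inversion of the allometry to 10⁻¹⁰ relative;
tree state in flat arrays so a 100-year, 1-ha run costs well under a
second. Standing checks use 600 generated years for the seasonal
rainfall means, 100 years for PET and fixed-LAI interception, and a
50-year, 8-replicate design for the drought monotonicity property; the
full 36-cell grid at 10 replicates × 100 years runs in a few minutes on
one CPU.

## Known limitations

Single-layer bucket, no water table, no lateral flow, no soil
evaporation; one weather series for the whole stand; WUE is a stand
constant rather than species- or climate-dependent; the interception
and percolation functional forms honor the documented constraints
(asymptote, initial slope, saturation anchor, conductivity at
saturation) but their exact published algebra is not recoverable, so
component-wise annual water-balance splits should be read as
order-of-magnitude; temperature affects PET only (no direct growth or
respiration response to warming).
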