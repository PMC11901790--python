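# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the synthetic experiments do and do not
demonstrate about real field data.

## Process model

**Reference evapotranspiration.** Daily ET₀ uses the FAO-56
Penman–Monteith combination equation with radiation in MJ m⁻² d⁻¹ (any
J m⁻² d⁻¹ source is converted at ingestion so the 0.408 coefficient is
dimensionally consistent). Humidity enters as relative humidity and is
converted to vapour pressures with the Tetens formula at the daily mean
temperature. The psychrometric constant is computed from barometric
pressure at a configurable station elevation (default 1220 m, typical of
loess-tableland terraces). Soil heat flux G defaults to zero at daily
resolution, the usual assumption when it is not measured; it is an
explicit input so a measured series can override it. ET₀ is clipped at
zero when the combined numerator is negative — negative reference demand
has no meaning in a green-water budget.

**Canopy partition.** Beer-law extinction splits ET₀ between canopy and
soil. The package's default assigns the absorbed fraction
(1 − e^(−μ·LAI)) to transpiration, which gives the correct bare-soil
limit (LAI = 0 ⇒ all demand is soil evaporation). Some published
variants print the transposed assignment; a `convention="as_printed"`
flag reproduces that literal form. The same flag idea applies to the
soil-evaporation reduction rule (below). Either way the two potentials
sum exactly to ET₀.

**Interception.** Daily interception uses a saturating hyperbolic
storage form with capacity a·LAI and initial slope controlled by the
cover fraction b = 1 − e^(−μ·LAI). The empirical parameter a
(dimensionless, initial value 0.25, calibrated per plot) is treated as a
plain scalar. Interception is applied per day (the forcing resolution),
removed from rainfall before it reaches the soil boundary, and is
continuous in its limits: zero when LAI = 0 or P = 0, approaching a·LAI
as P → ∞ and never exceeding P.

**Soil water.** Vertical flow over 0–200 cm follows the mixed-form
Richards equation with a root-extraction sink. Hydraulics are van
Genuchten–Mualem with pore-connectivity exponent l = 0.5 (the standard
value when not separately calibrated); pressure head is in cm (negative
under suction), depth positive downward, conductivity in cm d⁻¹. Root
uptake is Tp times the normalised root density β(z) times the Feddes
stress factor α(h) with thresholds h₁ > h₂ > h₃; the column integral
never exceeds Tp. Soil evaporation is reduced linearly between the
capillary-rupture content θ_c (zero evaporation) and 0.65·θ_f
(potential rate), evaluated on the mean water content of the top 10 cm —
a thin surface layer of the order of micro-lysimeter depth. The printed
form of this middle branch in some sources decreases with wetness; the
default here is the physically increasing form, with the literal variant
behind the same `as_printed` flag.

## Numerics

The solver uses cell-centred finite volumes (node spacing 2 cm,
configurable) and the mass-conservative modified-Picard scheme: each
iteration solves a tridiagonal system for the new heads, and at
convergence the discrete balance holds to the iteration tolerance
(default 10⁻⁶ cm of head, max 50 iterations). Internodal conductivity
is the arithmetic mean. Time stepping is adaptive inside each 1-day
forcing interval (growing on fast convergence, shrinking otherwise; a
non-convergent step is retried smaller before the run aborts with the
failing day). Seasonal closure errors in practice are at machine
precision; the acceptance tests require ≤ 0.1 % of inputs.

The upper boundary is atmospheric: a target flux (net rain minus
moisture-limited evaporation) switches to head control when the surface
saturates — the excess becomes instant runoff, with no ponding storage,
appropriate for sloping terraces — or when it dries to a minimum head
(default −10⁶ cm). The lower boundary is unit-gradient free drainage
(deep loess; groundwater does not interact with the root zone); a sealed
option exists for closed-column experiments such as the hydrostatic-
equilibrium test. The inner loop is JIT-compiled (numba): a full
184-day season runs in seconds, which is what makes the 104-run
sensitivity study and calibration practical.

Degenerate inputs: a fully saturated column would make the capacity
matrix singular, so the capacity carries a 10⁻¹² floor (inert at
convergence); boundary-mode switching is limited to four changes per
substep to prevent cycling.

## Component accounting

GW_H and GW_L are the day's actual transpiration and soil evaporation
(the 1-day reporting step). GW_A is storage above wilting, evaluated on
ten 10-cm layers (0–100 cm) plus five 20-cm layers (100–200 cm),
mirroring the TDR measurement scheme; the wilting content is the
retention curve at h₃ — plot-specific, rather than a fixed −1500 kPa —
because h₃ is defined as the permanent-wilting potential of that
vegetation. Sub-wilting water is unavailable, so per-layer deficits are
floored at zero.

## Plot templates

Four templates ship (two woodland, two grassland species) with
calibrated hydraulics for the 0–40 and 40–100 cm layers, Feddes
thresholds, canopy parameters, a root-profile decay scale and an LAI
phenology curve (piecewise-linear anchors; the alfalfa template includes
two cutting events with 30-day linear regrowth; the conifer template is
evergreen, starting the season leafy). Values not measured per layer
are completed by least-surprise rules, all overridable: the 100–200 cm
layer inherits the 40–100 cm hydraulics, the top-layer residual content
equals the measured 40–100 cm value, and saturated conductivity is
uniform with depth. Field capacity is anchored at the retention curve
at −330 cm and θ_c at 45 % of field capacity; both affect only the
evaporation reduction rule. One template's printed stress thresholds
arrive with h₂ and h₃ out of order; the template enforces the physical
ordering (wilting most negative) by swapping them.

## Calibration and sensitivity

Skill is Nash–Sutcliffe efficiency per observed series, banded
qualitatively (very good > 0.75; good (0.65, 0.75]; satisfactory
[0.50, 0.65]; unsatisfactory below — the lower cut follows common
hydrological practice since only the upper bands are conventionally
fixed). Calibration maximises the mean NSE across the water-content
depth series; evaporation skill is reported but not optimised, matching
how the two observation types are treated separately in practice. The
search is derivative-free — Latin-hypercube screening (default 64
points, seeded) then Nelder-Mead refinement — chosen for robustness with
a stiff simulator; the nominal start is always screened so the result
cannot be worse than it. Sensitivity is one-at-a-time: each of the 13
template parameters perturbed by ±10 % of its admissible range around
the nominal point, scored by the mean absolute change in the simulated
water-content output at the three observation depths, ranked descending
with ties broken by parameter order. Parameter ranges keep lower bounds
strictly away from zero (and head upper bounds strictly negative) so
perturbed parameter sets remain physically valid; a perturbation that
still fails is recorded and the parameter is scored from the remaining
side.

## Statistical layer

Storage-change box statistics attribute the change over day t to day t's
rainfall class and growth stage — the simplest causal alignment of rain
with same-day recharge. Rainfall classes follow the operational daily
convention: rain-free < 0.1, light [0.1, 10), moderate [10, 25), heavy
[25, 50), rainstorm ≥ 50 mm/24 h; heavy and rainstorm pool into one
group for regression. Growth stages are month/day anchored (early
15 Apr–15 May, middle 16 May–31 Aug, late 1 Sep–15 Oct). Whiskers
extend to the most extreme point within 1.5 IQR of the box edges.

The dominance threshold samples cumulative GW_H, GW_L and ET₀ every
5 days, fits an ordinary-least-squares line through each component's
points (not forced through the origin — the crossing behaviour depends
on the intercepts), and reports the crossing abscissa only when it lies
inside the sampled range; parallel or identical lines give "none" /
"undefined".

The interception regression GW_I = b_P·P + b_LAI·LAI + c is ordinary
least squares per rainfall group and pooled, with per-coefficient
t-statistics and two-tier significance flags (** p<0.01, * p<0.05).
Seasons are pooled by default with a season filter available. The
pruning trial scans LAI at 0.1 m²·m⁻² resolution for the smallest value
whose predicted interception still reaches a target at a design
rainfall, after verifying the response is monotone in LAI; both a fitted
regression and the full simulator can serve as the response. Scenario
outputs are reported at one decimal (mm and LAI).

## Synthetic data

The weather generator emulates a semi-arid loess growing season:
per-month Bernoulli wet days with a two-component exponential depth
mixture (light bulk + heavier tail), monthly means scaled so the
expected season total matches the requested value (default 560 mm,
inside the observed 480–660 mm span of wet/normal seasons, with rain
concentrated July–September); sinusoidal temperature and net-radiation
cycles with Gaussian weather noise, reduced radiation and raised
humidity on wet days; uniform wind. Observations are sampled every
5 days plus the day after any ≥ 10 mm event — the field cadence — with
additive Gaussian noise. All randomness flows from one integer seed.

What the generator does *not* reproduce: real storm structure
(sub-daily intensity, multi-day systems), radiation–humidity coupling
beyond the wet-day adjustment, interannual persistence, spatial
correlation between plots, and measurement biases that are not additive
Gaussian noise. Passing tests therefore demonstrate that the *methods*
are implemented correctly and behave physically (conservation,
equilibria, recovery of known truths), not that any specific field
dataset would be reproduced; published site-specific numbers that
depend on the unpublished observation series (calibrated parameter
values, seasonal component ranges, field dominance thresholds, field
NSE values) are out of reach at desk scale by construction.

## Problem sizes used

Default experiment sizes keep every check honest but fast: one 184-day
season per forward run; sensitivity = 4 templates × 13 parameters × 2
perturbations (~104 season runs); calibration demonstrations use a
60-day window with one free parameter, 12 screening points and ≤ 60
refinement iterations; the grid-refinement oracle compares 4 cm vs 1 cm
node spacing over a 5-day infiltration event; the hydrostatic test
relaxes a sealed column for 600 days.

## Known limitations

No hysteresis, vapour flow, heat coupling, 2-D/3-D effects or
groundwater capillary rise. Interception has no event-scale canopy
storage dynamics (no Gash/Rutter energy balance) and no stemflow. The
calibration is single-objective (no uncertainty quantification). The
OAT sensitivity is a local measure around the calibrated optimum, not a
global variance decomposition.
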