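# Methods

This note documents the model structure, the default parameterization, what
the synthetic-data generators do and do not emulate, and the numerical and
design choices a maintainer should know.

## Model structure

The simulator couples a cell-based state-and-transition model (STSM) to a
gain–loss carbon stock-flow model. The annual loop per Monte-Carlo rep is:

1. sample land-use transition area targets (baseline years use the historical
   rate table verbatim; projection years sample with replacement from
   scenario-specific windows),
2. simulate disturbances (wildfire events against an ecoregional burn-area
   target; drought mortality from the 60-month SPEI),
3. apply transitions in uniformly random order and advance stand ages,
4. apply event-triggered carbon flows,
5. apply automatic carbon flows with the year's Q10 and CO₂-fertilization
   multipliers,
6. append an accounting row.

All randomness flows from integer seeds through `numpy.random.Generator`
streams; one stream per (seed, rep) drives the baseline period in every
scenario, and a (seed, rep, scenario) stream takes over at the 2016 branch
point, so all scenarios share bit-identical baselines.

## Accounting definitions

- **NPP**: the growth flow (atmosphere → live), summed over cells.
- **Rh**: litter and soil gaseous emissions only. The model's other
  atmosphere-bound flows (background biomass emission, fire and land-use
  emissions) are counted in LULCC removals, not Rh. This operational
  definition makes Rh the heterotrophic baseline respiration and reproduces
  the flux composition of published statewide tables (where mean Rh ≈ litter
  emission + soil emission and LULCC ≈ ag harvest + biomass emission +
  leaching + disturbance/harvest/land-use losses).
- **LULCC removals** (stored positive): agricultural grain/straw harvest,
  background biomass emission, leaching, plus every event-triggered flow to
  the atmosphere or product pools. Live→deadwood mortality transfers stay
  inside the ecosystem and are excluded.
- **NECB = NEP − LULCC**; **TEC** sums pools over ecosystem classes (forest,
  grassland, shrubland, annual/perennial crop).
- **Transfer**: stocks remaining in a cell when it converts to a
  non-ecosystem class are frozen in a global transfer pool (they neither
  grow nor respire); `ΔTEC = NECB − Δtransfer` holds to float precision.
- The atmosphere pool is a signed accumulator starting at 0, so the grand
  total over every pool is exactly conserved; runs audit it at ≤1e-9
  relative (measured ~1e-15 per century).

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| Q10, down-dead decay / litter decomposition / soil emission | 2.0 | rate multiplier `q10^(ΔT/10)`, ΔT vs the ecoregion's baseline normal |
| Q10, litter emission | 2.65 | the litter pool's gaseous flux; whether it should override the 2.0 decomposition value is ambiguous — both are config-switchable in `Q10Params` |
| CFE β | 0 (off); 0.027–0.136 explored | fractional NPP gain per 100 ppm CO₂; multiplier `1 + ΔCa·β/100`, ΔCa vs the 2001 baseline (371 ppm), optional 600-ppm cap |
| Minimum harvest age | 40 (clear-cut), 20 (selection) | clear-cut resets age; selection does not |
| Selection harvest transfer | 0.20 of live → HWP | |
| Drought area draw | Normal(mean, 0.5·mean), truncated [0, eligible] | truncation (not clipping) via `scipy.stats.truncnorm` |
| SPEI window | 60 months | Thornthwaite PET (temperature-only); z-score standardization over the calibration window |
| Fire spread | 8-connected, greedy by weight, rng tie-break | events confined to their ecoregion so targets reconcile |
| Cell area | 1 km² (config) | all fluxes scale linearly with it |

Flow-rate defaults (per class) and triggered-flow fractions live in
`carbon.DEFAULT_FLOWS` and `carbon.TRIGGERED_FLOW_DEFAULTS`. The clear-cut,
urbanization, orchard and fire fractions are plausibility choices, exposed in
config and **not** calibrated against any published parameterization.

## Synthetic data: what it does and does not emulate

`synthdata` generates: contiguous row-block ecoregions split into counties;
land-cover labels drawn i.i.d. from a mix (defaults: 40% forest, 20%
grassland, 20% shrubland, 12% crops, 8% other); uniform initial ages (0–200
years for forest — a stand-in, since no empirical age distribution is
available at this scale); log-normal NPP spatial multipliers renormalized to
mean exactly 1 per (ecoregion, class); trended, seasonally-cycling monthly
climate with log-normal annual precipitation (CV 0.25) and drought years
(2012–2015) scaled to 0.4× precipitation; a quadratic CO₂ ramp anchored at
371 ppm in 2001 reaching ~540 ppm (low forcing) or ~930 ppm (high) at 2100;
jointly log-normal historical rate tables with target cross-group correlation
(harvest types 0.6, agricultural types 0.4) and era structure (agricultural
growth 1997–2002, harvest more intense 2002–2009 than 2010–2014 — the eras
the scenario windows sample); Michaelis–Menten age-to-carbon curves
(`live(a) = A·a/(a+h)`, half-age 30 yr, forest asymptote 6,500 Mg C/km²)
with DOM/soil fractions placed near the steady state of the default flow
rates so a mature landscape neither sheds nor hoards carbon at
initialization.

Not emulated: realistic geography and spatial autocorrelation of land cover,
orography, within-year climate persistence, age-structured NPP, and the
empirical calibration of burn-area or mortality models to survey maps.
Passing tests therefore demonstrate the *mechanics and accounting* of the
coupled model — covariance-preserving sampling, constraint enforcement,
conservation, directional climate responses — not predictive skill on real
landscapes.

## Scenarios

Four land-use scenarios differ in sampling windows and urbanization:
high (agriculture 1997–2002, harvest 2002–2009, urbanization ×1.3), low
(agriculture 1993–1996, harvest 2010–2014, ×0.6), BAU and medium (full
series; ×1.0 and ×0.85). The urbanization multiplier stands in for exogenous
population projections, preserving the defining property that BAU and medium
differ only in the urbanization source, with low < medium < BAU < high
intensity. Two forcing pathways (2.0 and 4.5 °C/century warming; low/high CO₂
ramps) cross with climate-model variants (hot-dry, hot-wet, average,
complementary: warming offsets and projection-period precipitation factors).
Fire targets ramp up under stronger forcing (+100% by 2100 under high
forcing, +50% under low).

## Numerical choices

- Area targets are rounded to whole cells by probabilistic rounding
  (floor + Bernoulli remainder), unbiased in expectation; shortfalls
  (eligible < target) are reported, never carried to later years.
- Automatic flows compute all amounts from start-of-year pool values, then
  apply in a fixed order; if fractional outflows would overdraw a pool they
  are rescaled proportionally with a warning.
- Weighted sampling without replacement uses `Generator.choice`; equal-weight
  ties are broken by the rng, never by cell id.
- Time-since-transition resets on every applied transition, including
  non-class-changing ones (fire, drought, selection).
- A cell transitions at most once per year per transition group; eligibility
  is re-evaluated at each target's turn in the random order, so competing
  class-changing transitions resolve by permutation symmetry.
- The drought GLM is fit by statsmodels' IRLS (binomial/logit); under
  (quasi-)separation, coefficients are capped at |25| with a warning.
- Monte-Carlo intervals are 2.5th/97.5th percentiles across reps; window
  means divide the window sum by flux-years.

## Problem sizes

The default world is 20×20 cells (1 km² each), 3 ecoregions, 6 counties —
chosen so a century with 10 reps audits in seconds while every mechanism
(multi-cell fires, county-stratified sampling, protected masks) is exercised.
The analysis drivers use 5 reps per scenario for the crossing and 3 for the
CFE sweep; the fire and GLM recovery experiments use 500 simulated years and
n = 2,000 observations respectively.

## Known limitations

- Product pools (HWP, grain, straw) are terminal accumulators — no decay.
- Transferred (developed) stocks are frozen rather than respiring.
- The 39-pathway transition network of full statewide applications is
  represented by its constituent groups (11 pathways); the config is
  extensible but the full network is not reconstructed.
- SPEI uses z-score standardization rather than a fitted log-logistic
  distribution; indices are comparable within a run, not across datasets.
- Fire events cannot cross ecoregion boundaries.
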