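# Methods

`bogsim` is a cohort-based peatland development model on a hydrologically
coupled transect, plus the core-analysis toolkit needed to study *apparent*
carbon-accumulation rates.  This note documents the model equations, the
parameterisation and its calibration, the synthetic climate driver, the
numerical choices, and what the test suite does and does not establish.

## Model structure

### Cohorts and columns

A peatland is a line of contiguous 2 m x 2 m peat columns on a flat
impermeable base.  Each column is an ordered stack of *cohorts*: the parcel
of litter added in one year.  A cohort tracks its deposition year, initial
dry mass `m0` and current mass `m` (g m⁻²).  Two derived quantities tie the
stack to the hydrology:

    thickness    = m / ρ                      ρ  = dry bulk density
    conductivity = K_s (m / m0)^c             K_s = fresh-peat conductivity

so decomposition simultaneously thins a layer and (because decomposed peat
is denser-packed and less permeable) reduces its hydraulic conductivity.
The power-law decline with remaining mass fraction is this package's
closure; only its qualitative form (strong decline with decomposition
state) is constrained by the literature.

### Annual cycle

Each simulated year:

1. **Hydrology (weekly).** 52 explicit Boussinesq steps (below) driven by
   the weekly net-rainfall series; weekly water-table elevations recorded.
2. **Oxic exposure.** Each cohort's oxic fraction `f` for the year is the
   share of the 52 weeks in which the water table sat below the cohort's
   midpoint.
3. **Decay.** Every cohort decays `m ← m·exp(−α_eff)` with

       α_eff = [f·α_ox + (1−f)·α_an] · Q10^((T − T_ref)/10)

   where `T` is the year's air temperature and `T_ref = 7.1 °C`.  Decay
   rates are constant per regime — there is no explicit recalcitrance
   term.  The observed slow-down of decay with age *emerges* from burial
   below the water table, which is the mechanism behind the near-surface
   artefact this package demonstrates.
4. **Litter.** Production from the annual-mean water-table depth `z` (m)
   and temperature:

       P(z, T) = P_max · max(0, 1 − ((z − z_opt)/z_range)²) · e^{b (T − T_ref)}

   unimodal in `z` (reduced under inundation, zero beyond
   `z_opt + z_range`), monotone in `T`, equal to `P_max` at the optimum
   and reference temperature.  The new cohort is added at the end of the
   year.
5. **Aggregation.** Adjacent cohorts thinner than 2.5×10⁻³ m that lie
   wholly below the water table are merged (masses summed exactly;
   deposition year = mass-weighted mean; the (oldest, youngest) span is
   retained).  Cohorts above the water table are never merged so the
   0–200-yr analysis window keeps annual age resolution.

### Hydrology

Lateral saturated flow between columns follows Darcy's law with the
depth-integrated transmissivity `T(h) = ∫₀ʰ K(z) dz` of the saturated part
of the cohort profile; storage changes divide by the drainable porosity
`s`.  The centre of the bog is a no-flow (symmetry) boundary; the margin
face is a Dirichlet lagg at a fixed low water level, applied through a
ghost node half a cell beyond the last column.  Face transmissivities are
arithmetic means of the nodal values, which reduces the scheme to the
classic Dupuit finite-difference form: for homogeneous conductivity its
steady state reproduces `h² = H_b² + (P/K)(L² − x²)` at the nodes exactly
(one acceptance test checks this to <1% RMS).

Within a week the explicit update is sub-stepped with
`dt ≤ 0.4·s·dx²/coeff_max`, where `coeff_max` bounds the nodal update
coefficients using the *fully saturated* transmissivities (an upper bound
over all admissible heads), so the step count is fixed within a year.  A
configurable ceiling (default 20,000 sub-steps/week) turns runaway
transmissivities into an explicit error rather than a silent hang.  Water
tables are capped at the peat surface — the excess is recorded as runoff,
which is the reason the driver imposes a seasonal cycle at all — and
floored at the base, with unmet evapotranspiration demand recorded.  Both
budgets (water, per week; dry mass, per year) close to ≤10⁻¹⁴ relative and
are enforced at ≤10⁻⁶ by property tests.

### Ditch drainage

The drained scenario cuts ten 0.5 m deep contour-parallel ditches, the
first 10 m from the margin and the rest at 12 m spacing, 200 years before
the end of the run; they stay open to the end.  Excavation removes the top
0.5 m of each ditched column (the partially intersected cohort is split
pro-rata by thickness, preserving its decomposition state `m/m0`) and
converts the column to a fixed-head node at the new surface.  Design
choices the sources leave open, resolved here: the ditch water level is
fixed at the excavation-time level and does **not** track subsequent
subsidence; ditch columns receive no litter while open (they are open
water); only the top 0.5 m is removed, not the whole column.

The natural and drained scenarios share climate and seed.  Because the
model is deterministic given the climate series, the experiment runner
advances one simulation to the ditch-opening year and branches it, which
is exactly equivalent to two full runs (a test asserts bit-identical
results) at half the cost.

## Core analysis

A *virtual core* is the end-of-run cohort inventory of one column —
normally the centre–margin midpoint, comfortably between two ditches in
the drained scenario.  Ages are years before the notional present (the end
of the run).

The apparent C accumulation rate between sequential layers is half the
summed pair mass divided by the pair's age increment, times the carbon
fraction (0.5 g C per g dry peat):

    rate_i = 0.5 · [(m_i + m_{i+1})/2] / Δage_i

Age increments use the layers' mass-weighted **mean** ages.  For unmerged
annual layers this is 1 yr, identical to using span edges; for merged
layers it is the consistent choice — a uniform profile yields the same
rates before and after aggregation, and windowed means are invariant to
aggregation within 5% (tested).  Using span edges instead would divide a
multi-year pair mass by a 1-yr increment wherever a merged layer abuts
annual layers and inflate rates severalfold.

Windowed means are Δage-weighted (entries represent unequal spans after
aggregation).  `LORCA = 0.5·Σm / basal age`.  The drainage-period budget
partitions the stock change of a column as `net = N − A_o − C_s`: `N` is C
remaining in material deposited after the period start, `A_o` losses from
peat that then lay above the annual-mean water table (original acrotelm),
`C_s` losses from peat below it (original upper catotelm).  The partition
is tracked exactly by per-cohort mass components that follow every decay,
merge and excavation, so the identity closes to rounding.

## Synthetic climate driver

The driver emulates a 6,000-year Holocene-style reconstruction with known
long-term means: 96.2 cm yr⁻¹ net rainfall and 7.1 °C.  Both variables are
AR(1) processes affinely rescaled so the sample mean (and sd) hit their
targets exactly — the analogue of using one fixed reconstruction.  Chosen
once as field-realistic, not revisited: rain sd 8 cm, temperature sd
0.4 °C, lag-1 autocorrelation 0.85 for both (multidecadal persistence).

Annual net rainfall is distributed into 52 weekly depths by a fixed
seasonal pattern of share-of-annual-total weights (so weekly depths always
sum to the annual value).  The default pattern is a sinusoid with
amplitude 1.8: a winter surplus and ~15 mid-summer weeks in deficit
(negative net rainfall ≈ −1.5 cm wk⁻¹ at the trough), which drives the
summer water-table drawdown (to ~0.45 m at the midpoint) that creates the
acrotelm.  A measured 52-week pattern can be supplied via
`derive_seasonal_pattern`; "proportional difference" is read as
share-of-total, the only reading under which multiplying an annual value
by the 52 weights returns depths that sum to that value.

## Parameters and calibration

Defaults (all in `ModelParams` / the default config):

| parameter | value | units | note |
|---|---|---|---|
| α_ox | 0.0493 | yr⁻¹ | calibrated |
| α_an | 1.3×10⁻⁴ | yr⁻¹ | calibrated; α_ox/α_an ≈ 380 |
| Q10 | 2.5 | – | typical soil-respiration range |
| P_max | 800 | g m⁻² yr⁻¹ | calibrated |
| z_opt / z_range | 0.15 / 0.45 | m | production optimum / zero cutoff |
| b (production T ramp) | 0.08 | °C⁻¹ | mild sensitivity |
| ρ | 1.0×10⁵ | g m⁻³ | 0.1 g cm⁻³ |
| K_s | 30 | m wk⁻¹ | fresh surface peat |
| c (K exponent) | 3 | – | |
| s (drainable porosity) | 0.3 | – | |
| carbon fraction | 0.5 | g C g⁻¹ | |
| aggregation threshold | 2.5×10⁻³ | m | |
| lagg level | 0.05 | m above base | |

The per-process equations and parameter values are this package's own
construction and were **calibrated**, by running the full natural
configuration, so that the default 6,000-year run reproduces the published
core statistics of a temperate raised bog: a ~3.4 m mid-transect core, a
pre-industrial (ages 150–1,150 yr) mean apparent rate near 27 g C m⁻² yr⁻¹
(well inside the 3–80 field range), a 200–600-yr rate near 30, and a
0–200-yr rate several-fold higher.  Two points a maintainer should know:

* The cohort/water-table feedback makes the deep-peat equilibrium very
  sensitive to α_ox (acrotelm residence time scales inversely with the
  mass flux that survives it), so seemingly small rate changes move the
  catotelm stock a lot.
* The published statistics over-determine a constant-ρ model: the mass
  implied by the 0–200-yr rate inside the reported thickness of <200-yr
  peat implies ρ ≈ 0.13 g cm⁻³, while the reported total thickness with
  the deep-layer masses implies ρ ≈ 0.10 and much slower anoxic decay.
  Calibration therefore prioritises the window rates and total thickness;
  the thickness-of-young-peat diagnostic is reported but sits ~15% above
  the published value, and the 0–200-yr rate sits at the low edge of its
  ±15% band (~120 vs 139.7).

## What the synthetic experiment does and does not show

The driver is statistically stationary: it reproduces the *means* and a
plausible persistence structure, not the actual Holocene sequence of wet
and dry centuries.  Consequently (i) run statistics vary a few percent
across seeds — the acceptance checks average ≥3 seeds; (ii) the model's
late-Holocene window rates carry no real climate-history signal, whereas a
real reconstruction imprints its own centennial structure on them.  The
near-surface artefact itself is robust to all of this: under *zero*
climate variance the 0–200-yr rate still exceeds the 200–600-yr rate more
than two-fold, demonstrating that the hockey-stick in apparent rates
requires no change in climate or management.  Real peat additionally has
depth-varying bulk density, vegetation succession, and recalcitrance
dynamics that this model deliberately omits; passing tests validate the
mechanism and the accounting, not a site-specific hindcast.

## Numerical and degenerate-input choices

* All randomness lives in the climate driver; a run is a pure function of
  (parameters, climate series).  Seeds reproduce runs bit-for-bit.
* Zero litter years are skipped (no empty cohorts); a fully decayed cohort
  keeps `m ≥ 0` exactly and merges into neighbours once below the
  threshold.
* Merged-layer deposition years are mass-weighted means with the `m0`
  weighting as fallback for fully decayed material; merged spans are kept
  for pro-rata selections (thickness-younger-than, mass-deposited-before).
* Empty analysis windows raise an explicit error in the library; the
  experiment pipeline records them as NaN (they occur only in short smoke
  runs whose cores are younger than the default windows).
* The Dupuit acceptance oracle uses long (10-week) steps purely to reach
  steady state quickly; stability sub-stepping makes this equivalent to
  many weekly steps.
* Excavating with `depth ≥ column height` is an error (a ditch cannot
  remove a whole column); comparing scenario directories with different
  climate hashes is refused.

## Problem sizes used by the checks

The acceptance suite runs the full study configuration: 6,000 years x 75
columns (three seeds for the natural statistics, one shared-seed
natural/drained pair, one constant-climate run).  Conservation property
suites use randomized 8–20-year, 3–6-column runs (100 cases).  Examples
use reduced sizes (≤1,500 yr, ≤40 columns) chosen to finish in seconds
while showing the same qualitative behaviour.
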