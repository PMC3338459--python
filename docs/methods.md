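# Methods

`larvadrift` couples four components: a kinematic wind-driven shelf
circulation, a Lagrangian individual-based model (IBM) of shore-crab larvae
with diel vertical migration (DVM), stage-structured growth and physiological
mortality, and the recruitment/validation statistics used to compare predicted
larval supply with observations. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The idealized ocean

The domain is a straight-coast Cartesian shelf: coast at `x = 0` (km, positive
offshore), `y` alongshore (km, positive poleward), `z` depth (m, positive
down). The real, curved coastline of an eastern-boundary upwelling region is
mapped onto the alongshore coordinate; the mechanisms the package tests
(alongshore advection, cross-shore Ekman exchange, DVM shear-retention) do not
require coastline curvature. Default bathymetry rises from 40 m at the coast
to 100 m at 30 km offshore and steepens to 500 m by 50 km, placing the shelf
break near 43 km; the 40-m coastal depth keeps several 10-m vertical cells
wet inside the release boxes, so the overturning cell (which closes between
the first and last wet cell centers of each column) is resolved over the
inner shelf where the larvae are.

Circulation is **kinematic**: prescribed from an alongshore wind-stress series
`tau_y(t)` through transfer functions, not solved dynamically. The wind series
is an AR(1) process with a configurable decorrelation time (default 5 d,
emulating the alternation of upwelling and downwelling events in spring) and
stationary standard deviation `amplitude` (default 0.05 N m^-2).

* **Alongshore flow** `v = v_bg + g_v * tau_f * exp(-z / h_v)`, where `tau_f`
  is the stress low-pass filtered with a 1-d geostrophic-adjustment time
  scale, `g_v = 2.0 (m s^-1)/(N m^-2)` and `h_v = 80 m`. The background drift
  `v_bg = -0.03 m s^-1` represents the weak equatorward mean flow of the
  upwelling season. All are order-of-magnitude shelf values and
  config-exposed; no calibrated set exists for an idealized domain.
* **Cross-shore overturning**: `u` and `w` derive from a streamfunction
  `psi = U_E F(x) G(z)` with Ekman transport `U_E = -tau_f / (rho f)`
  (positive offshore under equatorward stress). `F` ramps 0 to 1 over 15 km
  from the coast; `G` is 0 at the uppermost cell center, 1 at the second, and
  decays to 0 at the deepest wet cell center, closing the cell. `psi` is held
  on a ghosted cell-center grid and differenced with the same centered
  operators used by the divergence check, so the discrete cross-section
  divergence is zero to rounding and the depth-integrated cross-shore
  transport telescopes to zero exactly. This is the structure the retention
  mechanism needs: offshore surface flow with a compensating onshore
  undercurrent during upwelling, and the reverse (coastal convergence) during
  downwelling.
* **Temperature** is stratified (11 degC at depth to 17 degC at the surface,
  80-m e-folding), with coastal surface cooling up to 2 degC during upwelling
  events. **Salinity** is 35.8 psu everywhere except fixed low-salinity
  plumes (up to 2 psu fresher) at estuary mouths.

Fields are archived every 4 h (the storage interval of typical hydrodynamic
hindcasts) and consumers interpolate linearly in time. Archives round-trip
losslessly through NetCDF (scipy backend, NetCDF3).

## The individual-based model

Larvae advance with a two-stage predictor-corrector (Heun) step on the
horizontal at `dt = 300 s`; a tiny-step Euler integration serves as the
accuracy oracle in tests. Because the archived fields are smooth, scheme
order beyond two is immaterial at this step size. Field values are sampled
trilinearly in space and linearly in time by a hand-rolled uniform-grid
sampler (exact at nodes; verified against scipy's RegularGridInterpolator).

Vertical position combines (i) vertical advection, (ii) swimming toward the
DVM target at up to `w_swim = 0.01 m s^-1` (enough to complete a 60-m
excursion within a 2-h transit window; a particle at its target holds depth),
and (iii) a random vertical velocity `N(0, 1e-3 m s^-1)` parameterising
unresolved turbulence, with reflection at the surface and bottom. The DVM
target is the deep level (bottom layer, or 60 m where the column is deeper)
between 06 h and 20 h local time, the surface layer between 22 h and 04 h,
and a linear ramp between the two during the dusk and dawn transits. The
transit kinematics, turbulence magnitude and boundary policy are not fixed by
any published source; all are config-exposed defaults. Local solar time is
the simulation clock modulo 24 h (no longitude correction on an idealized
domain).

Boundaries: offshore and alongshore exits set the fate `left_domain`;
onshore overshoots are repositioned to the nearest wet position (no beaching
deaths). Internal state can be recorded every 2 h.

Growth: age runs 0 (hatching) to 4 (moult to megalopa), one unit per zoeal
stage; the megalopa is competent until age 5, then dies of old age. Age
advances by `dt / stage_duration(stage, T)` with stage durations linearly
interpolated in temperature (clamped at the table ends). "Fast"/"slow"
growth modes shift every stage duration by -/+ 1 d (about 20% of the
estimated planktonic larval duration), floored at 0.5 d.

Mortality: an instantaneous rate `m(stage, T, S)` (d^-1), bilinearly
interpolated, converted per step to `p = 1 - exp(-m dt)` — stable at any dt
and equal to `m dt` to first order at 300 s. The shipped growth and
mortality tables are **synthetic stand-ins**: the laboratory rearing data
behind the original parameterisation are unpublished. The growth table is
constrained so total development spans ~42 d at 10 degC to ~28 d at 22 degC
(four to six weeks); the mortality table sits at the low end of the reported
envelope for marine larvae (0.0161 d^-1) over the tolerated shelf range
(12-20 degC, 25-36 psu — shore-crab larvae tolerate the region's T/S widely)
and rises quadratically toward the envelope's upper end (1.0100 d^-1)
outside it, with the earliest zoeal stages slightly more sensitive.
Megalopal duration is temperature-dependent like the zoeal stages, and
competence spans the whole megalopal stage. User tables load from CSV.

## Release and recruitment

Each estuary releases `225 larvae night^-1` on four consecutive nights per
fortnightly pulse (900 per pulse), within the release season. Release occurs
at a fixed nocturnal hour (23:00) — the tidal component of the natural
release rhythm cannot be honored in a tide-free model, but the nocturnal
surface release preserves the interaction with the DVM cycle. The fortnight
phase anchors to the season start (no lunar calendar is modelled). Positions
are uniform over the ~12 x 12 km shelf box adjacent to each estuary (the
plume's area of influence), in the surface layer.

The default eight-estuary table reproduces the documented alongshore
separations relative to the focal estuary (Aveiro): Mondego 57 km south,
Noia-Muros 232 km and Betanzos 377 km north, with all pairs at least 40 km
apart; remaining coordinates are spaced plausibly, since no full table is
published.

Supply is the number of competent megalopae (4 <= age < 5) *crossing* an
estuary box — entry transitions, not per-step occupancy, so a slow particle
lingering in a box counts once per passage. Any depth within the box's water
column counts. Base mode logs every distinct entry and keeps the particle;
Invasion mode recruits on first entry and removes the particle from further
accounting. Mortality replicates (default 3 in mortality experiments) share
bitwise-identical trajectories — physics randomness is drawn positionally
over particle slots from a stream independent of the per-replicate mortality
streams — so replicate supply series differ only by independent thinning,
and are combined by pointwise averaging. Within a step the precedence is
domain exit > senescence > mortality > recruitment.

## Validation statistics

Daily supply series are smoothed with a centered 5-d moving average (edges
trimmed — no padding fabricates values) and differenced at lag 1 to remove
the strong day-1 autocorrelation. Cross-correlation lags the observed series
relative to the predicted one: negative best lags mean predicted maxima
precede observations. The 95% significance bound is the large-sample
`1.96 / sqrt(N)` approximation on the differenced series; the effective N
after smoothing is an acknowledged approximation, not an exact test.

Cross-shelf trajectory density accumulates entry transitions per cross-shore
column within a stated alongshore band (consistent with the recruitment
crossing semantics); predicted and observed profiles are compared by Pearson
correlation of `log(x + 1)` values (admitting zero cells) with Bonferroni
correction over the batch.

Realized dispersal of each recruit is `d = y_source - y_destination`
(negative from south, positive from north; 0 for self-recruitment), with
means and extremes split by origin side and mean daily contributions per
source estuary. The survival budget splits hatched larvae into recruited,
died of physiological stress, and wastage = 100% minus the other two
(larvae lost from the shelf, dead of old age, or still at sea at the end);
the fate partition is exact by construction at every output time.

## Pseudo-observations

Field observations of megalopal supply are overdispersed daily counts: long
zero runs punctuated by multi-day pulses. The pseudo-observation generator
fabricates an "observed" series from a predicted one by shifting it a known
number of days, scaling, applying gamma-Poisson (negative-binomial-type)
noise with dispersion k = 2 (variance = mu + mu^2/k, strongly overdispersed)
and 10% random dropout days. These defaults are what the observed series'
pulsed character suggests; passing the lag-recovery test shows the statistics
chain recovers a known timing relationship under realistic count noise — it
does not validate the circulation or biology against real field data, which
would require a hindcast ocean, the laboratory rearing tables and the actual
net-sampled supply series.

## Problem sizes

The desk-scale reference run used by the heavier tests and the acceptance
script is a 120-day ocean (721 archived snapshots on a 20 x 40 x 50 cell
grid) with a 74-day release season — six fortnightly pulses from all eight
estuaries at 450 larvae per night, i.e. 86,400 larvae, the full design's
annual emission total compressed into the desk window so that supply counts
carry the same statistical weight — and two mortality replicates sharing one set
of trajectories. The full-design release
arithmetic (12 pulses, 86,400 larvae per year) is checked exactly on the
schedule itself, which needs no ocean.

## Known limitations

- No tides (and hence no semilunar supply component), no selective
  tidal-stream transport, no estuarine interior dynamics.
- No predation or food limitation; mortality is physiological only.
- No seasonal or spatial variation in hatching output.
- The circulation is kinematic and alongshore-uniform; it reproduces the
  qualitative upwelling/downwelling structure, not any particular hindcast.
- The growth/mortality tables are documented stand-ins, not the unpublished
  laboratory data; absolute rates (supply magnitudes, survival percentages)
  are therefore illustrative, while the mechanism-level properties (DVM
  retention direction, replicate consistency, lag recovery, bookkeeping
  identities) are the tested claims.
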