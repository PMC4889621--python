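# Methods

This note documents the model equations, the numerical and design choices
behind `casafusion`, and what the synthetic test bed does and does not
establish about behaviour on real data.

## Grids and rasters

All grids are regular geographic-degree grids with square cells,
pixel-is-area semantics, row 0 at the north edge and half-open cells:
pixel (r, c) covers `[lon0 + c·s, lon0 + (c+1)·s)` ×
`(lat0 − (r+1)·s, lat0 − r·s]`. Points on shared edges therefore belong
to exactly one cell, which makes fine-cell counting and point-in-pixel
extraction unambiguous. Internal computation is float64 throughout
(water-balance accumulation over 24+ months needs the headroom); files
are written float32. Two geotransforms are considered equal within
1e-9°, absorbing float noise in file metadata. GeoTIFF I/O goes through
`tifffile` with the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, a minimal WGS84 GeoKey directory) and the GDAL_NODATA
convention, one band per file, filename pattern `{var}_{YYYY}_{MM}.tif`.
Only geographic-degree grids are supported; there is no reprojection.
Climate rasters are brought onto the model grid by nearest-neighbour
resampling (target-cell-center containment); the resampling kernel for
scalar inputs is a declared choice of this package, kept to nearest so
that categorical and scalar inputs are treated identically and no values
are invented.

## Fusion

**Fractional cover.** The fraction of class k in a coarse pixel is the
count of valid fine cells of class k whose centers fall inside the pixel,
divided by the count of all valid fine cells there. Membership is by cell
center in half-open boxes, so no fine cell is double-counted. Pixels with
no valid fine coverage are nodata in every class. Fractions sum to 1
(±1e-6) wherever defined.

**Pure pixels.** A coarse pixel is pure for class k when its fraction is
**at least** the purity threshold (default 0.9); the boundary is
inclusive, matching a mask that removes values *below* 0.9. Pure pixels
become points at their pixel centers; the EVI of the containing coarse
pixel is sampled per point and month, with nodata months flagged missing
rather than zero. Classes without a single pure pixel are flagged
unavailable and excluded from compositing (the composite is renormalised;
see below).

**IDW.** The interpolated value at x is `Σ wᵢzᵢ / Σ wᵢ` with
`wᵢ = d(x, xᵢ)^(−p)` over the k nearest valid samples (default k = 12,
no distance cap — a reproducible, parameter-light realisation of a
variable-radius search). Distances are planar in degrees on the model
grid; at the ~0.004° scale of interest the metric distortion is a smooth,
nearly-constant anisotropy that IDW weights absorb, and the choice keeps
the interpolator exactly reproducible. IDW is an exact interpolator: a
query coinciding with a sample returns that sample's value (the mean over
coincident samples, which also removes the division-by-zero case
deterministically). Output is clipped to the EVI valid range [−0.2, 1].

**Power selection.** The exponent p is chosen per class from the
candidate grid {1.0, 1.5, …, 4.0} by leave-one-out cross-validation,
minimising the root mean square prediction error; scores within 1e-12 of
the minimum are treated as ties and the smallest power wins (weight-sum
rounding otherwise makes the argmin of a constant field arbitrary). By
default one power is fitted per class on a representative month — the
month of highest mean sampled EVI, i.e. peak greenness, when the signal
is strongest — with an optional per-month refinement.

## CASA light-use-efficiency model

`NPP = Sr × IVI × e_max × T × W`, per pixel and month, in gC m⁻²
month⁻¹, with `e_max = 0.55` gC/MJ PAR. The equation multiplies total
shortwave irradiance Sr directly; the irradiance→PAR conversion is
treated as absorbed into the constant rather than applied as a separate
0.5 factor, so `e_max` must not be reinterpreted as efficiency per unit
PAR absorbed. Negative IVI (water, snow) contributes zero NPP by default
(`npp_nonnegative`).

**Temperature scalar.** `T = T1 × T2` with
`T1 = 0.8 + 0.02·Topt − 0.0005·Topt²` and
`T2 = 1.1814 / [(1 + e^{0.2(Topt − 10 − t)})(1 + e^{0.3(−Topt − 10 + t)})]`,
clipped to [0, 1] — the classical CASA form: a broad optimum near
`t = Topt` collapsing in deep cold or extreme heat. `Topt` defaults to
the long-term mean temperature of the climatologically warmest month per
pixel, clipped to [0, 35] °C, giving a latitude/longitude-varying optimum
without an external map; a scalar or raster override is accepted.

**PET.** Priestley–Taylor:
`PET = α · Δ(t)/(Δ(t)+γ) · Rn/λ` with α = 1.26, γ = 0.066 kPa °C⁻¹,
λ = 2.45 MJ kg⁻¹ (1 kg water ≡ 1 mm), and Δ the slope of the saturation
vapour-pressure curve (Tetens form). Net radiation is taken equal to the
solar-irradiance input (no albedo or longwave correction); the
Priestley–Taylor α partially absorbs this simplification, and PET is only
consumed through the ratio EET/PET, which is insensitive to a common
scale factor whenever water is not limiting.

**Water balance.** Three buckets (surface organic, topsoil, subsoil to
rooting depth) with texture-class capacities, defaults in mm:

| texture | layer capacities |
|---|---|
| organic | 40 / 150 / 300 |
| 0–5 % clay | 25 / 100 / 200 |
| 5–15 % clay | 21.7 / 86.7 / 173.3 |
| 15–30 % clay | 18.3 / 73.3 / 146.7 |
| ≥30 % clay | 15 / 60 / 120 |
| lithosol | 10 / 40 / 80 |

The clay classes step linearly between their end members; the table is
configuration, not measurement — the workflow this package implements
published no capacity values, so these are order-of-magnitude defaults
chosen once (organic soils holding the most water, lithosols the least)
and exposed in full. A `rooting_multiplier` (default 1.0) scales the
subsoil capacity; 1.8 reproduces the deep-rooted woodland adjustment that
makes 80 % more soil water available to trees. Implementing the
multiplier as extra storage (rather than as an extraction factor) is what
keeps the conservation identity below exact while still giving
deep-rooted vegetation access to more water.

The monthly step: when precipitation meets the demand (`P ≥ PET`),
`EET = PET`, the surplus recharges the layers top-down to capacity and
the remainder leaves as drainage; otherwise all precipitation evaporates
and the deficit is drawn from the stores top-down, limited by their
content, so `EET = min(PET, P + extractable)` and drainage is zero. The
budget `P = Δstorage + EET + drainage` closes to better than 1e-9 mm per
step by construction. `W = 0.5 + 0.5·EET/PET` when `PET > 0`, else 1.0.

**Spin-up.** Layers start at half capacity and the balance runs over the
24 forcing months preceding the first reporting month, so the reported W
reflects an equilibrated reservoir carrying last year's moisture into the
current year. When the supplied climate covers only the reporting span,
the first reporting year is repeated twice as spin-up forcing (a
documented fallback, exact when the climate is periodic).

## Compositing

Per-class NPP is multiplied by the class's fractional cover and summed
per pixel; classes absent from a pixel contribute nothing. When some
class has no pure pixels anywhere, its fraction is missing from the sum;
the composite is then renormalised by the total contributing fraction
(configurable off) and that fraction is emitted as a coverage-diagnostic
raster, so partial class coverage is visible rather than a silent low
bias. A landscape that is 100 % one class composites to that class's
model output bit-for-bit.

## Tower evaluation

Sites qualify with ≥ 3 distinct calendar years in which all 12 months
carry a finite GPP value. Tower NPP = ratio × GPP with ratio ∈
[0.40, 0.50], default 0.40. Modelled NPP is extracted at the containing
pixel or as the mean of the valid cells in the 3×3 window centered on it
(truncated at grid edges). Regression is ordinary least squares with
tower NPP as the response and modelled NPP as the predictor; r² is the
squared Pearson correlation (orientation-free), bias% =
100·(mean modelled − mean tower)/mean tower, and groups with fewer than
3 pairs or zero variance report their statistics as missing, never as 0.
Seasons default to winter = {12, 1, 2}, spring = {3, 4, 5}, summer =
{6, 7, 8}, autumn = {9, 10, 11} (configurable). Because Pearson
correlation is invariant to rescaling either series, r² is *identical*
under any ratio in the admissible range — the testable core of the claim
that the ratio choice does not matter for correlation-based evaluation. A
neutral paired t-test utility compares absolute residuals under two
ratios; its interpretation is left to the user.

## Synthetic scenes

The generator is a pure function of its configuration (seed included).
Defaults define the reference study conditions: a 40×40 coarse grid at
0.004° with fine:coarse ratio 13 (~0.0003° land cover inside ~0.004°
EVI pixels), three land-cover classes allocated by per-class
Gaussian-smoothed random fields (argmax allocation → contiguous patches
with a realistic mix of pure and mixed pixels), three reporting years
plus two spin-up years of climate, and six towers generated at a true
NPP:GPP ratio of 0.47 — the published forest-site mean — with
configurable Gaussian GPP noise. Per-class EVI phenology is sinusoidal
(class-specific mean, amplitude, peak month, bounded inside [−0.2, 1]);
temperature and precipitation are sinusoidal annual cycles (peaks July
and June) with optional noise; solar irradiance is a deterministic
flat-surface clear-sky monthly total from extraterrestrial radiation
(declination, sunset hour angle, eccentricity) times a transmissivity of
0.75.

What the synthetic bed does *not* emulate: real land-cover spatial
statistics, MODIS compositing and cloud-contamination artifacts,
topographic shading and terrain solar effects, irrigation and harvest
cycles, disturbance. Passing the recovery tests therefore demonstrates
the internal consistency and exactness of the chain (counting, convex
interpolation, conservation, compositing algebra) — not predictive skill
on managed or disturbed landscapes, where the evaluation of the method on
real towers is known to degrade.

## Numerical choices and degenerate inputs

* IDW tie-break for power selection: 1e-12 absolute tolerance, smallest
  power wins; coincident samples average.
* Constant-recovery through the fusion chain is exact (to 1e-6) only when
  sampled pixels are *fully* pure; at the operational 0.9 threshold a
  pure pixel retains up to 10 % foreign signal by definition, and the
  recovery tests extract at threshold 1.0 accordingly.
* Fractions, scalars and NPP are clipped to their physical ranges after
  computation; exponential arguments in the temperature scalar are
  clipped at ±700 to avoid overflow far outside the physical range (the
  scalar is ≪ 1e-250 there regardless).
* Empty sample sets, all-mixed landscapes, incomplete tower years and
  zero-variance regressions are flagged (warning, `None`, or exclusion),
  never silently coerced to zero.
* Problem sizes in the test suite and the reproduction script (40×40
  coarse grids, 3 classes, 36 reporting months, 1000-pixel water-balance
  ensembles) were chosen as the smallest scenes that exercise every code
  path with spatial structure to spare; all complete in seconds.

## Known limitations

Single-CRS geographic grids only; planar degree distances in IDW; Rn
approximated by Sr in PET; no heterotrophic respiration, carbon pools or
nitrogen dynamics (NPP only, not NEP); land cover static in time;
elevation is accepted as an input but not used by the model equations.
The soil-capacity table and the synthetic phenology/climate parameters
are defaults to be overridden with site-specific values for any real
application.
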