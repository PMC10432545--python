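# Methods

`canopytherm` reproduces a complete urban-canopy thermal analysis for the
built-up area of Luoping County (Yunnan): land surface temperature (LST)
retrieval from a single thermal band, canopy patch delineation and landscape
metrics, cooling-rate statistics, and the regression analysis linking patch
geometry to its cooling effect. This note records the models, the parameter
choices, and the places where the design was genuinely open.

## LST retrieval (single-channel atmospheric correction)

The at-sensor thermal radiance of a surface at temperature `T_s` seen through
an atmosphere with transmittance `τ` and path radiances `L↑` (upwelling) and
`L↓` (downwelling) is

    L_λ = [ε B(T_s) + (1 − ε) L↓] τ + L↑

where `ε` is the surface emissivity and `B` the band-effective Planck
radiance. Retrieval inverts this analytically:

    B(T_s) = (L_λ − L↑ − τ (1 − ε) L↓) / (τ ε)
    T_s    = K2 / ln(K1 / B(T_s) + 1)

with band calibration constants `K1` (W·m⁻²·sr⁻¹·µm⁻¹) and `K2` (K).
Defaults are the Landsat 8 TIRS band-10 constants, `K1 = 774.89`,
`K2 = 1321.08`, and the atmospheric profile of the Luoping scene,
`τ = 0.91`, `L↑ = 0.75`, `L↓ = 1.29` W·m⁻²·sr⁻¹·µm⁻¹. The kelvin↔Celsius
offset is exactly 273.15.

Emissivity is linear in the vegetation fraction, `ε = 0.004 P_V + 0.986`,
with `P_V = (NDVI − NDVI_soil)/(NDVI_veg − NDVI_soil)`. The NDVI endpoints
are not part of the retrieval formula itself and are configurable; defaults
`NDVI_soil = 0.05`, `NDVI_veg = 0.70` follow common Landsat practice, and
`P_V` is clipped to [0, 1] outside the endpoints. Under the default
coefficients `ε ∈ [0.986, 0.990]`, so the retrieval is insensitive to the
endpoint choice at the 0.1 K level; the round-trip property below holds for
any endpoints as long as forward and inverse use the same ones.

Numerical care: `expm1`/`log1p` are used around the Planck exponential;
cells whose corrected radiance is non-positive (radiance at or below the
path radiance) become nodata and are counted in the log, as are zero-sum
NDVI denominators. Nodata (NaN) propagates through every stage.

## Temperature levels (natural breaks)

LST maps are classified into five ordered levels (low … high) by Jenks
natural breaks: the partition of the sorted values into `k` contiguous
classes minimising the total within-class sum of squared deviations. The
implementation is the exact Fisher–Jenks dynamic program (O(k n²)), not the
iterative heuristic; ties between equally good partitions are broken toward
the smallest upper bound of the lower class. Each interior break is the
smallest member of its upper class, and classification uses lower-closed /
upper-open intervals with the top class closed, so a value exactly on a
break goes to the upper class — this matches contiguous printed ranges such
as 28.32–30.15 / 30.15–31.56 °C. Correctness is tested against brute-force
enumeration of all break placements for n ≤ 25.

Because the DP is quadratic, whole-raster classification
(`jenks_breaks_sampled`) computes breaks on a seeded 6 000-value subsample —
the common practice for natural-breaks raster classification — while the
exact routine remains the API for vectors.

## Canopy patches and landscape metrics

Patches are maximal connected components of the tree-canopy class.
Connectivity defaults to 8 (diagonally touching crowns are one object, as in
object-based canopy delineation) and is configurable. Metrics per patch:

* area `S = n_cells · cell_size²`;
* perimeter `E` by exposed-edge counting: every cell edge adjacent to a
  non-member cell or the grid boundary contributes one cell side;
* shape index `A = E / (2 √(π S))` — the perimeter relative to that of the
  equal-area circle; 1 for a circle, `2/√π ≈ 1.128` is the raster optimum
  (a square), larger means more convoluted;
* size class on the hectare scale with lower-closed bounds: small ≤ 0.05
  hm² < medium ≤ 0.20 < large ≤ 1.00 < super-large ≤ 5.00 < extra-large.

The Luoping reference table's perimeters come from vectorised image objects,
which are shorter than raster edge-count perimeters for the same region;
raster-derived metrics are therefore validated against synthetic geometry,
while reproductions of the printed table use its own area/perimeter columns.
Areas are reported in hm² (1 hm² = 10 000 m²) and perimeters in km, matching
the exchange format.

## Cooling rate and coverage

A patch's cooling rate is its mean-LST deficit relative to the scene-wide
bare-land mean, on the percent scale:

    cooling rate (%) = 100 · (LST_bare − LST_patch) / LST_bare

Two conventions matter and are deliberate: the ×100 factor (the defining
ratio is dimensionless but the quantity is reported in percent, and the
reference values, e.g. 10.33, are only consistent with percent scaling), and
the use of Celsius in the ratio — physically arbitrary but required to
reproduce the reference arithmetic. The baseline is a single global
bare-land mean, not a per-patch local one. Patch mean LST is sampled over
the patch's cell mask on the congruent LST grid (nearest-neighbour
alignment; no area-weighted resampling).

Coverage arithmetic: current canopy coverage = canopy area / total area;
the possible additional canopy (PUTC) is the bare-land plus grassland area;
the attainable maximum coverage is their sum. The identity
`max = current + potential` holds exactly before rounding; percentages are
rounded only at presentation.

## Statistical analysis

On the 63-patch table (area, perimeter, shape index vs cooling rate):
Pearson product-moment correlations with two-tailed p from
`t = r √((n−2)/(1−r²))`; simple OLS fits with `R² = 1 − SS_res/SS_tot`
(defined as 0 for a constant response, logged); and the Durbin–Watson
statistic `DW = Σ(e_t − e_{t−1})² / Σe_t²` computed on residuals in the
table's row order — DW is order-dependent, so the loader preserves row order
and the reproduction command refuses reordered tables.

"Stepwise regression" is implemented as backward elimination: starting from
the full multiple OLS fit, repeatedly remove the predictor with the largest
p-value above α = 0.05 and refit. On the reference table this removes
perimeter first (area and perimeter are strongly collinear; p = 0.95 in the
full model), then shape index, retaining area. The reference analysis, run
with a different stepwise algorithm, reports shape index as the removed
variable and then two separate simple regressions; both analyses agree that
shape index carries no significant independent information, and the two
simple fits (cooling rate on area, and on perimeter) are reported as the
headline models in either case. No multiple-testing correction is applied
(none is in the reference analysis).

Tolerances for reproducing the printed statistics are ±0.005 on r, slopes
and intercepts and ±0.01 on R²/DW: the packaged table carries values rounded
to two decimals, whereas the original fits used unrounded data.

## Synthetic scenes

The generator paints a five-class mosaic (rectangles/discs over a background
class, later shapes overwriting earlier), draws per-cell LST and NDVI from
per-class Gaussians (NDVI clipped to [−1, 1]), synthesises reflectances as
`nir = 0.3 (1 + NDVI)`, `red = 0.3 (1 − NDVI)` — which yields the target
NDVI exactly, and only the ratio matters downstream — and forward-models
radiance through the same physics the retrieval inverts, using the
emissivity implied by the scene's own NDVI.

The default demo scene is 300×300 cells of 30 m with ≥ 10⁴ cells per class;
class mean LSTs are the Luoping values (impervious 31.44, bare 30.21, grass
30.09, canopy 29.98, water 28.43 °C) so the published class ordering is the
ground truth. The within-class standard deviation is not fixed by any
reference measurement; the default 0.3 °C is an arbitrary but configurable
choice, small enough that 10⁴-cell class means recover the targets within
0.05 °C (3σ/√n ≈ 0.009 °C).

What the generator does **not** emulate: spatial autocorrelation of LST,
sensor PSF, DN quantisation, atmospheric variability across the scene,
mixed pixels, or classification error in the land-cover map. Passing tests
therefore demonstrate the correctness of the algorithms and the exact
invertibility of the radiative chain — not retrieval accuracy on real
imagery, where emissivity error and atmospheric heterogeneity dominate.
The published whole-scene LST range (24.73–37.63 °C) depends on the original
satellite scene and is not reproducible from synthetic data; it is used only
as a plausible range for round-trip fields.

## Problem sizes

The round-trip check runs on a 512×512 grid (max |error| < 0.01 °C,
observed ~10⁻¹³ °C in float64); zonal recovery on the 300×300 demo scene;
the Jenks oracle on 200 random vectors with n ≤ 25, k ∈ {2,…,5}. The
analysis drivers use the same demo scene.

## Known limitations

* Raster perimeters exceed vector perimeters of the same region; shape
  indices from rasters and from vectorised objects are not directly
  comparable.
* The reference patch table's extra-large areas sum to 348.96 hm², while the
  published per-level composition lists 438.19 hm² for that level — the two
  printed sources disagree; the package keeps both (the table as the fixture,
  the composition values as study-area inputs) and does not reconcile them.
* The cooling rate's Celsius denominator makes it non-invariant to the
  temperature origin; it is retained for comparability, not recommended for
  new analyses.
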