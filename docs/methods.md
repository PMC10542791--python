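# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-scene tests do and do not
establish about real data.

## Processing chain

### Isolated-point filter

Space is partitioned into a fixed lattice of cubic blocks of
`block_extent` (default 4) voxels of `voxel_size` (default 1 m); a
return's block is the lattice cube containing it, anchored at coordinates
≡ 0 (mod 4 m). The return's neighbour count is the number of *other*
returns in its block, and it is removed when that count is below
`min_neighbors` (default 5) — a return with exactly five neighbours
survives. The anchored-lattice reading (rather than a per-point centred
window) makes the filter a single pass, order-independent, and exactly
reproducible; the voxel implementation is verified against an O(n²)
brute-force counter.

### Ground classification

Axelsson-style progressive TIN densification. Seeds are the lowest return
per `seed_cell_size` (10 m) cell; the Delaunay TIN over the seeds grows by
admitting returns that are (a) within `max_distance` (1.0 m) vertically of
the facet below them and (b) subtend at most `max_angle` (6°) at the
nearest facet vertex, iterating to convergence (cap 20 passes; the ground
set grows monotonically, so termination is guaranteed). These defaults
stand in for the unpublished "standard values" of production tools and are
fully configurable; the tests depend only on ground-truth recovery, not on
matching any tool bit for bit.

Densification alone under-labels: near an accepted vertex, an honest
ground echo differing only by ranging noise subtends a large angle and is
never admitted, so the strict criterion starves. The implementation
therefore separates surface construction from membership: after the TIN
converges, a final pass classifies as ground every return within
`classification_distance` (default 0.5 m) of the finished surface; outside
the TIN hull the surface is extrapolated by the nearest ground return,
matching the DTM's hull rule. 0.5 m is > 3× the ground-noise SD of the
scene model, giving ≥ 99% recall, while the lowest crown returns (crown
base ≥ half the local tree height, ≥ 1.5 m) remain untouchable.

### DTM, normalization, canopy metrics

The DTM is linear TIN interpolation of ground returns at 1-m cell centres;
hull-exterior cells take the nearest ground return's elevation so the
transect footprint has no nodata (which would break normalization at
edges). Normalization subtracts the containing DTM *pixel* value — not a
bilinear estimate — so a ground echo normalizes to approximately zero and
the operation is idempotent against a zero raster.

The CHM keeps the highest normalized return per 1-m cell, floored at zero
(negative heights are ground-noise artifacts); empty cells are nodata.
TCH is the 50-m block mean of valid CHM cells, with blocks below
`min_valid_fraction` = 0.9 coverage set to nodata rather than biased low.
The 250-m regrid uses the same rule at 0.5, looser because transect edges
only partially cover coarse cells. Conversion to biomass,

    AGB [kg m^-2] = 2 · (0.025 · TCH^1.99),

is applied *after* averaging to 50 m; because the exponent exceeds 1,
converting first would inflate the estimate (Jensen direction, asserted in
tests). kg m⁻² → Mg ha⁻¹ is exactly ×10.

### Field calibration and validation

Plot AGB is Σ stem AGB / plot area. The three growth-form allometries
(tree / palm / liana) ship as documented stand-ins — a pantropical
moist-forest ρD²H power law for trees (0.0673·(ρD²H)^0.976) and published
D-based power laws for palms and lianas — registered in an overridable
`AllometryRegistry` with citation tags; nothing downstream depends on the
specific coefficients. The validation crops the cloud to each plot
(boundary-inclusive), reuses the transect DTM, computes plot-level TCH
from CHM cells whose centres fall inside the polygon, applies the power
law, and compares the paired samples with the Wilcoxon–Mann–Whitney test.
Exact enumeration is used when n_x·n_y ≤ 400 and the pooled sample is
tie-free, else the tie-corrected normal approximation with continuity
correction; both the U statistic and the rank-sum W are reported because
software conventions differ.

### Wall-to-wall extrapolation

The training table holds one row per 250-m cell with valid LiDAR AGB and
all twelve predictors. The forest uses 500 trees, mtry = ⌈p/3⌉ = 4,
minimum leaf 5, a fixed seed, and a 20% hold-out on which R² and RMSE are
reported. Importance is scikit-learn's impurity importance, which for
regression trees is exactly the total squared-error reduction per variable
("relative influence"); it is reported raw, scaled by the maximum and as a
percentage of the sum — the normalization identities are tested against
the published example table to four decimals. Predictions with any nodata
covariate are nodata; negative predictions are clamped to zero. X and Y
enter as raw cell-centre coordinates (tree models are invariant to
monotone transforms).

### Uncertainty propagation

Level 1 (plot AGB error) multiplies each calibration plot's AGB by
1 + N(0, `plot_agb_relative_sd`); level 2 (plot sampling) bootstrap-resamples
the plot set and refits AGB = k·TCH^b by nonlinear least squares; level 3
(model residual) adds a heteroscedastic residual draw per 50-m cell
(default SD: 15% of the power-law prediction). The per-cell SD across
replicates (default 500; convergence against 1000 is < 5%) is the 50-m
uncertainty, aggregated to 250 m by block mean — full within-block
correlation, the conservative choice given the strong spatial correlation
of canopy structure at 250 m; a √(mean variance)/√n independence variant
is available. The power-law refit is initialized at the log-log linear
solution, which is already the exact optimum for noiseless data, so the
degenerate all-noise-off case collapses to exactly zero SD.

The satellite level redraws each training response from
Normal(AGB, SD) truncated at zero (negative biomass is unphysical; the
truncated-draw count is logged), retrains the forest and predicts the full
map per replicate; the uncertainty map is the per-pixel SD across maps
(25 for tests, 1000 for full runs). Replicate seeds derive from the master
seed by a counter. By default the forest seed also varies per replicate;
with `vary_model_seed=False` the forest is held fixed so that a zero SD
input provably collapses the output to zero — the variance accumulator
works on deviations from the first replicate, which makes that collapse
exact in floating point.

### Reporting

Carbon is AGB × 0.47. Map comparison nearest-resamples the reference onto
the candidate grid, restricts to a binary mask and reports candidate −
reference (negative = candidate lower). Map summaries are cell-weighted
(not area-weighted) over valid cells with the population (n) SD
convention; both choices are fixed so results are reproducible.

## The synthetic scene

The generator emulates the acquisition design — a rectangular transect at
4 returns m⁻² (default test extent 500 m × 300 m so a full run fits in a
test session; 12.5 km × 300 m remains a config choice) — over a model
forest chosen to behave like dense terra-firme Amazon canopy:

* **Terrain**: Gaussian-filtered white noise (σ = correlation/2 cells),
  min-max rescaled to `terrain_relief_amplitude` (12 m) peak-to-trough
  over a 150-m correlation length, around a 100-m base elevation.
* **Stand**: Poisson stems at 500 ha⁻¹ modulated by a mean-one smooth
  log-normal intensity field (CV 0.20, 400-m scale). Canopy height is a
  smooth patch field (80-m scale) plus small tree-to-tree scatter (0.5 m),
  total SD 6 m around a 24-m mean, floored at 3 m — real canopies are
  spatially autocorrelated, and this is what makes a 4-m voxel filter safe
  on real clouds. DBH couples to height as 0.377·H^1.3 with 10% log-normal
  scatter; wood density is N(0.62, 0.08) clipped to [0.3, 0.95]; growth
  forms are 90/6/4% tree/palm/liana; crown radius is 1.5 + 0.18·H.
* **Crowns and returns**: cone-capped cylinders (full height over the
  inner half radius, tapering 10% to the edge), composited by maximum and
  morphologically closed over 5 m — a continuous canopy mantle, not
  isolated cones. Each 1-m column draws Poisson(4) returns; under canopy a
  return is a crown echo with probability 0.70, vertically uniform within
  a 1.2-m mantle below the local surface, otherwise a ground echo. Ground
  echoes scatter as spatially correlated micro-relief (12-m scale) plus
  3-cm ranging noise, 0.15 m marginal SD — within the survey's stated
  0.5-m vertical accuracy. Isolated noise points are injected 10–100 m
  above the canopy in pairwise-distinct 4-m blocks, so the filter's 100%
  recall on them is a construction guarantee, and its false-removal rate
  (< 1% at these defaults) is the informative number.
* **Calibration consistency**: the DBH scale constant (0.377) was fixed
  once so that stem-allometry biomass and the canopy-height power law
  agree in the mean on the default scene — the synthetic forest is, by
  construction, a forest for which the published TCH power law is
  unbiased, exactly the property a real calibration campaign enforces.
  With it, plot means land at ≈ 28–36 kg m⁻² and the field-vs-LiDAR
  rank-sum test does not reject.
* **Covariates** (built when the extent divides the 250-m grid):
  vegetation indices are saturating functions of true AGB
  (e-folding 120–150 Mg ha⁻¹) over 23 pseudo-composites with 0.03
  per-composite noise and a small seasonal cycle, so q1/mean/q3 are
  non-degenerate; HV saturates at 130 Mg ha⁻¹ with 0.6 dB noise, HH more
  weakly at 250 Mg ha⁻¹ with 0.8 dB; precipitation is a smooth spatial
  gradient; SRTM is the mean-aggregated terrain; X/Y are exact cell
  centres.

Model-recovery and uncertainty experiments use a larger stand-only scene
(6.25 km × 2.5 km, 250 cells at 250 m, 10-m terrain cells, density-field
CV 0.35 at 500-m correlation) — regional heterogeneity is stronger than
within-transect heterogeneity, and 250 training cells keep a full forest
fit plus ~130 Monte Carlo retrains inside a test session.

### What the synthetic tests do not show

The generator has no multi-return pulse physics, scan-angle geometry,
GNSS error, waveform radiometry, within-transect density variation, or
sensor-specific noise; covariate links are idealized monotone curves with
independent noise rather than real atmospheric and phenological artifacts.
Passing tests therefore demonstrate that the *implementation* of each
stage is correct and that the chain recovers known truth under the stated
forest model — not that the published map's accuracies would be reproduced
on the real 901-transect archive, whose headline statistics are outside
desk scale by design.

## Numerical choices and degenerate inputs

* Rasters are lower-left-origin, south-up `values[row, col]` arrays with
  NaN as in-memory nodata; block aggregation requires exact divisibility
  and raises otherwise (the pipeline skips the 250-m regrid with a warning
  when a transect extent does not divide).
* Coordinates exactly on a grid's upper or right edge map into the last
  cell, so extent-spanning clouds lose no returns.
* LAS I/O quantizes to the declared scale (1 cm default); classification
  codes 2 / 7 (and 18 on read) map to ground / outlier.
* Empty clouds filter to empty outputs without error; an empty stem list
  gives plot AGB 0 with a warning; identical pooled samples give
  Wilcoxon p = 1 with a warning.
* Fewer than 3 (or collinear) seed minima, degenerate ground TINs, and
  constant regression responses raise typed errors.
* All generators are pure functions of (config, seed) via
  `numpy.random.default_rng([seed, stream])`; derived seeds stay below
  2³¹.

## Known limitations

* The progressive-TIN angle criterion is evaluated at the nearest facet
  vertex only (variants exist that test all three vertices).
* The 50 m → 250 m SD aggregation's full-correlation assumption is
  conservative; the independence variant will understate uncertainty where
  canopy structure truly decorrelates within 250 m.
* ESRI ASCII grids carry no CRS; the identifier travels in a `.crs`
  sidecar and in memory.
* `uniform_canopy_cloud` is a synthetic closure fixture (one ground and
  one crown echo per square metre), not a physically simulated scene.
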