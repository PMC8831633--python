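# Methods

## The model

The climate stability index treats per-pixel temporal dispersion as the
measure of (in)stability.  For one variable on a shared grid, the
pixel value series across periods is summarized either by the sample
standard deviation (denominator *n*−1) or by the range (max − min).
The index for a map set is the per-pixel sum of the *normalized*
dispersion maps of a collinearity-pruned variable subset, rescaled once
more to [0, 1].  Two workflows share this core:

- **past**: one layer per variable × period (single-model paleoclimate
  reconstructions); dispersion is taken directly across the periods.
- **future**: one layer per variable × period × GCM; each variable ×
  period is first collapsed across its *available* ensemble members by
  a per-pixel median (mean available for sensitivity checks), the
  present-day layer is prepended, and dispersion is taken across the
  resulting five periods.  Absent ensemble members are skipped, never
  imputed.

Assumptions worth stating: all inputs live on one grid (the package
refuses, rather than resamples, anything else); dispersion across a
handful of coarse time slices is a proxy for long-term variability, not
a rate estimate — a variable that oscillated between sampled slices is
invisible; and summing normalized dispersions weights every kept
variable equally regardless of its ecological importance.

### Why normalize before summing

Raw dispersions mix units — degrees Celsius for bio1–bio11, millimetres
for bio12–bio19 — and precipitation magnitudes are two orders larger,
so a raw sum would effectively be a precipitation index.  Per-variable
min–max normalization precedes both the collinearity screen and the
sum; it also makes the index invariant to any affine rescaling of a
single variable's raw values (unit changes are no-ops), which the test
suite asserts.  The collinearity screen therefore runs on the
normalized dispersion layers — the very quantities later summed; any
other aligned layer list can be substituted through the API.

### Sea-level masking

Glacial periods expose continental shelf that is ocean today.  Those
pixels carry values for only the low-sea-level slices; their low
dispersion is a record-length artifact, not stability, so every output
is masked to the *current* land surface using the most recent period as
template (written as `lgm_del_mask.tif`, polarity: 1 = current land,
kept).  The converse case — current land submerged during
high-sea-level warm slices — is mild (three of twelve periods in the
default configuration), so those pixels are *kept* in the index,
computed over their available periods, and flagged in
`intergl_affected.tif` (polarity: 1 = affected land) so users can
discount them.  A pixel additionally needs at least `min_valid = 2`
valid periods; dispersion of a single value is meaningless.

### Collinearity pruning

At `n_points` random land pixels (default 10,000, drawn uniformly
without replacement; an error, never a silent reduction, if the land
area is smaller), the pairwise Pearson matrix of the candidate layers
is computed with pairwise deletion of NoData points.  Variables are
linked when |r| exceeds the cut-off (default 0.8) and groups are the
connected components of that graph — the minimal, order-independent
closure of pairwise exceedance.  One uniformly random representative
per group is kept.  Absolute r is used because a strongly
anti-correlated variable is equally redundant; signed linking is a
config switch.  Both random draws use separate, logged seeds.
Raising the cut-off can only refine the partition (tested as a property
over random correlation matrices).

### Categories and histogram

Finished maps can be classed by ascending break schemes over [0, 1]
with half-open bins (lower-exclusive, upper-inclusive; the first bin
closed at 0).  Besides equal intervals, `BreakScheme.with_top_break`
builds histogram-adjusted 32-class schemes whose top class absorbs the
sparse right tail (top class from 0.71 for a past-style map, 0.356 for
a future-style one).  Histograms use equal-width bins over [0, 1];
empty bins are reported with count 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `statistic` | `sd` | sample SD (n−1) or `range` per pixel across periods |
| `min_valid` | 2 | fewest valid periods a pixel needs, else NoData |
| `reducer` | `median` | per-pixel GCM ensemble collapse (`mean` for checks) |
| `r_threshold` | 0.8 | collinearity cut-off on abs Pearson r (sweep: 0.7/0.9) |
| `n_points` | 10,000 | random land pixels for the correlation matrix |
| `sampling_seed`, `selection_seed` | 0 | independent seeds for point sampling and the random per-group pick |
| `warm_period_ids` | T2, T4, T10 | high-sea-level slices for the affected flag |

Sample SD rather than population SD is used: the screening convention
of the ecology tooling this workflow descends from, and the
conservative choice at T = 12.  The even-member ensemble median is the
midpoint of the two central values.

## The synthetic worlds

The generator emulates the *shape and statistical structure* of global
bioclim archives, not their physics:

- **Smooth fields.**  Every spatial component is Gaussian-filtered
  white noise (wrap-around edges, σ = 3 pixels by default),
  standardized.  Real climatologies are spatially smooth; the SD-vs-
  range agreement check depends on it.
- **Planted correlation.**  Each variable's dispersion pattern is an
  affine function of a per-variable amplitude field
  A_v = amp·clip(1 + 0.35·G_v).  Within a declared block,
  G_v = √ρ·L + √(1−ρ)·E_v shares a latent field L, giving pairwise
  corr(G_v, G_w) = ρ analytically; between blocks the fields are
  independent.  Because per-pixel dispersion is approximately
  proportional to A_v, the dispersion maps inherit the target
  correlation (the calibration test requires empirical |r| within
  [0.90, 0.99] of a 0.95 target).
- **Time.**  Pixel values are mean_v + A_v·(z_t + noise), where z_t is
  a standardized per-variable temporal profile plus a linear drift
  term, and the noise is a fresh smooth field per period (SD 0.1).
  GCM members add symmetric smooth noise (SD 0.05) around the shared
  base — which is why mean and median reducers agree to r ≈ 1.
- **Geography.**  A smooth elevation field is thresholded at quantiles:
  65 % of pixels are current land; a 5 % shelf band below sea level is
  valid only in the seven glacial slices; the lowest 4 % of land is
  NoData in the three warm slices.
- **Availability.**  The default GCM roster has nine models with the
  published-archive gap pattern (one model absent throughout for two
  pathways, two more absent in the first window), and five variables
  are marked absent from the three oldest paleo slices, leaving 14 of
  19 usable for the past map set.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: physically coherent climate dynamics,
latitudinal and orographic structure, skewed/bounded variable
distributions (fields are Gaussian, so synthetic "precipitation" can be
negative), spatially varying drift, and realistic *marginal*
correlations near the cut-off.  That last point matters for the
threshold sweep: planted correlations sit at 0.95 and ~0, far from
every cut-off, so the 0.7/0.8/0.9 partitions — and the resulting
maps — coincide exactly (r = 1 rows in the sweep).  On real data,
borderline variable pairs make those comparisons informative; here
they only demonstrate determinism and plumbing.

## Numerical choices

- Layers hold float32 values with NaN as the in-memory NoData; all
  reductions accumulate in float64 (a reduction over identical members
  must return the member bit-exactly).  Disk sentinel is a −3.4e38-class
  float stored float32-exact; masks and categories are uint8 with
  sentinel 255.
- Grid equality tolerates ≤ 1e-9 degrees on the geotransform and
  nothing on shape/CRS; every multi-layer operation validates
  alignment first and names the offending layer and field.  There is
  deliberately no resampling path.
- NoData propagation in the index sum is strict (NoData in any kept
  layer → NoData) because a partial sum over fewer variables is not
  comparable across pixels.
- Normalizing a constant layer yields all zeros with a warning rather
  than an error; correlating a constant layer is an error naming it.
- GeoTIFF I/O writes single-band files with the pixel-scale, tiepoint
  and GeoKey tags a GIS needs plus the GDAL_NODATA ASCII tag, and is
  deterministic: identical runs produce byte-identical files, which the
  manifest-replay test exploits.

## Problem sizes

Desk-scale runs and the acceptance script use a 120 × 80 grid
(~6,240 land pixels) with 5,000 sample points — the full 10,000-point
default exceeds that world's land area, and 5,000 points estimate the
handful of planted correlations to well within the decision margins.
The complete past (14 × 12 layers) and one-pathway future
(19 × 5 × ≤9 layers) workflows run in seconds.

## Known limitations

- Min–max normalization is outlier-sensitive: one extreme pixel
  compresses everybody else.  Rank or quantile normalization is a
  plausible extension.
- Connected-component grouping can chain weakly related variables
  through intermediaries (A–B and B–C above the cut-off pulls in A–C
  regardless of r(A, C)); that is the documented, order-independent
  reading of "groups of correlated variables", but other closures
  exist.
- The random representative per group makes the kept set seed-dependent
  by design; fixing the seed fixes the map, and the robustness sweep is
  the tool for judging how much that choice matters.
- Future and past map sets are built from different kinds of sources
  (single reconstructions vs multi-model ensembles), so their indices
  are not directly comparable in absolute terms.
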