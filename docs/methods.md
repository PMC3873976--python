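# Methods

This note documents the models, conventions and design choices behind
`stresscape`, in the spirit of a statistical package's model
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Marked-point-pattern smoothing

**Estimator.** The stress surface is the Nadaraya–Watson ratio smoother
`u(s) = Σ k_h(s−xᵢ) mᵢ / Σ k_h(s−xᵢ)`: a kernel-weighted mean of the
marks, which keeps the surface in mark units (pg/mg) and bounded by the
observed mark range (the weights are a convex combination). The
alternative *mark-intensity* form — edge-corrected `e(s)·Σ k_h(s−xᵢ) mᵢ`,
in marks per unit area — is provided (`mark_intensity`) but is not the
default, because surface-versus-marks distributional validation only
makes sense in mark units.

**Kernel and bandwidth.** Isotropic Gaussian kernel with bandwidth *h*
interpreted as the Gaussian σ in metres. Some traditions parameterize
kernels by other radii; the convention here is recorded so surfaces are
comparable. The kernel is evaluated out to 6σ and treated as zero beyond,
which changes weights by at most e^(−18) relative but keeps distance
matrices sparse-able. The default *h* = 9000 m reflects the daily-range
scale of the female grizzly bear, the species context the package was
built around; `lscv_bandwidth` selects *h* over a user grid by minimising
the summed squared leave-one-out error Σᵢ (mᵢ − u₋ᵢ(xᵢ))², ties resolved
toward the smallest candidate.

**Window and edge correction.** The observation window is the MCP
(convex hull) of the sample locations; a cell belongs to the window iff
its centre is covered by the polygon (consistent with cell-centre
registration everywhere else). The edge factor e(s) is the reciprocal of
the kernel mass inside the window, computed by quadrature over in-window
cell centres (cell-area weights). In the ratio estimator e(s) multiplies
numerator and denominator and cancels analytically; it is still computed
(and exposed on the surface object) because the intensity variant needs
it. Cells whose entire kernel support contains no point (possible at
small *h*) are set to nodata and counted, not invented.

**Bootstrap stability.** "99 leave-one-out bootstrap surfaces" is read
literally: 99 replicates, each deleting one point drawn uniformly with
replacement across replicates. (A jackknife — each point deleted exactly
once — is a config choice away, since the replicate loop only needs the
deletion index; the uniform reading was kept as the closest literal one.)
Stability is the fraction of in-window pixels whose full-data value lies
inside the 2.5–97.5 percentile interval of replicate values; the
percentile pair is configurable. A strict "95% confidence interval at
p < 0.01" is internally inconsistent as a description, so the percentile
interval honours the 95% while this note documents the discrepancy. A
relative tolerance of 1e-9 pads the interval so analytically identical
replicates (all-equal marks) are not pushed outside by floating-point
jitter.

**Distribution checks.** Two-sided two-sample Kolmogorov–Smirnov and
Mann–Whitney U tests compare in-window pixel values with the raw marks.
Constant-vs-equal-constant inputs saturate the rank tests with ties; that
case returns p = 1 with a degeneracy flag instead of raising, so
synthetic edge cases cannot crash a pipeline run.

## Covariate engineering

* **Distance decay** `e^(−a·d)`, a = 0.002 per metre, d the Euclidean
  distance from the cell centre to the nearest feature geometry (not to
  rasterized feature cells, avoiding rasterization bias at 1-km cells).
  The value is *not* truncated at 2 km; e^(−4) ≈ 0.018 is kept. Prose
  descriptions of this decay as "linear to zero at 2000 m" are treated as
  loose; the formula governs.
* **Linear density**: exact clipped line length per cell / cell area,
  km/km². Additive over disjoint feature subsets by construction.
* **Harvest age split** at reference_year − year ≤ 15 (inclusive) for the
  young class; proportion harvested is the exact polygon∩cell area ratio,
  overlapping blocks unioned first so area is never double-counted.
* **Protected proportion**: a 10-km disc centred on each cell centre,
  exact polygon intersection; the denominator is the area of the
  discretized disc polygon (64 quadrant segments), which makes a
  half-plane park through the centre exactly 0.5 and full coverage
  exactly 1.
* **TRI** uses the square-root-of-summed-squared neighbour differences
  form, √Σ₈(z_n − z_c)²; the index family in the literature has several
  variants, so absolute TRI values are convention-dependent. Edge cells
  use the neighbours they have. Translation-invariant in elevation and
  linear under elevation scaling.
* **CTI / topographic wetness** = ln(specific catchment area / tan β),
  with priority-flood pit filling, single-direction D8 flow (steepest
  descent, ties to the first direction in a fixed order), accumulation in
  decreasing-elevation order, specific catchment area = (upslope cells +
  1) × cell size, and a slope floor tan β ≥ 0.001 so flats are finite. A
  constant DEM yields the clamp value everywhere and warns. Published CTI
  values vary across flow-routing conventions; only within-convention
  comparisons are meaningful.
* **Co-registration** is enforced exactly (shape, origin, cell size); no
  resampling is performed — misaligned inputs are an error naming the
  offending layers, not something silently fixed.

## Forest models

The ensemble is bagged scikit-learn regression trees with explicit
bookkeeping: per-tree bootstrap index sets are retained, because both
importance metrics and the conservation identity need per-tree
in-bag/out-of-bag partitions (the stock forest class does not expose
them). Protocol defaults: 1000 trees, mtry = 18 candidate predictors per
split, 50/50 simple-random train/validation split, minimum leaf size 5.
The leaf floor is the conventional regression-forest minimum; fully
maximal trees on a smoothed (hence spatially autocorrelated) response
overfit pathologically. The simple-random validation split matches the
original protocol; spatially blocked splits would be the statistically
safer alternative and can be layered on by passing a stratum mask.

* **OOB variance explained** = 100·(1 − oob_mse / var(y_train)), may be
  negative on no-signal data and is reported as is.
* **%IncMSE**: per tree, OOB MSE after permuting a predictor within that
  tree's OOB rows minus baseline; averaged over trees and divided by the
  standard error across trees. A zero-variance normalizer (e.g. constant
  predictor) falls back to the raw mean with a flag. Whether the original
  analyses used the SE normalization is not stated anywhere authoritative;
  the normalized form is the common default and is labelled in the output.
* **IncNodePurity**: weighted-impurity drop summed over a variable's
  splits, averaged over trees. Per tree, the drops sum exactly to root
  RSS minus leaf RSS (tested to 1e-8).
* **Categoricals**: landcover is one-hot expanded before splitting (no
  fake ordinality) and importances are re-aggregated to the parent
  variable, permuting the whole dummy block with a single permutation.
  RSF ranks 0–10 are used directly as ordinal integers: they are ranked
  selection probabilities by construction. mtry stays at its configured
  value even though one-hot expansion changes the column count (the
  effective value is logged and clipped with a warning when it exceeds
  the design width).

A caveat inherited from the method itself: because the response is a
smoothed surface, neighbouring cells are highly dependent, so OOB errors
are optimistic relative to truly held-out landscapes, and spatially
autocorrelated covariates that carry no generative weight can still show
non-zero importance. The parameter-recovery tests therefore assess
recovery on cell-level (unsmoothed) synthetic responses, where the
generative R² is well defined.

## Prediction and summaries

Predictions cover cells valid in every predictor layer, outside the
smoothing windows, and inside the habitat mask (landcover codes water,
barren, snow/ice are non-habitat by default; configurable). Class breaks
are the pooled lower/upper quartiles of the *input* marks —
linear-interpolation sample quantiles, logged because printed breaks are
convention-sensitive — with the boundary rule value ≤ q1 → low,
q1 < value ≤ q3 → moderate, else high, reproducing half-open printed
ranges. Unit-area percentages are over each unit's valid cells and must
sum to 100; both habitat-only and all-cell denominators are available,
since published tables rarely state which they use. Overlapping zone
polygons assign the cell to every zone (with the overlap logged) rather
than arbitrating silently.

## Synthetic landscapes

The generator emulates the *structure* of the study inputs, not their
geography: stationary Gaussian random fields (white noise convolved with
an exponential kernel, restandardized to the requested mean/sill, so
autocorrelation rises with the range parameter and zero sill degenerates
to a constant); categorical landcover and ordinal RSF layers by quantile
binning of additional fields; random chords for roads/railways (total
length trimmed onto the density target), uniform well points,
non-overlapping rectangles for harvest blocks (area trimmed onto the
target fraction, each with a cut year) and parks; a vertical split into
core/secondary conservation zones; and three horizontal bands clipped to
the non-park extent as secure/sink/non-critical habitat states.

Marks follow `m = exp(b0 + Σ βⱼ zⱼ + ε)`, ε ~ N(0, sd²), with zⱼ
standardized over valid raster cells — strictly positive and
right-skewed, like hair cortisol. Default scale: intercept ln(1.2) and
log-sd ≈ 0.45–0.6 total, giving means near 1.2–1.5 pg/mg and ranges of
roughly 0.2–10 pg/mg, consistent with reported bear HCC scales
(~0.16–24 pg/mg). Point placement is stratified-random on a 7-km grid
(one point per occupied stratum, strata revisited when n exceeds the
stratum count), echoing hair-snag sampling geometry without modelling
detection. The field data's true spatial covariance is unknown; the
exponential family here is a free modelling choice, not an inference.
The `TruthRecord` carries the realized signal/noise variance split
(generative R²), the signal variable ranking, and the zero-weight
variable list, which is what the recovery tests consume.

What the generator does **not** emulate: bear movement and home-range
structure, multi-year hair-growth dynamics, detection bias, genetic
structure, or any geographic realism. Passing tests demonstrate the
pipeline's internal correctness and recovery behaviour under a known
data-generating process — not that field HCC surfaces would reach any
particular variance explained.

## Problem sizes and determinism

The bundled study (`configs/small.yaml`) uses a 40 × 40 km landscape at
1-km cells, 220 samples in a central window covering 65% of each extent
dimension, 99 bootstrap replicates, and 300-tree forests; the recovery
tests use ≥ 1000-cell tables over 10 seeds with 300 trees. These sizes
were chosen so the whole suite exercises every stage at honest scale on a
single CPU. All randomness flows from one master integer seed through
named substreams (CRC-keyed seed sequences), so any run is bit-for-bit
reproducible: the run manifest records a SHA-256 checksum per output
file, and determinism is asserted by rerunning and comparing all of them.

## Known limitations

* No adaptive or anisotropic bandwidths; no temporal smoothing across
  years.
* No reprojection: inputs must already share a projected metric grid.
* OOB statistics are not corrected for spatial autocorrelation of the
  smoothed response (see above).
* No prediction-uncertainty quantification; tree ensembles only predict
  within the convex range of training responses.
* ESRI ASCII grid / GeoJSON / CSV are the interchange formats; no
  GeoTIFF or Shapefile I/O.
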