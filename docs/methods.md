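# Methods

## The modelling grid

All layers live on a regular, unprojected lat/lon grid (`GridSpec`),
conventionally 0.5° (30 arc minutes, ≈56 km at the equator). A point
belongs to the cell whose half-open interval `[edge, edge + cell_size)`
contains it; points on the global east/north boundary fold into the last
cell. Native-region polygons are rasterized by **cell-center containment**
(a cell is a member iff its center falls inside any polygon) — fractional
coverage is not considered. This is our documented choice; it is the common
raster default, deterministic, and exactly testable, but a different
inclusion rule would change membership of boundary cells.

Fine rasters are aggregated to the modelling grid by block averaging
(missing fine cells ignored); categorical land-cover products become one
fraction layer per class by averaging the class indicator, so fraction
layers partition unity where no data is missing.

## Occurrence filtering

The cleaning cascade produces three data types:

1. **raw data** — drop records with missing coordinates or any quality
   flag; if ≥ 25 records fall in the 2000–2020 window, keep only those
   (species with fewer recent records keep all years so data-poor species
   are not starved); drop records outside the native region; drop exact
   duplicates of (lon, lat, year) after rounding coordinates to 1e-6°.
   Records without a year are dropped only while the temporal filter is
   active. The dedup key and the quality-before-temporal order are our
   choices; the source protocol does not pin them down.
2. **presence cells** — one record per occupied cell (the first in input
   order; the retained *cell set* is order-invariant).
3. **thinned data** — spatial thinning of presence cells to a minimum
   pairwise great-circle distance of `min_dist_cells × cell_size ×
   111.32 km/degree` (two 0.5° cells ⇒ ≈111.32 km, anchored to the
   equatorial cell width). The algorithm repeatedly deletes the point with
   the most remaining conflicts (random tie-break), runs `reps = 10`
   randomized repetitions and keeps the run retaining the most points.
   Note the subtlety that haversine distances use the mean Earth radius
   (111.195 km/degree), so two points exactly two cells apart east-west
   conflict at the default threshold; tests therefore compare against an
   exhaustive maximum-retention oracle rather than hand counts.

Moran's I of the per-cell raw counts uses binary queen contiguity over
native cells (zero-count cells included, no row standardization) — the
weight structure is our documented choice.

## The maximum-entropy model

`fit_maxent` minimizes the convex penalized objective by FISTA
(accelerated proximal gradient with backtracking line search and adaptive
restart), converging when the relative objective change drops below 1e-7
(cap 10,000 iterations; non-convergence raises). Per-feature penalties
interpolate the published default regularization tables by presence count
(linear [1, 1, 0.2, 0.05] at n = [0, 10, 30, 100]; quadratic and product
analogues; hinge 0.5; threshold 2→1), scaled by the presence standard
deviation of the feature (floored at 1e-3 so every penalty stays positive;
this floor guarantees rm → ∞ gives the uniform null) divided by √n.

Feature scaling bounds are frozen from the training background; values are
clamped to [0, 1] after scaling at prediction, so hinges never
extrapolate. Hinge knots are evenly spaced on the scaled range (forward
knots in [0, 1), reverse in (0, 1]; K of each per variable), threshold
knots at (i + ½)/K. The default K = 50 mirrors standard practice; the test
suite and the acceptance script use K = 5–10, which keeps the candidate
grids fast at the cost of coarser response curves — adequate for the
smooth synthetic niches but a real analysis should keep the default.

The entropy H of the trained raw distribution is computed on the training
background and frozen; cloglog predictions on any extent use that H,
matching the convention that the transform is fixed at training time.

AICc uses K = number of nonzero coefficients and the presence
log-likelihood under raw standardized over the full native grid; it is
reported as unavailable (not an error) when n − K − 1 ≤ 0 or a presence
has zero density.

Permutation importance permutes one variable's raw values jointly across
the pooled presence + background rows, recomputes all of that variable's
features, and measures the drop in training AUC without refitting;
negative drops floor at 0 and the drops normalize to 100 (uniform split
when all are zero).

## Calibration and selection

Eligibility: a prediction is attempted only with ≥ 5 raw records across
≥ 3 cells in a native region of ≥ 9 cells; presence-cell and thinned
models additionally need ≥ 3 points of their type.

Partitioning switches at exactly n = 25: below, leave-one-out jackknife
(k = n, full background on both sides, single-presence test AUC = fraction
of background scored below it with midrank ties); at or above, four
spatial blocks built by a rank-based split at the median longitude and
each half's median latitude (bin sizes differ by ≤ 2). Background cells
are assigned to blocks by the same split lines; a presence lying exactly
on a line can therefore sit on the opposite side of its own block's
background — harmless, but the reason tests use off-line points. Block
fits train on the training blocks' background and test against the left-out
block's background.

Model 0 runs the six combos at rm = 1 (regularization multipliers enter
only in Models 1–3). The winner is chosen by AICc unless AICc is
unavailable for ≥ 50 % of candidates or the finite minimum is tied within
1e-9, in which case mean test AUC decides — the only reading that makes
the fallback well-defined. Variable pruning is greedy in descending
permutation importance, keeping a variable iff |Spearman ρ| < 0.7 against
every kept one (ρ computed over all native background cells — stable and
identical for all data types). The greedy rule guarantees the kept set is
pairwise-uncorrelated, which a connected-component interpretation would not.

Across data types the overall winner maximizes the harmonic mean
2·AUC·AUC_PR/(AUC + AUC_PR) of the evaluation against the species'
presence cells; full ties break toward higher AUC, then fewer nonzero
coefficients, then the more heavily filtered data type.

## Evaluation

"Present" means score ≥ threshold. ROC-AUC is the Mann–Whitney
probability with midranks (hence identical for raw and cloglog outputs,
which are monotone transforms of each other). The PR curve is evaluated
at every distinct observed score, interpolated linearly in recall, with
the recall→0 precision anchored at the highest threshold — a documented
convention; nonlinear PR interpolation would give slightly different
areas, so cross-implementation PR-AUCs are not bit-comparable. max-F1
scans all observed scores (lowest optimal threshold on ties). The
no-omission threshold is the minimum predicted value over presences.
Degenerate cases: precision with an empty predicted-present set is
missing (NaN), not an error; evaluation with an empty positive or
negative class raises.

## Synthetic worlds

The generator emulates the structure of a continental-scale run: smooth
climate fields (sums of low-frequency sinusoids plus smoothed Gaussian
noise, standardized, sharing latent components so pairwise correlations
span low to high), land-cover fractions squashed into [0, 1], blob-shaped
native regions, and a known logistic niche
σ(intercept + Σβx + Σγx²) with concave quadratic terms (unimodal
responses). Records are sampled per cell ∝ suitability (optionally
× accessibility^bias, a distance-decay field from random hotspots that
mimics road/herbarium bias), jittered uniformly within the cell, dated
uniformly in 2000–2020. Contaminants (missing coordinates, pre-2000
years, out-of-native points, exact duplicates) are appended as labelled
extra rows — default fraction 0, so contamination is always explicit.
Reference ranges threshold the true suitability at a quantile over native
cells (default q = 0.5).

What the synthetic worlds do **not** emulate: taxonomic noise, coordinate
precision artefacts beyond whole-cell scale, non-stationary niches,
dispersal limitation within suitable area, and the extreme class imbalance
of real global grids. Passing tests therefore demonstrate the machinery is
correct and the estimator recovers a knowable niche under honest sampling
— not that real-world predictions reach any particular accuracy.

## Problem sizes and numerics

The test suite and acceptance script run on 40 × 40 / 60 × 40 grids with
60–80 presence records, 5 hinge knots and 10 seeded worlds — sizes chosen
so a complete 96-model species takes seconds while exercising every code
path (block + jackknife partitions, all combos and multipliers). Niche
recovery is judged by the median Spearman correlation across worlds
(≥ 0.8) and by true-variable selection in ≥ 8/10 worlds; both are
stochastic summaries, stable across seeds in our runs.

Known limitations: no clamping/extrapolation diagnostics (MESS), no
categorical features, no CRS reprojection, GeoTIFF I/O is out (netCDF via
the scipy backend and GeoJSON polygons cover the text-based formats), and
the fitted coefficients are not expected to reproduce the Java
implementation's numeric output, only the estimator it defines.
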