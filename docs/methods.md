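# Methods

## Scope and data model

The pipeline estimates how a species' modeled potential distribution
responds to the accumulation of occurrence records over decades. Its
in-memory containers are deliberately few: a `RasterStack` (aligned
gridded layers, lower-left origin, square cells, a shared validity mask
with the mask-union rule — a cell nodata in any layer is nodata in all),
a pandas occurrence table (`longitude, latitude, year, source`), and
plain dataclasses for fitted results. Rasters are exchanged as ESRI
ASCII grids, a plain-text format sufficient for aligned single-band
layers; grids must already be co-registered — there is no reprojection.

## Record cleaning and windows

Cleaning applies four rules in a fixed order, attributing each removed
record to the first rule it fails: (1) missing year; (2) missing
coordinates; (3) year before `min_year` (default 1900); (4) outside the
study region (a shapely geometry or bounding box; boundary points count
as inside). The tallies are returned as a `FilterReport` whose counts
always sum to the input size, and filtering is idempotent.

Windows are cumulative: window *k* holds every record with
`year ≤ end_years[k]` (right-inclusive, so a "…–1950" window includes
1950). The default eight end years are 1950–2020 by decades. Before
model fitting, records are thinned to one per raster cell (earliest year
kept; ties resolved by table order) so duplicated localities do not
dominate the likelihood. The distance-to-center analysis deliberately
uses the *unthinned* table — its unit is the individual record.

## Environmental axes

Bioclim-style layers have incommensurable units, so layers are centered
and scaled to unit variance before PCA (fitted on all non-nodata cells
of the region, not just occupied cells). The retained axes are the
smallest leading set whose cumulative explained variance reaches the
threshold (default 0.95); zero-variance layers are dropped with a
warning; axis signs are fixed by making each axis's largest-magnitude
loading positive, so output is reproducible across runs. Points map to
cells by the half-open containing-cell rule (a point on a shared edge
belongs to the lower-left cell in index space).

## Suitability models

True absences are unavailable, so two contrast sets are built from the
score stack:

* **Envelope pseudo-absences** (default n = 50) — drawn uniformly
  without replacement from cells failing the presences' per-axis
  min–max envelope on at least one axis (an optional `trim_fraction`
  tightens the envelope to inner quantiles). If fewer candidates exist
  than requested, all are used with a warning; an envelope covering the
  whole region is an error.
* **Background** (default n = 10,000) — uniform with replacement over
  all non-nodata cells.

The three learners share a fit/predict surface and emit values in [0, 1]:

* **MXT** — a ridge-regularized presence-vs-background binomial model on
  linear + quadratic features of the score axes (the standard open
  reformulation of the maximum-entropy suitability model). Default
  C = 1.0.
* **RDF** — random forest, 500 trees; suitability is the fraction of
  trees voting presence.
* **SVM** — RBF support vector machine with Platt-calibrated
  probabilities. Default C = 1.0, `gamma='scale'`.

All learners use balanced class weights, since the contrast sets are
much larger (or occasionally smaller) than the presence set. Every
stochastic step is seeded; the pipeline derives per-stage substreams
from one master seed.

## Evaluation, thresholding, ensembles

Evaluation uses a checkerboard geographic two-fold split: blocks of
`block_size` cells alternate between folds by the parity of
`⌊row/b⌋ + ⌊col/b⌋`, and points inherit their cell's fold. The default
block size is chosen automatically so each fold holds at least 25% of
the presences, doubling (with a log message) when infeasible. Each fold
is fitted and scored on the other; a fold containing a single class is
an error suggesting a larger block size.

The operating threshold maximizes sensitivity + specificity over the
candidate set of observed scores, with the prediction rule
`score ≥ τ` (ties predict presence) and ties in the objective broken
toward the smallest maximizing τ — the choice that keeps the largest
predicted area. Internally the scan uses integer-scaled counts so ties
are exact, never float-rounded. Two thresholds play different roles:

* the **per-fold** threshold is selected on *training-fold* scores and
  applied to the held-out fold. Selecting it on held-out scores would
  optimistically bias TSS — on label-shuffled data that variant showed a
  mean TSS near +0.14 where an honest null should sit at 0.
* the **map** threshold is re-derived from the pooled out-of-fold
  scores, and the final per-window maps come from a refit on all window
  data; the checkerboard split serves only to measure skill.

Reported sensitivity/specificity are fold means and
TSS = sensitivity + specificity − 1 by construction. Binary maps from
the three algorithms are summed into a 0–3 agreement ensemble. The
conservative area proportion is the share of non-nodata cells with
value 3; the non-conservative proportion uses value ≥ 1; the former can
never exceed the latter.

Windows with fewer than 5 (thinned) presences are skipped with a
warning and excluded from the area series.

## Trend tests

**Decade effect.** Beta regression of the windowed area proportion on
the cumulative record count (window index available as an alternative
predictor), fitted by maximum likelihood with a logit mean link and a
log-linked precision φ. Proportions touching 0 or 1 are first squeezed
by `(y·(n−1) + 0.5)/n`. Small window series defeat the default
optimizer occasionally, so fitting retries from a Nelder–Mead warm
start with a BFGS polish. Coefficients carry Wald z and p values
(the convention of the reference beta-regression implementations); a
likelihood-ratio p value for the slope is reported alongside because at
n ≈ 8 windows the Wald test is anticonservative (measured size ≈ 14% at
nominal 5% over 500 simulated null series) while the LR test stays near
nominal (≈ 10%). At these sample sizes the LR p value is the one to
trust. The pseudo-R² is the squared correlation between the linear
predictor and logit(y).

**Wallacean distance.** Distances are planar Euclidean in the input
coordinate units by default (matching the common, if crude, practice of
computing Euclidean distance on geographic coordinates); a great-circle
alternative in kilometres is available. Per year with records, the
response is the maximum nearest-center distance and the weight defaults
to the number of records that year ("total distances calculated" is
ambiguous between count and sum; the sum is exposed as an option).
Weighted least squares of yearly maxima on year reports the slope, the
**adjusted** R² (plain R² cannot be negative, adjusted R² can and does
occur in practice), the overall F and its p value. With equal weights
the fit reduces exactly to OLS.

Caveat: if yearly record counts trend upward over time, yearly *maxima*
drift upward even when the underlying distance distribution is
time-constant (more draws, larger extremes). The calibration tests use
count series unrelated to year; real accumulating datasets confound
these, which is a limitation of the max-per-year design itself.

## Synthetic data

The generator emulates the study conditions end to end:

* **Landscape** — each layer is a superposition of 25 seeded Gaussian
  bumps (random centers, signed amplitudes, widths 8–25% of the extent
  diagonal), giving smooth, spatially autocorrelated fields. It does not
  attempt to mimic real bioclim covariance structure.
* **Virtual species** — suitability is the inverse-logit of a linear
  combination of layers; truth presence is the symmetric cut at 0.5.
  Default coefficients (2, −1.5, 1, −0.5) give a strong, recoverable
  signal occupying roughly a third of the landscape.
* **Research centers** — uniform draws strictly inside the extent
  (default 5).
* **Sampling** — records are drawn from presence cells with weight
  suitability × exp(−bias_strength × distance-to-nearest-center);
  `bias_strength` = 2 (in units of 1/map-extent) is the default
  collection bias, 0 disables it. How detectability relates to
  suitability is not identified by the motivating data; weighting by
  suitability is a modeling choice, and the unbiased arm of the tests
  depends only on the bias term being off. Coordinates are cell centers
  jittered uniformly within ±45% of a cell so extraction round-trips to
  the generating cell; years are uniform integers within each period,
  with the first period starting at 1900. The default plan adds
  30, 1, 9, 8, 3, 23, 70, 9 records over the eight periods (153 total),
  the accumulation schedule of the motivating dataset.

Because the landscape is smooth, the species logistic, and sampling
noise-free in the covariates, passing recovery tests shows the pipeline
machinery is sound — not that real, noisy, autocorrelated occurrence
data would yield comparable skill.

## Problem sizes and numerical choices

The validation suite and the acceptance script run on a 100×100 grid
(10,000 cells), 4 layers, the 153-record plan, 50 pseudo-absences and
10,000 background points — sizes at which every stage's behavior is
already representative while a full eight-window, three-algorithm run
completes in well under a minute. Reproducibility is exact under a
fixed seed: same-seed reruns produce hash-identical report CSVs.
Degenerate inputs fail loudly rather than silently: constant layers,
boundary proportions, constant predictors, single-class folds,
envelope-covering regions and empty presence masks all raise typed
errors with actionable messages.

## Known limitations

* No reprojection or grid alignment; inputs must share a grid.
* No spatial-autocorrelation correction in either trend test, and no
  AUC-style threshold-free evaluation — the design is fixed at TSS with
  a three-algorithm agreement ensemble.
* The maximum-entropy reformulation uses linear + quadratic features
  only, not the full feature-class/regularization schedule of the
  original implementation.
* Wald inference in the decade-effect test is anticonservative at few
  windows (see above); use the LR p value at n ≲ 10.
* The max-per-year Wallacean response confounds record-count trends
  with genuine spatial frontier shifts.
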