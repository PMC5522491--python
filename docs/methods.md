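# Methods

## Scope and coordinate conventions

The package implements a presence / pseudo-absence species-distribution
workflow on a single, regular, projected grid. All coordinates are planar
metres in an unspecified projected system; geometry is Euclidean
throughout, which is what a kilometre-scale analysis grid and
kilometre-scale dispersal buffers assume. Rasters follow the north-up
GeoTIFF convention (row index grows as y decreases; the origin is the
top-left corner of cell (0,0); cells are square), and point-in-cell
assignment is half-open, so every point maps to exactly one cell. All
rasters participating in one analysis must share origin, cell size and
shape; alignment is checked, never assumed. Reprojection, multi-CRS
mosaics and resampling between misaligned grids are out of scope.

## Training design

Presences are occurrence records; pseudo-absences are drawn uniformly
without replacement from a regular background lattice at an exact
absences-per-presence ratio (default 100, i.e. 183 presences pair with
18,300 pseudo-absences). Lattice cells containing a presence are excluded
from the draw so no location carries both labels; the exclusion can be
disabled. Points that fall outside the grid or hit nodata in any layer are
flagged, and flagged rows are dropped from the design with a logged count
— tree ensembles need complete rows, and silently imputing them would
contaminate the labels.

## The suitability model

The classifier is a forest of fully grown CART trees, each trained on a
uniform bootstrap of the design with per-split feature subsampling
(`max_features="sqrt"`) and **balanced class weights**
w_c = N / (2 N_c), so the rare presence class carries the same total
weight as the background. The model's presence-class probability is the
relative index of occurrence (RIO) in [0, 1].

The forest is assembled as bagged class-weighted trees rather than a
stock random-forest estimator for one load-bearing reason: an
implementation whose bootstrap is itself weighted by the class weights
will, at 1:100 imbalance, draw every presence row into essentially every
bag — presences then have no out-of-bag trees and no valid OOB score.
With a uniform bootstrap every row is out-of-bag for ≈ e⁻¹ ≈ 37% of
trees, and with the default 1,000 trees the probability of any row
lacking an OOB estimate is negligible (< 10⁻¹⁹⁰); the fit raises if it
happens. OOB probabilities are the mean presence-class probability over
the trees that did not see the row.

Categorical land cover is one-hot encoded inside the model; importance
scores of the indicator columns are summed back into the parent variable.
Variable importance is mean impurity importance rescaled so the top
variable scores 100.0.

### Response curves

Response curves are partial dependence computed directly on the fitted
forest: for each grid value v, the covariate is clamped to v in every
(sub-sampled) training row and the mean predicted RIO recorded. Two
numerical choices matter:

* The evaluation grid spans the 1st–99th percentile of the training data,
  not the absolute range. Tree ensembles extrapolate erratically outside
  the data-supported range, and with skewed covariate distributions the
  extreme tail (< 1% of rows) can grow a spurious plateau that exceeds the
  real curve and defeats threshold detection. (`percentiles=(0, 100)`
  restores the absolute range.)
* `half_maximum_crossing` locates the covariate value where the curve
  crosses halfway between its minimum and maximum, by linear
  interpolation. An optional direction argument restricts the search to
  rising or falling crossings and takes the steepest candidate — fitted
  curves carry small artifacts in data-sparse regions, and for a monotone
  threshold response the steepest directed crossing is the inflection.

## Assessment

* **AUC** uses the rank (Mann–Whitney) formulation on OOB scores: the
  probability a random presence outscores a random background point, ties
  counted half. It is checked in the tests against an O(n²) pairwise
  counting oracle to 1e-12.
* The **threshold table** tabulates sensitivity, specificity and TSS over
  thresholds {0, 0.01, …, 1}, with the inclusive rule "positive iff
  score ≥ t". The step of 0.01 matches two-decimal reporting of operating
  points. The selected threshold is the exhaustive argmax of
  sensitivity + specificity; ties break toward the smaller threshold.
* **TSS** = sensitivity + specificity − 1 is reported both at the
  selected threshold and as the table maximum (for the
  sensitivity-specificity-sum rule these coincide).
* **Testing points** are scored by extracting the continuous RIO surface
  at their locations; the summary is the median with a percentile
  bootstrap 95% CI (1,000 seeded resamples). The bootstrap CI is clamped
  to bracket the sample median in degenerate resampling cases.

Note that the threshold is selected on OOB scores but applied to
non-OOB forest scores when binarizing the map; the two scales differ
(OOB scores are systematically more conservative), which is inherent to
the two-step design and is why the selected threshold on the synthetic
landscape is small.

## Surfaces

IDW interpolation assigns each cell centre the weighted mean of its k
nearest scored points (defaults: power 2, k = 12 — common GIS practice;
both exposed). A zero-distance match short-circuits to the point's own
value, so when the full lattice is scored the interpolation degenerates
to per-cell assignment and is exactly the identity. Binarization is
RIO ≥ threshold with nodata propagated as the mask's own sentinel (255).

## Conservation gaps

gap = predicted presence ∧ HII ≥ cutoff ∧ outside protected areas, with
the human-influence index (integers 0–64) reclassified in 5-unit bins
(class = floor(v/5); 64 folds into class 12) and a default safety cutoff
of HII = 10. Polygons are rasterized by the centre rule (a cell belongs
to a polygon iff its centre does, boundary-inclusive), and all areas are
cell counts on the equal-area planar grid. The summary records the
protected fraction of predicted presence, the HII class shares, the
pressured fraction, the protected share of the pressured area, and the
gap fraction; the identity
gap = pressured × (1 − protected_of_pressured) holds exactly by
construction. Applied to one published overlay's printed marginals
(37.0% pressured, 30.7% of that protected) the identity gives 25.6%,
about a point below the separately printed 26.7% headline — a rounding /
resolution residual of that original overlay, which is why the tests
check the identity, not equality with the headline.

## Potential breeding areas

Predicted presence cells whose centres lie within a Euclidean,
boundary-inclusive buffer (default 67 km, the species' breeding-season
dispersal scale; the synthetic default uses 10 km, scaled to the
150-km demo landscape) of any known-range polygon or breeding record are
removed. Remaining cells are aggregated into 8-connected components;
components below `min_pixels` (default 10) stay unassigned but count in
the total, so cluster shares sum to ≤ 100%. Point density is a
moving-disc count of presence-pixel centres divided by the full disc
area πr² with no edge correction (documented; edge cells are biased low).
Focal regions are clusters ordered by pixel share (ties: pixel count,
then id), each annotated with its maximum-density cell.

## The synthetic landscape

The generator produces everything the pipeline consumes, as pure
functions of (parameters, seed):

* **Covariates.** Gaussian-smoothed white noise (sigma = 6 cells by
  default) rank-transformed to a uniform marginal, then skewed by a power
  and scaled to plausible ranges: elevation 1,000–6,000 m (skew 3 — high
  plateau is rare in a continental window), warmest-month maximum
  temperature −5–35 °C (skew 0.45 — warm summers dominate), temperature
  seasonality 2,000–12,000 units (skew 1.5). Two distance-to-feature
  layers (Euclidean distance transforms of random sparse features) act as
  realistic nuisance covariates, and land cover is an integer-coded field
  cut at fixed quantiles (40% herbaceous, 30% shrubland, 20% bare, 10%
  water). The rank transform pins each layer's marginal exactly, so the
  skew exponents give predictable area fractions above any threshold;
  jointly they keep the suitable niche to roughly 0.5–2% of the
  landscape. That concentration is the study condition that makes an
  OOB-validated learner attainable: with a diffuse niche the background
  sample outnumbers presences inside the niche and no out-of-bag
  evaluation can rank held-out presences highly.
* **Truth.** Suitability is the product of per-covariate responses times
  a prevalence scaler (0.9 at a fully suitable cell — the species'
  prevalence on its own niche is not an observable here and 0.9 keeps
  sampled presences concentrated). Continuous responses are logistic
  with widths ≈ 2.3% of each range (10–90% transition over ~a tenth of
  the range), inflections at 2,800 m, 20.5 °C (decreasing) and 7,800
  units; land cover weights are 1.0 / 0.3 / 0.05 / 0.0.
* **Occurrences.** Cells are drawn without replacement with probability
  proportional to suitability; points sit at cell centres (no jitter, so
  cell membership is unambiguous). An optional survey window restricts
  the draw — the pipeline default confines all 285 records to the eastern
  60% of the domain, emulating campaigns that cover only the known range;
  suitable habitat in the unsurveyed west is what the potential-area
  stage should find.
* **Human influence.** Exponentially decaying footprints
  (intensity 30–80, decay 8 cells) around random settlement centres,
  cellwise maximum, rounded and clipped to [0, 64].
* **Protected areas.** Random rectangles (each 1–4% of the domain) added
  until their union first reaches the requested coverage; the small
  rectangle size keeps the overshoot well inside ±20% relative.

What the generator does **not** emulate: the correlation structure among
real bioclimatic layers (covariates are independent fields; a lapse-rate
coupling of temperature to elevation was evaluated and rejected because
the collinearity made response-curve attribution between the two
ambiguous), observation bias (roadside sampling), spatial error in
coordinates, and temporal dynamics. Passing tests therefore demonstrate
that the pipeline recovers a known niche from clean, spatially
autocorrelated data at realistic prevalence — not robustness to real
survey artifacts.

## Default problem sizes

The default configuration is a desk-scale analogue of a continental
analysis: a 150 × 150 grid of 1-km cells, 183 presences + 102 testing
points in the survey window, ratio 100 (18,300 pseudo-absences), 1,000
trees, threshold step 0.01, HII cutoff 10, protected-area coverage 0.25,
10-km buffers, 8-connected clusters of ≥ 10 pixels, 5-km density discs.
One full run takes well under a minute on a single CPU. Parameter-
recovery checks run at the same 150 × 150 scale because 183
without-replacement draws exhaust the suitable core of anything much
smaller and the sampled niche itself becomes biased; the
single-informative-variable importance check is robust down to 64 × 64.

## Determinism

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by fixed offsets and records them in
the run manifest together with a hash of the full configuration.
Re-running an identical configuration reproduces every output
bit-for-bit, including the forest (seeded bagging) and the bootstrap CI.

## Known limitations

* OOB probabilities and forest scores are on systematically different
  scales; thresholds tuned on one are conservative on the other.
* Impurity-based importance is biased toward high-cardinality continuous
  covariates; with the default landscape this does not change the
  top-rank results, but a permutation importance would be the robust
  alternative.
* IDW with k neighbours is discontinuous at neighbour-set changes; on a
  fully scored lattice this is irrelevant (identity), and for thinned
  lattices the maps are for visualization, not inference.
* Density surfaces have no edge correction.
* The GeoTIFF writer stores no CRS key directory; readers of the files
  assume planar metres (and this package warns on read).
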