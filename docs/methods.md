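# Methods

## The problem and the approach

`esdm` implements an ensemble species-distribution-modelling (SDM) workflow of
the kind used to map habitat suitability for wide-ranging terrestrial birds
from opportunistic occurrence records: citizen-science and survey points are
cleaned and spatially thinned, pseudo-absences are manufactured with an
explicit correction for uneven survey effort, a set of presence/absence
learners is fitted and gated on predictive skill, the skilful ones are
averaged into a weighted consensus map, and that map is projected onto
perturbed future climates and intersected with management polygons and
wind-energy footprints.

Because real inputs of this kind (national occurrence archives, 30-arc-second
climate surfaces, CMIP6 scenario grids) cannot ship with a package, the
synthetic-landscape generator is a first-class module: it produces every
input with the statistical structure the method assumes *and a known ground
truth*, so each stage — and the pipeline end to end — is tested by parameter
recovery rather than by fixture snapshots.

## Model components and assumptions

**Occurrence cleaning** is an ordered filter funnel: record-type restriction
(human observations only), missing coordinates, a date-range pass (default
1970–2024; records without a parseable date pass through), exact duplicates of
(species, lon, lat, date), equal-coordinate errors (lon == lat exactly, a
data-entry signature), and a validity mask for sea/out-of-extent points. The
report records removals per filter in application order and must balance
exactly. **Thinning** keeps one record per grid cell (default 15 km — a
home-range-scale cell for a wide-ranging ground bird), chosen uniformly under
the seed. Grid membership is `floor((coord − origin)/cell)`, with the grid
anchored at the raster origin; thinning is idempotent for a fixed grid and
seed. Distance-based thinning (the spThin flavour) is deliberately not
implemented: the grid rule is deterministic and exactly testable.

**Predictor screening** uses the iterative variance-inflation-factor rule:
`VIF_j = 1/(1 − R²_j)` from regressing layer *j* on all others over a seeded
subsample of valid cells (default 10,000 — the statistic stabilises quickly
and full-raster regressions buy nothing), dropping the largest-VIF layer
until all VIFs fall below the threshold (default 5). An exactly collinear
duplicate yields `R² = 1` and is treated as infinite VIF, so it is dropped
first. Ties on the maximum are broken by dropping the lexicographically later
name — an arbitrary but deterministic convention.

**Pseudo-absence generation** is the two-step scheme at the core of the
package. Step one builds an envelope suitability index from presence-cell
statistics: per layer, `z = (x − μ)/σ` with μ, σ taken at presence cells, and
`index = −(1/p) Σ|z|`. Zero is the attainable maximum (a cell sitting on the
presence centroid) and the index is invariant to affine rescaling of any
layer. The study area is split at the *median of the index at presence
cells*: cells at or above the median form the high-suitability zone (off
limits to pseudo-absences), cells strictly below form the low zone. (A
median-of-presences split need not halve the study area; the presence-median
rule is the one implemented because it is the operational definition — a
Mahalanobis-type index would respect predictor covariance but needs a
well-conditioned covariance at presences, which thin presence sets do not
guarantee.) Step two rasterises target-group records (other species with
similar detectability, sharing the observers' accessibility bias) into a
survey-effort surface under a 3×3 focal mean — edge cells average over the
neighbours that exist, so a corner cell is the mean of its 4 in-grid
neighbours — and removes candidate cells with less than 40% of the maximum
effort. If the candidate pool cannot supply the requested `n` (default
10,000 per replicate, 3 replicates), the floor is relaxed in steps of 0.05
down to 0; if the pool is still short, cells are drawn with replacement and
the output is flagged as degraded, never silently. Presence cells are always
excluded from candidacy (a label-noise guard). Presences carry weight 1 and
pseudo-absences weight `n_presence/n`, so the two classes carry equal total
weight within each replicate.

**Learners.** Ten algorithm ids are supported behind one contract (predictor
matrix → score in [0, 1]): GLM (logistic regression), GAM (cubic-spline basis
+ logistic), MARS (hinge-basis logistic written in-package), GBM (gradient
boosting), ANN (a small multilayer perceptron), RF (random forest), MAXENT
(linear + quadratic + product features under a regularised logistic fit —
the standard maxent feature classes short of hinges), SRE (the native
quantile surface range envelope: presence quantiles `q`/`1−q` per layer,
default q = 0.025, predict 1 iff all layers fall inside), CTA (decision
tree), FDA (linear discriminant). Sample weights are honoured where the
estimator supports them. The framework runs with any subset; nothing
hard-requires all ten.

**Evaluation and the ensemble.** Data are split 70/30, stratified by label,
independently per (pseudo-absence replicate × CV replicate); the full design
is algorithms × 3 CV × 3 PA (= 90 runs for ten algorithms). AUC is the
rank-based probability that a presence outscores an absence (ties ½),
computed from midranks — algebraically identical to exhaustive pairwise
counting, which the tests use as the oracle. TSS = sensitivity + specificity
− 1 is maximised over a fixed 101-point threshold grid on [0, 1]
(`score ≥ t` predicts presence; ties resolve to the smallest threshold). The
ensemble keeps runs with TSS **strictly greater than** 0.60 and weights them
by raw TSS normalised to sum 1; if nothing passes, building the ensemble is
an error, not a silent fallback. Binary maps use the threshold that maximises
ensemble TSS on the pooled validation records. Variable importance is the
permutation-correlation convention: `1 − cor(reference predictions,
predictions with one layer shuffled)`, averaged over permutations (default
3) and normalised to 100%.

**Projection and change accounting.** A scenario is an SSP label, a year and
≥1 GCM stack; GCM stacks are averaged cell-wise first (nodata propagates),
and the future map is binarised at the *same* threshold as the current map —
re-optimising the threshold on the future would conflate threshold drift
with climate signal. Change maps classify (current, future) pairs into
stable-suitable/stable-unsuitable/loss/gain; by construction
`stable_suitable + loss` equals the current suitable count and
`stable_suitable + gain` the future one, exactly. Net change is
`(gain − loss)/current suitable × 100`.

**Overlays.** Zonal statistics assign a cell to the zone containing
(covering) its centre, first match wins, so a polygon partition reproduces
the whole-map totals exactly. Wind-farm footprints convert installed capacity
to cleared land at 0.3 ha/MW and draw a circular buffer of that area
(64-segment polygon; the overlap count itself uses the exact centre-in-disc
test). Suitable pixel counts convert to km² with a configurable per-pixel
area: 0.8606 km² is the default for 30-arc-second rasters
(`(6378.137 km × 30″ in radians)²`); synthetic landscapes use `cell_size²`.
Buffers smaller than a pixel quantise to 0 or 1 whole cell, so per-status
percent overlap is a pixel-count statistic and can exceed 100% for
sub-pixel buffers; a merged-union variant is reported alongside the
per-farm sum because overlapping buffers of the same status would otherwise
double-count cells.

## The synthetic world

Planar coordinates in km; one pixel is `cell_size` km square; presences sit
at cell centres so grid membership is exact in tests. Predictor fields are
Gaussian white noise blurred at a configurable radius (default σ = 3 cells),
then **orthogonalised over cells (Gram–Schmidt) and standardised** before
engineered collinear pairs are mixed in as
`layer_j = ρ·layer_i + √(1−ρ²)·residual`. The orthogonalisation step means
requested pair correlations are reproduced exactly (not merely in
expectation), and the VIF closed form `1/(1−ρ²)` holds exactly whenever the
screening sample covers the grid — smoothed random fields have few effective
degrees of freedom, and without it incidental correlations of ±0.1 between
"independent" layers are common at this grid size.

Ground truth is `inverse-logit(β₀ + Σ βⱼ·layerⱼ)`. The reference world
(pipeline defaults and the strong-signal benchmark) uses a 100×100 grid of
3-km cells, coefficients (6, −4.5, 3) on three layers with two further noise
layers, and intercept −2.5: a steep, *rare* niche occupying a minority of the
landscape. Both choices matter for identifiability: a steep logistic
concentrates presences in genuinely suitable cells, and a rare niche keeps
the envelope low zone mostly genuinely unsuitable. (Half of presence cells
necessarily score below the median envelope index, so with a widespread
species the low zone is heavily contaminated with suitable habitat and no
learner can separate the classes — a property of the pseudo-absence design
itself, worth knowing when applying it.)

Observer bias is a smooth accessibility field or a two-block field (an
under-surveyed half at 0.5); presences are drawn with probability ∝ truth ×
bias. Target-group surrogates (default 19 species × 200 records) get their
own random niches but share the bias field — if surrogates shared the focal
niche, survey effort would be a proxy for suitability and the effort floor
would *select* suitable cells as pseudo-absences, inverting the labels; the
diverse-niche pool makes pooled record density track the bias, which is the
premise of target-group effort correction. Futures shift named layers by
per-scenario deltas plus smooth per-GCM noise (default sd 0.05). Zones are
Voronoi cells of seeded points clipped to the extent (an exact partition);
wind farms are uniform points with uniform capacities and categorical
status.

What the generator does **not** emulate: real bioclimate semantics and their
cross-correlations, geographic (curved-earth) coordinates, anisotropic or
non-stationary spatial structure, temporal trends in recording effort,
detection error at presences, and spatial aggregation of wind farms along
coasts. Passing tests therefore demonstrate that the machinery is correct
and that the design recovers a known signal under its own assumptions — not
that any particular real-world result is right.

## Numerical conventions

- NaN is nodata everywhere; stacks harmonise member masks to their union.
- Raster row 0 is the northernmost row; ESRI ASCII grids are the text I/O
  format, GeoJSON the vector one.
- Resampling: bilinear for continuous layers, nearest for categorical;
  cells outside the source extent (or within half a cell of it, under
  bilinear support) become nodata.
- Terrain: Horn 3×3 finite differences; border cells are nodata; flat cells
  get slope 0 and the aspect sentinel −1 (aspect undefined at zero
  gradient); aspect is the compass bearing of the downslope direction.
- Seeds: every stochastic step takes an explicit seed; the pipeline derives
  per-stage seeds as `sha256(master:stage:replicate) mod 2³¹`, so stages are
  reproducible in isolation and two stages never share a stream.
- Stratified splits redraw up to 10 times if a class is missing from train
  or test, then raise.
- Weight equality between classes is exact in the arithmetic
  (`n · n_presence/n`) and asserted to 1e-12 relative in tests, the
  realistic float bound for a 10⁴-term sum.

## Scale of the shipped benchmarks

The default configuration reproduces the reference design exactly
(15 km thinning; 10,000 pseudo-absences × 3 replicates behind a 0.40 effort
floor; VIF < 5; ten algorithms × 3 CV × 3 PA = 90 runs; 70/30 split;
TSS > 0.60 gate; four SSPs × two horizon years) on the 100×100-cell world —
a deliberate desk scale at which the full design runs in about a minute.
On a 10⁴-cell landscape a 10,000-point pseudo-absence request exceeds any
candidate pool, so the default run exercises the relaxation-then-replacement
path and flags it; the pseudo-absence contract tests use a larger (200×200)
world where the pool suffices at a positive floor. The strong-signal
benchmark (GLM/RF/GBM/SRE × 3 CV on 500 presences and 2,000 pseudo-absences)
is the parameter-recovery workload: ensemble holdout AUC and the Pearson
correlation between the ensemble map and the true suitability surface are
its outputs, and `scripts/acceptance.py` recomputes them from scratch.

## Known limitations

- No geodetic support: real-data use requires pre-projected planar rasters.
- MAXENT and MARS are principled stand-ins built from standard learners (the
  feature-class constructions above), not re-implementations of the original
  software's regularisation paths.
- The envelope index ignores predictor covariance (by design; see above).
- Sub-pixel wind-farm buffers quantise; use a finer grid or the fractional
  interpretation consciously.
- No dispersal limits, demographic structure, or no-analog (extrapolation)
  screening in projections.
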