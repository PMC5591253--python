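# Methods

## Ordinal class codings and binning

The three field scales are coded as continuous class units: the 7-class
soil drainage and SMR scales at midpoints 0.5 … 6.5 over [0, 7], the
5-class SNR scale at 0.5 … 4.5 over [0, 5].  Half classes — field calls
between two adjacent classes, common where the optimal class is unclear —
sit at the integers between midpoints (very poor/poor = 1.0).  Class
order is stored wettest/poorest → driest/richest so labels and numeric
codings increase together; labels are case-normalized on input.

Two binning rules convert continuous values back to labels:

* **full mode** — unit-width bins, half-open below, `(k, k+1]`, with the
  bottom bin closed at 0 (0.1–1.0 → wet, 1.1–2.0 → moist/wet, …);
* **half mode** — a quarter-offset scheme: `[0, 0.25]` → first full
  class, then 0.5-wide upper-inclusive bins alternating half and full
  labels (0.26–0.75 → wet/moist-wet, 0.76–1.25 → moist/wet, …), the top
  bin absorbing the remainder of the range.

The half-mode bins are offset half a class unit below the label
midpoints; this is the scheme the source field protocol prints, adopted
as-is.  One consequence is that the half-mode roundtrip of a half-class
midpoint does not return that half class; only the full-mode roundtrip
identity holds, and it is asserted for every class of every system.
Values outside the range are clamped by default — a mapped landscape must
be exhaustively classified, and regression predictions can slightly
overshoot [0, 7] — with a strict mode that raises instead.

## Regime calibration

SMR is regressed on model-predicted continuous soil drainage per
ecoregion by ordinary least squares (`scipy.stats.linregress`; a
constant-response input is handled as a flat, perfect-fit line).  Field
ordinal classes are converted to midpoints (half classes included) before
fitting.  Predictions are affine and unclamped; NaN predictors propagate
to NaN rather than silently becoming zero.  The bundled calibrations are
SMR = 0.1997 + 0.9869·SD (Acadian, r² = 0.88, n = 1384) and SMR = 0.2683
+ 0.9500·SD (Maritime-Boreal, r² = 0.89, n = 123).  The SNR ~ clay
calibration was never published in equation form, so the package ships no
coefficients for it; the same linear machinery fits one from plot data
(the CLI `calibrate` command does this whenever clay and SNR columns are
present).

## Edatopic grids

Axis convention: SNR horizontal ([0, 5]), SMR vertical ([0, 7]).  The
original grids draw each ecosite as an axis-aligned ellipse (rotation is
not identifiable from any published source, and the drawn ellipses appear
axis-aligned).  A point in several overlapping ellipses is assigned to
the one whose center is nearest in normalized coordinates
(((Δsnr/a)² + (Δsmr/b)²)^½); the original work does not state its
tie-break, so nearest-normalized-center was chosen as the natural
distance on the ellipse geometry.

**Combination.**  Ecosites distinguishable only by soil and/or vegetation
type — never by field SMR/SNR — are merged: 17 Acadian originals become
10 combined ecosites, 11 Maritime-Boreal originals become 10.  The rules
live in the grid configs as data (condition tags 1–3 record the reason
for each merge); nothing is inferred from vegetation or soil types at run
time.

**Transformation.**  Overlapping combined ellipses are replaced by
disjoint rectangles by a greedy search: ecosites in descending plot
count; for each, exhaustive search over a cut lattice (default 0.25 class
units) for the rectangle maximizing (own plots inside) − λ·(foreign plots
inside), λ = 1, disjoint from already-fixed rectangles; ties break toward
smaller area, then lexicographically smaller bounds, making the result
deterministic.  A plotless ecosite is seeded from its ellipse's bounding
box snapped outward to the lattice.  A final pass grows rectangle faces
one lattice step at a time, round robin, until no face can grow, annexing
the uncovered domain; on the bundled grids and test instances this yields
an exact partition.  Classification is total regardless: a point in no
rectangle is assigned to the nearest one (Euclidean distance, ties to the
lower ecosite id), flagged `inside=False`.

**Bundled grid coordinates.**  No published source tabulates the ellipse
or rectangle coordinates.  The shipped configs are synthetic
approximations (marked as such in their comments): rectangles generated
by the transform from the ellipse approximation and synthetic plots, then
hand-adjusted to satisfy the two printed worked-example constraints — at
SNR 0.5, SMR 3.6 falls in Acadian ecosite 2 and SMR 3.4 in ecosite 3, so
the 2/3 boundary sits at SMR 3.5 — and the qualitative layout (ecosites 5
and 6 central; 1, 3, 7 and 10 peripheral).  All coordinates live in YAML
config, never in code, and user grids load through the same validated
schema.  Rectangle intervals are half-open `[lo, hi)` with the upper
domain edge inclusive, so the ten rectangles tile the domain exactly.

## Accuracy assessment

Error matrices put field classes in rows and predicted classes in
columns.  Continuous predictions are binned in full mode (matrices have
7/7/5 columns); half-class field calls are resolved to the nearest full
class with ties toward the wetter/poorer class, since matrix rows are
full classes.  Producer's accuracy divides the diagonal (exact) or the
diagonal ± one column (within ±1 class) by the row total; empty rows are
reported as missing, not 0, so they cannot bias summaries.  Overall
accuracy pools all plots and equals the row-weighted mean of producer's
accuracies.

Ecosite accuracy has three modes: *ellipse* (field coordinates on the
original ellipses, relabelled to combined ids for comparison), *rectangle*
(field coordinates on the rectangle grid) and *model* (predicted
coordinates on the rectangle grid).  A plot outside all ellipses counts
as incorrect.  Within-±1 is not computed for ecosites: they are
categorical, not ordinal.  No kappa or user's accuracy is reported.

A center-distance diagnostic compares, per ecosite, the mean field
(SNR, SMR) of its plots with the mean predicted coordinates of the same
plots; systematic prediction bias toward the middle of the scales shows
up as predicted centers converging toward the domain center.

## Raster mapping and the sieve

`map_ecosites` applies the point classifier to every cell of aligned
SMR/SNR rasters (10-m cells by default, the footprint of one field
plot), using each cell's ecoregion grid; nodata in any input is nodata
out.  Raster I/O uses the ESRI ASCII grid text format with the nodata
value honoured exactly.

`eliminate_small_polygons` removes map noise: connected components of
like-labelled cells (4-connectivity by default, 8 by flag) smaller than
25 ha (2,500 cells at 10 m) are merged into the neighbouring component
sharing the longest border — ties to the larger neighbour, then the lower
ecosite id — smallest components first, with components recomputed
between passes so the result is order-independent and idempotent.
Ecoregion boundaries are hard barriers and nodata is never merged; a
region entirely below the threshold is left intact.  The published work
states only the 25-ha threshold; connectivity and the merge rule are this
package's choices, documented here.

## Synthetic data

The field data behind the published accuracy tables (1,507 plots) are not
public, so the generator emulates their statistical structure.  Defaults
are the study conditions: 1,384 Acadian and 123 Maritime-Boreal plots;
drainage classes uniform over the seven classes; SMR = calibration line +
N(0, σ) with σ = 0.73 (Acadian) and 0.70 (Maritime-Boreal), chosen to
reproduce the published r² of 0.88/0.89; SNR classes from a mildly
center-weighted prior (0.10/0.25/0.35/0.20/0.10 — the published row
totals are not recoverable, so a realistic unimodal prior is used, with
override); the field ecosite is the rectangle-grid classification of the
field coordinates, so rectangle-mode accuracy on exact coordinates is
100% by construction.

Predictions perturb the field class under a three-outcome error model
(exact / off-by-one / worse) calibrated to the published marginals:
drainage 0.36/0.48/0.16 (36% exact, 84% within ±1), SMR 0.52/0.34/0.14
(52%/86%, inside the published 47–58%/83–91% bands), SNR 0.62/0.37/0.01
(62%/99%, inside 57–68%/98–100%).  The continuous prediction is the field
value shifted by whole classes, so the binned prediction realizes the
drawn class exactly and a zero-error draw reproduces the field value —
giving the degenerate-generator identity (all accuracies 100%, diagonal
matrices) that anchors the test suite.  The middle-class clumping of real
predictions is implemented as a directional bias: errors go toward the
central class with probability 0.5 + clump/2 (default clump 0.3).  A
shrinkage of continuous values toward the domain midpoint would also
produce clumping but would distort the calibrated exact-agreement rates;
the directional bias preserves them while reproducing the
predicted-centers-converge-inward diagnostic.  Half classes are emitted
for a configurable 10% of field SMR/SNR calls (the real rate is
unpublished beyond "often").

Regime rasters are Gaussian random fields: white noise smoothed with a
Gaussian kernel of σ = L/(2·cell) cells, so the empirical autocorrelation
falls to 1/e at the configured correlation length L (default 100 m),
rescaled so ±2.5 sd spans the class range.  The region map splits the
scene ~88/12 into a large Acadian block and a Maritime-Boreal strip,
mirroring the real landscape's proportions.  The generator does **not**
mimic real geography, geology, the plot network's spatial design, or
spatially structured prediction error (errors are independent across
plots); passing tests therefore validate the pipeline's logic and its
behaviour under the published error magnitudes, not map accuracy on real
terrain.

A single seeded generator stream is consumed in documented order, so a
fixed seed gives bitwise-reproducible plot tables and rasters.

## Problem sizes

The test suite and acceptance script run at the study's plot counts
(1,384 + 123) and on rasters up to 400×400 cells (autocorrelation check)
and 200×200 (sieve census); the full suite completes in well under a
minute.

## Known limitations

* The bundled grid geometry is a constrained reconstruction, not the
  published figure; absolute per-ecosite accuracies on synthetic data are
  therefore not comparable to the published per-ecosite values, though
  the mode ordering (rectangle > ellipse ≈ model) and the regime-class
  marginals are.
* The published error-matrix cell values are corrupted in the available
  source text; only prose-quoted marginals are used for calibration.
* The face-growing expansion is not guaranteed to produce an exact
  partition for adversarial rectangle arrangements; classification
  remains total via the nearest-rectangle fallback.
* The ANN soil-property models and the two-stage large-area extension
  that produce the drainage and clay inputs are out of scope; their
  outputs are emulated synthetically.
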