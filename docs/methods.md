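# Methods

## Pipeline model

The pipeline treats a multiplexed immunofluorescence image as four named
2-D intensity channels sharing one physical pixel size: a nuclear stain
(DAPI), an epithelial/cancer marker (pan-cytokeratin), a stromal surrogate
(fibronectin), and one marker of interest. All lengths are in µm with the
QuPath convention: origin at the image top-left, x rightward, y downward,
pixel (0,0) spanning [0, pixel_size)².

### Cell model

Cells are nucleus-seeded. The built-in segmenter is classical — Gaussian
blur (default σ = 1 µm), global threshold (Otsu unless fixed), hole
filling, distance-transform watershed seeded at local maxima ≥ 3 µm apart,
removal of objects below 4 µm². It is deliberately simple; deep-learning
masks produced elsewhere can be imported as labeled TIFF or GeoJSON and
used unchanged downstream. Whole cells are the nuclei expanded radially by
5 µm (in pixels: round(5/pixel_size)). Where expansions compete, each
contested pixel joins the nucleus whose boundary is nearest in exact
Euclidean distance, ties to the lower label id, so cells partition the
plane deterministically and never overlap; the cytoplasm is the expanded
cell minus its nucleus. Per-image QC drops cells whose nuclear area is
strictly below the 5th or strictly above the 99th percentile of that
image (linear-interpolation percentiles; boundary-equal areas kept — the
filter removes cells "smaller than" / "larger than" the bounds).

### Stromal border and signed distances

The stroma is `gaussian(fibronectin, σ) > threshold`. σ is accepted in µm
or in pixels because smoothing scales for this step are commonly reported
in image-native units; both are explicit flags. The signed distance field
assigns each pixel +EDT to the nearest stromal pixel outside the mask and
−EDT to the nearest non-stromal pixel inside it (exact Euclidean distance
transform, scaled to µm). Consequences of this nearest-opposite-phase
convention worth knowing:

* pixels adjacent to the border carry |d| = 1 pixel, not 0.5, so crossing
  the border steps from +1 to −1 pixel units; |d| is 1-Lipschitz within
  each phase and changes by at most twice the step across the border;
* it matches a brute-force "minimum distance to any opposite-phase pixel"
  oracle exactly, which is how it is tested.

Cells sample the field at the pixel containing their nuclear centroid (no
interpolation — distances feed 10 µm bins, ~8× coarser than even the
scaled-up phantom pixel). Cells at d = 0 count as outside the stroma
everywhere (side splits and binning share the half-open convention).

### Threshold calibration (percentile mapping)

Per image and feature, a pool of non-negative families — log-normal, Wald,
Burr, beta, gamma — is fitted to the cell-level feature values.
Estimation is maximum likelihood with the location pinned at 0 (these are
models of non-negative intensities; beta keeps a free scale so its support
covers the data range). Model *selection* is least-squares: the
density-normalized histogram (default N_b = 200 equal-width bins) is
compared with the fitted pdf at bin centers and the family with minimal
SSE wins; all per-family SSEs are retained for reporting. MLE-then-SSE is
used instead of minimizing SSE over parameters because it is numerically
stable and matches the behavior of the standard distribution-fitting
tooling this procedure mirrors; the SSE criterion decides only which
family is kept. Fitting uses raw values — the 1st/99th percentile clipping
applied elsewhere is a visualization device only.

A threshold t_ref chosen on reference image i maps to image j by
percentile preservation, t_j = F_j⁻¹(F_i(t_ref)). The mapping is strictly
increasing in t_ref, exact under identity (the reference image's threshold
is t_ref by construction), and for a batch differing only by a
multiplicative intensity scale c the closed form is t_j = c·t_ref — the
property the recovery tests measure. Thresholds sitting exactly at CDF 0
or 1 are refused as unmappable. The calibration operates on per-cell
feature values; raw pixel samples can be fed instead (any 1-D array is
accepted), but cell measurements are the intended input.

Direct empirical thresholds are also provided: the top-N% threshold is the
linearly interpolated (1−N%) quantile, and positivity is strict
(value > threshold), so on continuous data exactly round(n·N%) cells land
above it. Tie-heavy discrete data therefore yields *fewer* positives, never
more.

### Spatial statistics

Profiles bin cells by signed distance into uniform half-open bins with an
edge pinned at 0 (default width 10 µm ≈ one cell diameter, range −100 to
+300 µm; a range not divisible by the width is snapped outward). Per bin:
mean feature value, cell count, sample SD, and a bootstrap SEM — the SD of
the bin mean over n_boot = 500 seeded with-replacement resamples of that
bin's cells. Bootstrapping is per-bin over cells; resampling across images
belongs to the sensitivity analysis, which is a different question
(stability across slides rather than within-bin sampling error).
Differences of two same-binned profiles propagate error as
SEM = √(σ_a²/n_a + σ_b²/n_b); the formula is written with the radical
because the quantity is a standard error, and the equal-group case reduces
to √2·σ/√n. The side-wise summary statistic is the Pearson correlation
between feature and signed distance, computed separately for d < 0 and
d ≥ 0; a side with fewer than two cells or zero variance reports NaN and
is flagged rather than fabricated.

### Sensitivity analysis

The (σ, threshold) grid rebuilds the mask, the distance field, and the
side-wise correlations per image at every point; empty/full masks flag the
point without aborting the grid. Inside-vs-outside correlation differences
are paired within an image, tested with a two-sided Wilcoxon signed-rank
test: zero differences are dropped, tied magnitudes mid-ranked, and for
n ≤ 25 pairs the p-value comes from exact enumeration of the null
(implemented by convolution over doubled ranks, so mid-ranks stay exact);
above that the tie-corrected normal approximation is used and documented
in the function contract. Per-point p-values pair images at that point; a
pooled p-value additionally treats every (grid point × image) pair as one
paired observation, since both correlations of a pair always come from the
same image under identical conditions. Bootstrap summaries across images
use 500 iterations by default.

## Phantom data: what it emulates, what it does not

The phantom generator provides the study conditions for every test:

* geometry — a vertical stromal band by default (also annulus and random
  blobs), with analytic signed distances for band and annulus;
* intensities — per-cell marker values are log-normal,
  value = c · exp(µ + g(d) + σ·z), with µ = 5.0 and σ = 0.5 (log-scale
  location/spread typical of arbitrary-unit fluorescence features), the
  distance effect g entering the log-location (a multiplicative effect,
  consistent with the log-normal model of the intensities themselves), and
  c a per-image multiplicative batch scale;
* distance effects — `peak` (Gaussian bump at the border, amplitude 1,
  width 30 µm), `decreasing` (slope 0.01 per µm on the log scale), or
  `none` (the regime where mapped thresholds have the exact c·t_ref
  answer);
* ground truth — mask, true distances, cancer subset (70% of cells),
  marker draws, and the generating positivity threshold, defined as the
  90th percentile of the baseline log-normal scaled by c.

Image phantoms default to 512×512 px at 1.286 µm/px — the 0.3215 µm
scanner pixel scaled up 4× so that ~300 cells and a 5 µm expansion remain
resolvable in a desk-sized image; table phantoms generate any cell count
directly without rendering. Everything is deterministic under a seed.

What the phantoms do *not* emulate: tissue texture, optical PSF and
shading, autofluorescence, segmentation-error correlations, non-log-normal
or non-multiplicative batch effects, and 3-D structure. Passing tests
therefore demonstrate the statistical machinery is correct under its
stated model — multiplicative batch shifts of log-normal intensities
around a well-defined stromal geometry — not that any biological claim
holds on real slides. Problem sizes in the test-suite and acceptance runs
(50,000-cell tables for recovery tests, 100 replicates at 20,000 cells for
model selection, three ~300-cell images for the end-to-end chain) are the
package's chosen desk-scale conditions.

## Numerical choices and degenerate inputs

* Percentiles/quantiles are always the linear-interpolation definition.
* Distribution fits require ≥ 100 finite values; constant samples are an
  error; a family that fails to converge is skipped with a warning rather
  than failing the pool.
* Native CSV cell tables write floats with `repr` and read with
  round-trip parsing, so read(write(x)) is bit-exact.
* Mask polygons are traced at the 0.5 iso-level, holes resolved by
  containment parity; re-rasterization (pixel-center containment) can
  disagree with the source mask only in a one-pixel border band.
* The expansion tie-break (lower label id) and the seeded bootstrap make
  every stochastic or order-sensitive step deterministic; the CLI derives
  per-stage seeds from one global seed, and two identically seeded runs
  are byte-identical.
* Blank segmentation inputs, empty masks, out-of-bounds centroids, bins
  with < 2 cells, and sides with zero variance all degrade to flagged/NaN
  results with warnings instead of exceptions; masks with no border
  (empty/full) are errors because no distance is defined.

## Design choices that were genuinely open

* **Learning-based classification** is a pluggable interface (any
  cells → labels callable) plus an external-label importer, not a bundled
  trained model: the analytic use of a trained classifier here is
  agreement computation against threshold labels, which is fully covered.
* **QuPath header vocabulary** varies across versions, so the export
  dialect is a configurable mapping table with sensible defaults rather
  than a hard-coded parser.
* **Sigma units** for stroma smoothing are explicit (`um` or `px`) rather
  than guessed from magnitude.
* **d = 0 is outside**: one convention shared by binning, side splits and
  sign reporting.

## Limitations

* The stroma model is a smoothed global threshold; texture- or
  learning-based segmentation is out of scope.
* Whole-slide pyramidal formats are not read; inputs are plain
  multi-plane TIFFs or measurement tables.
* All distances are 2-D; sectioning effects and 3-D interactions are not
  modeled.
* The classical nucleus segmenter is a baseline, not a competitor to
  trained models; import external masks for production segmentation.
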