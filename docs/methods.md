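# Methods

## The measurement model

A Live/Dead-stained sludge sample yields two kinds of confocal frames: green
(SYTO9, viable cells) and red (propidium iodide, non-viable cells), one marker
per frame, 8-bit RGB, natively 1024×1024 although any size is accepted. The
stain encodes a binary state — a cell is alive or dead, with no intermediate
gradation — so the analysis treats a dim bright pixel the same as a saturated
one and deliberately avoids object segmentation or cluster morphometry:
bacterial aggregates are too variable in shape and size for those to be
reliable. What is quantified is brightness mass.

The pipeline per frame:

1. **V channel.** `V = max(R, G, B)` per pixel, kept as an integer in
   [0, 255]. V is invariant under any permutation of the color planes, which
   is the point: the same spot pattern scores identically whether it is green
   or red, removing the perceptual bias that makes red look dimmer to a human
   counter. Hue and saturation are computed (standard hexcone formulas, hue in
   degrees [0, 360), first matching branch on channel ties) but are
   diagnostics only.
2. **Dark-normalized histogram.** `h(v)` = number of pixels with `V = v`,
   256 levels; `ĥ(v) = h(v)/h(0)`. Bacteria cluster, so frames contain large
   areas with no information; `h(0)` measures that background and dividing by
   it makes frames of different bacterial density comparable. Duplicating a
   frame doubles both `h(v)` and `h(0)` and leaves every `ĥ(v)` bit-identical
   (IEEE division of exactly doubled integers rounds identically). A frame
   with `h(0) = 0` is rejected as non-conforming rather than patched — a
   confocal frame without any dark pixel violates the acquisition model the
   normalization relies on.
3. **Feature.** `max_binned` (default): levels 1–255 are partitioned into
   `n_bins = 127` contiguous bins, bin `b` covering
   `[1 + ⌊255·b/n⌋, 1 + ⌊255·(b+1)/n⌋ − 1]`; the feature is the maximum bin
   content. `sum_all`: `Σ_{v=1}^{255} ĥ(v)`. Level 0 is excluded from both —
   it is the normalizer, its normalized value is identically 1, and including
   it would pin the max feature at a constant. `max_binned` with 1 bin equals
   `sum_all`; with 255 bins it equals the largest single normalized entry.
   The floor-based edge rule is fixed so results are bit-reproducible; 127 is
   an empirical default exposed as a parameter, and sample rankings are stable
   across 63/127/255 bins and `sum_all` (checked by test and acceptance run).
4. **Ratio.** Per (sample, time): arithmetic mean of the 1–4 green features,
   likewise red, ratio = green/red. Mean-of-features rather than
   feature-of-pooled-histogram, so each frame counts equally regardless of its
   dark-area fraction; ratio-of-aggregates rather than mean-of-pairwise-ratios
   because green and red frames are unpaired captures of the same sample.
   Swapping the two marker sets maps the ratio to its reciprocal exactly. A
   zero red aggregate is an error ("no detectable dead-cell signal"), not an
   infinite ratio.

Frame quality is scored as `mean(V) ×` Tenengrad energy (mean squared Sobel
gradient of V/255): zero for dark or uniform frames, decreasing under blur.
The score operationalizes "brightest and best focus" frame selection but is
advisory — manifest-listed frames are never silently dropped.

## Synthetic frames

No reference micrographs are distributable, so validation uses a simulator
that emulates the described image character rather than confocal optics:

- **Spatial model:** Thomas-type cluster process — `n_clusters` parents
  uniform over the frame, each cell offset from its parent by an isotropic
  Gaussian of sd `cluster_spread` px. Cells falling outside the frame render
  truncated (edge effects are real).
- **Rendering:** each cell is a Gaussian spot of width `spot_sigma` px whose
  peak is truncated-normal on (1, 255] (`peak_mean = 180`, `peak_sd = 40` by
  default). Spots add, then the frame is clipped to [0, 255] and quantized,
  so dense clusters saturate — as real bright aggregates do.
- **Channels:** the green and red scenes are independent draws; each frame
  carries signal in exactly one color plane.
- **Noise:** `noise_sd = 0` by default. The emulated frames have truly black
  background ("large areas without information"), which is what anchors the
  normalization. Gaussian noise above the quantization threshold
  (sd ≳ 0.5) floods levels 1–6 of *both* markers, the binned max then measures
  the marker-independent noise floor, and all ratios collapse toward 1. That
  is a genuine limitation of dark-count normalization on noisy exports, so
  `noise_sd` is kept as an explicit stress parameter rather than a default
  condition. A noise-free render with fewer than 1% dark pixels triggers a
  degeneracy warning.

Defaults: 1024×1024 frames, 8 clusters, spread 20 px, `spot_sigma` 2 px
(chosen for visual plausibility — the stated field of view fixes no per-cell
pixel size). Panels hold the total cell count per pair fixed (default 400)
and vary only the live/dead split, `n_live = round(total·r/(1+r))`; every
image gets an independent child seed derived from the panel seed. Recovery
tests run 256×256 frames, planted ratios 0.25–4, three replicates: the
estimated ratio is monotone in the planted ratio (Spearman ρ ≥ 0.9 on the
seeded test panel) with magnitudes compressed toward 1 by cluster-overlap
saturation, and the planted-equal case mean falls in the tested 0.8–1.25 band
on that panel; at three replicates per condition the scatter of that mean is
substantial, so orderings are the robust output.

What passing on synthetic panels does **not** show: performance under
bleed-through between channels, nonzero detector offset, z-stack projection
artifacts, or point-spread physics — none of which the simulator models.

## Reactor-variable integration

Nine per-reactor variables (TOC removal, cumulative CH₄ and CO₂, ecotoxicity,
EST/GST/CAT enzyme activities, ROS generation, non-viable cell fraction) are
z-scored column-wise (mean 0, sd 1, n−1 denominator; a constant column is an
error naming the column) and decomposed by correlation-matrix PCA, computed
as the SVD of the standardized matrix: eigenvalues are squared singular
values over n−1 and sum to the number of variables, so variance fractions
read directly. Sign convention: each loading column is flipped so its
largest-magnitude element is positive — biplot orientation is otherwise
arbitrary, and the convention makes repeated runs and row reorderings
bit-identical. The biplot table scales variable arrows by √eigenvalue
(correlation scaling) and plots raw scores for observations; any grouping of
reactors is left to the reader, backed by pairwise score-space distances
rather than an algorithmic clustering.

`planted_two_factor_metrics` generates validation input from a known
two-factor model: column `j` is `a_j1·f1 + a_j2·f2 + e_j` with unit-variance
factors, `a_j1² + a_j2² + var(e_j) = 1`, and default factor shares
(0.52, 0.23). Note the model's true top-two PCA share is
`s1 + s2 + 2(1 − s1 − s2)/p`, not `s1 + s2`: isotropic noise raises every
population eigenvalue, including the top two. The generator returns that
closed-form share and the recovery check compares the sample estimate to it.
It defaults to 100 simulated observations because eigenvalue estimates from a
handful of rows are dominated by small-sample inflation (a 6-row matrix has
rank ≤ 5 and its top-two share overshoots the population value by far more
than the check's ±5 points); with 100 rows the sampling sd is ≈1.6 points.

## Numerical and interface choices

- Only lossless rasters (TIFF/PNG) are read or written; JPEG is rejected
  because compression artifacts perturb `h(0)`. 16-bit input is an explicit
  error, never silently rescaled. RGBA alpha is dropped with a warning.
- The marker of record comes from the manifest, not from pixel content; a
  consistency check warns when the declared marker's plane has lower total
  intensity than the other plane.
- Manifest groups are limited to 1–4 frames per (sample, time, marker),
  matching the acquisition protocol the pipeline expects.
- Binned sums use `np.add.reduceat` over fixed integer edges; with the
  default fine binnings (≥ 37 bins, ≤ 8 levels per bin) the accumulation
  order coincides with sequential summation, so oracle agreement is exact.
- All simulator randomness flows through `numpy.random.default_rng` seeded
  from the spec; panel children are derived via `SeedSequence` and kept below
  2³¹.
- Ratios are plain quotients of features: the method yields a *relative*
  viability proportion, not a calibrated percentage of live cells.

## Known limitations

- Absolute ratio magnitudes are attenuated toward 1 at high spot density
  (clipping); orderings, not magnitudes, are the reliable output.
- Detector noise above the 8-bit quantization threshold breaks the
  dark-count anchor (see above); frames should be exported with the
  background at true zero.
- The quality score ranks frames but no objective inclusion threshold is
  applied; frame selection remains the operator's decision.
- PCA on a real 6-reactor table estimates eigenvalues from 6 observations;
  the decomposition is exact for the data at hand but generalizes weakly, and
  no inferential statistics (confidence ellipses) are attached by design.
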