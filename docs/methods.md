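# Methods

## Model

A continuous-mode MSI datacube is a matrix of nonnegative peak
intensities *P*ᵢ(x, y): one row per pixel on a 0-based (col, row) grid,
one column per channel of a shared m/z axis. The axis is uniform — the
interval [start, end) split into *n* half-open bins of width
*w* = (end − start)/*n*; the package's default mirrors a lipid-range
TOF acquisition, m/z 550–1050 over 2500 channels (*w* = 0.2 Da). A pixel
is *valid* when its total intensity is strictly positive; all-zero
pixels (off-tissue background, or blanked spots) are carried in the grid
but excluded from every statistic.

Each valid pixel's spectrum is normalized to relative intensities
*p*ᵢ = *P*ᵢ/Σⱼ*P*ⱼ and reduced to its Shannon entropy
*H* = −Σᵢ *p*ᵢ log₂ *p*ᵢ in bits, with the continuity convention
0·log₂ 0 = 0. All channels, including zeros, are part of the
calculation, so 0 ≤ *H* ≤ log₂ *n* with equality at 0 iff a single
channel carries all intensity and at log₂ *n* iff the spectrum is
uniform. *H* is invariant to rescaling a spectrum by any positive
constant, so entropy maps are insensitive to per-pixel total-ion-current
variation — this is what distinguishes them from TIC images. Undefined
(invalid) pixels carry NaN in the map, never 0, because 0 is a
meaningful entropy.

All entropy arithmetic is done in double precision regardless of the
storage dtype of the input; log₂ is evaluated only on strictly positive
entries.

## Low-entropy pixels

Samples under comparison are pooled: the entropies of all their valid
pixels form one empirical distribution, and the threshold *H*₁ is its
`percentile` quantile (default 0.01) computed by linear interpolation
between order statistics. A pixel is low-entropy when *H* ≤ *H*₁,
inclusive, so ties at the threshold are flagged; the pooled flagged
count equals ⌊percentile·N⌋ within ±1 for continuous data and can exceed
it under heavy ties, which the result marks with a `degenerate` flag
when the whole pool is constant. Per-sample masks and flagged fractions
are reported: with a common pooled threshold, the sample that contains
more low-entropy structure shows the larger fraction. Whether off-tissue
pixels belong in the pool is a modelling choice; this package excludes
invalid pixels everywhere, and a user who wants them included can assign
them a nominal positive intensity upstream.

## Resolution operators

- **Spectral binning** averages every `factor` consecutive channels,
  left-anchored; `factor` must divide *n* exactly (the supported factors
  of the default axis — 2, 5, 10 — give 1250, 500, 250 channels), and a
  remainder is an error rather than a silent drop. Averaging equals
  summing up to the global constant 1/`factor`, so entropies are
  unaffected by the choice; merging probability mass can only decrease a
  pixel's entropy, so mean map entropy decreases monotonically with bin
  size. Binning composes: factor *a* then *b* equals factor *a·b*.
- **Spatial binning** partitions the grid into `factor`×`factor` blocks
  anchored at (0, 0); each output pixel is the mean spectrum over the
  block's valid members, partial edge blocks average over what they
  contain, and a block with no valid member becomes an invalid all-zero
  pixel. Pixel pitch metadata scales by the factor. For pixels of equal
  total intensity the averaged spectrum's entropy is at least the mean
  of the member entropies (concavity), which is why coarse spatial
  binning washes low-entropy spots out.
- **Top-N selection** sums each channel over all pixels (invalid pixels
  contribute zero) and keeps the N largest, ties to the lower channel
  index, per dataset. The restricted cube keeps the original channel
  order on a non-uniform subset axis, and downstream entropy uses
  *n* = N as its bound.
- **Lock-mass recalibration** is a one-point multiplicative correction:
  the channel with the largest dataset-mean intensity within
  ±`tolerance` (default 0.2 Da) of the reference (default m/z 885.5493,
  PI(38:4) [M−H]⁻) is mapped onto the reference by scaling the whole
  axis. It is approximate — a single point cannot correct nonlinear mass
  drift — and is a no-op with a warning flag when no channel falls in
  the window. Intensities are untouched, so entropy maps are invariant
  under it.

## ROI ranking and annotation

ROIs are ellipses, polygons or explicit masks; membership is a
deterministic pixel-center test, so the identical shape applied to two
conditions selects the identical coordinates. Per-channel ROI sums are
divided by the condition's total ROI intensity (the scale-invariant
choice; dividing both conditions by the reference total instead shifts
every ratio by one global constant and never changes the rank order — a
`normalize` flag exposes both). The change ratio r = normalized test
sum / normalized reference sum is ranked descending, ties to the lower
channel index; channels whose reference sum is below 10⁻¹² of the
reference total are flagged undefined and excluded rather than ranked
off a division blow-up. The extremes of the ranking are the candidate
channels. Annotation reports every compound within ±0.2 Da
(configurable) of an observed m/z, sorted by ppm error
|obs − theo|/theo × 10⁶, rounded to two decimals in reports only. The
observed m/z attributed to a binned channel is its center; sub-channel
refinement requires profile substructure the binned cube no longer has.

## Synthetic data

The generator emulates the geometry and contrast structure of a tissue
section, not MALDI physics. An elliptical tissue area sits on a
zero-intensity background; an embedded low-entropy region and
high-entropy region provide contrast, and condition pairs plant fold
changes inside a designated ROI ellipse. Each pixel draws a
channel-probability vector from a Dirichlet — symmetric with
concentration 5.0 in bulk tissue (mean entropy ≈ 11.1 bits on 2500
channels), 50.0 in the high-entropy region (≈ 11.25 bits), and 0.05 on
10 randomly chosen support channels in the low-entropy region
(≈ 0.8 bits, more than 10 bits below tissue) — times a log-normal total
intensity (median 10⁴ counts, log-sigma 0.3, roughly the TIC spread of a
stable acquisition) times mean-one multiplicative gamma noise with
coefficient of variation 0.2 per channel. Concentrations were chosen so
the region ordering low < tissue < high holds in every seeded replicate
with a ≥ 1-bit planted gap. Planting multiplies the Dirichlet
concentration of a channel by its fold factor for ROI pixels of
condition B, which scales its expected relative intensity by the fold
with renormalization built in. The default grid is 60 × 80 pixels at
50 μm pitch. One seed drives three child streams (support-channel
choice, condition A, condition B), so datasets are bit-reproducible and
conditions are statistically identical except at planted channels.

What the generator does **not** emulate: isotope envelopes, matrix
cluster peaks, peak-shape/centroiding effects, spatial autocorrelation
of biological tissue, and detector nonlinearity. Passing planted-truth
tests therefore shows the estimators recover known spectral structure
under realistic noise magnitudes — not that any particular biological
contrast will be detectable in a given real acquisition.

## Numerical and design choices

- Quantiles everywhere use linear interpolation between order
  statistics; probability-vector validation tolerates |Σp − 1| ≤ 10⁻⁶.
- Histogram bin width for entropy summaries defaults to 0.1 bits.
- imzML support is continuous/profile mode only; processed mode
  (per-pixel axes) is rejected explicitly because the method indexes
  channels identically across pixels. imzML's 1-based coordinates are
  shifted to the package's 0-based image convention on read.
- The CSV datacube dialect writes `repr(float)` values, so round trips
  are exact to the double; imzML round trips are exact with the
  float64 writer settings used.
- Rendering is a pure palette lookup (default `autumn_r`: yellow = low,
  red = high) composed with PIL, one image pixel per grid pixel times an
  integer scale, with a min/max-annotated color bar — byte-identical
  across runs. Maps being compared should be rendered with a shared
  explicit (vmin, vmax).
- The channel-space operators are sklearn estimators (`PixelEntropy`,
  `SpectralBinner`, `TopNChannels` as a SelectorMixin,
  `LowEntropyDetector` with the −1/+1 outlier convention) so they can
  sit in sklearn pipelines; dataset-level functions wrap them with
  axis/grid bookkeeping. Geometry-bound operations (spatial binning,
  lock mass, ROI resolution, I/O) are plain functions.

## Problem sizes

The replicate studies (planted recovery, region ordering) run 100
condition pairs at the generator's default scale — 60 × 80 pixels ×
2500 channels per condition — which completes in about two minutes on
one CPU; unit and property tests use grids of ≤ 30 × 40 pixels and
axes of 20–100 channels.

## Known limitations

- Only two-condition fold-change ranking is implemented; a multi-level
  control parameter would need a trend statistic the ranking step
  deliberately does not define.
- No statistical test accompanies the ranking or the entropy
  comparison between samples; extremes are descriptive.
- One-point lock mass cannot correct nonlinear calibration drift.
- Entropy values depend on the channel count *n*; maps computed at
  different binnings or top-N selections are comparable in structure
  but not in absolute bits.
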