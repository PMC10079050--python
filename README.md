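# msientropy

Pixel-wise Shannon-entropy analysis of mass spectrometry imaging (MSI)
datacubes.

MSI acquires a full mass spectrum at every spatial spot of a tissue
section, yielding a datacube (x, y, m/z). Most analyses look at one ion
image at a time; this package instead summarizes *the whole spectrum* at
each pixel by its Shannon entropy and maps that quantity over the tissue.
Entropy heat maps expose structure — e.g. compact groups of unusually
low-entropy pixels — that neither optical images nor single-ion images
show, and those regions can then be mined for the m/z channels that drive
them.

## The method

For the spectrum at pixel (x, y) with peak intensities *P*ᵢ(x, y) on a
shared m/z axis of *n* channels, define relative intensities and entropy

&nbsp;&nbsp;&nbsp;&nbsp;*p*ᵢ(x, y) = *P*ᵢ(x, y) ⁄ Σⱼ *P*ⱼ(x, y),
&nbsp;&nbsp;&nbsp;&nbsp;*H*(x, y) = − Σᵢ *p*ᵢ log₂ *p*ᵢ  (bits),

with 0 ≤ *H* ≤ log₂ *n*: 0 when one channel carries all intensity,
log₂ *n* when intensity is equidistributed. On top of this the package
provides:

- **Entropy heat maps** and histogram/box-plot summaries (`entropy_map`,
  `entropy_summary`), with sklearn-style estimators (`PixelEntropy`,
  `LowEntropyDetector`, `SpectralBinner`, `TopNChannels`) that compose
  with sklearn pipelines on the raw pixels × channels matrix.
- **Low-entropy pixel detection**: pool the valid-pixel entropies of the
  samples under comparison, set the threshold *H*₁ at the pooled 1%
  quantile, and flag *H* ≤ *H*₁ per sample (`low_entropy_threshold`).
- **Resolution-robustness operators**: average every *k* neighboring m/z
  channels (`spectral_bin`), average spectra over *k* × *k* pixel blocks
  (`spatial_bin`), keep the N channels with the largest sample-summed
  intensity (`top_n_channels`), and one-point lock-mass recalibration
  against m/z 885.5493, PI(38:4) (`lock_mass_recalibrate`).
- **ROI fold-change ranking**: sum each channel over a region of interest
  in two conditions, normalize per condition, rank channels by the change
  ratio, and annotate the extremes against a compound table by ppm mass
  error, |obs − theo|/theo × 10⁶ (`rank_candidates`, `annotate`).
- **Synthetic datacubes with ground truth** (`simulate_dataset`,
  `simulate_condition_pair`): tissue-shaped grids with regions of
  contrasting entropy and condition pairs with planted fold changes, so
  every stage is testable offline.
- **I/O**: continuous-mode imzML/ibd (via pyimzml) and a plain CSV
  datacube dialect (`col,row,<mz…>` header, one row per pixel); TSV
  compound tables; CSV map grids; deterministic PNG rendering.

## Worked example

```python
import numpy as np
from msientropy import (simulate_condition_pair, entropy_map,
                        low_entropy_threshold, resolve_roi,
                        roi_channel_sums, rank_candidates)

# two conditions on the default 60 x 80 grid, 2500 channels (m/z 550-1050);
# channel 500 planted at fold 4 and channel 1500 at fold 0.25 in B's ROI
ds_a, ds_b, truth = simulate_condition_pair(
    planted=[(500, 4.0), (1500, 0.25)], seed=1)

result = low_entropy_threshold([entropy_map(ds_a), entropy_map(ds_b)],
                               percentile=0.01)
print(f"H1 = {result.threshold:.2f} bits, "
      f"fractions = {result.fractions[0]:.2%} / {result.fractions[1]:.2%}")

pix = resolve_roi(truth.region_spec.roi, ds_a)
ranked = rank_candidates({"A": roi_channel_sums(ds_a, pix),
                          "B": roi_channel_sums(ds_b, pix)},
                         reference="A", mz_centers=ds_a.axis.centers)
print(f"top channel {ranked.top_channel} (m/z "
      f"{ds_a.axis.centers[ranked.top_channel]:.1f}), "
      f"ratio {ranked.max_ratio:.2f}")
print(f"bottom channel {ranked.bottom_channel}, ratio {ranked.min_ratio:.3f}")
```

prints

```
H1 = 0.21 bits, fractions = 1.09% / 0.92%
top channel 500 (m/z 650.1), ratio 4.08
bottom channel 1500, ratio 0.247
```

The pooled 1% threshold lands far below the tissue bulk (≈ 11.1 bits)
and inside the sparse low-entropy region's range, so the flagged pixels
are exactly the spikiest spectra of that region; both samples carry the
region, so each flags ≈ 1% of its pixels. The ROI ranking recovers the
planted channels with change ratios close to the planted folds 4 and
0.25.

The same pipeline is available from the shell:

```
msientropy simulate --seed 1 --out cube.csv
msientropy entropy cube.csv --out map.csv
msientropy render map.csv --out map.png
msientropy lowentropy cube.csv --percentile 0.01 --out low.tsv
```

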