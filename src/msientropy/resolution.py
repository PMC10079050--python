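"""Resolution-robustness operators and lock-mass recalibration.

The entropy heat map should be robust to the instrument's effective
resolution.  Three operators probe this: spectral (m/z) binning — the
average over every ``factor`` neighboring channels; spatial binning — the
average spectrum over ``factor x factor`` blocks of adjacent pixels; and
top-N channel selection — restriction to the N channels with the largest
sample-summed intensity.  A one-point multiplicative lock-mass correction
rescales the m/z axis onto a known reference ion (m/z 885.5493, PI(38:4),
in negative mode).
"""

from __future__ import annotations

import warnings

import numpy as np

from .axis import MzAxis
from .dataset import MSIDataset
from .estimators import SpectralBinner, TopNChannels

#: PI(38:4) [M-H]- reference ion used for one-point lock-mass correction.
DEFAULT_LOCK_MASS = 885.5493
#: Mass-tolerance window for locating the reference channel, in Da.
DEFAULT_LOCK_TOLERANCE = 0.2


def spectral_bin(dataset: MSIDataset, factor: int) -> MSIDataset:
    """Average every ``factor`` neighboring m/z channels.

    The new axis has ``n_channels / factor`` channels whose centers are the
    group means of the original centers; ``factor`` must divide the channel
    count exactly (remainders are an error, never silently dropped).
    Pixel validity is preserved: averaging cannot zero a positive total.
    """
    if not dataset.axis.is_uniform:
        raise ValueError("spectral binning requires a uniform m/z axis")
    binner = SpectralBinner(factor=factor).fit(dataset.intensities)
    f = int(factor)
    if f == 1:
        return dataset.replace()
    binned = binner.transform(dataset.intensities)
    centers = dataset.axis.centers.reshape(-1, f).mean(axis=1)
    return dataset.replace(axis=MzAxis.from_centers(centers), intensities=binned)


def spatial_bin(dataset: MSIDataset, factor: int) -> MSIDataset:
    """Average spectra over ``factor x factor`` blocks of adjacent pixels.

    Blocks are anchored at grid position (0, 0); each output pixel at
    block coordinates ``(col // factor, row // factor)`` carries the mean
    spectrum of the block's valid member pixels (partial edge blocks
    average over the pixels they contain).  A block with no valid member
    becomes an all-zero, invalid pixel.  Pixel pitch metadata is scaled
    by ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    f = int(factor)
    if f == 1:
        return dataset.replace()

    block_ids = dataset.coords // f
    valid = dataset.valid_mask
    blocks: dict[tuple[int, int], list[int]] = {}
    for i, (bc, br) in enumerate(block_ids):
        blocks.setdefault((int(bc), int(br)), []).append(i)

    coords = np.array(sorted(blocks), dtype=np.int64).reshape(-1, 2)
    intens = np.zeros((coords.shape[0], dataset.n_channels))
    for j, key in enumerate(map(tuple, coords)):
        members = np.array(blocks[key])
        members = members[valid[members]]
        if members.size:
            intens[j] = dataset.intensities[members].mean(axis=0)

    meta = dict(dataset.meta)
    if "pitch_um" in meta:
        meta["pitch_um"] = meta["pitch_um"] * f
    return dataset.replace(coords=coords, intensities=intens, meta=meta)


def top_n_channels(dataset: MSIDataset, n: int) -> MSIDataset:
    """Restrict the datacube to the N channels with the largest summed
    intensity over all (valid) pixels; ties favor the lower channel index.

    Downstream entropy uses ``n = N`` as the channel count, so the entropy
    bound becomes ``log2 N``.
    """
    selector = TopNChannels(n=n).fit(dataset.intensities)
    selected = selector.selected_
    return dataset.replace(
        axis=dataset.axis.subset(selected),
        intensities=dataset.intensities[:, selected],
    )


def lock_mass_recalibrate(
    dataset: MSIDataset,
    reference_mz: float = DEFAULT_LOCK_MASS,
    tolerance: float = DEFAULT_LOCK_TOLERANCE,
) -> MSIDataset:
    """One-point multiplicative mass recalibration against a reference ion.

    The channel with the largest dataset-mean intensity (over valid
    pixels) within ``reference_mz +- tolerance`` is taken to be the
    reference ion; the whole axis is multiplied by
    ``reference_mz / found_center``.  Intensities — and therefore entropy
    maps, which ignore axis labels — are unchanged.  If no channel lies in
    the window the dataset is returned unchanged with
    ``meta["lock_mass_warning"] = True`` and a warning is emitted.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    centers = dataset.axis.centers
    in_window = np.abs(centers - reference_mz) <= tolerance
    if not np.any(in_window):
        warnings.warn(
            f"no channel within {tolerance} Da of m/z {reference_mz}; "
            "lock-mass correction skipped"
        )
        out = dataset.replace()
        out.meta["lock_mass_warning"] = True
        return out

    valid = dataset.valid_mask
    pool = dataset.intensities[valid] if np.any(valid) else dataset.intensities
    mean_spectrum = pool.mean(axis=0) if pool.shape[0] else np.zeros(len(centers))
    window_idx = np.nonzero(in_window)[0]
    found = window_idx[np.argmax(mean_spectrum[window_idx])]
    scale = reference_mz / centers[found]
    out = dataset.replace(axis=dataset.axis.scaled(scale))
    out.meta["lock_mass_scale"] = float(scale)
    out.meta["lock_mass_channel"] = int(found)
    return out
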