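"""Pixel-wise Shannon entropy of MSI spectra.

At each pixel (x, y) the spectrum of peak intensities ``P_i(x, y)`` is
normalized to relative intensities

    p_i(x, y) = P_i(x, y) / sum_j P_j(x, y)

and summarized by its Shannon entropy in bits,

    H(x, y) = - sum_i p_i log2 p_i          (0 * log2 0 := 0),

bounded by ``0 <= H <= log2 n`` for ``n`` channels: 0 when a single channel
carries all intensity, ``log2 n`` when intensity is equidistributed.  All
channels, including zeros, enter the calculation.  The map of H over the
pixel grid is the entropy heat map; pixels whose entropy falls in the
smallest pooled percentile (default 1%) are flagged low-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MSIDataset

__all__ = [
    "relative_intensities",
    "shannon_entropy",
    "entropy_rows",
    "entropy_map",
    "entropy_summary",
    "low_entropy_threshold",
    "EntropyMap",
    "EntropySummary",
    "LowEntropyResult",
]

#: Allowed deviation of a probability vector's sum from 1.
_PROB_SUM_TOL = 1e-6


def relative_intensities(spectrum: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative intensity vector to a probability vector.

    Raises
    ------
    ValueError
        If any entry is negative or all entries are zero (an undefined
        pixel; callers mark such pixels invalid instead of computing H).
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if np.any(spectrum < 0):
        raise ValueError("intensities must be nonnegative")
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: relative intensities undefined")
    return spectrum / total


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in bits.

    Uses the continuity convention ``0 * log2 0 = 0``.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > _PROB_SUM_TOL:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0  # avoid -0.0


def entropy_rows(intensities: np.ndarray) -> np.ndarray:
    """Per-row Shannon entropy (bits) of an intensity matrix.

    Rows are normalized internally; all-zero rows yield NaN.  This is the
    vectorized workhorse behind :func:`entropy_map` and the
    :class:`~msientropy.estimators.PixelEntropy` transformer.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=np.float64))
    if np.any(intensities < 0):
        raise ValueError("intensities must be nonnegative")
    totals = intensities.sum(axis=1)
    out = np.full(intensities.shape[0], np.nan)
    ok = totals > 0
    if np.any(ok):
        p = intensities[ok] / totals[ok, None]
        logs = np.zeros_like(p)
        np.log2(p, out=logs, where=p > 0)  # 0 * log2 0 := 0
        out[ok] = -(p * logs).sum(axis=1)
    return out


# ----------------------------------------------------------------------
# Maps
# ----------------------------------------------------------------------

@dataclass
class EntropyMap:
    """Per-pixel Shannon entropy H(x, y) on the pixel grid.

    ``values`` is a (rows, cols) array in bits; pixels that are off the
    tissue or carried zero total intensity are NaN (undefined), never 0.
    """

    values: np.ndarray
    n_channels: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        bound = np.log2(self.n_channels) if self.n_channels > 1 else 0.0
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > bound + 1e-9):
            raise ValueError(f"entropy values outside [0, log2({self.n_channels})]")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


def entropy_map(dataset: MSIDataset) -> EntropyMap:
    """Compute the Shannon-entropy heat map of a datacube.

    H is computed for every valid pixel; invalid pixels are NaN in the
    resulting grid.
    """
    from .estimators import PixelEntropy

    h = PixelEntropy().fit_transform(dataset.intensities).ravel()
    grid = dataset.to_grid(h, fill=np.nan)
    return EntropyMap(values=grid, n_channels=dataset.n_channels,
                      sample_id=str(dataset.meta.get("sample_id", "")))


# ----------------------------------------------------------------------
# Summaries
# ----------------------------------------------------------------------

@dataclass
class EntropySummary:
    """Histogram + five-number summary of an entropy map's valid pixels."""

    bin_edges: np.ndarray
    frequencies: np.ndarray  # relative, sums to 1 over valid pixels
    mean: float
    q1: float
    q2: float
    q3: float
    fence_low: float
    fence_high: float
    outliers: np.ndarray
    n_valid: int


def entropy_summary(emap: EntropyMap, histogram_bin_width: float = 0.1) -> EntropySummary:
    """Summarize an entropy map: relative-frequency histogram, quartiles
    by linear-interpolation empirical quantiles, and Tukey-fence outliers
    (values outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``)."""
    values = emap.valid_values
    if values.size == 0:
        raise ValueError("entropy map has no valid pixels")
    if histogram_bin_width <= 0:
        raise ValueError("histogram bin width must be positive")

    lo = np.floor(values.min() / histogram_bin_width) * histogram_bin_width
    hi = np.ceil(values.max() / histogram_bin_width) * histogram_bin_width
    if hi <= lo:
        hi = lo + histogram_bin_width
    edges = np.arange(lo, hi + histogram_bin_width / 2, histogram_bin_width)
    counts, edges = np.histogram(values, bins=edges)
    freqs = counts / values.size

    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    fence_low, fence_high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < fence_low) | (values > fence_high)]
    return EntropySummary(
        bin_edges=edges, frequencies=freqs, mean=float(values.mean()),
        q1=float(q1), q2=float(q2), q3=float(q3),
        fence_low=float(fence_low), fence_high=float(fence_high),
        outliers=np.sort(outliers), n_valid=int(values.size),
    )


# ----------------------------------------------------------------------
# Low-entropy pixels
# ----------------------------------------------------------------------

@dataclass
class LowEntropyResult:
    """Pooled percentile threshold H1 with per-sample low-entropy masks.

    The threshold is the empirical ``percentile`` quantile (linear
    interpolation) of the entropies of all valid pixels pooled across the
    supplied samples; a pixel is low-entropy when ``H <= H1`` (inclusive).
    """

    threshold: float  # H1, bits
    percentile: float
    masks: list[np.ndarray] = field(default_factory=list)
    fractions: list[float] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    n_pooled: int = 0
    n_low: int = 0
    degenerate: bool = False

    def to_frame(self, maps: Sequence[EntropyMap]) -> pd.DataFrame:
        """Low-entropy pixels as a table: sample, col, row, H."""
        rows = []
        for emap, mask, sid in zip(maps, self.masks, self.sample_ids):
            rr, cc = np.nonzero(mask)
            for r, c in zip(rr, cc):
                rows.append((sid, int(c), int(r), float(emap.values[r, c])))
        return pd.DataFrame(rows, columns=["sample", "col", "row", "H"])


def low_entropy_threshold(
    maps: EntropyMap | Sequence[EntropyMap],
    percentile: float = 0.01,
) -> LowEntropyResult:
    """Pooled-percentile low-entropy detection across one or more samples.

    All valid-pixel entropies from every map are pooled; H1 is the pooled
    empirical ``percentile`` quantile; each sample's mask flags its pixels
    with ``H <= H1`` and the per-sample flagged fraction is reported.
    """
    if isinstance(maps, EntropyMap):
        maps = [maps]
    maps = list(maps)
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    pooled = np.concatenate([m.valid_values for m in maps]) if maps else np.array([])
    if pooled.size == 0:
        raise ValueError("no valid pixels in the pooled maps")

    from .estimators import LowEntropyDetector

    det = LowEntropyDetector(percentile=percentile).fit(pooled.reshape(-1, 1))
    h1 = float(det.threshold_)
    degenerate = bool(np.all(pooled == pooled[0]))

    masks, fractions, ids = [], [], []
    for i, emap in enumerate(maps):
        mask = np.isfinite(emap.values) & (emap.values <= h1)
        n_valid = int(emap.valid_mask.sum())
        masks.append(mask)
        fractions.append(float(mask.sum() / n_valid) if n_valid else 0.0)
        ids.append(emap.sample_id or f"sample{i}")
    return LowEntropyResult(
        threshold=h1, percentile=percentile, masks=masks, fractions=fractions,
        sample_ids=ids, n_pooled=int(pooled.size),
        n_low=int((pooled <= h1).sum()), degenerate=degenerate,
    )
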