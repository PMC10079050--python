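"""In-memory MSI datacube: pixels on a grid, spectra on a shared m/z axis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .axis import MzAxis


@dataclass
class MSIDataset:
    """A pixel-indexed intensity matrix on a shared m/z axis.

    Parameters
    ----------
    axis : MzAxis
        Shared channel grid.
    coords : ndarray of shape (n_pixels, 2), int
        0-based ``(col, row)`` grid coordinates; row increases downward.
    intensities : ndarray of shape (n_pixels, n_channels)
        Nonnegative peak intensities ``P_i(x, y)``.
    meta : dict
        Free-form metadata (``sample_id``, ``condition``, ``pitch_um`` ...).

    A pixel is *valid* when its total intensity across channels is strictly
    positive; all-zero (off-tissue) pixels are kept in the grid but excluded
    from entropy maps, histograms and percentile pools.
    """

    axis: MzAxis
    coords: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=np.float64))
        if self.coords.shape[0] == 0:
            self.intensities = self.intensities.reshape(0, self.axis.n_channels)
        if self.intensities.shape != (self.coords.shape[0], self.axis.n_channels):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{self.coords.shape[0]} pixels x {self.axis.n_channels} channels"
            )
        if self.coords.size and self.coords.min() < 0:
            raise ValueError("pixel coordinates must be 0-based nonnegative")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != self.coords.shape[0]:
            raise ValueError("duplicate (col, row) pixel coordinates")

    # ------------------------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_channels(self) -> int:
        return self.axis.n_channels

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean per pixel: total intensity across channels > 0."""
        return self.intensities.sum(axis=1) > 0

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid."""
        if self.n_pixels == 0:
            return (0, 0)
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter one value per pixel onto the (rows, cols) grid."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape[0] != self.n_pixels:
            raise ValueError("one value per pixel required")
        grid = np.full(self.grid_shape, fill, dtype=np.float64)
        grid[self.coords[:, 1], self.coords[:, 0]] = values
        return grid

    def pixel_index(self) -> dict[tuple[int, int], int]:
        """Map (col, row) -> row index into ``intensities``."""
        return {(int(c), int(r)): i for i, (c, r) in enumerate(self.coords)}

    def replace(self, **kwargs: Any) -> "MSIDataset":
        """Copy with some fields replaced; metadata is shallow-copied."""
        out = {
            "axis": self.axis,
            "coords": self.coords,
            "intensities": self.intensities,
            "meta": dict(self.meta),
        }
        out.update(kwargs)
        return MSIDataset(**out)
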