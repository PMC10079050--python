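"""The shared m/z axis of a continuous-mode MSI datacube.

Every pixel of a datacube shares one channel grid.  A uniform axis covers
``[start, end)`` with ``n_channels`` half-open bins of width
``w = (end - start) / n_channels``; channel ``i`` covers
``[start + i*w, start + (i+1)*w)`` and its center is the bin midpoint.
Channel subsets produced by top-N selection keep their original centers and
are flagged non-uniform; uniform-only operations (I/O, spectral binning)
reject them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Relative tolerance for uniform-spacing checks.
UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class MzAxis:
    """An ordered set of m/z channel centers, in Daltons.

    Parameters
    ----------
    centers : ndarray
        Strictly increasing channel-center m/z values.
    is_uniform : bool
        Whether the centers lie on a uniform grid (required for file I/O
        and spectral binning).
    """

    centers: np.ndarray
    is_uniform: bool = True
    _width: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=np.float64)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("axis needs a 1-D, non-empty array of centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("m/z centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)
        if self.is_uniform:
            object.__setattr__(self, "_width", _uniform_width(centers))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_range(cls, start: float, end: float, n_channels: int) -> "MzAxis":
        """Uniform axis splitting ``[start, end)`` into ``n_channels`` bins."""
        if n_channels < 1:
            raise ValueError("n_channels must be a positive integer")
        if not end > start:
            raise ValueError("end must exceed start")
        w = (end - start) / n_channels
        centers = start + (np.arange(n_channels) + 0.5) * w
        return cls(centers=centers)

    @classmethod
    def from_centers(cls, centers: np.ndarray) -> "MzAxis":
        """Uniform axis inferred from its centers; rejects uneven spacing."""
        centers = np.asarray(centers, dtype=np.float64)
        if centers.size > 1:
            _uniform_width(centers)  # raises on non-uniform spacing
        return cls(centers=centers)

    # -- properties ------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return int(self.centers.size)

    @property
    def width(self) -> float:
        """Uniform bin width in Da."""
        if not self.is_uniform:
            raise ValueError("non-uniform axis has no single bin width")
        if self.centers.size == 1:
            return self._width if self._width > 0 else 0.0
        return float(self.centers[1] - self.centers[0])

    @property
    def start(self) -> float:
        """Left edge of the first bin (uniform axes only)."""
        return float(self.centers[0] - self.width / 2.0)

    @property
    def end(self) -> float:
        """Right edge of the last bin (uniform axes only)."""
        return float(self.centers[-1] + self.width / 2.0)

    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_channels + 1`` (uniform axes only)."""
        w = self.width
        return np.concatenate([self.centers - w / 2.0, [self.centers[-1] + w / 2.0]])

    def index_of(self, mz: float) -> int:
        """0-based channel index whose half-open bin contains ``mz``."""
        w = self.width
        i = int(np.floor((mz - self.start) / w))
        if not 0 <= i < self.n_channels:
            raise ValueError(f"m/z {mz} outside axis [{self.start}, {self.end})")
        return i

    def scaled(self, factor: float) -> "MzAxis":
        """Axis with every center multiplied by ``factor`` (mass recalibration)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return MzAxis(centers=self.centers * factor, is_uniform=self.is_uniform)

    def subset(self, indices: np.ndarray) -> "MzAxis":
        """Non-uniform axis restricted to ``indices`` (kept in ascending m/z)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return MzAxis(centers=self.centers[idx], is_uniform=False)


def _uniform_width(centers: np.ndarray) -> float:
    if centers.size < 2:
        return 0.0
    diffs = np.diff(centers)
    w = float(diffs.mean())
    if not np.allclose(diffs, w, rtol=UNIFORM_RTOL, atol=w * UNIFORM_RTOL):
        raise ValueError("channel centers are not uniformly spaced")
    return w
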