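"""ROI-based fold-change ranking of m/z channels and compound annotation.

The candidate-peak identification workflow: (1) choose a region of
interest (ROI) on the entropy heat map and apply the *same* region to
every condition; (2) sum each channel's intensity over the ROI pixels and
normalize per condition; (3) rank channels by the change ratio of the
normalized sums between conditions, taking the extremes as informative
peaks; (4) annotate the extreme channels against a compound table by ppm
mass error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import MSIDataset

#: Default matching window for compound annotation, in Da.
DEFAULT_MASS_TOLERANCE = 0.2
#: Channels whose reference ROI sum is below this fraction of the
#: reference total are excluded from ranking (ratio undefined).
EPSILON_REL = 1e-12


# ----------------------------------------------------------------------
# ROI shapes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseROI:
    """Ellipse in pixel units: center (col, row), semi-axes, rotation (deg)."""

    center_col: float
    center_row: float
    semi_col: float
    semi_row: float
    rotation_deg: float = 0.0

    def contains(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        if self.semi_col <= 0 or self.semi_row <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        theta = np.deg2rad(self.rotation_deg)
        dx = np.asarray(cols, dtype=float) - self.center_col
        dy = np.asarray(rows, dtype=float) - self.center_row
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        return (u / self.semi_col) ** 2 + (v / self.semi_row) ** 2 <= 1.0


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon; membership by the pixel-center point-in-polygon test."""

    vertices: tuple[tuple[float, float], ...]  # (col, row) pairs

    def contains(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        from matplotlib.path import Path

        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        path = Path(np.asarray(self.vertices, dtype=float))
        pts = np.column_stack([np.asarray(cols, float), np.asarray(rows, float)])
        # tiny positive radius makes boundary pixels members deterministically
        return path.contains_points(pts, radius=1e-9)


@dataclass(frozen=True)
class MaskROI:
    """Explicit boolean mask aligned to the pixel grid (rows, cols)."""

    mask: np.ndarray

    def contains(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        mask = np.asarray(self.mask, dtype=bool)
        cols = np.asarray(cols, dtype=int)
        rows = np.asarray(rows, dtype=int)
        inside = (rows < mask.shape[0]) & (cols < mask.shape[1])
        out = np.zeros(cols.shape, dtype=bool)
        out[inside] = mask[rows[inside], cols[inside]]
        return out


ROI = EllipseROI | PolygonROI | MaskROI


def parse_roi_file(path: str) -> ROI:
    """Read an ROI spec: ``key=value`` text (ellipse/polygon) or a 0/1
    mask CSV aligned to the grid (``shape=mask`` + ``path=<csv>``)."""
    import os

    spec: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            spec[key.strip()] = value.strip()
    shape = spec.get("shape", "")
    if shape == "ellipse":
        return EllipseROI(
            center_col=float(spec["center_col"]),
            center_row=float(spec["center_row"]),
            semi_col=float(spec["semi_col"]),
            semi_row=float(spec["semi_row"]),
            rotation_deg=float(spec.get("rotation", 0.0)),
        )
    if shape == "polygon":
        verts = tuple(
            tuple(float(t) for t in v.split(":"))
            for v in spec["vertices"].split(";") if v
        )
        return PolygonROI(vertices=verts)  # type: ignore[arg-type]
    if shape == "mask":
        mask_path = spec["path"]
        if not os.path.isabs(mask_path):
            mask_path = os.path.join(os.path.dirname(os.path.abspath(path)), mask_path)
        grid = np.loadtxt(mask_path, delimiter=",", ndmin=2)
        return MaskROI(mask=grid > 0)
    raise ValueError(f"unknown ROI shape {shape!r}")


def resolve_roi(roi: ROI, dataset: MSIDataset) -> np.ndarray:
    """Indices of the dataset's pixels whose centers fall inside the ROI.

    Membership is deterministic (pixel-center test); the same ROI applied
    to datasets on the same grid selects the same coordinates.
    """
    member = roi.contains(dataset.coords[:, 0], dataset.coords[:, 1])
    idx = np.nonzero(member)[0]
    if idx.size == 0:
        raise ValueError("ROI does not intersect any dataset pixel")
    return idx


# ----------------------------------------------------------------------
# Sums, ranking, annotation
# ----------------------------------------------------------------------

def roi_channel_sums(dataset: MSIDataset, pixels: np.ndarray) -> np.ndarray:
    """Per-channel sum of intensities over the given ROI pixel indices."""
    pixels = np.asarray(pixels, dtype=int)
    if pixels.size == 0:
        raise ValueError("empty ROI pixel set")
    if pixels.min() < 0 or pixels.max() >= dataset.n_pixels:
        raise ValueError("ROI pixel index outside the dataset")
    return dataset.intensities[pixels].sum(axis=0)


@dataclass
class CandidateTable:
    """Ranked fold-change table for one ROI across two conditions.

    ``table`` has one row per channel: m/z center, raw and normalized ROI
    sums per condition, change ratio ``r`` (test condition over
    reference), and dense rank by descending ratio (rank 1 = largest r;
    ties favor the lower channel index).  Channels whose reference sum is
    below the epsilon guard are flagged undefined and never ranked.
    """

    table: pd.DataFrame
    reference: str
    test: str
    top_channel: int
    bottom_channel: int

    @property
    def max_ratio(self) -> float:
        return float(self.table.loc[self.table.channel == self.top_channel, "ratio"].iloc[0])

    @property
    def min_ratio(self) -> float:
        return float(self.table.loc[self.table.channel == self.bottom_channel, "ratio"].iloc[0])


def rank_candidates(
    sums_by_condition: Mapping[str, np.ndarray],
    reference: str,
    mz_centers: np.ndarray | None = None,
    normalize: str = "condition_total",
    epsilon_rel: float = EPSILON_REL,
) -> CandidateTable:
    """Rank channels by the change ratio of normalized ROI sums.

    Parameters
    ----------
    sums_by_condition : mapping of condition label -> per-channel ROI sums
        Exactly two conditions on a shared axis.
    reference : str
        The condition the ratio is taken against (denominator).
    normalize : {"condition_total", "reference_total"}
        Divide each condition's sums by its own ROI total (default,
        scale-invariant) or divide both by the reference condition's
        total.  The two choices differ by one global constant per
        condition, so the resulting rank order is identical.
    """
    if reference not in sums_by_condition:
        raise ValueError(f"reference condition {reference!r} not present")
    if len(sums_by_condition) != 2:
        raise ValueError("exactly two conditions are required")
    (test,) = [c for c in sums_by_condition if c != reference]

    s_ref = np.asarray(sums_by_condition[reference], dtype=np.float64)
    s_test = np.asarray(sums_by_condition[test], dtype=np.float64)
    if s_ref.shape != s_test.shape or s_ref.ndim != 1:
        raise ValueError("conditions must share one channel axis")
    t_ref, t_test = s_ref.sum(), s_test.sum()
    if t_ref <= 0:
        raise ValueError("all-zero reference condition")
    if normalize == "condition_total":
        norm_ref = s_ref / t_ref
        norm_test = s_test / (t_test if t_test > 0 else 1.0)
    elif normalize == "reference_total":
        norm_ref = s_ref / t_ref
        norm_test = s_test / t_ref
    else:
        raise ValueError(f"unknown normalization {normalize!r}")

    defined = s_ref >= epsilon_rel * t_ref
    ratio = np.full(s_ref.shape, np.nan)
    ratio[defined] = norm_test[defined] / norm_ref[defined]

    n = s_ref.size
    channels = np.arange(n)
    rank = np.full(n, np.nan)
    if np.any(defined):
        dchan = channels[defined]
        # sort by descending ratio, ties by lower channel index
        order = dchan[np.lexsort((dchan, -ratio[defined]))]
        rank[order] = np.arange(1, order.size + 1)
    else:
        raise ValueError("no channel has a usable reference sum")

    table = pd.DataFrame({
        "channel": channels,
        "mz": (np.asarray(mz_centers, dtype=float) if mz_centers is not None
               else np.full(n, np.nan)),
        f"sum_{reference}": s_ref,
        f"sum_{test}": s_test,
        f"norm_{reference}": norm_ref,
        f"norm_{test}": norm_test,
        "ratio": ratio,
        "rank": rank,
        "defined": defined,
    })
    top = int(table.loc[table["rank"] == 1, "channel"].iloc[0])
    bottom = int(table.loc[table["rank"] == rank[defined].max(), "channel"].iloc[0])
    return CandidateTable(table=table, reference=reference, test=test,
                          top_channel=top, bottom_channel=bottom)


def annotate(
    observed_mz: float,
    compounds: pd.DataFrame,
    tolerance: float = DEFAULT_MASS_TOLERANCE,
) -> pd.DataFrame:
    """Match an observed m/z against a compound table.

    Returns all compounds with ``|observed - theoretical| <= tolerance``,
    sorted by absolute ppm mass error
    ``|obs - theo| / theo * 1e6`` ascending.  ``ppm_error`` is the exact
    value; reports round it to 2 decimals.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(compounds) == 0:
        raise ValueError("empty compound table")
    theo = compounds["mz"].to_numpy(dtype=float)
    delta = np.abs(observed_mz - theo)
    hits = compounds.loc[delta <= tolerance].copy()
    hits["observed_mz"] = observed_mz
    hits = hits.rename(columns={"mz": "theoretical_mz"})
    hits["ppm_error"] = (np.abs(hits["observed_mz"] - hits["theoretical_mz"])
                         / hits["theoretical_mz"] * 1e6)
    return hits.sort_values("ppm_error", kind="stable").reset_index(drop=True)


def ion_image(dataset: MSIDataset, target_mz: float, window: float) -> np.ndarray:
    """Per-pixel summed intensity over channels within ``target_mz +- window``.

    Returns a (rows, cols) grid; grid positions without a pixel are NaN.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    centers = dataset.axis.centers
    sel = np.abs(centers - target_mz) <= window
    if not np.any(sel):
        raise ValueError(
            f"no channel within {window} Da of m/z {target_mz}")
    values = dataset.intensities[:, sel].sum(axis=1)
    return dataset.to_grid(values, fill=np.nan)
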