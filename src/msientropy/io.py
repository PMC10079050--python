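"""Reading and writing MSI datacubes and derived tables.

Two datacube formats are supported:

* **imzML** (continuous/profile mode, via :mod:`pyimzml`) — the open XML +
  binary MSI standard.  Processed mode (per-pixel m/z axes) is rejected
  because the entropy method indexes peaks identically across pixels.
* **CSV datacube** — a plain-text dialect with header
  ``col,row,<mz1>,<mz2>,...`` and one data row per pixel.  The header m/z
  values must form a uniform grid.

Plus a TSV compound-annotation table (``name``, ``formula``, ``adduct``,
``mz``) and CSV/TSV writers for entropy maps and low-entropy pixel lists.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .axis import MzAxis
from .dataset import MSIDataset

if TYPE_CHECKING:  # pragma: no cover
    from .entropy import EntropyMap


class UnsupportedDialectError(ValueError):
    """Raised for imzML files this package deliberately does not read."""


# ----------------------------------------------------------------------
# imzML
# ----------------------------------------------------------------------

def read_imzml(path: str | os.PathLike) -> MSIDataset:
    """Read a continuous-mode imzML/ibd pair into an :class:`MSIDataset`.

    imzML coordinates are 1-based; they are shifted to the package's
    0-based ``(col, row)`` convention on read.

    Raises
    ------
    FileNotFoundError
        If the ``.ibd`` binary companion is missing.
    UnsupportedDialectError
        For processed-mode files (per-pixel m/z axes).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"missing imzML binary companion: {ibd}")

    parser = ImzMLParser(path)
    mode_params = parser.metadata.file_description.param_by_name
    if "processed" in mode_params and "continuous" not in mode_params:
        raise UnsupportedDialectError(
            "processed-mode imzML (per-pixel m/z axes) is not supported; "
            "the entropy method requires one shared channel grid"
        )

    n = len(parser.coordinates)
    if n == 0:
        raise ValueError("imzML file contains no spectra")
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=np.float64)
    if not np.all(np.diff(mz0) > 0):
        raise ValueError("non-monotonic m/z axis")
    axis = MzAxis.from_centers(mz0)

    coords = np.empty((n, 2), dtype=np.int64)
    intens = np.empty((n, axis.n_channels), dtype=np.float64)
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        if len(mz) != axis.n_channels:
            raise UnsupportedDialectError(
                "spectra with differing channel counts; shared-axis imzML required"
            )
        coords[i] = (x - 1, y - 1)  # imzML is 1-based
        intens[i] = inten
    return MSIDataset(axis=axis, coords=coords, intensities=intens,
                      meta={"source": path})


def write_imzml(dataset: MSIDataset, path: str | os.PathLike) -> None:
    """Write a dataset as continuous-mode profile imzML (plus ``.ibd``)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not dataset.axis.is_uniform:
        raise ValueError("imzML export requires a uniform m/z axis")
    with ImzMLWriter(os.fspath(path), mode="continuous", spec_type="profile",
                     intensity_dtype=np.float64) as writer:
        for (col, row), spectrum in zip(dataset.coords, dataset.intensities):
            writer.addSpectrum(dataset.axis.centers, spectrum,
                               (int(col) + 1, int(row) + 1, 1))


# ----------------------------------------------------------------------
# CSV datacube dialect
# ----------------------------------------------------------------------

def read_csv_cube(path: str | os.PathLike) -> MSIDataset:
    """Read the CSV datacube dialect (header ``col,row,<mz...>``)."""
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["col", "row"]:
        raise ValueError("CSV cube header must start with 'col,row'")
    try:
        centers = np.array([float(c) for c in frame.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric m/z column header: {exc}") from exc
    if centers.size == 0:
        raise ValueError("CSV cube has no m/z columns")
    axis = MzAxis.from_centers(centers)  # enforces uniform spacing
    coords = frame[["col", "row"]].to_numpy(dtype=np.int64)
    intens = frame.iloc[:, 2:].to_numpy(dtype=np.float64)
    if intens.size and intens.min() < 0:
        raise ValueError("negative intensity in CSV cube")
    return MSIDataset(axis=axis, coords=coords, intensities=intens,
                      meta={"source": os.fspath(path)})


def write_csv_cube(dataset: MSIDataset, path: str | os.PathLike) -> None:
    """Write a dataset in the CSV datacube dialect (lossless round trip)."""
    # float.__repr__ is the shortest round-trippable decimal form
    header = ["col", "row"] + [repr(float(c)) for c in dataset.axis.centers]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for (col, row), spectrum in zip(dataset.coords, dataset.intensities):
            fh.write(f"{col},{row},"
                     + ",".join(repr(float(v)) for v in spectrum) + "\n")


# ----------------------------------------------------------------------
# Compound table, maps, pixel lists
# ----------------------------------------------------------------------

def read_compound_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV of candidate compounds: name, formula, adduct, mz."""
    table = pd.read_csv(path, sep="\t")
    required = {"name", "formula", "adduct", "mz"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    if (table["mz"] <= 0).any():
        raise ValueError("theoretical m/z must be positive")
    if table.duplicated(subset=["name", "adduct"]).any():
        raise ValueError("duplicate (name, adduct) in compound table")
    return table


def write_map_csv(entropy_map: "EntropyMap", path: str | os.PathLike) -> None:
    """Persist a per-pixel map as a CSV grid; undefined pixels as empty cells."""
    grid = entropy_map.values
    with open(path, "w") as fh:
        for row in grid:
            fh.write(",".join("" if np.isnan(v) else repr(float(v))
                              for v in row) + "\n")


def read_map_csv(path: str | os.PathLike) -> np.ndarray:
    """Read a CSV grid written by :func:`write_map_csv` (NaN for empty cells)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            rows.append([np.nan if cell == "" else float(cell)
                         for cell in line.split(",")])
    return np.asarray(rows, dtype=np.float64)


def write_low_entropy_tsv(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write low-entropy pixels as TSV with columns sample, col, row, H."""
    records.to_csv(path, sep="\t", index=False)
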