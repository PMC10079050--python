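"""Synthetic MSI datacubes with known ground truth.

Emulates the structure of a tissue-section acquisition: an elliptical
tissue area on a rectangular raster with zero-intensity (off-tissue)
background, an embedded low-entropy region whose spectra concentrate on a
few dominant channels, an embedded high-entropy region with near-uniform
spectra, and — for condition pairs — an ROI region in which designated
channels are planted with known fold factors between conditions.

Each pixel's spectrum is a log-normal total intensity times a
channel-probability vector drawn from a symmetric Dirichlet: entropy is
directly tunable by the Dirichlet concentration (large concentration ->
near-uniform spectra -> entropy near log2 n; a small concentration on a
few support channels -> spiky spectra -> entropy near 0).  Channel counts
are perturbed by mean-one multiplicative gamma noise.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import MzAxis
from .dataset import MSIDataset
from .roi import EllipseROI

__all__ = [
    "RegionSpec", "SyntheticTruth", "default_region_spec",
    "default_axis", "simulate_dataset", "simulate_condition_pair",
    "write_truth_tsv",
]

#: Region labels on the truth grid.
BACKGROUND, TISSUE, LOW_ENTROPY, HIGH_ENTROPY = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", TISSUE: "tissue",
               LOW_ENTROPY: "low_entropy", HIGH_ENTROPY: "high_entropy"}


def default_axis() -> MzAxis:
    """m/z 550-1050 split into 2500 channels (0.2 Da bins)."""
    return MzAxis.from_range(550.0, 1050.0, 2500)


@dataclass(frozen=True)
class RegionSpec:
    """Geometry and concentration parameters of the simulated tissue.

    Dirichlet concentrations set the expected spectral entropy of each
    region: ``tissue_concentration`` (moderate, default 5.0) for the bulk,
    ``high_concentration`` (default 50.0) for the near-uniform high-entropy
    region, and ``low_concentration`` (default 0.05) spread over
    ``low_support`` dominant channels (default 10) for the sparse
    low-entropy region.  Totals are log-normal with median ``total_mean``
    counts and log-sigma ``total_sigma``; each channel count is perturbed
    by mean-one multiplicative gamma noise with coefficient of variation
    ``noise_sigma``.
    """

    tissue: EllipseROI
    low_entropy: EllipseROI | None = None
    high_entropy: EllipseROI | None = None
    roi: EllipseROI | None = None
    tissue_concentration: float = 5.0
    high_concentration: float = 50.0
    low_concentration: float = 0.05
    low_support: int = 10
    total_mean: float = 1.0e4
    total_sigma: float = 0.3
    noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        for name in ("tissue_concentration", "high_concentration",
                     "low_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.low_support < 1:
            raise ValueError("low_support must be >= 1")


def default_region_spec(width: int = 60, height: int = 80) -> RegionSpec:
    """Kidney-like layout on a ``width x height`` grid (default 60 x 80)."""
    w, h = float(width), float(height)
    return RegionSpec(
        tissue=EllipseROI(0.50 * w, 0.50 * h, 0.45 * w, 0.45 * h),
        low_entropy=EllipseROI(0.32 * w, 0.30 * h, 0.10 * w, 0.10 * h),
        high_entropy=EllipseROI(0.68 * w, 0.30 * h, 0.10 * w, 0.10 * h),
        roi=EllipseROI(0.50 * w, 0.68 * h, 0.14 * w, 0.12 * h),
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated datacube."""

    labels: np.ndarray  # (rows, cols) region codes
    planted: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0
    region_spec: RegionSpec | None = None
    #: region names ordered by expected mean entropy, ascending
    expected_entropy_order: tuple[str, ...] = (
        "low_entropy", "tissue", "high_entropy")
    low_support_channels: np.ndarray | None = None

    def region_pixel_indices(self, coords: np.ndarray, label: int) -> np.ndarray:
        """Dataset row indices of pixels carrying a given region code."""
        return np.nonzero(self.labels[coords[:, 1], coords[:, 0]] == label)[0]


def _label_grid(width: int, height: int, spec: RegionSpec) -> np.ndarray:
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    cc, rr = cols.ravel(), rows.ravel()
    labels = np.full(cc.shape, BACKGROUND, dtype=np.int8)
    labels[spec.tissue.contains(cc, rr)] = TISSUE
    for roi, code in ((spec.low_entropy, LOW_ENTROPY),
                      (spec.high_entropy, HIGH_ENTROPY)):
        if roi is not None:
            member = roi.contains(cc, rr)
            if not member.any():
                raise ValueError("degenerate region geometry: empty region")
            if (labels[member] == BACKGROUND).any():
                raise ValueError("entropy regions must lie inside the tissue")
            labels[member] = code
    if (spec.low_entropy is not None and spec.high_entropy is not None
            and (spec.low_entropy.contains(cc, rr)
                 & spec.high_entropy.contains(cc, rr)).any()):
        raise ValueError("low- and high-entropy regions overlap")
    return labels.reshape(height, width)


def _draw_pixels(rng: np.random.Generator, k: int, alpha: np.ndarray,
                 spec: RegionSpec) -> np.ndarray:
    """k spectra: lognormal total x Dirichlet(alpha) x multiplicative noise.

    The per-channel noise is a mean-one gamma variate with coefficient of
    variation ``noise_sigma`` (shape 1/sigma^2, scale sigma^2).
    """
    n = alpha.shape[-1]
    gam = rng.standard_gamma(alpha, size=(k, n))
    sums = gam.sum(axis=1, keepdims=True)
    dead = sums[:, 0] <= 0  # pathological underflow guard
    if dead.any():
        gam[dead, int(np.argmax(alpha))] = 1.0
        sums = gam.sum(axis=1, keepdims=True)
    gam /= sums  # Dirichlet probabilities, in place
    totals = spec.total_mean * np.exp(rng.normal(0.0, spec.total_sigma, size=(k, 1)))
    if spec.noise_sigma > 0:
        shape = 1.0 / spec.noise_sigma ** 2
        noise = rng.standard_gamma(shape, size=(k, n))
        noise /= shape
        gam *= noise
    gam *= totals
    return gam


def _simulate(rng: np.random.Generator, width: int, height: int, axis: MzAxis,
              spec: RegionSpec, labels: np.ndarray,
              support: np.ndarray,
              planted: list[tuple[int, float]] | None,
              meta: dict) -> MSIDataset:
    n = axis.n_channels
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    coords = np.column_stack([cols.ravel(), rows.ravel()])
    flat_labels = labels[coords[:, 1], coords[:, 0]]
    intens = np.zeros((coords.shape[0], n))

    in_roi = np.zeros(coords.shape[0], dtype=bool)
    if planted and spec.roi is not None:
        in_roi = spec.roi.contains(coords[:, 0], coords[:, 1])

    base_alpha = {
        TISSUE: np.full(n, spec.tissue_concentration),
        HIGH_ENTROPY: np.full(n, spec.high_concentration),
    }
    low_alpha = np.zeros(n)
    low_alpha[support] = spec.low_concentration
    base_alpha[LOW_ENTROPY] = low_alpha

    # fixed group order keeps the random stream reproducible
    for code in (TISSUE, LOW_ENTROPY, HIGH_ENTROPY):
        for roi_flag in (False, True):
            sel = (flat_labels == code) & (in_roi == roi_flag)
            k = int(sel.sum())
            if k == 0:
                continue
            alpha = base_alpha[code]
            if roi_flag and planted:
                alpha = alpha.copy()
                for channel, fold in planted:
                    alpha[channel] *= fold
            if code == LOW_ENTROPY:
                # draw only on the support; zeros elsewhere stay exact
                sub = _draw_pixels(rng, k, alpha[support], spec)
                block = np.zeros((k, n))
                block[:, support] = sub
                intens[sel] = block
            else:
                intens[sel] = _draw_pixels(rng, k, alpha, spec)

    return MSIDataset(axis=axis, coords=coords, intensities=intens,
                      meta={"pitch_um": 50.0, **meta})


def simulate_dataset(
    width: int = 60,
    height: int = 80,
    axis: MzAxis | None = None,
    region_spec: RegionSpec | None = None,
    seed: int = 0,
) -> tuple[MSIDataset, SyntheticTruth]:
    """Simulate one datacube with contrasting-entropy regions.

    Returns the dataset (background pixels all-zero, hence invalid) and
    the ground truth (region label per pixel, seed, expected entropy
    ordering of the regions).
    """
    axis = axis or default_axis()
    spec = region_spec or default_region_spec(width, height)
    rng = np.random.default_rng(seed)
    labels = _label_grid(width, height, spec)
    support = np.sort(rng.choice(axis.n_channels,
                                 size=min(spec.low_support, axis.n_channels),
                                 replace=False))
    ds = _simulate(rng, width, height, axis, spec, labels, support, None,
                   meta={"sample_id": f"sim-{seed}", "seed": seed})
    truth = SyntheticTruth(labels=labels, seed=seed, region_spec=spec,
                           low_support_channels=support)
    return ds, truth


def simulate_condition_pair(
    base_spec: RegionSpec | None = None,
    planted: list[tuple[int, float]] | None = None,
    seed: int = 0,
    width: int = 60,
    height: int = 80,
    axis: MzAxis | None = None,
) -> tuple[MSIDataset, MSIDataset, SyntheticTruth]:
    """Simulate two conditions differing only at planted channels.

    Condition B's Dirichlet concentration at each planted channel is
    multiplied by its fold factor for pixels inside the spec's ROI region
    (expected relative intensity scales by the fold, renormalization
    included); everything else is shared between A and B up to sampling
    noise.
    """
    axis = axis or default_axis()
    spec = base_spec or default_region_spec(width, height)
    planted = list(planted or [])
    for channel, fold in planted:
        if not 0 <= channel < axis.n_channels:
            raise ValueError(f"planted channel {channel} not on the axis")
        if fold <= 0:
            raise ValueError("fold factors must be positive")
    if planted and spec.roi is None:
        raise ValueError("planting requires a ROI region in the spec")

    ss = np.random.SeedSequence(seed)
    rng_support, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))
    labels = _label_grid(width, height, spec)
    support = np.sort(rng_support.choice(
        axis.n_channels, size=min(spec.low_support, axis.n_channels),
        replace=False))

    ds_a = _simulate(rng_a, width, height, axis, spec, labels, support, [],
                     meta={"sample_id": f"simA-{seed}", "condition": "A",
                           "seed": seed})
    ds_b = _simulate(rng_b, width, height, axis, spec, labels, support, planted,
                     meta={"sample_id": f"simB-{seed}", "condition": "B",
                           "seed": seed})
    truth = SyntheticTruth(labels=labels, planted=planted, seed=seed,
                           region_spec=spec, low_support_channels=support)
    return ds_a, ds_b, truth


def write_truth_tsv(truth: SyntheticTruth, path: str) -> None:
    """Persist ground truth: planted channels as header comments, then a
    TSV of per-pixel region labels."""
    with open(path, "w") as fh:
        for channel, fold in truth.planted:
            fh.write(f"# planted\t{channel}\t{fold}\n")
        fh.write(f"# seed\t{truth.seed}\n")
        fh.write("col\trow\tlabel\n")
        h, w = truth.labels.shape
        for r in range(h):
            for c in range(w):
                fh.write(f"{c}\t{r}\t{LABEL_NAMES[int(truth.labels[r, c])]}\n")
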