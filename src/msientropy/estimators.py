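"""Scikit-learn-compatible estimators over pixels-by-channels matrices.

These operate on the raw ``(n_pixels, n_channels)`` intensity matrix of a
datacube (the natural feature matrix of MSI data) and compose with sklearn
pipelines and model selection.  The dataset-level functions in
:mod:`msientropy.entropy` and :mod:`msientropy.resolution` are thin
wrappers that add grid/axis bookkeeping.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted


class PixelEntropy(TransformerMixin, BaseEstimator):
    """Transform spectra into per-pixel Shannon entropy (bits).

    Each row is normalized to relative intensities and reduced to its
    Shannon entropy ``H = -sum p_i log2 p_i``; output shape is
    ``(n_pixels, 1)``.

    Parameters
    ----------
    on_empty : {"nan", "raise"}
        What to do with all-zero rows (invalid pixels): emit NaN
        (default) or raise.
    """

    def __init__(self, on_empty: str = "nan"):
        self.on_empty = on_empty

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        if np.any(X < 0):
            raise ValueError("intensities must be nonnegative")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from .entropy import entropy_rows

        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count changed between fit and transform")
        h = entropy_rows(X)
        if self.on_empty == "raise" and np.any(np.isnan(h)):
            raise ValueError("all-zero spectrum encountered")
        return h.reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["shannon_entropy_bits"], dtype=object)


class SpectralBinner(TransformerMixin, BaseEstimator):
    """Average every ``factor`` consecutive m/z channels (coarse-graining).

    Groups are consecutive and left-anchored; ``factor`` must divide the
    channel count exactly.  Averaging rescales each pixel's total by
    ``1/factor``, which leaves entropies unchanged relative to summing;
    merging channels can only decrease a pixel's entropy.
    """

    def __init__(self, factor: int = 1):
        self.factor = factor

    def fit(self, X, y=None):
        X = check_array(X)
        if int(self.factor) != self.factor or self.factor < 1:
            raise ValueError("factor must be a positive integer")
        if X.shape[1] % self.factor:
            raise ValueError(
                f"factor {self.factor} does not divide {X.shape[1]} channels")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count changed between fit and transform")
        f = int(self.factor)
        return X.reshape(X.shape[0], X.shape[1] // f, f).mean(axis=2)


class TopNChannels(SelectorMixin, BaseEstimator):
    """Keep the N channels with the largest total intensity over all pixels.

    Per-channel sums are taken over the fitted matrix (all-zero, i.e.
    invalid, pixels contribute nothing); ties are broken in favor of the
    lower channel index.  Selected channels keep their original order.
    """

    def __init__(self, n: int = 100):
        self.n = n

    def fit(self, X, y=None):
        X = check_array(X)
        if int(self.n) != self.n or not 1 <= self.n <= X.shape[1]:
            raise ValueError(f"n must be an integer in [1, {X.shape[1]}]")
        self.n_features_in_ = X.shape[1]
        self.channel_sums_ = X.sum(axis=0)
        # stable argsort on -sums keeps the lower index first among ties
        order = np.argsort(-self.channel_sums_, kind="stable")
        self.selected_ = np.sort(order[: int(self.n)])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


class LowEntropyDetector(OutlierMixin, BaseEstimator):
    """Flag pixels whose entropy lies in the smallest pooled percentile.

    Fit on a column of per-pixel entropies (the output of
    :class:`PixelEntropy`, possibly pooled over several samples); the
    fitted ``threshold_`` (H1) is the empirical ``percentile`` quantile
    with linear interpolation.  ``predict`` returns -1 for low-entropy
    pixels (``H <= threshold_``, inclusive) and +1 otherwise; NaN
    entropies (invalid pixels) are never flagged.
    """

    def __init__(self, percentile: float = 0.01):
        self.percentile = percentile

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must lie in (0, 1)")
        vals = X.ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no finite entropy values to pool")
        self.n_features_in_ = X.shape[1]
        self.threshold_ = float(np.quantile(vals, self.percentile, method="linear"))
        self.n_pooled_ = int(vals.size)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite="allow-nan")
        vals = X.ravel()
        low = np.isfinite(vals) & (vals <= self.threshold_)
        return np.where(low, -1, 1)

    def score_samples(self, X):
        """Entropy margin above the threshold (negative = low-entropy)."""
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite="allow-nan")
        return X.ravel() - self.threshold_
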