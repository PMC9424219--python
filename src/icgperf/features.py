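"""Green-band histogram-area features for perfusion assessment.

The tracked ROI is divided into 20 equal vertical slices.  For slice
``i`` the 256-level histogram of the green channel is computed and its
thresholded area

    A_i = sum_{l=k}^{255} count_i(l) * [b(l+1) - b(l)]

is one feature, where ``count_i(l)`` is the number of slice pixels with
green intensity exactly ``l``, ``b`` are the histogram bin edges and
``k`` excludes pixels with low green (default k=25, which in the
original clinical evaluation gave the best classification performance).
With the default unit bins ``b(l) = l`` the area is exactly the number
of slice pixels with green >= k.  The 20 areas, ordered left to right,
form the feature vector handed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "HistogramSpec",
    "split_roi",
    "green_histogram",
    "histogram_area",
    "extract_features",
    "GreenHistogramFeatures",
    "N_SLICES",
    "N_LEVELS",
]

N_SLICES = 20
N_LEVELS = 256

GREEN = 1  # index of the green channel in a logical-RGB patch


def _unit_edges() -> np.ndarray:
    return np.arange(N_LEVELS + 1, dtype=float)


@dataclass(frozen=True)
class HistogramSpec:
    """Threshold and binning of the green-band histogram area.

    ``k`` is the minimum included intensity level; ``bin_edges`` are the
    257 monotone values b(0)..b(256), defaulting to unit bins b(l)=l so
    that every bin has width 1 and the area is a pixel count.
    """

    k: int = 25
    bin_edges: np.ndarray = field(default_factory=_unit_edges)

    def __post_init__(self):
        if not 0 <= self.k <= 255:
            raise ValueError(f"k={self.k} outside [0, 255]")
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.shape != (N_LEVELS + 1,):
            raise ValueError(
                f"bin_edges must have {N_LEVELS + 1} values, got {edges.shape}"
            )
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)


def split_roi(patch: np.ndarray, n_slices: int = N_SLICES) -> list:
    """Split a patch into ``n_slices`` vertical slices, left to right.

    Slice ``i`` (0-based) covers columns floor(i*W/n) .. floor((i+1)*W/n)-1,
    full height: the slices are disjoint, cover every column, and their
    widths differ by at most one pixel.
    """
    patch = np.asarray(patch)
    w = patch.shape[1]
    if w < n_slices:
        raise ValueError(f"patch width {w} < number of slices {n_slices}")
    bounds = [(i * w) // n_slices for i in range(n_slices + 1)]
    return [patch[:, bounds[i] : bounds[i + 1]] for i in range(n_slices)]


def green_histogram(slice_: np.ndarray) -> np.ndarray:
    """Occurrence count of each 8-bit green level within one slice."""
    slice_ = np.asarray(slice_)
    green = slice_[..., GREEN] if slice_.ndim == 3 else slice_
    if green.dtype != np.uint8:
        if np.any((green < 0) | (green > 255)):
            raise ValueError("green values outside 8-bit range")
        green = green.astype(np.uint8)
    return np.bincount(green.ravel(), minlength=N_LEVELS)


def histogram_area(counts: np.ndarray, spec: HistogramSpec = HistogramSpec()) -> float:
    """Thresholded histogram area: sum over l >= k of count(l) * bin width."""
    counts = np.asarray(counts)
    widths = np.diff(spec.bin_edges)
    return float(np.dot(counts[spec.k :], widths[spec.k :]))


def extract_features(
    patch: np.ndarray,
    spec: HistogramSpec = HistogramSpec(),
    n_slices: int = N_SLICES,
    normalize: bool = False,
) -> np.ndarray:
    """The slice-wise green histogram-area feature vector of one patch.

    Composition split -> histogram -> area per slice, in slice order.
    With ``normalize`` each area is divided by its slice's pixel count
    (off by default; the raw areas otherwise scale with ROI size).
    """
    slices = split_roi(patch, n_slices)
    out = np.empty(n_slices, dtype=float)
    for i, s in enumerate(slices):
        a = histogram_area(green_histogram(s), spec)
        if normalize:
            a /= s.shape[0] * s.shape[1]
        out[i] = a
    return out


class GreenHistogramFeatures(BaseEstimator, TransformerMixin):
    """Sklearn transformer mapping RGB ROI patches to feature matrices.

    Parameters
    ----------
    k : int
        Minimum green level included in each slice's histogram area.
    n_slices : int
        Number of equal vertical slices (the feature dimensionality).
    normalize : bool
        Divide each area by the slice pixel count.

    The transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(self, k: int = 25, n_slices: int = N_SLICES, normalize: bool = False):
        self.k = k
        self.n_slices = n_slices
        self.normalize = normalize

    def fit(self, X: Sequence[np.ndarray], y=None):
        HistogramSpec(k=self.k)
        self.n_features_out_ = self.n_slices
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        spec = HistogramSpec(k=self.k)
        return np.vstack(
            [extract_features(p, spec, self.n_slices, self.normalize) for p in X]
        )
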