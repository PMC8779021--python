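"""Dark-normalized brightness histograms and the per-image viability feature.

Confocal frames of stained sludge are mostly black: bacteria cluster, so the
bright spots are sparse on a dark background.  The 256-level occurrence
histogram of the V channel is therefore dominated by the zero-brightness bin.
Dividing every level's count by that zero count makes frames with different
bacterial densities comparable — tiling an image with itself doubles both the
counts and the dark-pixel count and leaves every normalized entry unchanged.

The scalar feature of a frame is, by default, the maximum bin content after
rebinning the 255 nonzero brightness levels into 127 near-equal bins
(``MAX_BINNED``); the plain sum over all nonzero levels (``SUM_ALL``) is the
robustness variant.  V = 0 is excluded from both: it is the normalizer, not
signal — its normalized value is identically 1 and would otherwise dominate
every binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from viaquant.colorspace import HSVImage
from viaquant.errors import NormalizationError
from viaquant.images import Marker

DEFAULT_N_BINS = 127


class FeatureMethod(Enum):
    MAX_BINNED = "max_binned"
    SUM_ALL = "sum_all"

    @classmethod
    def parse(cls, text: "str | FeatureMethod") -> "FeatureMethod":
        if isinstance(text, cls):
            return text
        try:
            return cls(str(text).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown feature method {text!r}; expected 'max_binned' or 'sum_all'"
            ) from None


@dataclass(frozen=True)
class BrightnessHistogram:
    """256-level V-channel counts of one frame plus their dark-normalized form."""

    counts: np.ndarray      # 256 non-negative ints, counts[v] = #pixels with V == v
    normalized: np.ndarray  # counts / counts[0]
    sample_id: str = ""
    time_h: float = 0.0
    marker: Marker | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError(f"counts must have 256 levels, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "normalized", np.asarray(self.normalized, dtype=np.float64))

    @property
    def zero_count(self) -> int:
        return int(self.counts[0])

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-level dump: columns v, count, normalized (257 rows incl. header)."""
        return pd.DataFrame(
            {"v": np.arange(256), "count": self.counts, "normalized": self.normalized}
        )


@dataclass(frozen=True)
class ViabilityFeature:
    """Scalar brightness feature of one frame."""

    value: float
    method: FeatureMethod
    n_bins: int
    sample_id: str = ""
    time_h: float = 0.0
    marker: Marker | None = None
    source_path: str = ""


def brightness_histogram(image: HSVImage) -> BrightnessHistogram:
    """Exact 256-level occurrence counts of V, normalized to the dark-pixel count.

    Raises :class:`~viaquant.errors.NormalizationError` when the frame has no
    V = 0 pixel: confocal frames are expected to show large dark areas, so a
    frame without any signals non-conforming input rather than being patched.
    """
    counts = np.bincount(image.value.ravel(), minlength=256).astype(np.int64)
    zero = int(counts[0])
    if zero == 0:
        raise NormalizationError(
            f"frame {image.source_path or image.sample_id!r} has no zero-brightness "
            "pixel; dark-pixel normalization is undefined"
        )
    return BrightnessHistogram(
        counts=counts,
        normalized=counts / zero,
        sample_id=image.sample_id,
        time_h=image.time_h,
        marker=image.marker,
        source_path=image.source_path,
    )


def bin_edges(n_bins: int) -> np.ndarray:
    """Start levels of the n_bins near-equal partitions of V ∈ [1, 255].

    Bin ``b`` covers V from ``1 + floor(255·b/n_bins)`` to
    ``1 + floor(255·(b+1)/n_bins) − 1`` inclusive; the returned array holds the
    ``n_bins + 1`` boundary levels (last entry 256).  The floor rule is fixed
    so results are bit-reproducible.
    """
    if not 1 <= n_bins <= 255:
        raise ValueError(f"n_bins must be in [1, 255], got {n_bins}")
    return 1 + (255 * np.arange(n_bins + 1, dtype=np.int64)) // n_bins


def extract_feature(
    hist: BrightnessHistogram,
    method: FeatureMethod | str = FeatureMethod.MAX_BINNED,
    n_bins: int = DEFAULT_N_BINS,
) -> ViabilityFeature:
    """Reduce a normalized histogram to the frame's scalar viability feature.

    MAX_BINNED: partition levels 1–255 into ``n_bins`` contiguous near-equal
    bins, sum the normalized entries in each, return the maximum bin content.
    SUM_ALL: return the sum of normalized entries over levels 1–255.  Level 0
    is excluded from both.  Ties in the max need no resolution: only the value
    is used downstream.
    """
    method = FeatureMethod.parse(method)
    edges = bin_edges(n_bins)  # validates n_bins
    if method is FeatureMethod.SUM_ALL:
        value = float(hist.normalized[1:].sum())
    else:
        sums = np.add.reduceat(hist.normalized, edges[:-1])
        # reduceat's final segment runs to index 255 inclusive, as required
        value = float(sums.max())
    return ViabilityFeature(
        value=value,
        method=method,
        n_bins=int(n_bins),
        sample_id=hist.sample_id,
        time_h=hist.time_h,
        marker=hist.marker,
        source_path=hist.source_path,
    )
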