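"""Independent brute-force oracles and small fixture builders.

The oracles deliberately loop pixel-by-pixel / level-by-level so they share no
code path with the vectorized implementation they check.
"""

from __future__ import annotations

import numpy as np

from viaquant.images import ConfocalImage, Marker


def rgb_image(
    pixels,
    sample_id: str = "S",
    time_h: float = 0.0,
    marker: Marker = Marker.GREEN_SYTO9,
) -> ConfocalImage:
    return ConfocalImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        sample_id=sample_id,
        time_h=time_h,
        marker=marker,
    )


def v_image(v_plane, marker: Marker = Marker.GREEN_SYTO9, **kw) -> ConfocalImage:
    """Frame whose marker plane holds ``v_plane`` and other planes are zero."""
    v_plane = np.asarray(v_plane, dtype=np.uint8)
    rgb = np.zeros((*v_plane.shape, 3), dtype=np.uint8)
    rgb[:, :, marker.plane] = v_plane
    return rgb_image(rgb, marker=marker, **kw)


def brute_v_plane(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel max over the three color planes, by explicit loops."""
    h, w, _ = rgb.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            out[i, j] = max(int(rgb[i, j, 0]), int(rgb[i, j, 1]), int(rgb[i, j, 2]))
    return out


def brute_counts(v_plane: np.ndarray) -> np.ndarray:
    """256-level occurrence counts by explicit per-pixel accumulation."""
    counts = np.zeros(256, dtype=np.int64)
    for val in np.asarray(v_plane).ravel():
        counts[int(val)] += 1
    return counts


def brute_max_binned(normalized: np.ndarray, n_bins: int) -> float:
    """Assign each nonzero level to its bin, accumulate, take the max.

    Bin b covers V from 1 + floor(255·b/n_bins) to
    1 + floor(255·(b+1)/n_bins) − 1 inclusive; level 0 is excluded.
    """
    sums = []
    for b in range(n_bins):
        lo = 1 + (255 * b) // n_bins
        hi = 1 + (255 * (b + 1)) // n_bins - 1
        total = 0.0
        for v in range(lo, hi + 1):
            total += float(normalized[v])
        sums.append(total)
    return max(sums)


def brute_corr_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the explicitly formed correlation matrix.

    ``X`` must already be standardized (z-scores, n−1 denominator); returns
    eigenvalues descending and the matching eigenvector columns.
    """
    n = X.shape[0]
    corr = X.T @ X / (n - 1)
    w, vec = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    return w[order], vec[:, order]


def sparse_v_frame(rng: np.random.Generator, shape=(32, 32), n_levels=20) -> np.ndarray:
    """Mostly-dark V plane with a handful of occupied brightness levels."""
    v = np.zeros(shape, dtype=np.uint8)
    n_bright = int(rng.integers(1, shape[0] * shape[1] // 4))
    idx = rng.choice(shape[0] * shape[1], size=n_bright, replace=False)
    levels = rng.integers(1, 256, size=n_levels)
    v.ravel()[idx] = rng.choice(levels, size=n_bright)
    return v
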