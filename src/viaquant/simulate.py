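"""Synthetic Live/Dead confocal image pairs with known ground truth.

The study's micrographs are not deposited, so validation runs on simulated
frames that reproduce their described character: sparse clustered bright spots
("bacteria tend to form clusters") on a predominantly dark background ("large
areas without information"), one marker per frame, 8-bit 1024×1024 RGB.

Cells follow a Thomas-type cluster process — cluster parents uniform over the
frame, cells scattered around their parent with an isotropic Gaussian — the
simplest point process producing the described clustering.  Each cell renders
as a Gaussian spot whose peak is drawn from a truncated normal on the 8-bit
scale; spots add, then optional Gaussian noise is applied, and the frame is
clipped to [0, 255] and quantized, so saturation in dense bright clusters is a
testable regime.  The green and red scenes are independent draws: each frame
carries one marker, exactly as acquired.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from viaquant.images import (
    ConfocalImage,
    ManifestEntry,
    Marker,
    SampleManifest,
    load_manifest,
    save_image,
    write_manifest,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full seeded parameterization of one simulated Live/Dead image pair.

    Defaults follow the acquisition geometry of the emulated frames
    (1024×1024, 8-bit, with the large truly-black background areas the
    dark-count normalization relies on — hence ``noise_sd = 0`` by default).
    ``peak_mean``/``peak_sd`` parameterize the truncated-normal spot peak on
    the 0–255 scale; ``cluster_spread`` and ``spot_sigma`` are in pixels.
    ``noise_sd`` adds detector-like Gaussian noise to every color plane of
    both frames; it is a stress parameter — noise above the quantization
    threshold floods the low brightness levels of both markers equally and
    washes the ratio toward 1.
    """

    n_live: int
    n_dead: int
    width: int = 1024
    height: int = 1024
    n_clusters: int = 8
    cluster_spread: float = 20.0
    spot_sigma: float = 2.0
    peak_mean: float = 180.0
    peak_sd: float = 40.0
    background_level: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise ValueError("cell counts must be non-negative")
        if self.width < 1 or self.height < 1:
            raise ValueError("frame dimensions must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit value")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Planted cell counts (and positions, row/col pixels) of one pair."""

    n_live: int
    n_dead: int
    live_positions: np.ndarray  # (n_live, 2) float
    dead_positions: np.ndarray  # (n_dead, 2) float

    def __iter__(self):
        return iter((self.n_live, self.n_dead))


def _draw_positions(
    n_cells: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Thomas process: uniform cluster parents, Gaussian offsets per cell."""
    centers = rng.uniform(
        low=[0.0, 0.0], high=[spec.height, spec.width], size=(spec.n_clusters, 2)
    )
    counts = rng.multinomial(n_cells, np.full(spec.n_clusters, 1.0 / spec.n_clusters))
    parts = []
    for center, count in zip(centers, counts):
        if count:
            parts.append(center + rng.normal(0.0, spec.cluster_spread, size=(count, 2)))
    if not parts:
        return np.empty((0, 2))
    return np.concatenate(parts, axis=0)


def _draw_peaks(n_cells: int, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if n_cells == 0:
        return np.empty(0)
    if spec.peak_sd == 0:
        return np.full(n_cells, float(np.clip(spec.peak_mean, 1.0, 255.0)))
    a = (1.0 - spec.peak_mean) / spec.peak_sd
    b = (255.0 - spec.peak_mean) / spec.peak_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.peak_mean, scale=spec.peak_sd, size=n_cells, random_state=rng
    )


def _render_plane(
    positions: np.ndarray, peaks: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    """Additive Gaussian spots on a float plane (no clipping yet)."""
    plane = np.zeros((spec.height, spec.width), dtype=np.float64)
    radius = int(math.ceil(4.0 * spec.spot_sigma))
    for (cy, cx), peak in zip(positions, peaks):
        y0 = max(int(math.floor(cy)) - radius, 0)
        y1 = min(int(math.floor(cy)) + radius + 1, spec.height)
        x0 = max(int(math.floor(cx)) - radius, 0)
        x1 = min(int(math.floor(cx)) + radius + 1, spec.width)
        if y0 >= y1 or x0 >= x1:
            continue  # cell fell outside the frame
        yy = np.arange(y0, y1, dtype=np.float64)[:, None]
        xx = np.arange(x0, x1, dtype=np.float64)[None, :]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        plane[y0:y1, x0:x1] += peak * np.exp(-d2 / (2.0 * spec.spot_sigma**2))
    return plane


def _finish_frame(
    signal_plane: np.ndarray,
    marker: Marker,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    sample_id: str,
    time_h: float,
) -> ConfocalImage:
    h, w = signal_plane.shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    rgb[:, :, marker.plane] = signal_plane + spec.background_level

    clean = np.clip(np.rint(rgb[:, :, marker.plane]), 0, 255)
    dark_fraction = float(np.mean(clean == 0))
    if dark_fraction < 0.01:
        warnings.warn(
            f"fewer than 1% dark pixels in a noise-free render "
            f"({dark_fraction:.2%}); the zero-brightness normalization anchor "
            "is degenerating",
            stacklevel=3,
        )

    if spec.noise_sd > 0:
        rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return ConfocalImage(
        pixels=pixels, sample_id=sample_id, time_h=time_h, marker=marker
    )


def simulate_pair(
    spec: SyntheticSpec, sample_id: str = "SYN", time_h: float = 0.0
) -> tuple[ConfocalImage, ConfocalImage, GroundTruth]:
    """Simulate one green/red frame pair, fully reproducible from ``spec.seed``.

    The green frame holds ``n_live`` rendered cells in its green plane, the
    red frame ``n_dead`` cells in its red plane; off-marker planes carry only
    noise.  Returns the pair and the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed)

    live_pos = _draw_positions(spec.n_live, spec, rng)
    live_peaks = _draw_peaks(len(live_pos), spec, rng)
    green_plane = _render_plane(live_pos, live_peaks, spec)

    dead_pos = _draw_positions(spec.n_dead, spec, rng)
    dead_peaks = _draw_peaks(len(dead_pos), spec, rng)
    red_plane = _render_plane(dead_pos, dead_peaks, spec)

    green = _finish_frame(green_plane, Marker.GREEN_SYTO9, spec, rng, sample_id, time_h)
    red = _finish_frame(red_plane, Marker.RED_PI, spec, rng, sample_id, time_h)
    truth = GroundTruth(spec.n_live, spec.n_dead, live_pos, dead_pos)
    return green, red, truth


def split_total(total: int, ratio: float) -> tuple[int, int]:
    """Split a fixed total cell count by a live/dead ratio r: live = round(total·r/(1+r))."""
    if ratio <= 0:
        raise ValueError(f"planted ratio must be positive, got {ratio}")
    n_live = int(round(total * ratio / (1.0 + ratio)))
    return n_live, total - n_live


def simulate_panel(
    base: SyntheticSpec,
    ratios: list[float],
    times: list[float],
    replicates: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[SampleManifest, pd.DataFrame]:
    """Write a full synthetic panel: TIFF frames, manifest CSV and truth CSV.

    The total cell count per pair (``base.n_live + base.n_dead``) is held
    constant so only the live/dead split varies; per (ratio, time, replicate),
    ``n_live = round(total·r/(1+r))``.  Sample ids encode ratio and replicate
    (e.g. ``r0.25-2``); exposure time is a grouping label.  Returns the loaded
    manifest (paths resolved) and the ground-truth table.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    total = base.n_live + base.n_dead

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(ratios) * len(times) * replicates) % (2**31)

    rel_entries: list[ManifestEntry] = []
    truth_rows = []
    i = 0
    for ratio in ratios:
        n_live, n_dead = split_total(total, ratio)
        for rep in range(1, replicates + 1):
            sample_id = f"r{ratio:g}-{rep}"
            for time_h in times:
                spec = replace(
                    base, n_live=n_live, n_dead=n_dead, seed=int(child_seeds[i])
                )
                i += 1
                green, red, _ = simulate_pair(spec, sample_id, time_h)
                for img, tag in ((green, "green"), (red, "red")):
                    rel = Path("images") / f"{sample_id}_t{time_h:g}_{tag}.tif"
                    save_image(img, out_dir / rel)
                    rel_entries.append(
                        ManifestEntry(sample_id, float(time_h), img.marker, rel)
                    )
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "time_h": float(time_h),
                        "n_live": n_live,
                        "n_dead": n_dead,
                        "planted_ratio": ratio,
                    }
                )

    manifest_path = write_manifest(SampleManifest(rel_entries), out_dir / "manifest.csv")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return load_manifest(manifest_path), truth
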