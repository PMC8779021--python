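"""Per-sample viable/non-viable ratios and the radial-chart table.

Each stained sample contributes one to four green (SYTO9, viable) frames and
one to four red (PI, non-viable) frames.  The per-marker aggregate is the
arithmetic mean of the per-frame features — mean-of-features rather than a
pooled histogram, so each frame contributes equally regardless of its
dark-area fraction — and the sample's viability ratio is the green aggregate
divided by the red aggregate.  Green and red frames are unpaired captures of
the same stained sample, so the ratio is formed from the aggregates, never
averaged over arbitrary frame pairings.  Higher ratio = healthier population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from viaquant.colorspace import HSVImage, rgb_to_hsv
from viaquant.errors import UndefinedRatioError
from viaquant.histogram import (
    DEFAULT_N_BINS,
    FeatureMethod,
    ViabilityFeature,
    brightness_histogram,
    extract_feature,
)
from viaquant.images import Marker, SampleManifest

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViabilityRatio:
    """Aggregate green/red feature quotient for one (sample, time)."""

    sample_id: str
    time_h: float
    green_feature: float
    red_feature: float
    ratio: float
    n_green: int
    n_red: int


def quality_score(image: HSVImage) -> float:
    """Brightness × focus score used to rank candidate frames.

    score = mean(V) × Tenengrad energy of V (mean squared Sobel gradient
    magnitude, computed on V/255 so the factor is dimensionless).  An all-dark
    frame scores 0 (mean V = 0); a uniform frame scores 0 (no edges); blurring
    reduces gradient energy and hence the score.  Advisory only — manifest
    frames are never silently dropped.
    """
    v = image.value.astype(np.float64) / 255.0
    gx = ndimage.sobel(v, axis=0)
    gy = ndimage.sobel(v, axis=1)
    tenengrad = float(np.mean(gx**2 + gy**2))
    return float(image.value.mean()) * tenengrad


def _aggregate(feats: list[ViabilityFeature], marker: Marker) -> float:
    if not 1 <= len(feats) <= 4:
        raise ValueError(
            f"expected 1-4 {marker.value} features per sample, got {len(feats)}"
        )
    for f in feats:
        if f.marker is not None and f.marker is not marker:
            # advisory: side assignment is positional (green list / red list)
            log.warning(
                "feature from %s frame %s supplied on the %s side",
                f.marker.value,
                f.source_path,
                marker.value,
            )
    return float(np.mean([f.value for f in feats]))


def sample_ratio(
    green_feats: list[ViabilityFeature],
    red_feats: list[ViabilityFeature],
) -> ViabilityRatio:
    """Form the viable/non-viable ratio of one stained sample.

    All features must come from the same (sample_id, time_h) and share one
    extraction method and bin count.  A zero red aggregate raises
    :class:`~viaquant.errors.UndefinedRatioError` (no detectable dead-cell
    signal), never an infinite ratio.
    """
    feats = list(green_feats) + list(red_feats)
    methods = {(f.method, f.n_bins) for f in feats}
    if len(methods) > 1:
        raise ValueError(f"mixed feature methods/bin counts in one sample: {methods}")
    keys = {(f.sample_id, f.time_h) for f in feats}
    if len(keys) > 1:
        raise ValueError(f"features from different (sample, time) groups: {keys}")
    sample_id, time_h = next(iter(keys))

    green = _aggregate(list(green_feats), Marker.GREEN_SYTO9)
    red = _aggregate(list(red_feats), Marker.RED_PI)
    if red == 0:
        raise UndefinedRatioError(
            f"sample {sample_id!r} at {time_h} h: no detectable dead-cell signal "
            "(red aggregate feature is zero), ratio undefined"
        )
    return ViabilityRatio(
        sample_id=sample_id,
        time_h=time_h,
        green_feature=green,
        red_feature=red,
        ratio=green / red,
        n_green=len(green_feats),
        n_red=len(red_feats),
    )


def radial_chart_table(ratios: list[ViabilityRatio]) -> pd.DataFrame:
    """Tidy (sample_id × time_h → ratio) table spanning the full grid.

    Missing (sample, time) cells are emitted as explicit NaN rows so the grid
    stays rectangular; duplicate cells raise a validation error.
    """
    seen: set[tuple[str, float]] = set()
    for r in ratios:
        key = (r.sample_id, r.time_h)
        if key in seen:
            raise ValueError(f"duplicate ratio for sample {r.sample_id!r} at {r.time_h} h")
        seen.add(key)
    samples: list[str] = []
    times: list[float] = []
    for r in ratios:
        if r.sample_id not in samples:
            samples.append(r.sample_id)
        if r.time_h not in times:
            times.append(r.time_h)
    times = sorted(times)
    lookup = {(r.sample_id, r.time_h): r.ratio for r in ratios}
    rows = [
        {"sample_id": s, "time_h": t, "ratio": lookup.get((s, t), np.nan)}
        for s in samples
        for t in times
    ]
    return pd.DataFrame(rows, columns=["sample_id", "time_h", "ratio"])


def radial_chart_plot(table: pd.DataFrame, ax=None):
    """Render the ratio table as a polar (radial) chart, one trace per time."""
    import matplotlib.pyplot as plt

    samples = list(dict.fromkeys(table["sample_id"]))
    angles = np.linspace(0.0, 2.0 * np.pi, len(samples), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for time_h, sub in table.groupby("time_h", sort=True):
        vals = [
            float(sub.loc[sub["sample_id"] == s, "ratio"].iloc[0]) if (sub["sample_id"] == s).any() else np.nan
            for s in samples
        ]
        theta = np.concatenate([angles, angles[:1]])
        rho = np.asarray(vals + vals[:1], dtype=float)
        ax.plot(theta, rho, marker="o", label=f"{time_h:g} h")
    ax.set_xticks(angles)
    ax.set_xticklabels(samples)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    ax.set_title("viable / non-viable cell ratio")
    return ax


def quantify_manifest(
    manifest: SampleManifest,
    method: FeatureMethod | str = FeatureMethod.MAX_BINNED,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full image → feature → ratio pipeline over a manifest.

    Returns ``(features, ratios)``: a per-frame feature table
    (sample_id, time_h, marker, path, zero_count, n_pixels, feature,
    quality) and a per-sample ratio table
    (sample_id, time_h, n_green, n_red, green_feature, red_feature, ratio).
    Every (sample, time) must carry both markers.
    """
    method = FeatureMethod.parse(method)
    feature_rows = []
    per_group: dict[tuple[str, float, Marker], list[ViabilityFeature]] = {}
    for (sample_id, time_h, marker), _ in manifest.groups().items():
        images = manifest.load_group(sample_id, time_h, marker)
        feats = []
        for img in images:
            hsv = rgb_to_hsv(img)
            hist = brightness_histogram(hsv)
            feat = extract_feature(hist, method, n_bins)
            feats.append(feat)
            feature_rows.append(
                {
                    "sample_id": sample_id,
                    "time_h": time_h,
                    "marker": marker.value,
                    "path": img.source_path,
                    "zero_count": hist.zero_count,
                    "n_pixels": hist.n_pixels,
                    "feature": feat.value,
                    "quality": quality_score(hsv),
                }
            )
        per_group[(sample_id, time_h, marker)] = feats

    ratios = []
    for sample_id, time_h in manifest.sample_times():
        green = per_group.get((sample_id, time_h, Marker.GREEN_SYTO9))
        red = per_group.get((sample_id, time_h, Marker.RED_PI))
        if green is None or red is None:
            missing = "GREEN_SYTO9" if green is None else "RED_PI"
            raise ValueError(
                f"sample {sample_id!r} at {time_h} h has no {missing} frames; "
                "both markers are required to form a ratio"
            )
        ratios.append(sample_ratio(green, red))

    features_df = pd.DataFrame(feature_rows)
    ratios_df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "time_h": r.time_h,
                "n_green": r.n_green,
                "n_red": r.n_red,
                "green_feature": r.green_feature,
                "red_feature": r.red_feature,
                "ratio": r.ratio,
            }
            for r in ratios
        ]
    )
    return features_df, ratios_df
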