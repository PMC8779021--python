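"""Reading confocal frames and the sample manifest.

Images are 8-bit RGB rasters (TIFF or PNG; lossless only — JPEG compression
artifacts would perturb the zero-brightness pixel count that anchors the
histogram normalization).  Each frame carries information in a single color
plane: green for SYTO9-stained viable cells, red for PI-stained non-viable
cells.  A plain CSV manifest groups frames into per-(sample, time, marker)
sets of one to four images.
"""

from __future__ import annotations

import csv
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from viaquant.errors import ManifestError, UnsupportedDepthError, UnsupportedFormatError

log = logging.getLogger(__name__)

#: File suffixes accepted for input/output frames (lossless rasters only).
ACCEPTED_SUFFIXES = {".tif", ".tiff", ".png"}

#: Maximum number of frames per (sample, time, marker) group.
MAX_GROUP_SIZE = 4


class Marker(Enum):
    """Fluorescence marker carried by a frame."""

    GREEN_SYTO9 = "GREEN_SYTO9"
    RED_PI = "RED_PI"

    @property
    def plane(self) -> int:
        """Index of the RGB plane this marker occupies (0 = red, 1 = green)."""
        return 1 if self is Marker.GREEN_SYTO9 else 0

    @classmethod
    def parse(cls, text: str) -> "Marker":
        """Map a manifest marker string to the enum, case-insensitively.

        Accepts the full enum names plus the short aliases ``green``/``syto9``
        and ``red``/``pi``.
        """
        key = str(text).strip().lower()
        aliases = {
            "green_syto9": cls.GREEN_SYTO9,
            "green": cls.GREEN_SYTO9,
            "syto9": cls.GREEN_SYTO9,
            "red_pi": cls.RED_PI,
            "red": cls.RED_PI,
            "pi": cls.RED_PI,
        }
        if key not in aliases:
            raise ManifestError(
                f"unknown marker {text!r}; expected GREEN_SYTO9 or RED_PI "
                "(case-insensitive; aliases: green, red)"
            )
        return aliases[key]


@dataclass(frozen=True)
class ConfocalImage:
    """One single-marker confocal frame with its acquisition metadata.

    ``pixels`` is an H×W×3 uint8 array holding the red, green and blue planes
    exactly as stored on disk (no rescaling, no gamma).  The frame carries
    signal in only one color plane, identified by ``marker``; the other planes
    may hold noise.
    """

    pixels: np.ndarray
    sample_id: str
    time_h: float
    marker: Marker
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise UnsupportedDepthError(
                f"ConfocalImage requires 8-bit pixels, got dtype {px.dtype}"
            )
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"ConfocalImage requires an H×W×3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("ConfocalImage requires H >= 1 and W >= 1")
        if self.time_h < 0:
            raise ValueError(f"time_h must be non-negative, got {self.time_h}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def marker_consistent(self) -> bool:
        """Check that the declared marker's plane dominates the other color plane.

        Advisory only: the marker of record always comes from the manifest.
        """
        red = int(self.pixels[:, :, 0].sum())
        green = int(self.pixels[:, :, 1].sum())
        declared = green if self.marker is Marker.GREEN_SYTO9 else red
        other = red if self.marker is Marker.GREEN_SYTO9 else green
        return declared >= other


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    time_h: float
    marker: Marker
    path: Path


@dataclass
class SampleManifest:
    """Validated list of frames grouped by (sample_id, time_h, marker)."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key, group in self.groups().items():
            if not 1 <= len(group) <= MAX_GROUP_SIZE:
                raise ManifestError(
                    f"group {key} has {len(group)} entries; "
                    f"expected 1 to {MAX_GROUP_SIZE} frames per stained sample"
                )

    def groups(self) -> "OrderedDict[tuple[str, float, Marker], list[ManifestEntry]]":
        """Partition entries by (sample_id, time_h, marker), preserving order."""
        out: OrderedDict[tuple[str, float, Marker], list[ManifestEntry]] = OrderedDict()
        for entry in self.entries:
            out.setdefault((entry.sample_id, entry.time_h, entry.marker), []).append(entry)
        return out

    def sample_times(self) -> list[tuple[str, float]]:
        """Distinct (sample_id, time_h) pairs, in first-appearance order."""
        seen: OrderedDict[tuple[str, float], None] = OrderedDict()
        for entry in self.entries:
            seen.setdefault((entry.sample_id, entry.time_h))
        return list(seen)

    def load_group(self, sample_id: str, time_h: float, marker: Marker) -> list[ConfocalImage]:
        group = self.groups().get((sample_id, time_h, marker))
        if group is None:
            raise ManifestError(
                f"no {marker.value} frames listed for sample {sample_id!r} at {time_h} h"
            )
        return [load_image(e.path, e.sample_id, e.time_h, e.marker) for e in group]


def _check_suffix(path: Path) -> None:
    if path.suffix.lower() not in ACCEPTED_SUFFIXES:
        raise UnsupportedFormatError(
            f"{path}: only lossless TIFF/PNG frames are accepted "
            f"(got {path.suffix or 'no suffix'!r}); JPEG is rejected because "
            "compression artifacts perturb the zero-brightness count"
        )


def load_image(
    path: str | Path,
    sample_id: str,
    time_h: float,
    marker: Marker | str,
) -> ConfocalImage:
    """Read one 8-bit RGB(A) frame from disk, pixels exactly as stored.

    RGBA alpha is discarded with a logged warning.  Non-8-bit depth raises
    :class:`~viaquant.errors.UnsupportedDepthError` rather than silently
    converting, since rescaling would distort the brightness histogram.
    """
    path = Path(path)
    if isinstance(marker, str):
        marker = Marker.parse(marker)
    _check_suffix(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except UnsupportedDepthError:
        raise
    except Exception as exc:  # decoder failure
        raise IOError(f"could not decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"{path}: expected 8-bit pixels, got dtype {arr.dtype}; "
            "re-export the frame at 8 bits per channel"
        )
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise IOError(f"{path}: expected an RGB or RGBA raster, got shape {arr.shape}")
    if arr.shape[-1] == 4:
        log.warning("%s: discarding alpha plane of RGBA image", path)
        arr = arr[:, :, :3]
    arr = np.ascontiguousarray(arr)
    image = ConfocalImage(
        pixels=arr,
        sample_id=sample_id,
        time_h=float(time_h),
        marker=marker,
        source_path=str(path),
    )
    if not image.marker_consistent():
        log.warning(
            "%s: declared marker %s but the other color plane has higher total "
            "intensity; manifest marker kept",
            path,
            marker.value,
        )
    return image


def save_image(image: ConfocalImage, path: str | Path) -> Path:
    """Write a frame losslessly (TIFF via tifffile, PNG via imageio)."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)
    return path


MANIFEST_COLUMNS = ("sample_id", "time_h", "marker", "path")


def load_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a sample manifest CSV.

    The manifest has header columns ``sample_id,time_h,marker,path``; marker
    strings are folded case-insensitively onto GREEN_SYTO9/RED_PI.  Relative
    image paths are resolved against the manifest's own directory.  Every
    (sample_id, time_h, marker) group must hold 1–4 entries and every path
    must point at a readable file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest file not found: {path}")
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        got = tuple(reader.fieldnames or ())
        if set(MANIFEST_COLUMNS) - set(got):
            raise ManifestError(
                f"{path}: manifest header must contain columns "
                f"{','.join(MANIFEST_COLUMNS)}; got {','.join(got) or '(empty)'}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                time_h = float(row["time_h"])
            except (TypeError, ValueError):
                raise ManifestError(f"{path} line {i}: time_h {row['time_h']!r} is not a number")
            if time_h < 0:
                raise ManifestError(f"{path} line {i}: time_h must be non-negative")
            marker = Marker.parse(row["marker"])
            img_path = Path(row["path"])
            if not img_path.is_absolute():
                img_path = path.parent / img_path
            if not img_path.exists():
                raise ManifestError(f"{path} line {i}: image file not found: {img_path}")
            entries.append(ManifestEntry(str(row["sample_id"]), time_h, marker, img_path))
    if not entries:
        raise ManifestError(f"{path}: manifest lists no images")
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | Path) -> Path:
    """Write a manifest CSV (paths as given, no resolution applied)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for e in manifest.entries:
            writer.writerow([e.sample_id, f"{e.time_h:g}", e.marker.value, str(e.path)])
    return path
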