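"""RGB → HSV conversion with an integer 8-bit V plane.

Brightness perception is not color-neutral: at equal saturation and lighting a
red object looks dimmer to the eye than a green one, so comparing raw color
planes would bias red (PI, non-viable) frames against green (SYTO9, viable)
ones.  Working in HSV removes that bias: the value channel is the per-pixel
maximum of the three color planes, identical for a green spot pattern and the
same pattern painted red.

Only V is consumed downstream and it is deliberately kept on the native
integer 0–255 scale — the 256-level histogram and the zero-brightness count
are defined on 8-bit levels, not on a rescaled [0, 1] axis.  H and S are
exposed for diagnostics only (hue in degrees [0, 360), saturation in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from viaquant.images import ConfocalImage, Marker


@dataclass(frozen=True)
class HSVImage:
    """HSV planes of one confocal frame, metadata carried over."""

    hue: np.ndarray          # degrees in [0, 360)
    saturation: np.ndarray   # [0, 1]
    value: np.ndarray        # uint8, 0-255
    sample_id: str
    time_h: float
    marker: Marker
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.value.dtype != np.uint8:
            raise ValueError("V plane must be 8-bit (uint8)")
        if not (self.hue.shape == self.saturation.shape == self.value.shape):
            raise ValueError("H, S and V planes must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.value.shape


def rgb_to_hsv(image: ConfocalImage) -> HSVImage:
    """Convert a frame to HSV by the standard hexcone formulas.

    V = max(R, G, B) per pixel, kept as uint8.  S = (V − min)/V with S = 0
    where V = 0.  H follows the piecewise hexcone formula with H = 0 where
    S = 0; on max-channel ties the first matching branch (R, then G) applies.
    """
    rgb = image.pixels.astype(np.float64)
    r, g, b = rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2]

    v_int = image.pixels.max(axis=2)  # uint8 stays uint8
    v = v_int.astype(np.float64)
    mn = rgb.min(axis=2)
    delta = v - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, delta / np.where(v > 0, v, 1.0), 0.0)

        safe = np.where(delta > 0, delta, 1.0)
        h = np.select(
            [delta == 0, v == r, v == g],
            [
                np.zeros_like(v),
                np.mod((g - b) / safe, 6.0) * 60.0,
                ((b - r) / safe + 2.0) * 60.0,
            ],
            default=((r - g) / safe + 4.0) * 60.0,
        )
    h = np.mod(h, 360.0)

    return HSVImage(
        hue=h,
        saturation=s,
        value=v_int,
        sample_id=image.sample_id,
        time_h=image.time_h,
        marker=image.marker,
        source_path=image.source_path,
    )
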