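"""In-memory containers for mammographic images and breast masks.

All pixel rasters are 2-D numpy arrays in row-major order with 0-based
coordinates; crops and blocks use half-open index ranges throughout the
package.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VIEWS = ("CC", "MLO")
LATERALITIES = ("L", "R", "flipped-R")


@dataclass
class GrayImage:
    """A single-view grayscale mammogram.

    Parameters
    ----------
    pixels
        2-D array of nonnegative integers, ``max pixel < 2**bits_stored``.
    view
        ``"CC"`` (craniocaudal) or ``"MLO"`` (mediolateral oblique).
    laterality
        ``"L"``, ``"R"``, or ``"flipped-R"`` for a right image that has been
        mirrored into left orientation.
    bits_stored
        Bit depth of the intensity scale (8 for the standardised pipeline
        input, commonly 12-16 for raw DICOM).
    photometric
        ``"MONO2"`` (brighter = denser, the working convention), ``"MONO1"``
        (inverted scale), or ``"unknown"``.
    """

    pixels: np.ndarray
    view: str = "CC"
    laterality: str = "L"
    bits_stored: int = 8
    photometric: str = "MONO2"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **meta) -> "GrayImage":
        """Copy of this image with new pixel data (and optional metadata)."""
        return replace(self, pixels=pixels, **meta)


@dataclass
class BreastMask:
    """Binary raster marking breast tissue; same shape as its image."""

    pixels: np.ndarray = field()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a nonempty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        return int(self.pixels.sum())
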