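"""Core image container shared by all stages.

A FLIP micrograph is a single-channel grayscale image of protein A/G
agarose beads taken on a fluorescence microscope. Only relative
intensities within one experiment are meaningful, so pixel values are
kept in raw camera units and never normalised here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ImageFormatError(ValueError):
    """Raised when an input image violates the single-channel contract."""


@dataclass(frozen=True)
class FluorImage:
    """A single-channel 2-D fluorescence micrograph.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities. Stored as float64 so that
        noise models and region statistics do not lose precision; values
        are expected to lie within the declared bit-depth range.
    bit_depth : int
        8 or 16; fixes the valid intensity range [0, 2**bit_depth - 1].
    source_path : str, optional
        Provenance string (file the image was read from), if any.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ImageFormatError(
                f"expected a single-channel 2-D image, got shape {px.shape}"
            )
        if px.size == 0:
            raise ImageFormatError("zero-area image")
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.any(px < 0) or np.any(px > self.max_value):
            raise ImageFormatError(
                f"pixel values outside [0, {self.max_value}] for {self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def is_saturated(self) -> bool:
        """True when every pixel sits at the top of the bit-depth range."""
        return bool(np.all(self.pixels >= self.max_value))
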