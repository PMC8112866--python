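"""Shared primitives: the image container and the package's exception types.

Conventions used throughout the package (stated once, applied everywhere):
pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left;
areas are converted to square micrometres via ``pixel_size_um ** 2``;
intervals and histogram bins are half-open ``[a, b)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageField",
    "MicrodomainError",
    "ParameterError",
    "CalibrationError",
    "SizingError",
    "DegenerateFieldError",
    "ConfigError",
]


class MicrodomainError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(MicrodomainError, ValueError):
    """Invalid simulation or analysis parameters."""


class CalibrationError(MicrodomainError):
    """Single-molecule calibration could not be established."""


class SizingError(MicrodomainError, ValueError):
    """Requested geometry does not fit in the field."""


class DegenerateFieldError(MicrodomainError):
    """A field with no usable signal was passed to a quantification step."""


class ConfigError(MicrodomainError, ValueError):
    """Invalid or unknown configuration keys."""


@dataclass
class ImageField:
    """A single-channel 2-D fluorescence image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative, finite intensities (ADU). Stored as
        float64.
    pixel_size_um : float
        Side length of one pixel in micrometres. Must be positive.
    channel_name : str
        Free-text channel label (e.g. ``"membrane"`` or ``"S1R-647"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError("ImageField requires a 2-D pixel grid")
        if self.pixels.size == 0:
            raise ParameterError("ImageField requires a non-empty pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("ImageField pixels must be finite")
        if np.any(self.pixels < 0):
            raise ParameterError("ImageField pixels must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ParameterError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    @property
    def field_area_um2(self) -> float:
        return self.pixels.size * self.pixel_area_um2
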