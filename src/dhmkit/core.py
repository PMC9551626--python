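"""Shared data containers and grid conventions.

All arrays are 2D with shape (M rows, N cols).  Pixel indices are 0-based
(row, col).  Physical coordinates are centred on the array:

    x = (col - N//2) * dx,    y = (row - M//2) * dy

so the optical axis (and the DC bin of every centred spectrum) sits at index
(M//2, N//2).  Wavelength and pixel pitches must share one length unit;
micrometres are recommended throughout.  When a quantity is genuinely
dimensionless (e.g. a hologram loaded without metadata) the calibration
defaults to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_2d(a: np.ndarray, name: str) -> np.ndarray:
    if a.ndim != 2:
        raise ValidationError(f"{name} must be a 2D array, got shape {a.shape}")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValidationError(f"{name} must be at least 2x2, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name} contains non-finite values")
    return a


@dataclass
class RealImage:
    """A 2D real raster: a recorded/simulated hologram or an amplitude,
    intensity or phase map.  Pixel pitches are optional metadata."""

    pixels: np.ndarray
    dx: Optional[float] = None
    dy: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = _check_2d(np.asarray(self.pixels, dtype=float), "pixels")
        for name, v in (("dx", self.dx), ("dy", self.dy)):
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class ComplexField:
    """A calibrated complex wavefield u(x, y).

    Parameters
    ----------
    values : (M, N) complex array
    wavelength : illumination wavelength (same unit as the pitches)
    dx, dy : pixel pitches along columns (x) and rows (y)
    """

    values: np.ndarray
    wavelength: float = 1.0
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        _check_2d(self.values.real, "values")
        if not np.all(np.isfinite(self.values.imag)):
            raise ValidationError("values contains non-finite imaginary parts")
        for name, v in (("wavelength", self.wavelength), ("dx", self.dx), ("dy", self.dy)):
            if not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def wavenumber(self) -> float:
        """k = 2*pi / wavelength."""
        return 2.0 * np.pi / self.wavelength


@dataclass
class Spectrum:
    """A 2D complex spectrum stored DC-centred: the DC bin sits at index
    (M//2, N//2).  Frequency pitches follow from the source calibration:
    du = 1/(N*dx) along columns, dv = 1/(M*dy) along rows."""

    values: np.ndarray
    wavelength: float = 1.0
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        _check_2d(self.values.real, "values")
        for name, v in (("wavelength", self.wavelength), ("dx", self.dx), ("dy", self.dy)):
            if not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def du(self) -> float:
        return 1.0 / (self.shape[1] * self.dx)

    @property
    def dv(self) -> float:
        return 1.0 / (self.shape[0] * self.dy)

    @property
    def dc_index(self) -> Tuple[int, int]:
        M, N = self.shape
        return (M // 2, N // 2)


def centered_coords(shape: Tuple[int, int], dx: float, dy: float):
    """Physical coordinate grids (x as a row vector, y as a column vector)
    centred on the array per the package convention."""
    M, N = shape
    x = (np.arange(N) - N // 2)[None, :] * dx
    y = (np.arange(M) - M // 2)[:, None] * dy
    return x, y


def centered_freqs(shape: Tuple[int, int], dx: float, dy: float):
    """Spatial-frequency grids (u along columns, v along rows) matching the
    DC-centred spectrum layout."""
    M, N = shape
    u = (np.arange(N) - N // 2)[None, :] / (N * dx)
    v = (np.arange(M) - M // 2)[:, None] / (M * dy)
    return u, v


def as_array(img) -> np.ndarray:
    """Accept a RealImage, ComplexField, Spectrum or bare ndarray."""
    if isinstance(img, RealImage):
        return img.pixels
    if isinstance(img, (ComplexField, Spectrum)):
        return img.values
    return np.asarray(img)
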