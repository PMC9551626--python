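"""Image I/O, centred Fourier transforms, spectral filtering and speckle
reduction.

Every spectrum handled here is DC-centred (see :mod:`dhmkit.core`).  The
transforms use the unitary ("ortho") normalisation so that Parseval's theorem
holds exactly: sum(|field|^2) == sum(|spectrum|^2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .core import (
    ComplexField,
    RealImage,
    Spectrum,
    ValidationError,
    as_array,
    centered_coords,
)

__all__ = [
    "read_image",
    "save_image",
    "ft_centered",
    "ift_centered",
    "amplitude",
    "intensity",
    "phase",
    "CircularFilter",
    "RectangularFilter",
    "spatial_filter",
    "manual_rectangular_filter",
    "find_order_peak",
    "hybrid_median_mean",
    "save_complex_field",
    "load_complex_field",
]


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def read_image(path: Union[str, os.PathLike]) -> RealImage:
    """Read a grayscale raster (TIFF/PNG/BMP, 8/16-bit or float) and scale it
    to [0, 1] by the full scale of its integer dtype.

    RGB inputs are converted to grayscale by the channel mean.  Float inputs
    are passed through unscaled.
    """
    path = os.fspath(path)
    try:
        import imageio.v3 as iio

        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image file {path!r}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr.astype(float).mean(axis=-1)
        # luminance average of the channels; keep the source dtype scale
        scale = _dtype_full_scale(raw.dtype)
    else:
        scale = _dtype_full_scale(arr.dtype)
        arr = arr.astype(float)
    if scale is not None:
        arr = arr / scale
    return RealImage(arr)


def _dtype_full_scale(dtype) -> Optional[float]:
    dtype = np.dtype(dtype)
    if dtype.kind in "ui":
        return float(np.iinfo(dtype).max)
    return None


def save_image(path: Union[str, os.PathLike], img, dtype=np.float32) -> None:
    """Write a real raster as TIFF (float) via tifffile."""
    import tifffile

    tifffile.imwrite(os.fspath(path), np.asarray(as_array(img), dtype=dtype))


# ---------------------------------------------------------------------------
# centred Fourier transforms
# ---------------------------------------------------------------------------

def ft_centered(field) -> Spectrum:
    """2D Fourier transform with the DC bin at the array centre.

    Accepts a RealImage, ComplexField or bare array; the result carries the
    input's calibration so frequency pitches can be derived from it.
    """
    values = as_array(field)
    if not np.all(np.isfinite(values)):
        raise ValidationError("input to ft_centered contains non-finite values")
    spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(values), norm="ortho"))
    wavelength, dx, dy = _calibration_of(field)
    return Spectrum(spec, wavelength=wavelength, dx=dx, dy=dy)


def ift_centered(spec) -> ComplexField:
    """Inverse of :func:`ft_centered`; same layout and normalisation."""
    values = as_array(spec)
    if not np.all(np.isfinite(values)):
        raise ValidationError("input to ift_centered contains non-finite values")
    out = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(values), norm="ortho"))
    wavelength, dx, dy = _calibration_of(spec)
    return ComplexField(out, wavelength=wavelength, dx=dx, dy=dy)


def _calibration_of(obj) -> Tuple[float, float, float]:
    if isinstance(obj, (ComplexField, Spectrum)):
        return obj.wavelength, obj.dx, obj.dy
    if isinstance(obj, RealImage):
        return 1.0, obj.dx or 1.0, obj.dy or 1.0
    return 1.0, 1.0, 1.0


# ---------------------------------------------------------------------------
# display-ready maps
# ---------------------------------------------------------------------------

def amplitude(field, log: bool = False) -> RealImage:
    """|u|, optionally log10(1 + |u|) for display."""
    a = np.abs(as_array(field))
    if log:
        a = np.log10(1.0 + a)
    return RealImage(a)


def intensity(field, log: bool = False) -> RealImage:
    """|u|^2, optionally log10(1 + |u|^2)."""
    i = np.abs(as_array(field)) ** 2
    if log:
        i = np.log10(1.0 + i)
    return RealImage(i)


def phase(field) -> RealImage:
    """Four-quadrant arctangent of the wavefield, in (-pi, pi].

    The phase of an exactly-zero sample is 0 by convention.
    """
    return RealImage(np.angle(as_array(field)))


# ---------------------------------------------------------------------------
# spectral filters
# ---------------------------------------------------------------------------

@dataclass
class CircularFilter:
    """Circular pass-band: ``radius`` px around ``center`` = (row, col)."""

    radius: float
    center: Tuple[float, float]

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        if self.radius < 1:
            raise ValidationError(f"filter radius must be >= 1 px, got {self.radius}")
        M, N = shape
        r0, c0 = self.center
        if not (0 <= r0 < M and 0 <= c0 < N):
            raise ValidationError(f"filter centre {self.center} outside {shape} array")
        rr = np.arange(M)[:, None] - r0
        cc = np.arange(N)[None, :] - c0
        return (rr * rr + cc * cc) <= self.radius * self.radius

    @property
    def mask_center(self) -> Tuple[float, float]:
        return self.center


@dataclass
class RectangularFilter:
    """Rectangular pass-band with corners (x1, y1) upper-left and (x2, y2)
    lower-right, where x is the column index and y the row index."""

    x1: int
    y1: int
    x2: int
    y2: int

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        M, N = shape
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValidationError("rectangular filter requires x2 > x1 and y2 > y1")
        if self.x1 < 0 or self.y1 < 0 or self.x2 > N - 1 or self.y2 > M - 1:
            raise ValidationError(
                f"rectangle ({self.x1},{self.y1})-({self.x2},{self.y2}) outside {shape} array"
            )
        m = np.zeros(shape, dtype=bool)
        m[self.y1 : self.y2 + 1, self.x1 : self.x2 + 1] = True
        return m

    @property
    def mask_center(self) -> Tuple[float, float]:
        return ((self.y1 + self.y2) / 2.0, (self.x1 + self.x2) / 2.0)


FilterSpec = Union[CircularFilter, RectangularFilter]


def spatial_filter(
    holo,
    spec: FilterSpec,
    keep_centered: bool = False,
    wavelength: Optional[float] = None,
) -> ComplexField:
    """Mask the hologram spectrum and inverse-transform the kept region.

    The mask is 1 inside the filter region and 0 outside.  With
    ``keep_centered`` the kept region is first rolled so the filter centre
    sits on the DC bin, demodulating the carrier by translation.
    """
    values = as_array(holo)
    S = ft_centered(holo)
    mask = spec.mask(values.shape)
    masked = np.where(mask, S.values, 0.0)
    if keep_centered:
        M, N = values.shape
        r0, c0 = spec.mask_center
        masked = np.roll(
            masked, (M // 2 - int(round(r0)), N // 2 - int(round(c0))), axis=(0, 1)
        )
    wl, dx, dy = _calibration_of(holo)
    if wavelength is not None:
        wl = wavelength
    return ift_centered(Spectrum(masked, wavelength=wl, dx=dx, dy=dy))


def manual_rectangular_filter(holo, corners=None, keep_centered: bool = False, **kwargs):
    """Coordinate-driven replacement for the interactive rectangle selector.

    ``corners`` is (x1, y1, x2, y2).  An interactive hook may call this with
    coordinates picked from a display; headless callers pass them directly.
    """
    if corners is None:
        raise ValidationError(
            "manual_rectangular_filter requires corners=(x1, y1, x2, y2) in "
            "non-interactive use"
        )
    x1, y1, x2, y2 = corners
    return spatial_filter(
        holo, RectangularFilter(x1, y1, x2, y2), keep_centered=keep_centered, **kwargs
    )


# ---------------------------------------------------------------------------
# diffraction-order peak search
# ---------------------------------------------------------------------------

def find_order_peak(
    spec: Spectrum,
    upper: bool = True,
    dc_exclusion_radius: Optional[float] = None,
) -> Tuple[int, int]:
    """Locate the brightest bin of the +1 (or -1) diffraction order.

    The search is restricted to the half-plane of rows strictly above
    (``upper=True``) or below the DC row, with a disc of
    ``dc_exclusion_radius`` px (default min(M, N)/20) zeroed around DC.
    Ties break to the row-major first occurrence.
    """
    values = np.abs(as_array(spec))
    M, N = values.shape
    cr, cc = M // 2, N // 2
    if dc_exclusion_radius is None:
        dc_exclusion_radius = min(M, N) / 20.0
    if dc_exclusion_radius < 1:
        raise ValidationError("dc_exclusion_radius must be >= 1 px")
    rr = np.arange(M)[:, None] - cr
    cc_ = np.arange(N)[None, :] - cc
    search = values.copy()
    search[(rr * rr + cc_ * cc_) <= dc_exclusion_radius**2] = 0.0
    if upper:
        search[cr:, :] = 0.0
    else:
        search[: cr + 1, :] = 0.0
    if not np.any(search > 0):
        raise ValidationError("no diffraction order found in the selected half-plane")
    idx = int(np.argmax(search))
    return (idx // N, idx % N)


# ---------------------------------------------------------------------------
# speckle reduction
# ---------------------------------------------------------------------------

def hybrid_median_mean(img, kernel: int) -> RealImage:
    """Hybrid median-mean speckle filter.

    Averages median-filtered copies of the image computed at every odd window
    size 3, 5, ..., ``kernel``.  ``kernel`` is the largest window; with
    kernel=3 this is a plain 3x3 median filter.  The output range never
    exceeds the input range.
    """
    values = as_array(img).astype(float)
    M, N = values.shape
    if kernel % 2 == 0 or kernel < 3:
        raise ValidationError(f"kernel must be an odd integer >= 3, got {kernel}")
    if kernel > min(M, N):
        raise ValidationError(f"kernel {kernel} exceeds image extent {min(M, N)}")
    acc = np.zeros_like(values)
    sizes = range(3, kernel + 1, 2)
    for size in sizes:
        acc += ndimage.median_filter(values, size=size, mode="nearest")
    out = acc / len(list(sizes))
    dx = img.dx if isinstance(img, RealImage) else None
    dy = img.dy if isinstance(img, RealImage) else None
    return RealImage(out, dx=dx, dy=dy)


# ---------------------------------------------------------------------------
# complex-field persistence: two-plane float32 TIFF + text sidecar
# ---------------------------------------------------------------------------

def save_complex_field(path: Union[str, os.PathLike], field: ComplexField) -> None:
    """Persist a ComplexField as a two-page float32 TIFF (real, imaginary)
    plus a ``<path>.hdr`` text sidecar carrying wavelength and pitches."""
    import tifffile

    path = os.fspath(path)
    planes = np.stack(
        [field.values.real.astype(np.float32), field.values.imag.astype(np.float32)]
    )
    tifffile.imwrite(path, planes)
    with open(path + ".hdr", "w") as fh:
        fh.write(f"wavelength={field.wavelength!r}\n")
        fh.write(f"dx={field.dx!r}\n")
        fh.write(f"dy={field.dy!r}\n")


def load_complex_field(path: Union[str, os.PathLike]) -> ComplexField:
    import tifffile

    path = os.fspath(path)
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise IOError(f"{path!r} is not a two-plane complex-field TIFF")
    meta = {}
    try:
        with open(path + ".hdr") as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.strip().split("=", 1)
                    meta[k] = float(v)
    except FileNotFoundError:
        pass
    return ComplexField(
        planes[0].astype(float) + 1j * planes[1].astype(float),
        wavelength=meta.get("wavelength", 1.0),
        dx=meta.get("dx", 1.0),
        dy=meta.get("dy", 1.0),
    )
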