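"""Numerical diffraction of complex wavefields.

Three propagators are provided:

* :func:`angular_spectrum` — exact scalar propagation within the sampled
  band; output grid equals the input grid.
* :func:`fresnel` — single-transform paraxial propagator; the output pixel
  pitch is fixed by the sampling relation ``dxout = wavelength*|z|/(N*dx)``.
* :func:`fresnel_bluestein` — chirp-z evaluation of the Fresnel transform on
  an output grid of arbitrary pitch, i.e. selectable magnification.

Sign convention: the plane-wave kernel is exp(-i*2*pi*z/wavelength * sqrt(1 -
wavelength^2*(u^2+v^2))) and the Fresnel chirps are exp(-i*pi/(wavelength*z) *
r^2); positive z propagates from the hologram toward focus, negative z is
allowed everywhere.  Global constant phase factors (e.g. -i*exp(ikz)) are
dropped; phases are meaningful up to one global piston.
"""

from __future__ import annotations

import numpy as np

from .core import ComplexField, ValidationError, centered_coords, centered_freqs

__all__ = ["angular_spectrum", "fresnel", "fresnel_bluestein"]


def angular_spectrum(field: ComplexField, z: float) -> ComplexField:
    """Propagate by multiplying the centred spectrum with the plane-wave
    transfer function.  Evanescent bins (wavelength^2*(u^2+v^2) > 1) are
    zeroed."""
    from .utilities import ft_centered, ift_centered

    if not np.isfinite(z):
        raise ValidationError("propagation distance z must be finite")
    lam = field.wavelength
    u, v = centered_freqs(field.shape, field.dx, field.dy)
    arg = 1.0 - lam * lam * (u * u + v * v)
    kernel = np.where(
        arg > 0.0,
        np.exp(-2j * np.pi * z / lam * np.sqrt(np.maximum(arg, 0.0))),
        0.0,
    )
    S = ft_centered(field)
    out = ift_centered(
        type(S)(S.values * kernel, wavelength=lam, dx=field.dx, dy=field.dy)
    )
    return out


def _centered_dft(values: np.ndarray, sign: int) -> np.ndarray:
    """Plain (unnormalised) 2D DFT over centred indices with kernel
    exp(sign * 2j*pi*m*m'/N) per axis."""
    shifted = np.fft.ifftshift(values)
    if sign > 0:
        M, N = values.shape
        out = np.fft.ifft2(shifted) * (M * N)
    else:
        out = np.fft.fft2(shifted)
    return np.fft.fftshift(out)


def fresnel(field: ComplexField, z: float) -> ComplexField:
    """Single-transform Fresnel propagation.

    The output grid pitch is ``wavelength*|z|/(N*dx)`` per axis (the sampling
    relation of the discrete Fresnel transform) and is recorded in the
    returned calibration.  The amplitude prefactor dx*dy/(wavelength*|z|)
    makes the discrete chain energy preserving:
    sum(|out|^2)*dxout*dyout == sum(|in|^2)*dx*dy.
    """
    if z == 0:
        raise ValidationError("fresnel requires z != 0; use angular_spectrum for z = 0")
    lam = field.wavelength
    M, N = field.shape
    dx, dy = field.dx, field.dy
    dxout = lam * abs(z) / (N * dx)
    dyout = lam * abs(z) / (M * dy)

    x0, y0 = centered_coords(field.shape, dx, dy)
    chirp_in = np.exp(-1j * np.pi / (lam * z) * (x0 * x0 + y0 * y0))
    g = field.values * chirp_in
    G = _centered_dft(g, sign=1 if z > 0 else -1)
    x1, y1 = centered_coords(field.shape, dxout, dyout)
    chirp_out = np.exp(-1j * np.pi / (lam * z) * (x1 * x1 + y1 * y1))
    amp = dx * dy / (lam * abs(z))
    return ComplexField(amp * chirp_out * G, wavelength=lam, dx=dxout, dy=dyout)


def _chirp_z_axis(values: np.ndarray, alpha: float, axis: int) -> np.ndarray:
    """Evaluate out[m] = sum_{m'} values[m'] * exp(2j*alpha*m*m') over centred
    indices along ``axis`` via the Bluestein decomposition
    m*m' = (m^2 + m'^2 - (m - m')^2) / 2."""
    from scipy.signal import fftconvolve

    n = values.shape[axis]
    c = n // 2
    m = np.arange(n) - c
    quad = np.exp(1j * alpha * m * m)
    span = np.arange(-(n - 1), n)
    kern = np.exp(-1j * alpha * span * span)

    shape_a = [1, 1]
    shape_a[axis] = n
    shape_k = [1, 1]
    shape_k[axis] = 2 * n - 1
    a = values * quad.reshape(shape_a)
    full = fftconvolve(a, kern.reshape(shape_k), mode="full", axes=axis)
    sl = [slice(None), slice(None)]
    sl[axis] = slice(n - 1, 2 * n - 1)
    return full[tuple(sl)] * quad.reshape(shape_a)


def fresnel_bluestein(
    field: ComplexField, z: float, dxout: float, dyout: float
) -> ComplexField:
    """Fresnel propagation with a freely chosen output pixel pitch.

    The Fourier kernel of the Fresnel transform is evaluated by a chirp-z
    (Bluestein) convolution, so ``dxout``/``dyout`` — hence the lateral
    magnification of the propagated wavefield — can be chosen at will.  At
    the natural pitch ``wavelength*|z|/(N*dx)`` this coincides with
    :func:`fresnel`.
    """
    if z == 0:
        raise ValidationError("fresnel_bluestein requires z != 0")
    if not (dxout > 0 and dyout > 0):
        raise ValidationError("output pitches must be positive")
    lam = field.wavelength
    M, N = field.shape
    dx, dy = field.dx, field.dy

    x0, y0 = centered_coords(field.shape, dx, dy)
    chirp_in = np.exp(-1j * np.pi / (lam * z) * (x0 * x0 + y0 * y0))
    g = field.values * chirp_in

    alpha_x = np.pi * dx * dxout / (lam * z)
    alpha_y = np.pi * dy * dyout / (lam * z)
    G = _chirp_z_axis(g, alpha_y, axis=0)
    G = _chirp_z_axis(G, alpha_x, axis=1)

    x1, y1 = centered_coords(field.shape, dxout, dyout)
    chirp_out = np.exp(-1j * np.pi / (lam * z) * (x1 * x1 + y1 * y1))
    amp = dx * dy / (lam * abs(z))
    return ComplexField(amp * chirp_out * G, wavelength=lam, dx=dxout, dy=dyout)
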