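"""Forward model of hologram acquisition in a digital holographic microscope.

The model follows the standard image-plane description of a Mach-Zehnder
transmission microscope: the object wavefield at the image plane is

    u_IP(x, y) = [a(x, y) * exp(i*phi(x, y))]  (optionally pupil low-passed)
                 * exp(i*pi/(wavelength*C) * ((x-xC)^2 + (y-yC)^2))

where the quadratic factor with radius of curvature C appears only in
non-telecentric imaging (C = inf means telecentric: no quadratic phase).  The
recorded hologram is the irradiance of the interference with a tilted plane
reference of irradiance I_R, tilt sines (sin_tx, sin_ty) and phase shift
delta:

    h = |u + r|^2,   r = sqrt(I_R) * exp(i*(k*(sin_tx*x + sin_ty*y) + delta))

Defocus over a signed distance z (z < 0 in front of the image plane) is
realised by angular-spectrum propagation.  Optional additive Gaussian noise
(std ``noise_sigma``) on the irradiance is clipped at zero.  Constant phase
prefactors (global pistons) are dropped throughout: phases are relative.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import (
    ComplexField,
    RealImage,
    ValidationError,
    centered_coords,
    centered_freqs,
)
from .propagation import angular_spectrum

__all__ = [
    "AcquisitionConfig",
    "Phantom",
    "make_phantom",
    "image_plane_field",
    "reference_wave",
    "simulate_hologram",
    "simulate_ps_series",
    "write_fixture",
]


@dataclass
class AcquisitionConfig:
    """Full description of one simulated acquisition.

    Lengths share one unit (micrometres recommended).  Defaults emulate a
    red-laser microscope with a machine-vision sensor: wavelength 0.633 um,
    6.9 um pixels, 256x256 frames.
    """

    wavelength: float = 0.633
    dx: float = 6.9
    dy: float = 6.9
    shape: Tuple[int, int] = (256, 256)
    sin_tx: float = 0.0  # tilt sine along x (columns)
    sin_ty: float = 0.0  # tilt sine along y (rows)
    ref_irradiance: float = 1.0
    defocus: float = 0.0  # signed distance z from the image plane
    curvature: float = math.inf  # radius of curvature C; inf = telecentric
    curvature_center: Tuple[float, float] = (0.0, 0.0)  # (xC, yC), physical units
    numerical_aperture: Optional[float] = None  # pupil low-pass if set
    magnification: float = 1.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.wavelength > 0 and self.dx > 0 and self.dy > 0):
            raise ValidationError("wavelength and pixel pitches must be positive")
        if self.curvature == 0:
            raise ValidationError("curvature C must be nonzero (inf = telecentric)")
        if not self.ref_irradiance > 0:
            raise ValidationError("reference irradiance must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        nyq = self.wavelength / (2.0 * max(self.dx, self.dy))
        if abs(self.sin_tx) > nyq or abs(self.sin_ty) > nyq:
            raise ValidationError(
                "tilt sines put the carrier above Nyquist: "
                f"|sin| must be <= {nyq:.4g}"
            )

    @property
    def carrier_bins(self) -> Tuple[float, float]:
        """Carrier offset from DC in (row, col) frequency bins:
        (sin_ty*M*dy/wavelength, sin_tx*N*dx/wavelength)."""
        M, N = self.shape
        return (
            self.sin_ty * M * self.dy / self.wavelength,
            self.sin_tx * N * self.dx / self.wavelength,
        )

    @classmethod
    def from_carrier_bins(cls, rows: float, cols: float, **kwargs) -> "AcquisitionConfig":
        """Build a config whose carrier sits ``rows``/``cols`` bins from DC."""
        cfg = cls(**kwargs)
        M, N = cfg.shape
        return replace(
            cfg,
            sin_ty=rows * cfg.wavelength / (M * cfg.dy),
            sin_tx=cols * cfg.wavelength / (N * cfg.dx),
        )


@dataclass
class Phantom:
    """Ground-truth object: a phase map (radians) and a non-negative
    amplitude map on the acquisition grid."""

    phase: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValidationError("phantom phase and amplitude shapes differ")
        if not (np.all(np.isfinite(self.phase)) and np.all(np.isfinite(self.amplitude))):
            raise ValidationError("phantom maps must be finite")
        if np.any(self.amplitude < 0):
            raise ValidationError("phantom amplitude must be >= 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.phase.shape


def make_phantom(
    kind: str,
    size: Tuple[int, int] = (256, 256),
    peak_phase: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Deterministic test object with unit amplitude and phase in
    [0, peak_phase].

    Kinds
    -----
    ``disk``
        Hard-edged disk of radius min(M, N)/4; interior at ``peak_phase``.
    ``bars``
        Three vertical plus three horizontal bars (resolution-target style);
        bar width = min(M, N)//16, spacing one bar width.
    ``blobs``
        Sum of six Gaussian bumps with seeded random centres and widths,
        rescaled to peak at ``peak_phase``.  Spectrally compact; preferred
        for off-axis fixtures.
    ``star``
        Sixteen-spoke radial star inside radius min(M, N)/2.5.
    """
    if not np.isfinite(peak_phase):
        raise ValidationError("peak_phase must be finite")
    M, N = size
    rr = np.arange(M)[:, None] - M // 2
    cc = np.arange(N)[None, :] - N // 2
    if kind == "disk":
        radius = min(M, N) / 4.0
        phi = np.where(rr * rr + cc * cc <= radius * radius, peak_phase, 0.0)
    elif kind == "bars":
        w = max(2, min(M, N) // 16)
        phi = np.zeros((M, N))
        for i in range(3):
            c0 = N // 4 + 2 * i * w
            phi[M // 8 : M // 2, c0 : c0 + w] = peak_phase
            r0 = M // 2 + M // 16 + 2 * i * w
            if r0 + w <= M:
                phi[r0 : r0 + w, N // 4 : 3 * N // 4] = peak_phase
    elif kind == "blobs":
        rng = np.random.default_rng(seed)
        phi = np.zeros((M, N))
        for _ in range(6):
            r0 = rng.uniform(-M / 4, M / 4)
            c0 = rng.uniform(-N / 4, N / 4)
            s = rng.uniform(min(M, N) / 20, min(M, N) / 8)
            phi += np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s * s)))
        phi *= peak_phase / phi.max()
    elif kind == "star":
        theta = np.arctan2(rr, cc)
        radius = min(M, N) / 2.5
        spokes = np.cos(16 * theta) > 0
        phi = np.where(spokes & (rr * rr + cc * cc <= radius * radius), peak_phase, 0.0)
    else:
        raise ValidationError(f"unknown phantom kind {kind!r}")
    return Phantom(phase=phi, amplitude=np.ones((M, N)))


def image_plane_field(ph: Phantom, cfg: AcquisitionConfig) -> ComplexField:
    """Object wavefield at the image plane: a*exp(i*phi), optionally pupil
    low-passed, times the non-telecentric quadratic phase when C is finite."""
    if ph.shape != tuple(cfg.shape):
        raise ValidationError(f"phantom {ph.shape} does not match config grid {cfg.shape}")
    values = ph.amplitude * np.exp(1j * ph.phase)
    if cfg.numerical_aperture is not None:
        values = _pupil_lowpass(values, cfg)
    if math.isfinite(cfg.curvature):
        x, y = centered_coords(cfg.shape, cfg.dx, cfg.dy)
        xc, yc = cfg.curvature_center
        quad = np.exp(
            1j * np.pi / (cfg.wavelength * cfg.curvature)
            * ((x - xc) ** 2 + (y - yc) ** 2)
        )
        values = values * quad
    return ComplexField(values, wavelength=cfg.wavelength, dx=cfg.dx, dy=cfg.dy)


def _pupil_lowpass(values: np.ndarray, cfg: AcquisitionConfig) -> np.ndarray:
    """Circular pupil of cutoff u_c = NA/(wavelength*magnification) applied in
    the frequency domain."""
    u, v = centered_freqs(values.shape, cfg.dx, cfg.dy)
    cutoff = cfg.numerical_aperture / (cfg.wavelength * abs(cfg.magnification))
    mask = (u * u + v * v) <= cutoff * cutoff
    spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(values), norm="ortho"))
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec * mask), norm="ortho"))


def reference_wave(cfg: AcquisitionConfig, shift: float = 0.0) -> ComplexField:
    """Tilted plane reference sqrt(I_R)*exp(i*(k*(sin_tx*x + sin_ty*y) +
    shift)) on the centred grid."""
    x, y = centered_coords(cfg.shape, cfg.dx, cfg.dy)
    k = 2.0 * np.pi / cfg.wavelength
    values = np.sqrt(cfg.ref_irradiance) * np.exp(
        1j * (k * (cfg.sin_tx * x + cfg.sin_ty * y) + shift)
    )
    return ComplexField(values, wavelength=cfg.wavelength, dx=cfg.dx, dy=cfg.dy)


def simulate_hologram(
    ph: Phantom,
    cfg: AcquisitionConfig,
    shift: float = 0.0,
    seed: Optional[int] = 0,
    rng: Optional[np.random.Generator] = None,
) -> RealImage:
    """Record one hologram: h = |u + r|^2 (+ Gaussian noise, clipped at 0).

    The object field is defocused by angular-spectrum propagation when
    ``cfg.defocus`` is nonzero.  Pass an explicit ``rng`` to share one noise
    stream across a phase-shifted series.
    """
    u = image_plane_field(ph, cfg)
    if cfg.defocus != 0.0:
        u = angular_spectrum(u, cfg.defocus)
    r = reference_wave(cfg, shift)
    h = np.abs(u.values + r.values) ** 2
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        h = h + cfg.noise_sigma * rng.standard_normal(h.shape)
        h = np.clip(h, 0.0, None)
    return RealImage(h, dx=cfg.dx, dy=cfg.dy)


def simulate_ps_series(
    ph: Phantom,
    cfg: AcquisitionConfig,
    shifts: Sequence[float],
    seed: Optional[int] = 0,
):
    """Phase-shifted series: one hologram per reference shift, drawn from a
    single seeded noise stream so frames are independent but reproducible."""
    if len(shifts) == 0:
        raise ValidationError("shift list must not be empty")
    rng = np.random.default_rng(seed)
    return [simulate_hologram(ph, cfg, shift=s, rng=rng) for s in shifts]


def write_fixture(
    directory: str,
    frames: Sequence[RealImage],
    ph: Phantom,
    cfg: AcquisitionConfig,
    shifts: Sequence[float] = (),
) -> None:
    """Save a hologram stack as multi-page float32 TIFF plus ground truth:
    the phantom phase (float TIFF) and the config as key=value text."""
    import tifffile

    os.makedirs(directory, exist_ok=True)
    stack = np.stack([f.pixels.astype(np.float32) for f in frames])
    tifffile.imwrite(os.path.join(directory, "holograms.tif"), stack)
    tifffile.imwrite(
        os.path.join(directory, "phantom_phase.tif"), ph.phase.astype(np.float32)
    )
    with open(os.path.join(directory, "config.txt"), "w") as fh:
        for key in (
            "wavelength",
            "dx",
            "dy",
            "sin_tx",
            "sin_ty",
            "ref_irradiance",
            "defocus",
            "curvature",
            "noise_sigma",
        ):
            fh.write(f"{key}={getattr(cfg, key)!r}\n")
        fh.write(f"shape={cfg.shape[0]}x{cfg.shape[1]}\n")
        if len(shifts):
            fh.write("shifts=" + ",".join(f"{s!r}" for s in shifts) + "\n")
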