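"""Numerical refocusing: propagate a circular aperture to the far field.

The Fresnel propagator's first intensity zero should sit at the Airy radius
1.22*wavelength*z/D; the Fresnel-Bluestein propagator reproduces the same
field at the natural output pitch and lets you change the magnification.
"""

import numpy as np

import dhmkit as dk

n, dx, lam = 256, 5.0, 0.633
r = np.arange(n)[:, None] - n // 2
c = np.arange(n)[None, :] - n // 2
aperture = dk.ComplexField(((r**2 + c**2) <= 32**2).astype(complex),
                           wavelength=lam, dx=dx, dy=dx)
z = 450_000.0  # 45 cm
out = dk.fresnel(aperture, z)
profile = np.abs(out.values[n // 2, n // 2:]) ** 2
first_zero = next(i for i in range(1, len(profile) - 1)
                  if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1])
airy = 1.22 * lam * z / (64 * dx) / out.dx
print(f"output pixel pitch:   {out.dx:.1f} um (natural pitch)")
print(f"first zero measured:  {first_zero} px;  Airy prediction: {airy:.2f} px")

blue = dk.fresnel_bluestein(aperture, z, out.dx, out.dx)
piston = np.angle((blue.values * np.conj(out.values)).sum())
rms = np.sqrt(np.mean(np.abs(blue.values - out.values * np.exp(1j * piston)) ** 2))
print(f"Bluestein vs Fresnel RMS at natural pitch: {rms:.2e}")

zoom = dk.fresnel_bluestein(aperture, z, out.dx / 4, out.dx / 4)
print(f"zoomed reconstruction pitch: {zoom.dx:.1f} um "
      f"(4x finer sampling of the same diffraction pattern)")
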