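"""In-line phase shifting: record five pi/2-shifted holograms of a disk
phantom and recover its phase with the five-step estimator.

The printed spread is the maximum deviation of (recovered - true) phase from
a single global constant: for noiseless data it sits at machine precision.
"""

import numpy as np

import dhmkit as dk

phantom = dk.make_phantom("disk", (256, 256), peak_phase=1.2)
cfg = dk.AcquisitionConfig(shape=(256, 256))  # zero tilt: in-line geometry

shifts = [0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi]
frames = dk.simulate_ps_series(phantom, cfg, shifts)
recovered = dk.ps5(*[f.pixels for f in frames]).pixels

diff = np.exp(1j * (recovered - phantom.phase))
spread = np.abs(np.angle(diff * np.exp(-1j * np.angle(diff.sum())))).max()
print(f"frames recorded:        {len(frames)}")
print(f"phase spread vs truth:  {spread:.2e} rad  (constant offset removed)")
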