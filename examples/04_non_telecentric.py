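"""Non-telecentric compensation: remove the quadratic phase factor.

A hologram is simulated with a spherical aberration of radius of curvature
C = 12.3 cm.  The non-telecentric search filters the +1 order with a
rectangle, cancels the carrier, and estimates (xC, yC, C) by maximising the
compensation metric.
"""

import numpy as np

import dhmkit as dk

C_TRUE = 123000.0  # micrometres
phantom = dk.make_phantom("blobs", (256, 256), peak_phase=1.5, seed=3)
cfg = dk.AcquisitionConfig.from_carrier_bins(55, 45, curvature=C_TRUE)
holo = dk.simulate_hologram(phantom, cfg)

peak = (128 - 55, 128 - 45)
rect = dk.RectangularFilter(x1=peak[1] - 28, y1=peak[0] - 28,
                            x2=peak[1] + 28, y2=peak[0] + 28)
res = dk.cnt(holo, cfg.wavelength, cfg.dx, cfg.dy, filter_rect=rect)

q = res.quadratic
print(f"true C:      {C_TRUE:.0f} um")
print(f"estimated C: {q.curvature:.0f} um "
      f"({100 * abs(q.curvature - C_TRUE) / C_TRUE:.2f}% error)")
print(f"estimated centre (xC, yC): ({q.center[0]:.1f}, {q.center[1]:.1f}) um "
      f"(truth: (0, 0))")
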