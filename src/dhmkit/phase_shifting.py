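"""Phase-shifting reconstruction for in-line and slightly off-axis systems.

Known-shift estimators
----------------------
* :func:`ps5` — five frames at reference shifts {0, pi/2, pi, 3pi/2, 2pi}.
* :func:`ps4` — four frames at {0, pi/2, pi, 3pi/2}.
* :func:`ps3` — three frames at reference phases {pi/3, pi, 5pi/3}
  (inter-frame shift 2*pi/3).  The numerator factor is sqrt(3): with cosine
  fringes A + B*cos(phi - delta) the three-frame identity gives
  h(pi/3) - h(5pi/3) = sqrt(3)*B*sin(phi) and
  h(5pi/3) + h(pi/3) - 2*h(pi) = 3*B*cos(phi), so
  phi = atan2(sqrt(3)*(h0 - h2), h0 + h2 - 2*h1) exactly.
* :func:`sosr` — quadrature (four-frame, pi/2) synthesis of the complex
  field for slightly off-axis geometry, with an automatic grid search for
  the digital reference tilt.

Blind estimators (unknown shifts, slightly off-axis, telecentric)
-----------------------------------------------------------------
* :func:`bps3` — three frames; the shifts and the three spectral components
  {d0, d+1, d-1} of h = d0 + exp(-i*dt)*d+1 + exp(i*dt)*d-1 are estimated
  jointly by minimising the carrier-leakage cost of d0.
* :func:`bps2` — two frames; the pair {d0, d3} of h = d0 + exp(i*dt)*d3 is
  estimated the same way; the +1 lobe of d3 is then spatially filtered.

The leakage cost is |FT(d0)| summed over 3x3 neighbourhoods of the carrier
bins, normalised by |FT(d0)| at DC: it vanishes exactly when no object
energy leaks into d0, i.e. at the true shifts on noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ComplexField, RealImage, ValidationError, as_array, centered_coords
from .phase_compensation import (
    CompensationResult,
    _score,
    digital_reference,
    remove_piston,
    threshold_metric,
    tilt_sines_of_peak,
)
from .utilities import CircularFilter, find_order_peak, ft_centered, spatial_filter

__all__ = [
    "PSComponents",
    "BlindPSResult",
    "ps5",
    "ps4",
    "ps3",
    "sosr",
    "demodulate_3frame",
    "bps3",
    "bps2",
]


def _frames(*imgs) -> List[np.ndarray]:
    arrays = [np.asarray(as_array(i), dtype=float) for i in imgs]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValidationError("all phase-shifted frames must share one shape")
    return arrays


def _atan2_phase(num: np.ndarray, den: np.ndarray) -> RealImage:
    # atan2(0, 0) = 0: the degenerate (fringe-free) pixel convention
    return RealImage(np.arctan2(num, den))


def ps5(h0, h1, h2, h3, h4) -> RealImage:
    """Five-step phase reconstruction, shifts {0, pi/2, pi, 3pi/2, 2pi}:
    phi = atan2(2*(h3 - h1), 2*h2 - h0 - h4), wrapped to (-pi, pi]."""
    a0, a1, a2, a3, a4 = _frames(h0, h1, h2, h3, h4)
    return _atan2_phase(2.0 * (a3 - a1), 2.0 * a2 - a0 - a4)


def ps4(h0, h1, h2, h3) -> RealImage:
    """Four-step phase reconstruction, shifts {0, pi/2, pi, 3pi/2}:
    phi = atan2(h3 - h1, h2 - h0)."""
    a0, a1, a2, a3 = _frames(h0, h1, h2, h3)
    return _atan2_phase(a3 - a1, a2 - a0)


def ps3(h0, h1, h2) -> RealImage:
    """Three-step phase reconstruction at reference phases {pi/3, pi, 5pi/3}
    (inter-frame shift 2*pi/3): phi = atan2(sqrt(3)*(h0 - h2),
    h0 + h2 - 2*h1)."""
    a0, a1, a2 = _frames(h0, h1, h2)
    return _atan2_phase(math.sqrt(3.0) * (a0 - a2), a0 + a2 - 2.0 * a1)


# ---------------------------------------------------------------------------
# quadrature method with ROI search (slightly off-axis, pi/2 shifts)
# ---------------------------------------------------------------------------

def sosr(
    h0,
    h1,
    h2,
    h3,
    upper: bool = True,
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
    s: int = 1,
    steps: int = 4,
    threshold: float = 0.2,
) -> CompensationResult:
    """Quadrature phase-shifting synthesis with automatic tilt search.

    The object field is recovered as u = sum_m h_m * r_m where r_m is the
    digital tilted reference at shift m*pi/2 and candidate carrier; the DC
    and conjugate terms cancel through the quadrature phase factors.  The
    candidate tilts form a steps x steps grid over a (1+2s)-pixel region of
    interest centred on the brightest spectral bin of the selected
    half-plane; the candidate maximising the compensation metric wins.
    """
    if steps < 2:
        raise ValidationError(f"steps must be >= 2, got {steps}")
    if s < 1:
        raise ValidationError(f"s must be >= 1, got {s}")
    arrays = _frames(h0, h1, h2, h3)
    M, N = arrays[0].shape
    img0 = RealImage(arrays[0], dx=dx, dy=dy)
    peak = find_order_peak(ft_centered(img0), upper=upper)

    # quadrature synthesis: sum h_m * exp(i*m*pi/2) collapses the series to a
    # single complex frame; the candidate tilt is a pure multiplication
    synth = sum(a * np.exp(1j * m * np.pi / 2.0) for m, a in enumerate(arrays))

    offsets = np.linspace(-s, s, steps)
    best = None
    evaluations = 0
    for dr in offsets:
        for dc in offsets:
            cand = (peak[0] + dr, peak[1] + dc)
            ref = digital_reference((M, N), wavelength, dx, dy, cand)
            vals = synth * ref.values
            m = _score(vals, threshold)
            evaluations += 1
            if best is None or m > best[0]:
                best = (m, cand, vals)
    m, cand, vals = best
    return CompensationResult(
        field=ComplexField(vals, wavelength=wavelength, dx=dx, dy=dy),
        carrier_peak=cand,
        tilt_sines=tilt_sines_of_peak((M, N), wavelength, dx, dy, cand),
        metric=m,
        evaluations=evaluations,
    )


# ---------------------------------------------------------------------------
# blind phase shifting
# ---------------------------------------------------------------------------

@dataclass
class PSComponents:
    """Spectral components of a phase-shifted series: h_m = d0 +
    exp(-i*theta_m)*d_plus1 + exp(i*theta_m)*d_minus1."""

    d0: np.ndarray
    d_plus1: np.ndarray
    d_minus1: np.ndarray
    shifts: Tuple[float, ...]

    def reconstruct(self, m: int) -> np.ndarray:
        t = self.shifts[m]
        return self.d0 + np.exp(-1j * t) * self.d_plus1 + np.exp(1j * t) * self.d_minus1


@dataclass
class BlindPSResult:
    """Carrier-compensated object field plus the estimated shifts and the
    leakage cost at the optimum."""

    field: ComplexField
    shifts: Tuple[float, ...]
    cost: float
    evaluations: int = 0


def demodulate_3frame(h0, h1, h2, shifts: Sequence[float]) -> PSComponents:
    """Pixel-wise solve of the 3x3 linear system for (d0, d+1, d-1) given
    three frames and their reference shifts (distinct modulo 2*pi)."""
    arrays = _frames(h0, h1, h2)
    t = np.asarray(shifts, dtype=float)
    if t.shape != (3,):
        raise ValidationError("demodulate_3frame needs exactly three shifts")
    A = np.stack([np.ones(3), np.exp(-1j * t), np.exp(1j * t)], axis=1)
    det = np.linalg.det(A)
    if abs(det) < 1e-8:
        raise ValidationError(f"singular demodulation system for shifts {shifts}")
    Ainv = np.linalg.inv(A)
    H = np.stack([a.ravel() for a in arrays])
    D = Ainv @ H
    shape = arrays[0].shape
    return PSComponents(
        d0=D[0].reshape(shape),
        d_plus1=D[1].reshape(shape),
        d_minus1=D[2].reshape(shape),
        shifts=tuple(t),
    )


def _carrier_bins(img0: RealImage, min_separation: float = 1.5):
    """Locate the +1 peak (upper half-plane) and its mirrored -1 peak;
    reject quasi-in-line data whose peak hugs the DC exclusion disc."""
    S = ft_centered(img0)
    M, N = img0.shape
    peak_up = find_order_peak(S, upper=True)
    cr, cc = M // 2, N // 2
    dist = math.hypot(peak_up[0] - cr, peak_up[1] - cc)
    if dist <= min_separation * min(M, N) / 20.0:
        raise ValidationError(
            "no diffraction order found: the carrier is too close to DC for a "
            "slightly off-axis reconstruction"
        )
    peak_down = (2 * cr - peak_up[0], 2 * cc - peak_up[1])
    return peak_up, peak_down


def _leakage_cost(d0: np.ndarray, peaks) -> float:
    """|FT(d0)| summed over 3x3 neighbourhoods of the carrier bins,
    normalised by |FT(d0)| at DC."""
    S = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(d0), norm="ortho")))
    M, N = S.shape
    dc = S[M // 2, N // 2]
    if dc == 0:
        dc = S.max() or 1.0
    total = 0.0
    for (pr, pc) in peaks:
        r0, c0 = int(round(pr)), int(round(pc))
        total += S[max(0, r0 - 1) : r0 + 2, max(0, c0 - 1) : c0 + 2].sum()
    return float(total / dc)


def _coordinate_descent(cost, x0, width, tol=1e-4, max_iter=200, points=7):
    """Deterministic derivative-free minimiser: per-coordinate bracketed grid
    refinement with a shrinking bracket."""
    x = list(x0)
    fx = cost(x)
    evaluations = 1
    w = float(width)
    it = 0
    while w > tol and it < max_iter:
        it += 1
        improved = False
        for i in range(len(x)):
            grid = np.linspace(x[i] - w, x[i] + w, points)
            for g in grid:
                trial = list(x)
                trial[i] = g
                f = cost(trial)
                evaluations += 1
                if f < fx:
                    fx, x = f, trial
                    improved = True
        if not improved:
            w *= 0.5
    return x, fx, evaluations


def _compensate_component(
    comp: np.ndarray, wavelength: float, dx: float, dy: float, upper: bool = True
) -> Tuple[np.ndarray, Tuple[int, int]]:
    spec = ft_centered(ComplexField(comp, wavelength=wavelength, dx=dx, dy=dy))
    peak = find_order_peak(spec, upper=upper)
    ref = digital_reference(comp.shape, wavelength, dx, dy, peak)
    return comp * ref.values, peak


def bps3(
    h0,
    h1,
    h2,
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
) -> BlindPSResult:
    """Blind three-frame phase shifting.

    The shifts (0, t2, t3) are estimated by minimising the leakage of object
    energy into the demodulated d0 component at the +-1 carrier bins.  The
    search is seeded from inter-frame correlations (which fix cos(t) up to
    sign; all four sign combinations are tried) and refined by deterministic
    coordinate descent.  The object-bearing component — whichever of d+1 /
    d-1 peaks in the upper half-plane — is carrier-compensated with the
    digital reference wave and returned.
    """
    arrays = _frames(h0, h1, h2)
    img0 = RealImage(arrays[0], dx=dx, dy=dy)
    peaks = _carrier_bins(img0)

    def cost(t):
        try:
            comps = demodulate_3frame(
                arrays[0], arrays[1], arrays[2], (0.0, t[0], t[1])
            )
        except ValidationError:
            return np.inf  # singular shift combination: outside the domain
        return _leakage_cost(comps.d0, peaks)

    seeds = _correlation_seeds(arrays)
    # rank the four sign combinations by their initial cost and refine the
    # two most promising ones
    seeds.sort(key=lambda s: cost(s))
    best = None
    total_evals = len(seeds)
    for seed in seeds[:2]:
        try:
            x, f, n = _coordinate_descent(cost, seed, width=0.5)
        except ValidationError:
            continue
        total_evals += n
        if best is None or f < best[1]:
            best = (x, f)
    if best is None:
        raise ValidationError("blind shift estimation failed to converge")
    (t2, t3), fopt = best[0], best[1]
    comps = demodulate_3frame(arrays[0], arrays[1], arrays[2], (0.0, t2, t3))

    # sign convention: the +1 lobe (upper half-plane) carries the object
    obj = comps.d_plus1
    if _upper_energy(comps.d_minus1) > _upper_energy(comps.d_plus1):
        obj = comps.d_minus1
        comps = PSComponents(
            d0=comps.d0,
            d_plus1=comps.d_minus1,
            d_minus1=comps.d_plus1,
            shifts=(0.0, -t2 % (2 * np.pi), -t3 % (2 * np.pi)),
        )
        t2, t3 = comps.shifts[1], comps.shifts[2]
    vals, _ = _compensate_component(obj, wavelength, dx, dy)
    return BlindPSResult(
        field=ComplexField(remove_piston(vals), wavelength=wavelength, dx=dx, dy=dy),
        shifts=(0.0, t2 % (2 * np.pi), t3 % (2 * np.pi)),
        cost=fopt,
        evaluations=total_evals,
    )


def _upper_energy(comp: np.ndarray) -> float:
    S = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(comp))))
    M = S.shape[0]
    return float(S[: M // 2, :].sum())


def _correlation_seeds(arrays: List[np.ndarray]) -> List[List[float]]:
    """cos(t_m) estimated from zero-mean inter-frame correlations; both signs
    of each shift are plausible, so return every combination."""
    a0 = arrays[0] - arrays[0].mean()
    n0 = float(np.sqrt((a0 * a0).sum())) or 1.0
    cos_t = []
    for a in arrays[1:]:
        am = a - a.mean()
        nm = float(np.sqrt((am * am).sum())) or 1.0
        cos_t.append(float(np.clip((a0 * am).sum() / (n0 * nm), -1.0, 1.0)))
    angles = [math.acos(c) for c in cos_t]
    seeds = []
    for s2 in (+1, -1):
        for s3 in (+1, -1):
            seeds.append([s2 * angles[0] % (2 * math.pi), s3 * angles[1] % (2 * math.pi)])
    return seeds


def bps2(
    h0,
    h1,
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
) -> BlindPSResult:
    """Blind two-frame phase shifting.

    The two frames are modelled as h1 = d0 + d3 and h2 = d0 + exp(i*dt)*d3,
    so d3 = (h2 - h1)/(exp(i*dt) - 1) and d0 = h1 - d3.  The shift dt is
    estimated by minimising the leakage of the object lobe into d0; the +1
    lobe of the recovered d3 is then spatially filtered (it must not overlap
    the -1 lobe) and carrier-compensated.  Identical frames (dt -> 0) make
    the decomposition singular and raise a validation error.
    """
    a0, a1 = _frames(h0, h1)
    if float(np.max(np.abs(a1 - a0))) < 1e-12 * max(1.0, float(np.max(np.abs(a0)))):
        raise ValidationError(
            "singular two-frame decomposition: the frames are identical "
            "(phase shift ~ 0 modulo 2*pi)"
        )
    img0 = RealImage(a0, dx=dx, dy=dy)
    peak_up, peak_down = _carrier_bins(img0)
    diff = a1 - a0

    def decompose(dt: float):
        d3 = diff / (np.exp(1j * dt) - 1.0)
        return a0 - d3, d3

    def cost(t):
        dt = float(t[0])
        if not 0.05 < dt % (2 * math.pi) < 2 * math.pi - 0.05:
            return np.inf
        d0, _ = decompose(dt)
        return _leakage_cost(d0, [peak_up])

    # coarse scan then bracketed refinement; the landscape is 2*pi periodic
    grid = np.linspace(0.1, 2 * math.pi - 0.1, 64)
    coarse = [cost([g]) for g in grid]
    t0 = float(grid[int(np.argmin(coarse))])
    (dt_hat,), fopt, evals = _coordinate_descent(cost, [t0], width=float(grid[1] - grid[0]))
    evals += len(grid)

    _, d3 = decompose(dt_hat)
    d3_field = ComplexField(d3, wavelength=wavelength, dx=dx, dy=dy)
    _check_disjoint_orders(d3, peak_up, peak_down)

    M, N = d3.shape
    dist = math.hypot(peak_up[0] - M // 2, peak_up[1] - N // 2)
    radius = max(2.0, 2.0 * dist / 3.0)
    spec = ft_centered(d3_field)
    refined = find_order_peak(spec, upper=True)
    filt = spatial_filter(d3_field, CircularFilter(radius, refined), wavelength=wavelength)
    vals, _ = _compensate_component(filt.values, wavelength, dx, dy)
    return BlindPSResult(
        field=ComplexField(remove_piston(vals), wavelength=wavelength, dx=dx, dy=dy),
        shifts=(0.0, dt_hat % (2 * math.pi)),
        cost=float(fopt),
        evaluations=evals,
    )


def _check_disjoint_orders(d3: np.ndarray, peak_up, peak_down, rel_threshold=0.01):
    """The two-frame method needs the +-1 supports disjoint in the Fourier
    domain.  The d3 component contains only the two lobes (no DC), so any
    energy at their midpoint comes from colliding lobe tails: refuse when the
    spectral amplitude within a disc of radius dist/4 around the midpoint
    exceeds ``rel_threshold`` of the +1 peak amplitude."""
    S = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(d3))))
    M, N = S.shape
    pu = (int(round(peak_up[0])), int(round(peak_up[1])))
    mid = ((peak_up[0] + peak_down[0]) / 2.0, (peak_up[1] + peak_down[1]) / 2.0)
    dist = math.hypot(peak_up[0] - mid[0], peak_up[1] - mid[1])
    rr = np.arange(M)[:, None] - mid[0]
    cc = np.arange(N)[None, :] - mid[1]
    disc = (rr * rr + cc * cc) <= (dist / 4.0) ** 2
    if S[disc].max() > rel_threshold * S[pu]:
        raise ValidationError(
            "the +1 and -1 diffraction orders overlap in the Fourier domain; "
            "the two-frame blind method requires disjoint supports"
        )
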