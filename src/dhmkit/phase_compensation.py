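"""Single-shot off-axis phase reconstruction with automatic carrier
compensation.

Telecentric holograms: :func:`frs` (exhaustive grid over a region of interest
around the +1 spectral peak), :func:`ers` (path-oriented local refinement of
the same search), :func:`cfs` (continuous derivative-free minimisation of the
inverse compensation metric).  Non-telecentric holograms: :func:`cnt`, which
additionally estimates and removes the quadratic phase factor
exp(i*pi/(wavelength*C)*((x-xC)^2 + (y-yC)^2)).

All searches score candidates with the summation-and-thresholding metric
(:func:`threshold_metric`): the wrapped phase is normalised to [0, 1],
binarised, and the surviving pixels counted — a fringe-free (well
compensated) phase map maximises the count.  Before scoring, the global
piston of each candidate field is removed (the phase origin is arbitrary
after spatial filtering), which makes the metric a piston-invariant,
single-peaked function of the residual carrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize

from .core import (
    ComplexField,
    RealImage,
    Spectrum,
    ValidationError,
    as_array,
    centered_coords,
)
from .utilities import (
    CircularFilter,
    RectangularFilter,
    find_order_peak,
    ft_centered,
    spatial_filter,
)

__all__ = [
    "ROISearchParams",
    "QuadraticPhaseEstimate",
    "CompensationResult",
    "digital_reference",
    "threshold_metric",
    "remove_piston",
    "frs",
    "ers",
    "cfs",
    "cnt",
]


@dataclass
class ROISearchParams:
    """Search-grid description: the region of interest spans 1+2s pixels per
    dimension around the spectral peak and is sampled at step^2 equidistant
    candidate carriers (endpoints included; candidates may be fractional)."""

    s: int = 2
    step: int = 10
    upper: bool = True

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValidationError(f"ROI half-size s must be >= 1, got {self.s}")
        if self.step < 2:
            raise ValidationError(f"step must be >= 2, got {self.step}")

    @property
    def roi_side(self) -> int:
        return 1 + 2 * self.s

    @property
    def candidate_count(self) -> int:
        return self.step**2


@dataclass
class QuadraticPhaseEstimate:
    """Estimated non-telecentric aberration: radius of curvature C and
    centre (xC, yC) in physical units.  C = inf denotes a vanishing
    quadratic coefficient (telecentric limit)."""

    curvature: float
    center: Tuple[float, float]
    provenance: str = "automatic"  # "user" | "automatic"

    def __post_init__(self) -> None:
        if not self.curvature > 0:
            raise ValidationError("curvature must be positive")


@dataclass
class CompensationResult:
    """Compensated field plus search diagnostics."""

    field: ComplexField
    carrier_peak: Tuple[float, float]  # (row, col), possibly fractional
    tilt_sines: Tuple[float, float]  # (sin_tx, sin_ty)
    metric: int
    evaluations: int = 0
    quadratic: Optional[QuadraticPhaseEstimate] = None


def digital_reference(
    shape: Tuple[int, int],
    wavelength: float,
    dx: float,
    dy: float,
    peak: Tuple[float, float],
) -> ComplexField:
    """Digital replica of the tilted reference for carrier cancellation.

    The tilt follows from the offset of the +1 peak from DC:
    sin_tx = wavelength*(col - N//2)/(N*dx), sin_ty analogous.  The returned
    wave carries the conjugate tilt exp(-i*k*(sin_tx*x + sin_ty*y)), so
    multiplying the filtered field by it cancels the carrier.  Fractional
    peak coordinates are accepted.
    """
    M, N = shape
    pr, pc = peak
    sin_tx = wavelength * (pc - N // 2) / (N * dx)
    sin_ty = wavelength * (pr - M // 2) / (M * dy)
    x, y = centered_coords(shape, dx, dy)
    k = 2.0 * np.pi / wavelength
    values = np.exp(-1j * k * (sin_tx * x + sin_ty * y))
    return ComplexField(values, wavelength=wavelength, dx=dx, dy=dy)


def tilt_sines_of_peak(
    shape: Tuple[int, int], wavelength: float, dx: float, dy: float,
    peak: Tuple[float, float],
) -> Tuple[float, float]:
    M, N = shape
    pr, pc = peak
    return (
        wavelength * (pc - N // 2) / (N * dx),
        wavelength * (pr - M // 2) / (M * dy),
    )


def threshold_metric(phase_img, threshold: float = 0.2) -> int:
    """Summation-and-thresholding compensation metric.

    Normalise the wrapped phase to [0, 1] via (phi + pi)/(2*pi), binarise at
    ``threshold`` and count the surviving pixels.  Sawtooth discontinuities
    push pixels below the threshold, so a well-compensated (fringe-free)
    phase map maximises the count.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie strictly between 0 and 1")
    phi = as_array(phase_img)
    norm = (phi + np.pi) / (2.0 * np.pi)
    return int(np.count_nonzero(norm > threshold))


def remove_piston(values: np.ndarray) -> np.ndarray:
    """Rotate a complex field so its energy-weighted mean phase is zero."""
    s = values.sum()
    if s == 0:
        return values
    return values * np.exp(-1j * np.angle(s))


#: phase margin (radians) between the anchored background and the
#: binarisation boundary used when scoring candidate compensations
SCORE_MARGIN = 0.3


def _score(values: np.ndarray, threshold: float, margin: float = SCORE_MARGIN) -> int:
    """Piston-anchored compensation score.

    The global phase origin of a filtered field is arbitrary, so before
    binarising the candidate phase map we rotate the field so its circular
    mean phase (dominated by the fringe-free background) sits ``margin``
    radians above the binarisation boundary.  A perfectly compensated map
    then keeps every pixel above threshold, while a residual tilt of
    ~margin/pi frequency bins already pushes the down-ramp edge below it —
    the count is a single-peaked, piston-invariant function of the residual
    carrier.
    """
    a = np.abs(values)
    nz = a > 0
    if not np.any(nz):
        return 0
    # two-step anchor: a circular-mean rotation unwraps the bulk of the
    # distribution, then the median pins the (majority) background level
    # without being biased by the object's one-sided phase
    mean_dir = np.angle((values[nz] / a[nz]).sum())
    centred = values * np.exp(-1j * mean_dir)
    background = float(np.median(np.angle(centred[nz])))
    boundary = -np.pi + 2.0 * np.pi * threshold
    target = boundary + margin
    rotated = np.angle(centred * np.exp(1j * (target - background)))
    return threshold_metric(rotated, threshold)


def _filtered_plus_one(holo, upper: bool, wavelength: float, dx: float, dy: float):
    """Spatially filter the +1 lobe with a circular mask of radius one third
    of the DC-to-peak distance (guarantees DC exclusion for any carrier)."""
    values = as_array(holo)
    M, N = values.shape
    S = ft_centered(RealImage(values, dx=dx, dy=dy))
    peak = find_order_peak(S, upper=upper)
    dist = math.hypot(peak[0] - M // 2, peak[1] - N // 2)
    radius = max(1.0, dist / 3.0)
    filt = spatial_filter(
        RealImage(values, dx=dx, dy=dy),
        CircularFilter(radius, peak),
        wavelength=wavelength,
    )
    return filt, peak


def _compensate_at(filtered: ComplexField, peak) -> np.ndarray:
    ref = digital_reference(
        filtered.shape, filtered.wavelength, filtered.dx, filtered.dy, peak
    )
    return filtered.values * ref.values


def frs(
    holo,
    params: ROISearchParams = ROISearchParams(),
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
    threshold: float = 0.2,
) -> CompensationResult:
    """Full ROI search: score every candidate carrier on a step x step grid
    spanning +-s bins around the +1 peak and keep the best."""
    filtered, peak = _filtered_plus_one(holo, params.upper, wavelength, dx, dy)
    offsets = np.linspace(-params.s, params.s, params.step)
    best = None
    evaluations = 0
    for dr in offsets:
        for dc in offsets:
            cand = (peak[0] + dr, peak[1] + dc)
            vals = _compensate_at(filtered, cand)
            m = _score(vals, threshold)
            evaluations += 1
            if best is None or m > best[0]:
                best = (m, cand, vals)
    m, cand, vals = best
    return CompensationResult(
        field=ComplexField(vals, wavelength=wavelength, dx=dx, dy=dy),
        carrier_peak=cand,
        tilt_sines=tilt_sines_of_peak(filtered.shape, wavelength, dx, dy, cand),
        metric=m,
        evaluations=evaluations,
    )


def ers(
    holo,
    params: ROISearchParams = ROISearchParams(),
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
    threshold: float = 0.2,
) -> CompensationResult:
    """Efficient (path-oriented) ROI search.

    Starting from the peak bin, a small 3x3 stencil of spacing w (initially
    the ROI half-size s) is evaluated; the search re-centres on the best
    candidate, halves the spacing whenever the centre already wins, and stops
    once the spacing drops below 0.1 bin or the metric stops improving.
    Previously scored candidates are cached, so far fewer candidates are
    evaluated than the full step^2 grid of :func:`frs`.
    """
    filtered, peak = _filtered_plus_one(holo, params.upper, wavelength, dx, dy)
    center = (float(peak[0]), float(peak[1]))
    w = float(params.s)
    cache = {}

    def score(cand):
        key = (round(cand[0], 6), round(cand[1], 6))
        if key not in cache:
            cache[key] = (_score(_compensate_at(filtered, cand), threshold), cand)
        return cache[key]

    best_m, best_cand = score(center)
    while w >= 0.1:
        improved = False
        for dr in (-w, 0.0, w):
            for dc in (-w, 0.0, w):
                m, cand = score((center[0] + dr, center[1] + dc))
                if m > best_m:
                    best_m, best_cand = m, cand
                    improved = True
        if improved:
            center = best_cand
        else:
            w /= 2.0
    vals = _compensate_at(filtered, best_cand)
    return CompensationResult(
        field=ComplexField(vals, wavelength=wavelength, dx=dx, dy=dy),
        carrier_peak=best_cand,
        tilt_sines=tilt_sines_of_peak(filtered.shape, wavelength, dx, dy, best_cand),
        metric=best_m,
        evaluations=len(cache),
    )


def cfs(
    holo,
    wavelength: float = 0.633,
    dx: float = 6.9,
    dy: float = 6.9,
    upper: bool = True,
    threshold: float = 0.2,
) -> CompensationResult:
    """Cost-function search: minimisation of 1/(1 + metric) over fractional
    carrier coordinates, seeded at the +1 peak bin.

    The count landscape is rugged away from the optimum (each fringe crossing
    the field boundary makes a local extremum) and its attraction basin width
    scales with the piston margin of the score, so the search is
    multi-resolution: staged grids with a decreasing margin home in on the
    true carrier (each stage's grid is finer than the previous plateau), and
    a small-simplex Nelder-Mead polishes the fractional carrier."""
    filtered, peak = _filtered_plus_one(holo, upper, wavelength, dx, dy)
    evaluations = 0

    def cost(p, margin):
        nonlocal evaluations
        evaluations += 1
        m = _score(_compensate_at(filtered, (p[0], p[1])), threshold, margin=margin)
        return 1.0 / (1.0 + m)

    # staged bracketing: the true carrier lies within ~0.7 bin of the argmax
    # bin; (margin, half-range, #points) chosen so each stage's spacing sits
    # inside the previous stage's localisation radius (~margin/pi bins).
    # On the flat top of each stage (every pixel above threshold) the best
    # cost ties over a symmetric patch, so the centroid of the tied set is
    # the stage estimate.
    centre = np.array(peak, dtype=float)
    final_margin = 0.08
    for margin, half, n in (
        (1.2, 0.75, 7),
        (0.45, 0.3, 7),
        (0.15, 0.12, 7),
        (final_margin, 0.05, 7),
    ):
        offs = np.linspace(-half, half, n)
        cands = [(centre[0] + dr, centre[1] + dc) for dr in offs for dc in offs]
        costs = np.array([cost(p, margin) for p in cands])
        tied = np.flatnonzero(costs == costs.min())
        centre = np.mean(np.asarray(cands)[tied], axis=0)
    simplex = np.array([centre, centre + (0.02, 0.0), centre + (0.0, 0.02)])
    res = optimize.minimize(
        cost,
        centre,
        args=(final_margin,),
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": 1e-3,
            "fatol": 0.0,
            "maxfev": 40,
        },
    )
    cand = (float(res.x[0]), float(res.x[1]))
    if cost(cand, final_margin) > cost(tuple(centre), final_margin):
        cand = (float(centre[0]), float(centre[1]))
    vals = _compensate_at(filtered, cand)
    m = _score(vals, threshold)
    return CompensationResult(
        field=ComplexField(vals, wavelength=wavelength, dx=dx, dy=dy),
        carrier_peak=cand,
        tilt_sines=tilt_sines_of_peak(filtered.shape, wavelength, dx, dy, cand),
        metric=m,
        evaluations=evaluations,
    )


# ---------------------------------------------------------------------------
# non-telecentric compensation
# ---------------------------------------------------------------------------

def cnt(
    holo,
    wavelength: float,
    dx: float,
    dy: float,
    filter_rect: Optional[RectangularFilter] = None,
    centre_hint: Optional[Tuple[float, float]] = None,
    threshold: float = 0.2,
    levels: int = 4,
    points: int = 7,
    shrink: float = 0.4,
) -> CompensationResult:
    """Compensate an off-axis, non-telecentric hologram.

    Pipeline: (1) filter the +1 order with the supplied rectangle; (2) cancel
    the carrier with a digital reference at the brightest bin inside the
    mask; (3) obtain the quadratic-phase centre from ``centre_hint`` (pixel
    (row, col)) or automatically from the centroid of the largest connected
    component of the binarised residual phase; (4) seed the curvature from
    the mask size, C0 = R_field/(wavelength*W_half) — the spectral spreading
    of the +1 order and the curvature are inversely related; (5) refine
    (xC, yC, C) by a nested grid search (``levels`` levels, ``points`` points
    per parameter, range shrunk by ``shrink`` each level) maximising the
    compensation metric of the phase after multiplying by the conjugate
    quadratic factor exp(-i*pi/(wavelength*C)*((x-xC)^2 + (y-yC)^2)).
    """
    if filter_rect is None:
        raise ValidationError(
            "cnt requires a rectangular filter over the +1 order in "
            "non-interactive use"
        )
    values = as_array(holo)
    M, N = values.shape
    img = RealImage(values, dx=dx, dy=dy)
    S = ft_centered(img)
    mask = filter_rect.mask((M, N))
    if not np.any(np.where(mask, np.abs(S.values), 0.0) > 0):
        raise ValidationError("no diffraction order found inside the rectangle")
    # the quadratic aberration spreads the +1 order into a broad, flat
    # support whose brightest bin is unrelated to the carrier; the carrier is
    # the geometric centre of the user-drawn rectangle (residual mask
    # decentring is absorbed by the (xC, yC) search below, since a tilt and
    # a centre shift of the quadratic factor are equivalent)
    peak = filter_rect.mask_center

    filtered = spatial_filter(img, filter_rect, wavelength=wavelength)
    field1 = _compensate_at(filtered, peak)

    x, y = centered_coords((M, N), dx, dy)
    if centre_hint is not None:
        hr, hc = centre_hint
        xc0 = (hc - N // 2) * dx
        yc0 = (hr - M // 2) * dy
        provenance = "user"
    else:
        xc0, yc0 = _auto_centre(field1, x, y, threshold)
        provenance = "automatic"

    # curvature seed from the mask extent: half field over (wavelength * mask
    # half-width in frequency units); the search runs over the inverse
    # curvature q = 1/C, which is linear in the quadratic-phase coefficient
    # and includes the telecentric limit q = 0
    w_half_u = ((filter_rect.x2 - filter_rect.x1) / 2.0) / (N * dx)
    w_half_v = ((filter_rect.y2 - filter_rect.y1) / 2.0) / (M * dy)
    w_half = (w_half_u + w_half_v) / 2.0
    r_field = (N // 2 * dx + M // 2 * dy) / 2.0
    c0 = r_field / (wavelength * w_half)
    q_max = 2.0 / c0

    evaluations = 0

    def score_q(xc, yc, q, margin):
        nonlocal evaluations
        evaluations += 1
        conj = np.exp(
            -1j * np.pi * q / wavelength * ((x - xc) ** 2 + (y - yc) ** 2)
        )
        return _score(field1 * conj, threshold, margin=margin)

    # 1D bracket over q: spacing chosen so consecutive candidates differ by
    # at most `bracket_margin` radians of edge phase (stays inside the
    # metric's attraction basin)
    bracket_margin = 1.0
    n_q = min(241, int(math.ceil(q_max * math.pi * r_field**2 / (wavelength * bracket_margin))) + 1)
    n_q = max(n_q, 9)
    q_grid = np.linspace(0.0, q_max, n_q)
    q_scores = [score_q(xc0, yc0, q, bracket_margin) for q in q_grid]
    q_best = float(q_grid[int(np.argmax(q_scores))])
    dq = float(q_grid[1] - q_grid[0])

    # nested joint refinement of (xC, yC, q); the score margin shrinks with
    # the grid so each level's spacing stays inside the metric's attraction
    # basin (whose width is proportional to the margin)
    best = None
    centre = (xc0, yc0, q_best)
    widths = (8.0 * dx, 8.0 * dy, 2.0 * dq)
    margin = 2.0 * np.pi * r_field * max(dx, dy) * 8.0 / 3.0 * q_best / wavelength
    margin = float(np.clip(margin, SCORE_MARGIN, 1.5))
    for _ in range(levels):
        xs = np.linspace(centre[0] - widths[0], centre[0] + widths[0], points)
        ys = np.linspace(centre[1] - widths[1], centre[1] + widths[1], points)
        qs = np.linspace(max(0.0, centre[2] - widths[2]), centre[2] + widths[2], points)
        scores = np.empty((points, points, points))
        for iq, q in enumerate(qs):
            for iy, yc in enumerate(ys):
                for ix, xc in enumerate(xs):
                    scores[iq, iy, ix] = score_q(xc, yc, q, margin)
        # centroid of the tied best set: on a flat metric top the argmax is
        # arbitrary, its centroid is not
        tied = np.argwhere(scores == scores.max())
        centre = (
            float(np.mean(xs[tied[:, 2]])),
            float(np.mean(ys[tied[:, 1]])),
            float(np.mean(qs[tied[:, 0]])),
        )
        best = (float(scores.max()),) + centre
        widths = tuple(w * shrink for w in widths)
        margin = max(SCORE_MARGIN / 2.0, margin * shrink)
    m, bxc, byc, bq = best
    C = 1.0 / bq if bq > 1.0 / (1e6 * c0) else math.inf
    conj_quad = np.exp(-1j * np.pi * bq / wavelength * ((x - bxc) ** 2 + (y - byc) ** 2))
    vals = remove_piston(field1 * conj_quad)
    return CompensationResult(
        field=ComplexField(vals, wavelength=wavelength, dx=dx, dy=dy),
        carrier_peak=peak,
        tilt_sines=tilt_sines_of_peak((M, N), wavelength, dx, dy, peak),
        metric=m,
        evaluations=evaluations,
        quadratic=QuadraticPhaseEstimate(
            curvature=C, center=(bxc, byc), provenance=provenance
        ),
    )


def _auto_centre(field1: np.ndarray, x, y, threshold: float):
    """Locate the centre of the concentric quadratic-phase ring pattern.

    The local fringe frequency of exp(i*pi/(wavelength*C)*r^2) grows linearly
    with the distance from the centre, so the centre is the minimum of the
    smoothed local phase-gradient magnitude.  The gradient of the wrapped
    phase is taken through conjugate products of neighbouring pixels, which
    is insensitive to 2*pi wraps.
    """
    gx = np.angle(field1[:, 1:] * np.conj(field1[:, :-1]))
    gy = np.angle(field1[1:, :] * np.conj(field1[:-1, :]))
    mag = np.zeros(field1.shape)
    mag[:, 1:] += np.abs(gx)
    mag[1:, :] += np.abs(gy)
    sigma = max(2.0, min(field1.shape) / 32.0)
    smooth = ndimage.gaussian_filter(mag, sigma=sigma, mode="nearest")
    # ignore a border strip where the smoothing window is truncated
    b = int(2 * sigma)
    inner = smooth[b:-b, b:-b]
    idx = int(np.argmin(inner))
    r0 = idx // inner.shape[1] + b
    c0 = idx % inner.shape[1] + b
    M, N = field1.shape
    dx = float(x[0, 1] - x[0, 0])
    dy = float(y[1, 0] - y[0, 0])
    return (c0 - N // 2) * dx, (r0 - M // 2) * dy
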