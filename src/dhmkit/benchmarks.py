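"""End-to-end verification benchmarks.

Each function builds a synthetic acquisition with known ground truth, runs
one part of the reconstruction stack on it, and returns the measured
figures of merit.  The acceptance script and the acceptance tests both call
these; all randomness flows through the ``seed`` argument.

Problem sizes: 256x256 frames for the single-fixture checks, 192x192 for
the ten-fixture curvature study and 128x128 for pure bookkeeping runs.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

from .core import ComplexField, RealImage, ValidationError, centered_coords
from .phase_compensation import ROISearchParams, cfs, cnt, ers, frs
from .phase_shifting import bps2, bps3, ps3, ps4, ps5, sosr
from .propagation import angular_spectrum, fresnel, fresnel_bluestein
from .simulator import AcquisitionConfig, make_phantom, simulate_hologram, simulate_ps_series
from .utilities import RectangularFilter

__all__ = [
    "roi_combinatorics",
    "bluestein_magnification",
    "ps_identities",
    "compensation_recovery",
    "curvature_study",
    "propagation_checks",
    "blind_ps_recovery",
]

LAM = 0.633
PITCH = 6.9


def _blueprint(seed: int, size=(256, 256), peak_phase=1.5):
    """Canonical smooth test object; its seed co-determines every fixture."""
    return make_phantom("blobs", size, peak_phase=peak_phase, seed=seed)


def roi_combinatorics(seed: int = 3) -> Dict[str, float]:
    """Instrumented candidate counts of the grid searches."""
    ph = _blueprint(seed, size=(128, 128))
    cfg = AcquisitionConfig.from_carrier_bins(10, 8, shape=(128, 128))
    frames = simulate_ps_series(ph, cfg, [0, np.pi / 2, np.pi, 3 * np.pi / 2])
    res_sosr = sosr(
        *[f.pixels for f in frames],
        upper=True, wavelength=LAM, dx=PITCH, dy=PITCH, s=1, steps=4,
    )
    cfg2 = AcquisitionConfig.from_carrier_bins(30, 25, shape=(128, 128))
    holo = simulate_hologram(ph, cfg2)
    res_frs = frs(
        holo, ROISearchParams(s=2, step=10), wavelength=LAM, dx=PITCH, dy=PITCH
    )
    return {
        "sosr_candidates_s1_steps4": res_sosr.evaluations,
        "frs_candidates_s2_step10": res_frs.evaluations,
        "roi_side_s1": ROISearchParams(s=1, step=4).roi_side,
        "roi_side_s2": ROISearchParams(s=2, step=10).roi_side,
    }


def bluestein_magnification(seed: int = 3) -> Dict[str, float]:
    """Output-pitch bookkeeping of the scaled Fresnel propagator on a
    dice-like phantom (square aperture with circular pips)."""
    n, dx = 128, 7.4
    r = np.arange(n)[:, None] - n // 2
    c = np.arange(n)[None, :] - n // 2
    ap = (np.maximum(np.abs(r), np.abs(c)) <= 40).astype(complex)
    for pr, pc in ((-15, -15), (0, 0), (15, 15)):
        ap[((r - pr) ** 2 + (c - pc) ** 2) <= 16] = 0.0
    field = ComplexField(ap, wavelength=LAM, dx=dx, dy=dx)
    z = 300000.0
    dxout = 18.5
    out = fresnel_bluestein(field, z, dxout, dxout)
    magnification = out.dx / dx

    # feature-width scaling in the zoomed-in regime
    natural = LAM * z / (n * dx)
    w1 = _lobe_width(fresnel_bluestein(field, z, natural / 4, natural / 4))
    w2 = _lobe_width(fresnel_bluestein(field, z, natural / 2, natural / 2))
    return {
        "magnification_dx7p4_dxout18p5": magnification,
        "feature_width_ratio": w1 / w2,
    }


def _lobe_width(field) -> float:
    """Full width at half maximum of the central row profile, with linear
    sub-pixel interpolation of the two half-max crossings."""
    n = field.shape[0]
    profile = np.abs(field.values[n // 2]) ** 2
    half = profile.max() / 2.0
    above = np.flatnonzero(profile > half)
    lo, hi = int(above.min()), int(above.max())

    def crossing(i, j):
        return i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)

    left = crossing(lo - 1, lo) if lo > 0 else float(lo)
    right = crossing(hi + 1, hi) if hi < n - 1 else float(hi)
    return float(right - left)


def ps_identities(seed: int = 3) -> Dict[str, float]:
    """Wrapped-phase spread of the known-shift estimators on noiseless
    in-line series (ground truth from the simulator)."""
    ph = make_phantom("disk", (256, 256), peak_phase=1.2)
    cfg = AcquisitionConfig(shape=(256, 256))
    out = {}
    for name, fn, shifts in (
        ("ps5", ps5, [0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi]),
        ("ps4", ps4, [0, np.pi / 2, np.pi, 3 * np.pi / 2]),
        ("ps3", ps3, [np.pi / 3, np.pi, 5 * np.pi / 3]),
    ):
        frames = simulate_ps_series(ph, cfg, shifts)
        rec = fn(*[f.pixels for f in frames]).pixels
        z = np.exp(1j * (rec - ph.phase))
        spread = np.abs(np.angle(z * np.exp(-1j * np.angle(z.sum())))).max()
        out[f"{name}_phase_spread_rad"] = float(spread)
    return out


def compensation_recovery(seed: int = 3) -> Dict[str, float]:
    """Carrier recovery and residual background flatness of the telecentric
    searches, plus single-fixture curvature recovery of the non-telecentric
    search."""
    ph = _blueprint(seed)
    bg = ph.phase < 1e-3
    cfg = AcquisitionConfig.from_carrier_bins(60, 50)
    holo = simulate_hologram(ph, cfg)
    true_peak = (128 - 60, 128 - 50)

    res_frs = frs(holo, ROISearchParams(s=2, step=5), wavelength=LAM, dx=PITCH, dy=PITCH)
    res_ers = ers(holo, ROISearchParams(s=2, step=10), wavelength=LAM, dx=PITCH, dy=PITCH)
    res_cfs = cfs(holo, wavelength=LAM, dx=PITCH, dy=PITCH)

    cfg_off = AcquisitionConfig.from_carrier_bins(60.5, 50.5)
    holo_off = simulate_hologram(ph, cfg_off)
    res_cfs_off = cfs(holo_off, wavelength=LAM, dx=PITCH, dy=PITCH)

    c_true = 123000.0
    cfg_nt = AcquisitionConfig.from_carrier_bins(55, 45, curvature=c_true)
    holo_nt = simulate_hologram(ph, cfg_nt)
    peak_nt = (128 - 55, 128 - 45)
    rect = RectangularFilter(
        x1=peak_nt[1] - 28, y1=peak_nt[0] - 28, x2=peak_nt[1] + 28, y2=peak_nt[0] + 28
    )
    res_cnt = cnt(holo_nt, LAM, PITCH, PITCH, filter_rect=rect)

    def err(res, truth):
        return math.hypot(res.carrier_peak[0] - truth[0], res.carrier_peak[1] - truth[1])

    return {
        "frs_carrier_error_bins": err(res_frs, true_peak),
        "ers_carrier_error_bins": err(res_ers, true_peak),
        "cfs_carrier_error_bins": err(res_cfs, true_peak),
        "cfs_offgrid_carrier_error_bins": err(res_cfs_off, (67.5, 77.5)),
        "frs_background_phase_std_rad": float(
            np.angle(res_frs.field.values)[bg].std()
        ),
        "ers_evaluations": res_ers.evaluations,
        "cnt_curvature_error_percent": 100.0
        * abs(res_cnt.quadratic.curvature - c_true) / c_true,
    }


def curvature_study(seed: int = 3, n_fixtures: int = 10) -> Dict[str, float]:
    """Non-telecentric curvature recovery over seeded fixtures with C drawn
    log-uniformly over one decade (192x192 frames)."""
    rng = np.random.default_rng(seed)
    n, pitch = 192, PITCH
    errors = []
    for i in range(n_fixtures):
        c_true = 70000.0 * 10 ** rng.uniform(0.0, 1.0)
        ph = _blueprint(int(rng.integers(0, 2**31)), size=(n, n))
        cfg = AcquisitionConfig.from_carrier_bins(
            41, 34, shape=(n, n), curvature=c_true, dx=pitch, dy=pitch
        )
        holo = simulate_hologram(ph, cfg)
        peak = (n // 2 - 41, n // 2 - 34)
        r_field = n // 2 * pitch
        w_bins = int(round(r_field / (LAM * c_true) * n * pitch)) + 12
        w_bins = min(w_bins, 32)
        rect = RectangularFilter(
            x1=peak[1] - w_bins, y1=peak[0] - w_bins,
            x2=peak[1] + w_bins, y2=peak[0] + w_bins,
        )
        res = cnt(holo, LAM, pitch, pitch, filter_rect=rect)
        errors.append(abs(res.quadratic.curvature - c_true) / c_true)
    return {"cnt_median_curvature_error_percent": 100.0 * float(np.median(errors))}


def propagation_checks(seed: int = 3) -> Dict[str, float]:
    """Unitarity, invertibility, the Airy-radius oracle, scaled-propagator
    equivalence and the Gaussian-beam closed form."""
    rng = np.random.default_rng(seed)
    x, y = centered_coords((256, 256), 2.0, 2.0)
    w0 = 30.0
    gauss = ComplexField(
        np.exp(-(x * x + y * y) / w0**2) + 0j, wavelength=LAM, dx=2.0, dy=2.0
    )
    zr = np.pi * w0**2 / LAM
    prop = angular_spectrum(gauss, 3 * zr)
    energy_err = abs(
        (np.abs(prop.values) ** 2).sum() - (np.abs(gauss.values) ** 2).sum()
    ) / (np.abs(gauss.values) ** 2).sum()
    ident = angular_spectrum(gauss, 0.0)
    ident_err = float(np.max(np.abs(ident.values - gauss.values)))
    back = angular_spectrum(prop, -3 * zr)
    round_err = float(np.max(np.abs(back.values - gauss.values)))

    # Airy radius of a circular aperture in the far field
    n, dxa = 256, 5.0
    r = np.arange(n)[:, None] - n // 2
    c = np.arange(n)[None, :] - n // 2
    radius_px = 32
    ap = ComplexField(
        ((r * r + c * c) <= radius_px**2).astype(complex), wavelength=LAM, dx=dxa, dy=dxa
    )
    z = 450000.0
    out = fresnel(ap, z)
    profile = np.abs(out.values[n // 2, n // 2 :]) ** 2
    minima = [
        i for i in range(1, len(profile) - 1)
        if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]
    ]
    airy_offset = abs(minima[0] - 1.22 * LAM * z / (2 * radius_px * dxa) / out.dx)

    natural = LAM * z / (n * dxa)
    blue = fresnel_bluestein(ap, z, natural, natural)
    piston = np.angle((blue.values * np.conj(out.values)).sum())
    rms = float(
        np.sqrt(np.mean(np.abs(blue.values - out.values * np.exp(1j * piston)) ** 2))
        / np.sqrt(np.mean(np.abs(out.values) ** 2))
    )

    w_theory = w0 * np.sqrt(1 + 3**2)
    wide = np.abs(prop.values) ** 2
    xs = (np.arange(256) - 128) * prop.dx
    X, Y = np.meshgrid(xs, xs)
    w_as = 2.0 * np.sqrt((wide * X * X).sum() / wide.sum())
    fr = fresnel(gauss, 3 * zr)
    i_fr = np.abs(fr.values) ** 2
    xf = (np.arange(256) - 128) * fr.dx
    Xf, Yf = np.meshgrid(xf, xf)
    w_fr = 2.0 * np.sqrt((i_fr * Xf * Xf).sum() / i_fr.sum())
    return {
        "as_energy_error": float(energy_err),
        "as_identity_error": ident_err,
        "as_round_trip_error": round_err,
        "airy_radius_offset_px": float(airy_offset),
        "bluestein_fresnel_rms": rms,
        "gaussian_width_error_percent_as": 100.0 * abs(w_as - w_theory) / w_theory,
        "gaussian_width_error_percent_fresnel": 100.0 * abs(w_fr - w_theory) / w_theory,
    }


def blind_ps_recovery(seed: int = 3) -> Dict[str, float]:
    """Blind shift estimation accuracy and the two-frame overlap refusal."""
    ph = _blueprint(seed)
    cfg = AcquisitionConfig.from_carrier_bins(20, 16)
    rng = np.random.default_rng(seed)
    t2, t3 = rng.uniform(0.7, 1.6), rng.uniform(1.9, 2.6)
    frames = simulate_ps_series(ph, cfg, [0.0, t2, t3])
    res3 = bps3(*[f.pixels for f in frames], wavelength=LAM, dx=PITCH, dy=PITCH)

    def circ(a, b):
        return abs(float(np.angle(np.exp(1j * (a - b)))))

    err3 = min(
        max(circ(res3.shifts[1], t2), circ(res3.shifts[2], t3)),
        max(circ(res3.shifts[1], -t2), circ(res3.shifts[2], -t3)),
    )

    dt = rng.uniform(0.8, 1.3)
    pair = simulate_ps_series(ph, cfg, [0.0, dt])
    res2 = bps2(pair[0].pixels, pair[1].pixels, wavelength=LAM, dx=PITCH, dy=PITCH)
    err2 = min(circ(res2.shifts[1], dt), circ(res2.shifts[1], -dt))

    star = make_phantom("star", (256, 256), peak_phase=3.0, seed=seed)
    cfg_bad = AcquisitionConfig.from_carrier_bins(18, 14)
    bad = simulate_ps_series(star, cfg_bad, [0.0, 1.0])
    try:
        bps2(bad[0].pixels, bad[1].pixels, wavelength=LAM, dx=PITCH, dy=PITCH)
        refused = 0.0
    except ValidationError:
        refused = 1.0
    return {
        "bps3_shift_error_rad": err3,
        "bps2_shift_error_rad": err2,
        "bps2_overlap_refused": refused,
    }
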