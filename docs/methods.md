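# Methods

This note documents the models, numerical choices and known limitations of
`dhmkit`, in the spirit of a methods section: what is computed, under which
assumptions, and what the synthetic tests do and do not demonstrate.

## Image formation and the simulator

The simulator implements scalar, fully coherent image-plane holography.
The object is a *phantom*: an amplitude map `a(x,y) ≥ 0` and a phase map
`φ(x,y)` in radians.  The image-plane field is

    u_IP = P[a·e^{iφ}] · exp(i·π/(λC)·((x−x_C)² + (y−y_C)²))

where `P` is an optional circular pupil low-pass with cutoff
`u_c = NA/(λ·Mag)` and the quadratic factor models non-telecentric imaging
with radius of curvature `C` (`C = ∞`, the default, is telecentric and
leaves no quadratic phase).  Constant phase prefactors (global pistons and
the magnification-dependent amplitude scale) are dropped: only relative
phases are observable in a reconstruction, and every comparison in the
package is modulo one additive constant.

The sign convention for the quadratic factor is `exp(+i·π/(λC)·r²)` for the
aberration and its complex conjugate for compensation; `C` is exposed in
micrometres.  Wavelength and pitches must share one length unit throughout;
nothing converts units.

Defocus over a signed distance `z` (negative = in front of the image
plane) is applied with the angular-spectrum operator rather than a separate
paraxial convolution, so one propagation code path serves both the
simulator and the reconstruction; the paraxial equivalence is covered by a
direct-quadrature oracle test of the Fresnel propagator.

The hologram is `h = |u + r|²` with a tilted plane reference of irradiance
`I_R` and shift δ.  Noise, when requested, is additive Gaussian on the
irradiance with standard deviation σ, clipped at zero; a phase-shifted
series draws all frames from one seeded generator so series are
reproducible yet frames are independent.

**Default study conditions.**  256×256 frames, λ = 0.633 µm, 6.9 µm pixels
(a red HeNe source on a machine-vision sensor), unit reference irradiance,
σ = 0 unless a test varies it.  The canonical test object is `blobs`: six
seeded Gaussian bumps, peak phase 1.5 rad — a smooth, spectrally compact
stand-in for a cell-scale phase specimen.  Hard-edged phantoms (`disk`,
`bars`, `star`) exercise broad-spectrum behaviour.  Carriers in off-axis
fixtures are placed tens of bins from DC (e.g. (60, 50)), far enough that
the ±1 orders separate cleanly from the DC term.

**What the simulator does not emulate:** partial coherence, speckle from
rough surfaces, shot noise statistics, sensor nonlinearity, vibration
between phase-shifted frames, and aberrations beyond the single quadratic
term.  Passing tests therefore demonstrate algorithmic correctness under
the stated model, not robustness to every artifact of a physical bench.

## Fourier conventions

All spectra are DC-centred (`fftshift` layout; DC at (M//2, N//2)) and the
transforms are unitary, so Parseval's identity holds exactly and round
trips are identities to ~1e-15.  Physical coordinates are
`x = (col − N//2)·dx`, `y = (row − M//2)·dy`, which makes tilts and the
quadratic phase symmetric about the array centre.  `phase(0) = 0` by the
`atan2(0, 0)` convention.  Peak searches break ties by row-major first
occurrence and exclude a DC disc of radius `min(M, N)/20` pixels by
default, so results are deterministic.

## Phase shifting

`ps5`, `ps4`, `ps3` are the closed-form arctangent estimators for shifts
{0, π/2, π, 3π/2, 2π}, {0, π/2, π, 3π/2} and reference phases
{π/3, π, 5π/3} respectively.  The three-step numerator carries the factor
√3, which the cosine-model identity requires: with frames
`A + B·cos(φ − δ)`, `h(π/3) − h(5π/3) = √3·B·sin φ` and
`h(π/3) + h(5π/3) − 2h(π) = 3·B·cos φ`, so
`φ = atan2(√3·(h₀ − h₂), h₀ + h₂ − 2h₁)` exactly.  The three-step method's
*inter-frame* shift is 2π/3.  Degenerate pixels (zero numerator and
denominator) map to phase 0.

`sosr` implements the quadrature method for slightly off-axis series:
because the shifts are exactly {0, π/2, π, 3π/2}, the sum
`Σ_m h_m·e^{imπ/2}` cancels the DC and conjugate terms identically, and a
single digital-reference multiplication per candidate tilt completes the
reconstruction.  Candidate tilts form a `steps × steps` grid over a
`(1+2s)`-pixel region of interest centred on the brightest spectral bin of
the chosen half-plane; the compensation metric (below) picks the winner.
With `steps` even the grid does not contain its own centre, so a grid with
odd `steps` is the right choice when the carrier is known to sit on a bin.

### Blind estimation

The blind methods model each frame as
`h_m = d0 + e^{-iθ_m}·d₊₁ + e^{iθ_m}·d₋₁`.  Their cost is the *leakage
statistic*: |FT(d0)| summed over 3×3 neighbourhoods of the carrier bins,
normalised by |FT(d0)| at DC.  At the true shifts the demodulated d0
contains no object energy and the cost vanishes; the statistic is cheap,
differentiable almost everywhere in θ, and directly measures the
"expected vs actual" spectral composition.

* `bps3` solves the 3×3 linear system per pixel for (d0, d₊₁, d₋₁) given a
  shift hypothesis (0, θ₂, θ₃) and minimises leakage at both ±1 bins.  The
  search is seeded from inter-frame correlations (which determine cos θ up
  to sign; the four sign combinations are ranked by initial cost and the
  two best refined) and polished by deterministic coordinate descent
  (shrinking bracket, 7 points per sweep, tolerance 1e-4 rad, ≤200
  sweeps).
* `bps2` uses the two-component decomposition `h₁ = d0 + d₃`,
  `h₂ = d0 + e^{iΔθ}·d₃`, minimising leakage of the *object lobe only*
  into d0 (with two frames the conjugate lobe cannot be cancelled
  simultaneously; it is removed afterwards by spatially filtering the +1
  lobe of d₃).  Identical frames make the decomposition singular and are
  refused, as are shift hypotheses within 0.05 rad of 0 mod 2π.

Both methods return shifts modulo 2π with a global sign ambiguity — the
correlation seed only fixes |cos θ| — resolved so that the object-carrying
lobe lies in the upper half-plane.  Tests compare against either sign.

Two validity guards replace preconditions a human operator would check by
eye: (1) a carrier closer to DC than 1.5× the exclusion radius is treated
as in-line data ("no diffraction order found"); (2) for `bps2`, lobe-tail
energy at the midpoint between the ±1 peaks exceeding 1% of the peak
amplitude marks the orders as overlapping, and the input is refused.  The
1% figure separates spectrally compact objects (Gaussian-tailed, midpoint
energy ≈ 0) from hard-edged ones whose power-law tails collide; it is a
detector design choice, not a fitted constant.

## Carrier compensation and the metric

The digital reference maps a (possibly fractional) spectral peak position
to tilt sines via `sin θx = λ·(col − N//2)/(N·dx)` and multiplies the
filtered field by the conjugate tilt.  The +1 order is isolated with a
circular mask of radius one third of the DC-to-peak distance — this family
of methods does not prescribe a radius; one third guarantees DC exclusion
for any off-axis carrier at the cost of some spectral truncation (see
limitations).

`threshold_metric` normalises the wrapped phase to [0, 1] via
`(φ + π)/(2π)`, binarises at a threshold (default 0.2, exposed as a
parameter) and counts surviving pixels; sawtooth fringes push pixels below
the threshold, so fringe-free maps maximise the count.

**Piston anchoring.**  The count depends on the arbitrary global phase of
the filtered field, so candidates are scored after rotating the field so
its background phase sits a fixed *margin* above the binarisation
boundary.  The background level is found in two steps — a circular-mean
rotation followed by a median (the median is insensitive to the one-sided
phase of a minority object) — making the score piston-invariant and
single-peaked in the residual carrier: a perfectly compensated map keeps
every pixel above threshold, while a residual tilt of ~margin/π frequency
bins already pushes the down-ramp edge below it.  The margin therefore
*is* the localisation scale, which the searches exploit:

* `frs` scores every candidate of the `step²` grid (margin 0.3).
* `ers` refines a 3×3 stencil whose spacing starts at the ROI half-size
  and halves whenever the centre wins, stopping below 0.1 bin; scored
  candidates are cached, so it evaluates far fewer candidates than `frs`
  at equal settings (41 vs 100 on the standard fixture).
* `cfs` runs a multi-resolution bracket — staged grids with margins
  1.2 → 0.45 → 0.15 → 0.08, each stage's spacing inside the previous
  localisation radius, taking the *centroid of tied best candidates* on
  each flat top — then polishes with a small-simplex Nelder–Mead on
  1/(1 + metric).  Recovered carriers land within ~0.01 bin on-grid and
  well under 0.1 bin for half-bin off-grid carriers.

## Non-telecentric compensation

`cnt` filters the +1 order with a user-supplied rectangle.  Because the
quadratic aberration spreads the order into a broad flat support, the
carrier is taken as the rectangle's geometric centre rather than the
brightest bin (the brightest bin of a chirp-like lobe is uninformative);
residual mask decentring is absorbed by the centre search, since a tilt
and a shift of the quadratic centre are equivalent to first order.

The quadratic centre (x_C, y_C) comes from a hint, or automatically as the
minimum of the smoothed local fringe-frequency map (conjugate products of
neighbouring pixels give the wrapped-phase gradient; its magnitude
vanishes at the ring centre).  The curvature seed inverts the
spread–curvature relation: `C₀ = R_field/(λ·W_half)` with `W_half` the
rectangle half-width in frequency units.  The refinement searches the
*inverse* curvature `q = 1/C` — linear in the quadratic coefficient and
containing the telecentric limit `q = 0` — with a dense 1D bracket (step
chosen so consecutive candidates differ by ≤1 rad of edge phase) followed
by a nested (x_C, y_C, q) grid: 7 points per parameter, 4 levels, range
shrink 0.4 per level, and a score margin that shrinks with the grid so
each level's spacing stays inside the metric's attraction basin.  Reported
`C = 1/q`, with `C = ∞` when q underflows (telecentric input).

On the standard fixtures this recovers C within ~1–3% (5% bound asserted)
and the median error over ten fixtures spanning one decade of C is ~2%.

## Propagation

Kernels follow the time convention in which the plane-wave factor is
`exp(−i·2πz/λ·√(1 − λ²(u² + v²)))`; evanescent bins are zeroed (hard
cutoff).  The Fresnel chirps are `exp(−i·π/(λz)·r²)` with the transform
direction switching sign with z, and the amplitude prefactor
`dx·dy/(λ|z|)` makes the discrete chain exactly energy preserving on the
continuous measure (`Σ|out|²·dxout·dyout = Σ|in|²·dx·dy`).  The
single-transform Fresnel output pitch is the sampling relation
`λ|z|/(N·dx)`, surfaced in the returned calibration because the propagated
field's magnification is otherwise easy to misread.  The Bluestein variant
evaluates the same sum through the chirp-z decomposition
`m·m' = (m² + m'² − (m−m')²)/2` per axis (linear convolution via FFT), so
it equals `fresnel` at the natural pitch to machine precision and accepts
any output pitch otherwise.  Choosing an output pitch *above* the natural
pitch undersamples the spectral evaluation and aliases replicas into the
field of view — the useful regime is zooming in (dxout below natural), as
in the magnification examples.

Validation oracles: z = 0 identity, ±z round trip and semigroup at 1e-10;
Airy first zero of a circular aperture within one output pixel of
`1.22·λz/D`; Fraunhofer modulus match; direct O(N⁴) quadrature of the
paraxial integral on a 64×64 grid within 1% RMS intensity; Gaussian beam
width `w(z) = w₀·√(1 + (λz/(πw₀²))²)` within 1% for both propagators.

## Known limitations

* The compensated-phase background carries a floor from spectral
  truncation by the filter mask (~3·10⁻⁴ rad std for the smooth phantom
  with a generous mask; up to a few 10⁻³ for less compact objects).
* In `cnt`, truncation by the rectangle plus the metric's finite
  localisation leaves a residual background ripple (~0.1–0.35 rad std on
  the standard fixtures) even when C is recovered to ~1%; the threshold
  count is also slightly biased by the object's one-sided phase, which
  bounds the achievable C accuracy at roughly the percent level.
* The threshold metric assumes a majority fringe-free background with a
  one-sided (non-negative) object phase, the usual situation in
  quantitative phase imaging of cells; scenes that are mostly object
  would need a different anchor.
* Phase unwrapping is out of scope: all outputs are wrapped to (−π, π].
* The interactive rectangle selector is a coordinate-driven hook; no GUI
  is provided.
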