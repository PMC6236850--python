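# Methods

## The problem

Respiration-correlated CT (4DCT) sorts helical low-pitch projection data
retrospectively into breathing phases and reconstructs one image per
phase.  For this to work everywhere in the field of view, every
longitudinal position must stay illuminated for at least one breathing
period.  When the pitch is too high for the patient's breathing period,
the vendor reconstruction widens the temporal gate of each phase beyond
the half-rotation (pi) minimum; the extra, temporally redundant
projections are what blurs moving anatomy.  The conventional remedy
tapers the gate with a cosine-squared weight; the EXPO weighting
multiplies that taper by a decaying exponential so that temporally
distant projections contribute even less.  This package is a desk-scale
virtual 4DCT system built to make the resulting trade — sharper moving
boundaries against slightly higher noise — reproducible in simulation and
quantifiable.

## Acquisition-geometry temporal budget (`expo4dct.geometry`)

With source-isocenter distance `R_S`, field of view `FOV`, collimation
`COLL`, rotation time `RT` and pitch `PF` (all lengths mm, times s):

* visible length at the FOV edge: `Z_m = (R_S − FOV/2) · COLL / R_S`
* couch velocity: `V = PF · COLL / RT`
* transit time: `TT = Z_m / V`
* full-illumination condition: `BP ≤ (R_S − FOV/2)/R_S · RT/PF`
  (equivalently `PF ≤ (1 − FOV/(2 R_S)) · RT/BP`)
* gate widening when violated: `T_w = BP − RT/PF · (1 − FOV/(2 R_S))`,
  clamped at zero when the condition holds (negative widening is
  unphysical; the bound is treated as non-strict).

`T_w` is converted to projections at the scanner's uniform angular
sampling rate (`projections_per_rotation / RT`), rounded up, on top of the
half-rotation minimum.  The vendor's discretization is not public; the
linear mapping is this package's choice.  The half-rotation minimum is
expressed in projection counts under an exact parallel-beam 180°
completeness assumption (see the forward model below).

## Weight curves (`expo4dct.weighting`)

Over a gate of `I_t` projections with phase point (mid-phase index) `I_m`:

    cos2(i) = cos²( π (i − I_m) / I_t )
    EXPO(i) = cos2(i) · exp( −|i − I_h| · E_f / I_t )

Three readings of the printed formulas were genuinely open and are
resolved here as package design choices:

* the π inside the cosine is used for both schemes, so the taper reaches
  zero at the gate edges (a cosine window that never vanishes at the gate
  boundary would contradict the curves' intended shape);
* `I_h = I_m` by default, so the exponential peaks at the reconstruction
  phase point (it is exposed as a parameter);
* the exponent is grouped as `|i − I_h| · E_f / I_t`, so larger `E_f` is
  steeper.  `E_f = 2.0` is the fixed clinical default; the CLI unlocks it
  only behind `--research`.

Raw weights are normalized within *ray-redundancy groups* — projections
whose gantry angles coincide modulo π measure the same line integrals
(with the detector flipped) — so each ray enters the backprojection with
unit total weight.  This makes the weighting exactly transparent on
static data (the schemes' reconstructions coincide to float accumulation
error) and reduces both schemes to plain FBP at the π-minimum gate, where
the curve is forced to uniform: no weighting is employed when the
breathing period fits the transit time.

`effective_temporal_width` (FWHM of the weight curve in projections,
linear interpolation, support width for curves that never cross half
maximum) quantifies the narrowing: at `E_f = 2` the EXPO curve is ~28%
narrower than cosine-squared.

## Digital motion phantom (`expo4dct.phantom`)

2-D axial slices: disks and rectangles with additive attenuation
contrast.  The default study phantom is a 300×200 mm lung-mimicking slab
(μ = 0.001 /mm, ≈ −950 HU) carrying high-contrast soft-tissue disks
(contrast 0.018 /mm).  Superior-inferior platform motion is represented
as in-plane translation of slice content — the natural reduction for a
per-slice 2-D reconstruction model, and blur is measured along the motion
axis exactly as on a physical platform.  Rasterization uses exact
separable pixel overlap for rectangles and 16×16 sub-pixel area sampling
on the boundary ring for disks; translated-object mass is conserved to
well under 0.5% for objects ≥ 5 px across.

Waveforms (peak-to-peak `amplitude`, period `BP = 60/bpm`):

* `sinusoidal` — S-I target analog;
* `sawtooth` — A-P analog: linear ramp with a rapid 10% reset stroke (the
  duty cycle is this package's choice);
* `irregular` — sinusoid with per-cycle period and exhale depth scaled by
  `1 + irregularity · u`, `u ~ U[−1, 1]` from a seeded generator; peaks
  are pinned at `+amplitude/2` so cycle boundaries stay continuous.

The unitless surrogate (breathing-belt analog) is the displacement
normalized to [−1, 1], phase-locked by construction.  All generation is
bit-reproducible under a fixed seed.

The canonical factorial suites mirror the physical platform protocol:
S-I sinusoid at 10/12/15/20 bpm × pitches 0.06/0.08/0.10, A-P sawtooth at
8/10/12 bpm × the same pitches, plus a stationary ground truth.  The
movers are 20 mm and 30 mm disks with 30 mm excursion: the physical
insert's exact sizes are not published, and at the scaled grids used here
(≈ 2–4 mm pixels) objects must be small enough that their motion blur is
resolvable by an FWHM measurement yet a few pixels across; 20/30 mm with
3 cm excursion satisfies both while staying in the regime the platform
experiments probed.

## Forward model (`expo4dct.acquisition`)

Parallel-beam, 2-D, one projection every `RT / projections_per_rotation`
seconds, gantry angle advancing continuously with time.  Couch motion is
**not** geometrically simulated: pitch enters only through the temporal
budget above.  This is the central desk-scale simplification — the
weighting under study acts purely on the temporal axis, so the comparison
between schemes is unaffected by helical ray geometry, while parallel
geometry supplies the exact half-rotation completeness the gating logic
assumes.  Cone angle, scatter, beam hardening and detector effects are
out of scope.

Projections of each motion group (objects sharing axis and excursion) are
assembled from one reference-time sinogram per group via the shift
theorem of the parallel-beam transform (detector-coordinate shift `d·u`,
linear interpolation); static content is assembled without interpolation,
so a static phantom's sinogram equals the discrete forward projection of
its rasterized image bit for bit.  The projector itself samples the image
on the rotated grid with bilinear interpolation at pixel-pitch steps
(detector spacing = pixel spacing, center pixel `n//2`).

Noise is zero-mean Gaussian on the line integrals (seeded), not Poisson
on counts: simpler, and sufficient to exhibit the noise consequences of
weight concentration.  The default study sigma (0.03 in line-integral
units) produces a background noise sd in the high single digits of HU,
the order seen clinically.

Phase sorting detects surrogate maxima (end-inhale) with a prominence
threshold relative to the trace range — hence invariant to constant
offsets — refined by quadratic interpolation; a projection's phase
fraction is its elapsed fraction of the local peak-to-peak interval, and
bins are centered (`round(fraction · n) mod n`), bin 0 on end-inhale, bin
`n/2` on end-exhale for symmetric waveforms.  Fractions outside the
first/last peak are extrapolated with the edge intervals.

## Reconstruction (`expo4dct.reconstruction`)

Per phase: a contiguous gate of the budget's projection count is centered
on the projection whose phase tag is nearest the bin center (earliest on
ties, among placements that fit inside the acquisition; a single
contiguous window is used even when it spans several breathing cycles).
Raw scheme weights are laid over the gate, normalized per ray-redundancy
group, folded per gantry angle (backprojection is linear, so weighted
projections sharing an angle are summed before filtering), ramp-filtered
(band-limited ramp built from the exact spatial kernel, FFT
implementation, no apodization by default) and backprojected with the
standard `π / N` angular scale.  The reconstruction grid equals the
phantom grid.  HU conversion uses `μ_water = 0.019 /mm`.

Derivative images (MIP / minIP / AVG-CT) are voxelwise max / min / mean
over the phase stack.

## Evaluation (`expo4dct.metrics`)

*Residual blur*: a 1-D profile is taken through the object's static
centroid along the motion axis, restricted to a fixed window around the
object (excursion + size + 10 mm half-span).  Background = median of the
outer 20% of profile samples; half maximum = background + half the
peak-to-background contrast; crossings located walking outward from the
peak with linear interpolation (no spline, for determinism).  The FWHM
minus the same measurement on the matched static-truth reconstruction is
the residual; the reconstruction PSF subtracts out, and residuals are
reported unclamped.

Note one property of this metric: convolving a plateau with a *uniform*
position kernel leaves the FWHM unchanged (a trapezoid's half-maximum
width equals its mid-width), so the residual responds to the skirt shape
of the motion kernel rather than its full support.  Residuals here are
therefore numerically modest (0–7 mm at the default study sizes) even
when the underlying excursion is 30 mm; the *ordering* between schemes,
which is the claim under test, is unaffected.

The blur study is run without projection noise: the directional claim is
about motion, and a noiseless sweep is exactly deterministic under fixed
seeds.  Noise behavior is studied separately with matched-seed pairs
(both schemes reconstruct the same noisy acquisition), comparing
background-ROI mean and sd in HU.

Expected (and observed) behavior of the system, for gates widened beyond
the π minimum:

* EXPO residual blur ≤ cosine-squared essentially everywhere, strictly at
  the transitional phases (2–3, 7–9) where boundary speed peaks;
* both schemes are most faithful at end-exhale (phase 5) — note that for
  a *pure* sinusoid end-inhale (phase 0) has the same zero boundary
  velocity, so phases 0 and 5 tie within measurement resolution; real
  breathing dwells at end-exhale, which is why the clinical observation
  singles out phase 5;
* the scheme gap grows with pitch (longer gates) and shrinks as breathing
  quickens (at the π minimum the schemes are bit-identical);
* EXPO's background noise sd exceeds cosine-squared's on matched data
  (~7% at the defaults) while ROI means move by well under 1% of object
  contrast.

## Problem sizes and determinism

The packaged studies run on scaled grids chosen to keep a full factorial
sweep interactive on one CPU: 128×128 pixels over a 500 mm FOV with 360
projections per rotation for the blur study (acquisitions of 7–16
thousand projections, gates up to ~5000), 96×96 with 180/rotation for the
noise pairs, 64×64 for oracle comparisons.  All randomness (waveform
irregularity, projection noise) flows from explicit seeds; noiseless runs
are bit-reproducible regardless of seed.

## Known limitations

* 2-D parallel-beam only; pitch never enters ray geometry.  Vendor
  helical interpolation, cone angle and the exact vendor weighting
  normalization are not modeled, so absolute blur numbers are not
  comparable to scanner measurements — directional and ordering claims
  are.
* Phase-based sorting only; amplitude-based sorting is out of scope.
* The FWHM metric's insensitivity to uniform smear (above) compresses
  blur magnitudes relative to the excursion.
* The irregular-breathing generator varies period and depth cycle by
  cycle but keeps end-inhale pinned; baseline drift and apnea are not
  modeled.
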