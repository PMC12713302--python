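# Methods

This note documents the models, numerical choices and known limitations of
the `ibii` package: a complete, synthetic-data-validated processing chain
for Image-Based Inertial Impact (IBII) testing of bone-like orthotropic
plates.

## The measurement principle

An IBII test fires a short compressive pressure pulse into one edge of a
thin rectangular specimen. The pulse travels to the opposite (free) edge,
reflects as a tensile wave, and fractures the specimen — a spall-type test.
An ultra-high-speed camera images a printed grid on the specimen at MHz
rates; the grid's spatial phase encodes the displacement field, from which
strain and acceleration fields follow. The principle of virtual work with
suitable virtual displacement fields then turns the acceleration field into
a distributed load cell:

* **Stress-gauge (SG).** A rigid x-translation virtual field gives
  `mean_y sigma_xx(x0, t) = rho * x0 * mean_S a_x`, the surface mean running
  from the free edge to the section at `x0`. Plotting this stress against
  the section-mean strain `eps_xx + nu21 * eps_yy` and fitting the
  compressive part yields the axial stiffness `Q11` (or `Q22` for a
  transverse specimen) at every section.
* **Shear stress-gauge.** The rigid y-translation analogue relates the mean
  shear stress to `rho * x0 * mean_S a_y`; slight impact misalignment
  provides enough shear response to fit `G12 = Q66`.
* **Linear stress-gauge (LSG).** Adding a rigid rotation enriches the
  estimate to a stress profile linear in the height coordinate,
  `sigma_xx(y) = rho x0 <a_x> + (12 rho x0 y / H^2)(<a_x y> - <a_y x> + x0 <a_y>)`.
  Its height average equals the SG value identically (the enrichment is odd
  in y) — an exactness property the tests assert to machine precision.
* **Special optimized virtual fields (OVF).** Per frame, a piecewise
  bilinear virtual mesh (default 5x4 elements) with `u* = 0` on the impacted
  edge removes the unknown impact force. For each stiffness component a
  constrained quadratic program minimizes a strain-noise sensitivity
  functional subject to speciality constraints that make the internal
  virtual work isolate that component, which then equals minus the
  acceleration virtual work. One re-weighting pass feeds the identified
  stiffnesses back into the sensitivity weighting. Frames without enough
  strain richness (test start, wave-cancellation dips, no shear for a
  perfectly aligned impact) are marked unidentifiable via the constraint
  residual and skipped by the stable-range median.

Failure analysis reads the **tensile failure stress** from a virtual gauge:
the first crack is located in strain maps computed from *unsmoothed*
displacements (crack opening masquerades as unphysically large tensile
strain), and over a small box around it two independent stress measures are
compared — stress reconstructed from strains and identified stiffnesses,
and the LSG stress built purely from accelerations. They agree while the
response is elastic; at fracture the strain-derived trace shoots up, and
the failure stress is the LSG peak up to that separation.

## Synthetic data generator

The generator is a plane-stress orthotropic elastodynamics solver: regular
bilinear quadrilaterals, 2x2 Gauss quadrature, lumped mass,
central-difference explicit integration, CFL-stable substepping beneath the
camera frame interval. Default study conditions emulate the bovine-bone
regime: `Q11 = 26`, `Q22 = 15`, `Q12 = 4.16`, `Q66 = 7` GPa,
`rho = 2000 kg/m^3`, 20 x 12 x 2 mm specimen, 100x60 elements, half-sine
edge pressure pulse of 150 MPa over 6 us (an aluminium projectile of a few
centimetres produces a pulse of this length), recorded for 128 frames at
5 Mfps. This produces peak accelerations of order 1e7 m/s^2, strain rates
of order 1e3 1/s and compressive stress magnitudes near 150 MPa. A
misalignment coefficient tilts the pressure linearly across the impacted
edge; 0.3 produces the shear response used for `G12` recovery. Impulse–
momentum balance holds to ~1e-5 and energy balance to ~1e-5 relative.

The crack model is an instantaneous node release along one mesh column,
triggered at a frame index or when the adjacent-column mean axial stress
exceeds a threshold. There is no cohesive law and no contact: a crack
released under compression would interpenetrate, so stress triggers belong
in the tensile phase. Pre-trigger frames are bit-identical to the
uncracked run.

The camera samples 400x250 pixels anchored at the free edge with pixel size
`H/250 = 48 um` (FOV 19.2 x 12 mm inside the specimen) using the element
shape functions, so crack discontinuities are preserved; time uses the
nearest solver frame. The grid pitch is 6 px = 0.288 mm, keeping the
standard 6 px/period sampling exact on this pixel size.

## Grid-method imaging

Rendering evaluates the periodic pattern at the material point `X` solving
`X = x - u(X)` (fixed-point iterated inverse motion), supersampled 3x3 per
pixel and box-integrated, then corrupted with seeded Gaussian sensor noise
and quantized. The image is padded left of the free edge with
edge-replicated displacement — exact where the axial strain vanishes at a
traction-free edge — because a real field of view extends past the
specimen: the printed pattern stays in frame as the test pushes the
material toward the free edge (up to ~7 px here), and without the pad that
region of the synthetic image would be spuriously unmeasurable.

Extraction computes the windowed DFT at the grid frequency with a
bi-triangular (Fejer) window of width `2N-1`, whose spectral zeros sit on
every grid harmonic. The temporally unwrapped phase difference to the
reference frame seeds a fixed-point iteration that re-evaluates the
deformed phase at the displaced point (so the result is the displacement of
the material point at each reference pixel, directly comparable to solver
fields), capped at 10 iterations or 1e-3 px. The oscillating carrier is
removed before interpolating the modulation and restored analytically;
the modulation is interpolated with prefiltered cubic splines, because the
~1e-4 px systematic wiggles of bilinear interpolation are temporally rough
and double time-differentiation would amplify them into ~1e6 m/s^2
coherent acceleration bias. One pitch of data at each image border is
invalid (the window needs 2N-1 points) and is filled by linear
extrapolation — implemented as a least-squares line over the nearest 12
interior pixels rather than a two-point difference, since the border width
multiplies the slope and a two-point slope carries enough temporally rough
phase noise to corrupt the stress-gauge force integrals by up to 15%.
Pixels whose displaced evaluation point leaves the analysable window in
some frame are filled per-frame the same way and carry extrapolated
provenance in the mask. Inter-frame phase increments approaching the
half-pitch limit flag the unwrapping as unreliable.

Closed-loop performance on the study configuration: RMS displacement error
~1.5e-5 of a pitch noise-free and ~1/600 of a pitch at 0.3% grey-level
noise (both far inside the p/500 and p/100 working limits), and a static
resolution below p/200 at 0.5% noise.

## Kinematic processing

Strains come from spatially smoothed displacements (Gaussian kernel,
truncation radius 31 px with sigma = radius/3 — the radius is the only
figure usually quoted, and 3-sigma truncation is the common convention;
borders use mask-aware renormalized weights), differentiated by centred
finite differences with one-sided borders. Accelerations come from
temporally smoothed displacements (3rd-order Savitzky-Golay over 21
frames, polynomial-fit edges) differentiated twice by centred differences.
The two smoothing paths are never combined, matching ultra-high-speed grid
practice. Strain rates are centred time-differences of the strains. The
effective strain rate is the strain-weighted space-time average
`sum(eps * eps_rate) / sum(eps)`, reported signed.

## Identification settings

Stress/strain fitting excludes one pitch plus half a smoothing kernel
(6 + 31 px) at each edge, uses the through-origin least-squares slope over
the compressive part of each section's history (test start until the mean
stress first returns to zero after its compressive extremum), and averages
the slopes over `x0` in `[0.25 L, 0.75 L]`; the shear fit averages over
`[0.5 L, 0.85 L]` where the shear response survives, and reports "not
identifiable" when the peak section-mean shear strain is below 5e-5. The
assumed minor Poisson's ratio defaults to 0.16 (0.31 major). The
stable-range median of OVF traces takes the longest run of frames with
sliding-window relative variation below 10% (window 5), the median of an
even count being the mean of the central two; a manual frame range is
supported, mirroring per-specimen manual selection in practice.

On clean synthetic data the SG fit recovers `Q11` within ~1% and the OVF
median agrees with it within ~5%. The OVF per-frame trace oscillates by a
few percent around the true value because the acceleration path is
temporally filtered while the strain path is not — a property of the
processing recipe itself, visible in the real campaign as a 7% gap between
the two methods' medians (25.0 vs 27.0 GPa).

## Failure study configuration

The failure experiment runs in the spall regime: pulse 115 MPa over 10 us,
so the reflected tensile wave peaks a few percent above the 100 MPa crack
trigger — the threshold impact that produces a single first fracture near
the rounded wave peak, where the stress history is slowest. Because the
node-release crack removes traction within one frame, the gauge stress
trace ends in a near-step that a 21-frame filter structurally attenuates by
15–30%; the virtual-gauge traces are therefore differentiated with a
7-frame window (the strength stage's default, config-exposed). The
documented monotone growth of this attenuation with window length (tested
at 11/21/31 frames) quantifies what longer windows would do. Crack
detection thresholds at 3x the 99th-percentile pre-reflection strain
magnitude (the legitimate reflected tension is of the order of the incident
compression; on clean synthetic data there is no pre-reflection tensile
strain to reference). Divergence of the two gauge traces is detected on
the signed gap — the strain-derived stress shooting above the LSG one —
at 10% of the LSG tensile peak; the failure stress is the LSG peak up to
that frame, and the gauge effective strain rate is evaluated over the gauge
box and tensile-phase frames.

With this configuration the full chain detects the fracture frame within
+/-2 frames, reads the 100 MPa trigger back within 10%, and reports no
fracture on the uncracked twin.

## What the synthetic studies do and do not show

The generator produces linear elastic, homogeneous, noise-stationary data
with a perfectly regular grid. Passing tests therefore validate the
*processing chain* — phase extraction, smoothing, differentiation, the
virtual-fields algebra, the failure diagnostics — under the study's
kinematic regime. They do not probe grid defects (debonded squares),
through-thickness (3D) effects, out-of-plane motion, material rate
dependence within a test, heterogeneous stiffness, or multiple/gradual
cracks; the real campaign's scatter carries all of these. The published
per-specimen tables shipped with the package are the bridge: their robust
reductions (median / MAD / COV, with the even-count median as the mean of
the central two and COV normalized by |median| so signed strain-rate series
summarize positively) and the orthotropy cross-checks are recomputed
exactly.

## Known limitations

* The crack model is a single instantaneous full-height release; crack
  speed, multiple cracks and cohesive behaviour are out of scope.
* Stiffness profiles of *fractured* specimens are contaminated near the
  crack when a section's compressive window overlaps the crack frame —
  visible as profile dips near the crack position, analogous to the real
  campaign's specimen-to-specimen scatter.
* `nu12`/`nu21` identification by OVF is weakly conditioned for aligned
  impacts (lateral strains are small); the dynamic reciprocity check
  (0.18 vs 0.12–0.13) inherits this.
* The trapezoid pulse option and binary-square grid rendering exist as
  robustness hooks and are not part of the default studies.
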