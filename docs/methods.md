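# Methods

`nanoct` re-creates, end to end and on synthetic data, the processing chain of
a laboratory cone-beam nano-CT ("NanoCT") of a resin-embedded soft-tissue
specimen: flat-field normalisation, single-distance phase retrieval,
regularized deblurring, FDK reconstruction with centre-shift and per-view
detector-offset compensation, sparsity-metric projection alignment, partial-
volume stitching and CNR/line-profile quantification.  This note records the
models, the defaults and the numerical choices.

## Acquisition model

The instrument is a lens-less shadow microscope: a nanofocus source, a
rotating specimen and a flat photon-counting detector (1475 × 195 pixels of
172 µm pitch in the reference configuration).  Geometric magnification
M = SDD/SOD sets the effective pixel size `pitch / M`; the reference
configurations (540 nm and 290 nm effective voxels, FOVs of ~796 × 105 µm and
~428 × 56 µm, 1,599 views over 360°) are reproduced by the closed-form
helpers in `nanoct.geometry`.  The instrument's true source-object and
source-detector distances are not known here;
`ConeBeamGeometry.from_effective_pixel` treats
SOD as a free parameter (fixture default 0.6 mm, giving a few degrees of cone
angle) constrained to reproduce the effective pixel size.

Conventions, fixed once and shared by projector and reconstructor: angles in
degrees at interfaces and radians internally; sample rotation counter-
clockwise viewed from +z (z = rotation axis); detector u horizontal,
v vertical, origin at the detector centre, values at pixel centres; the
angular grid is end-exclusive over 360° so view 0 is not duplicated.

## Synthetic data

Real NanoCT scan data at this scale is not publicly deposited, so a simulator supplies
every input.  Its defaults define the study conditions; they are chosen once,
on physical grounds, and are not tuned.

**Phantom.** A resin cylinder (background attenuation, zero outside) holding
feature classes of the imaged specimen: a hollow gut tube and longitudinal
muscle rods along the rotation axis, scattered dense nuclei, one ellipsoidal
statocyst.  Attenuations (resin 8 mm⁻¹, tissue 12–25 mm⁻¹) are fixture-scaled:
a ~35 µm phantom stands in for a ~1 mm resin block, and the values are scaled
up so optical depths (transmission 0.6–0.8) and therefore photon statistics
match the real acquisition.  Reconstructed values are in the phantom's units,
so all recovery tests are self-consistent; only the absolute µ scale is
non-physical.

**Drift.** Per-view detector offsets per axis are the sum of (i) up to three
sinusoids with frequencies drawn uniformly in [1.2, 5] cycles per scan,
peak-normalised to the smooth amplitude (default 3 px); (ii) an optional
Gaussian random walk; (iii) white Gaussian jitter (default σ 0.5 px).
Frequencies below ~1 cycle/scan are excluded by construction: the 0- and
1-cycle components of a detector offset are gauge modes — indistinguishable
from a global centre shift and from a rigid in-plane object translation
respectively — which no projection-consistency method can or needs to
recover.  Slow thermal drift in a real scan is absorbed into exactly those
modes.  The drift magnitudes themselves are plausible fixture settings, not
measured instrument values.

**Projector.** Per view, line integrals from the point source to each
detector pixel, trilinear volume sampling at a fixed step of 0.5 voxel
(`interp_order=3` switches to cubic sampling when sub-voxel smoothness of the
projection matters more than speed), transmission = exp(−∫µ dl).  Drift
shifts the detector sampling grid, so a drifted view is exactly a resampling
of the continuous projection — the basis of the shift-equivariance tests.

**Noise.** Intensity i0 × transmission (default i0 = 5000 counts); Fresnel
edge enhancement approximated by a transport-of-intensity Laplacian boost
I ← I − α∇²I rather than full free-space propagation (the pipeline only needs
an edge signature that the phase-retrieval filter inverts); Gaussian source
blur; 2% low-frequency vignetting shared between projections and the
(noise-free, as if averaged) flat field; Poisson sampling.  Counts are kept in
float64 so the infinite-flux limit is exact.

What the simulator does **not** model: polychromatic beam hardening, detector
charge sharing, specimen motion within one exposure, rotation-axis tilt or
wobble.  Passing tests therefore demonstrate correctness of the processing
chain under the stated error model, not robustness to every instrumental
effect of a real scan.

## Preprocessing

Flat-field: (raw − dark)/(flat − dark), floored at 1e-6; pixels with
non-positive flat − dark are flagged and filled with their 4-neighbour
median.

Phase retrieval is the single-distance homogeneous-object inversion
(TIE-Hom): divide the transmission spectrum by
1 + (R_eff δ/µ)·4π²|f|², R_eff = R/M, then −ln(·)/µ gives projected
thickness.  The 60 kVp spectrum is reduced to its detected mean energy
(20 keV); δ and µ were image-quality tuning parameters in the original
processing and are free parameters here (δ/µ defaults give a filter length of
a few pixels at fixture geometry).  The filter has unit DC gain, so δ = 0
reduces exactly to pure attenuation.

Deblurring is concretised as Wiener-type regularized inversion of an assumed
Gaussian PSF, gain H/(H² + α); the weighting factor α is the tuning knob.
Default order: phase retrieval, then deblurring (configurable; the original
order is unstated).  Both operations pad symmetrically to the next regular
FFT size to suppress wrap-around.

## Reconstruction

Voxel-driven FDK: per view the projection is shifted by the negated
(centre shift + per-view offset) — Fourier phase-ramp shifting by default,
because it is all-pass and preserves the noise power spectrum (see
Alignment) — cosine pre-weighted, row-filtered with a ramp filter, and
back-projected with bilinear detector sampling and the (SOD/(SOD+w))²
distance weight, quadrature factor Δβ/2 over the full turn.  In the
small-cone-angle limit a uniform object reconstructs to its µ value (checked
against the simulator to <5%).  Ram-Lak is the default filter with
Shepp-Logan and Hann apodization available.  Filter rows are padded to twice
the next regular FFT size with **edge replication** rather than zeros: a
constant row then filters exactly to zero and detector truncation does not
ring; for compactly supported sinograms the two paddings agree.  Full 360°
scans only; no short-scan weighting; log-domain input is taken from phase
retrieval when it ran, else as −ln of the normalised stack (never both).

## Alignment

The per-view detector offset is estimated by optimising the reconstruction
itself: the metric is the normalised gradient sparsity ‖g‖₁/‖g‖₂ of the
gradient-magnitude field (forward differences), lower = sparser = sharper.
It is scale-invariant, which the line search requires, and 0 for constant
input.

*Centre shift*: candidates over ±6 px are scanned at 0.5-coarse-pixel steps
on a detector-binned (factor 2) grid, scoring a central-slab (8 coarse
slices) reconstruction, then refined inside the best bracket by golden
section.  A flat landscape (cylindrically symmetric content) triggers a
warning.

*Per-view offsets*: coordinate descent — sweeps over views in randomised
order (fixed seed), per view a bracketed gradient-free line search (golden
section by default, bounded parabolic optional) over du, accepting a
candidate only if the metric does not increase, until the largest update
falls below 0.1 px or the sweep limit.  Back-projection is linear across
views, so the slab contributions of unchanged views are cached and each
candidate costs one single-view filtered back-projection.  Only du is
optimised by default: at small cone angles vertical drift barely affects
in-slice sparsity.  The view-mean of the offsets is removed (gauge fixing)
and folded into the reported centre shift; offsets are returned at
full-resolution scale, with `upscale_offsets` available for view-count
transfer by linear interpolation.

A numerical point worth recording: scoring candidate offsets with an
interpolating (spline) shift biases any sharpness metric towards non-integer
offsets, because interpolation smooths noise and smoothing lowers the
gradient ℓ₁/ℓ₂ ratio.  The Fourier phase-ramp shift is all-pass, eliminating
the bias; with it the metric landscape over the offset is smooth and convex
around the truth.

On the standard study conditions (64³ phantom, 180 views, 2.5 px axis offset,
3 px smooth drift + 0.5 px jitter per axis, i0 = 5000) the alignment recovers
the gauge-fixed offsets to ≲0.3 px RMSE and reconstruction error orders
aligned < centre-shift-only < uncorrected.  Problem sizes were chosen so the
full study runs in minutes on one CPU; at much smaller scales (≤48³, ≤90
views) the metric loses the statistical power to pin individual offsets below
the pixel level.

## Stitching

Adjacent partial volumes are registered with zero-normalised cross-
correlation computed by FFT sliding sums (per-lag means and variances over
the actual overlap), lags restricted to ≥10% overlap of the smaller volume,
and a quadratic three-point subvoxel refinement per axis — skipped when the
peak is exactly 1, so integer displacements of identical content are
recovered exactly.  A peak below 0.2 flags low confidence.  Merging places
volumes at the accumulated displacements (subvoxel fractions by linear
interpolation) and blends with a linear ramp (default 8 voxels) along the
stacking axis; weights are normalised, so non-overlap regions are copied
unchanged and agreeing overlaps are conserved exactly.  Whether the original
processing blended or hard-cut overlaps is unstated; ramp blending avoids
visible seams.

## Analysis

ROI statistics use the population (1/n) standard deviation — n vs n−1 is a
matter of convention, and one is fixed for determinism.  CNR = (µ_ROI − µ_ref)/√(σ²_ROI + σ²_ref) with the resin
background as reference; reported means are referenced so resin = 0, which
never changes a CNR value.  Line profiles sample bilinearly at unit-pixel
spacing (endpoint included), subtract the resin background and normalise to
a maximum of 1; a profile with no positive value is flagged degenerate
instead of being divided by a non-positive maximum.

## Determinism and pipeline

Every stochastic component (phantom nuclei, drift, Poisson noise, sweep
order) is driven by explicit seeds derived from the pipeline's global seed;
the demonstration pipeline (32³ phantom, 90 views) writes SHA-256 hashes of
all artifacts into its run report, and a rerun with the same configuration
and seed reproduces every hash bit-for-bit.

## Known limitations

- The sparsity alignment estimates lateral detector offsets only; tilt,
  wobble and source drift are out of scope (the metric framework would
  extend to them).
- Truncated (local-tomography) projections are handled only by edge padding.
- The Fresnel model is a Laplacian edge boost, adequate for testing the
  phase-retrieval inversion but not a wave-optical simulation.
- Gauge modes of the drift (constant and one-cycle components) are
  unrecoverable in principle; recovery errors are always reported after
  gauge fixing.
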