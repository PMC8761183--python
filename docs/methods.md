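# Methods

This note documents the models behind `petquant`, the parameters that matter,
the numerical choices, and what the synthetic experiments can and cannot say
about real scanner data.

## Phantom model

The phantom is declarative: an ordered list of compartments (box, ellipsoid,
z-aligned elliptical cylinder, capsule-chain tube) plus spherical lesions.
Later compartments paint over earlier ones with fractional-occupancy
compositing; lesions always composite last as
`v = (1−f)·background + f·lesion`, `f` the fraction of the voxel inside the
sphere. Because compositing is convex, a lesion hotter than its surroundings
can never create a cold rim — the digital analogue of casting shell-less
radioactive spheres rather than filling plastic-walled ones.

**Rasterization.** Sphere occupancy is computed per voxel: voxels whose
farthest corner is inside the sphere are 1, voxels whose box misses it are 0,
and boundary voxels are supersampled on a fixed-order lattice of sub-centres.
Sub-centre counting has a curvature bias of order `(h/r)²` (`h` the sub-cell
size, `r` the sphere radius), so the subdivision adapts to keep
`h ≤ 0.05·r`, clamped to 4–40 per axis. Measured total-volume error is below
0.2 % for 3–16-mm spheres at the default 3.65 × 3.65 × 3.27 mm spacing
(chosen so one voxel is ≈ 0.0433 mL and six voxels enclose the 0.26-mL apex
ROI). Non-sphere compartments use plain 4×4×4 supersampling; their boundary
voxels are a vanishing fraction of organ-scale volumes.

**Dual-isotope dynamics.** Concentrations are stated at a reference time and
decayed per compartment isotope when an image is built: ¹⁸F background
(t½ = 109.7 min) against effectively stable ²²Na lesions (t½ = 2.6 y,
decay ≈ 0.006 % per half-day). The equal-count frame planner solves the
exponential count integral in closed form for contiguous frames; under
contiguity the last/first duration ratio equals `exp(λ·span)`, so large
duration ratios require schedules spanning several half-lives. Inter-frame
decay correction divides out the within-frame decay average and references
the value back to the reference time; it is the exact inverse of the
frame-averaging operator and round-trips to 1e-9.

The default torso sections honour the design compartment volumes within
10 % (the ureters use deliberately fat tubing so the design volume fits the
body outline); anatomical shape realism is out of scope.

## Acquisition and reconstruction

The projector is slice-wise 2-D parallel beam: 192 angles over [0, π) by
default (divisible by the 24- and 32-subset splits; the experiments below use
96 for speed), radial bins of one voxel width, ray integrals accumulated by
dense sampling with bilinear spreading into a cached sparse matrix. Expected
counts are `sensitivity · duration · line integral`; the default sensitivity
(1.3·10⁻³ counts·mL/(kBq·s·mm)) makes a ~2.5-min pelvis-scale frame collect
on the order of 10⁶ counts per slice, and the compact lesion-ring experiments
use frame durations that restore that per-slice count level. No attenuation,
scatter, randoms or TOF. PSF modelling is an image-space 3-D Gaussian
(default FWHM 4.7 mm) applied inside the forward operator and, being
symmetric, again in the adjoint — so `⟨Px, y⟩ = ⟨x, Pᵀy⟩` holds exactly for
every PSF setting, which the tests verify at 1e-8.

**OSEM** is the standard multiplicative update over angle-interleaved subsets
(deterministic order); one subset is exactly MLEM. Zero-sensitivity voxels
are frozen at zero.

**BSREM** performs one preconditioned gradient-ascent step per subset on the
penalized likelihood, step `α_n·(x/S)·(M·∇L_s − β_int·∇R)` with `S` the full
sensitivity image, `M` the subset count, relaxation `α_n = α₀/(1+η·n)`
(defaults α₀ = 1, η = 0.05), followed by projection onto `x ≥ 0`. With
β = 0, one subset and unit step (η = 0) the update reduces algebraically to
MLEM — the equivalence test pins η = 0 because the identity is a property of
the unit-step update, not of the relaxed schedule. A divergence detector
raises if the penalized objective drops on three consecutive full iterations.

**RDP.** The penalty is the edge-preserving relative-difference form on the
26-neighbourhood with inverse-distance weights and ε = 1e-9; γ defaults
to 2. Its analytic gradient is verified against central finite differences at
1e-5. Penalty weights are not transferable between implementations, so the
printed β scale (0–800) maps to an internal weight
`β_int = (β/β_ref)·mean(S)` with `β_ref = 60 000`: on this projector that
places the printed sweep on the informative part of the smoothing curve
(β = 800 ≈ 1.3 % of the data scale), giving strictly monotone background
noise suppression over β ∈ {0, 50, 200, 800} without destabilizing the
ascent. Vendor-exact equivalence is not claimed.

## Segmentation

Both methods hill-climb from a user seed to the local maximum
(26-neighbourhood, ties to the lowest linear index). The threshold reference
is that *local* maximum so a nearby hot organ (bladder) cannot hijack a
lesion's threshold.

**40 % fixed threshold** keeps whole voxels: the face-connected component of
voxels ≥ 0.4 × local max containing the maximum. On noisy low-contrast
images the component can flood into the background — visible as the enormous
MTV over-estimates for 3–5-mm lesions, which is the expected failure mode of
fixed thresholding at these sizes.

**Gradient (inflection) segmentation** is sub-voxel:

1. the profile origin is refined to the sub-voxel centroid of the
   ≥ 50 %-of-peak core (the hottest voxel can sit ~2 mm off-centre from
   noise or ringing, and radii from an off-centre origin shorten oblique
   chords systematically);
2. 64 spherical-Fibonacci rays are sampled by cubic-spline interpolation at
   ¼-voxel steps (trilinear profiles are piecewise linear and bias the
   inflection inward by a sizeable fraction of a voxel) and smoothed with a
   1-step Gaussian;
3. the boundary per ray is the first zero-crossing of the second derivative
   at/beyond the steepest-descent point, with sub-step linear interpolation;
4. profiles are clipped at half the distance to a *competing* local maximum —
   one above twice the background median, at least 30 % of the lesion's own
   peak, and separated by a valley dipping below 60 % of the smaller peak
   (noise spikes inside the lesion's own spill-out must not truncate rays);
5. per-ray radii are smoothed across neighbouring directions (Gaussian in
   angle, σ = 20°);
6. the radii are corrected for curvature: the radial inflection of a
   Gaussian-blurred ball sits *inside* the true boundary (≈ `R − σ²/R` for
   `R ≳ 2σ`), so the forward map `R ↦ r*(R)` is computed from the analytic
   blurred-ball profile at the working resolution
   (`σ_eff² = σ_PSF² + mean(spacing²)/12`) and inverted by monotone
   interpolation. `resolution_fwhm = 0` disables the compensation;
7. the star-convex surface becomes fractional voxel weights through the same
   supersampler as the phantom rasterizer.

On noiseless blurred balls this recovers the 14-mm sphere's equivalent
diameter to ~0.01 mm and beats the threshold's absolute MTV error at every
diameter from 3 to 16 mm. On reconstructed images an irreducible effect
remains: penalized or early-stopped reconstruction genuinely shrinks the
apparent mid-level isocontour of lesions near ~1.7× the PSF FWHM (8 mm
here), which an edge tool faithfully reports while 40 %-of-an-under-recovered
max partially self-compensates — at that one diameter the threshold's small
positive bias can win the absolute-error comparison.

## Quantitation

Spherical ROIs (peak 1 mL, apex 0.26 mL, both centred on the max voxel; a
mean-maximizing peak placement is available behind a flag) use fractional
weights and hit their nominal volume to 1e-6 relative by blending two nearby
rasterized radii — ROI volume is linear in the weights, so the blend is
exact. Ground truth comes from an ideal cold scan (background zeroed): total
activity in a 40-mm fractional ROI over the known volume, which is invariant
to PSF blur by conservation; in the experiment runners each lesion is
isolated in its own cold image so neighbouring lesions cannot contaminate
the 40-mm ROI. σ_bkg is the sample SD across the five 0.5-mL background ROI
means (between-ROI, not within-ROI voxel SD), which makes
`SNR − CNR = a_bkg/σ_bkg` an exact identity.

## Experiments and statistics

The runners sweep frames × reconstructions × lesions × methods × metrics into
tidy tables; a master seed spawns per-(frame, reconstruction) child seeds via
`numpy.random.SeedSequence`, recorded per row, and reruns are byte-identical.
MAE aggregates recovery coefficients against the 100 % reference; the paired
t statistic is `|mean d|/(sd(d)/√n)` with a two-sided Student p (no
multiple-testing correction, α = 0.05 per test); linear fits report
`r² = 1 − SS_res/SS_tot` and raise on degenerate inputs rather than defining
0/0.

Problem sizes: the acceptance experiments run a 42×42×16 lesion-ring phantom
and a 64×64×8 noise cylinder at 96 angles — small enough to re-run the whole
pipeline in minutes on one CPU while keeping ≥ 10⁶ expected counts per slice
and every qualitative effect of interest (Gibbs overshoot peaking at
10–12 mm, noise amplification with OSEM iterations, monotone β smoothing,
the peak ≤ apex ≤ max robustness ordering).

## What the synthetic data do and do not show

The generator reproduces the *design* of the physical study — compartment
concentrations, shell-less constant-activity lesions over a decaying
background, equal-count framing, PSF blur, Poisson statistics — but not
scanner physics (attenuation, scatter, randoms, TOF, detector geometry),
vendor reconstruction internals, heterogeneous foam texture (a lognormal
texture option exists but defaults to off), or patient anatomy. Passing
tests therefore validate the *relative* behaviour of metrics and
segmentation methods under controlled partial-volume, ringing and noise
conditions; absolute recovery values and the published scanner-derived
robustness SDs are not comparable and are not asserted anywhere.

## Known limitations

- Star-convex masks cannot represent genuinely non-convex lesions.
- The curvature compensation assumes locally sphere-like lesions at a known
  working resolution; a badly wrong `resolution_fwhm` biases MTV.
- The slice-wise projector has no axial system model beyond the 3-D PSF.
- The equal-count planner assumes contiguous frames; gapped protocols must be
  specified explicitly as `Frame` lists.
- BSREM's printed-β mapping is projector-specific by construction.
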