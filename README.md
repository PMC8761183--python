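# petquant

Desk-scale quantitative evaluation of PET lesion metrics for high-contrast,
sub-10-mm lesions — the imaging situation typical of PSMA-targeted
prostate-cancer scans, where conventional NEMA-style phantom work (large
fillable spheres at 4:1 contrast, cold plastic shells) does not apply.

The package builds a digital anthropomorphic torso phantom with *shell-less*
spherical lesions (no cold rim), simulates dynamic dual-isotope acquisitions
with Poisson counting noise, reconstructs them with OSEM and BSREM, segments
lesions with a 40 %-of-max fixed threshold and a sub-voxel gradient
(inflection-point) method, and measures the full metric suite used to compare
them. It is aimed at physicists and image-analysis researchers who want a
fully seeded, re-runnable sandbox for studying how reconstruction parameters
and segmentation choices bias lesion quantitation.

## The model

**Phantom.** Compartments (body, liver, lungs, bladder, ureters) are painted
in order onto a voxel grid with fractional-occupancy rasterization; spherical
lesions composite last as `v = (1−f)·background + f·lesion`, so a hot sphere
never produces a cold rim. Lesions carry a long-lived ²²Na surrogate
(t½ = 2.6 y, effectively constant) against a decaying ¹⁸F background
(t½ = 109.7 min): the lesion-to-background ratio rises monotonically during
one multi-hour session, giving many contrast levels from a single fill
(nominal design: 7.2 / 28.8 / 57.6 kBq/mL lesions over 1.8 kBq/mL background,
i.e. 4:1, 16:1, 32:1).

**Acquisition and reconstruction.** A slice-wise 2-D parallel-beam projector
produces expected counts `ȳ = s·Δt·P x` (no attenuation/scatter/TOF), with an
image-space Gaussian PSF inside the forward and adjoint operators. OSEM is
the standard multiplicative ordered-subsets EM; BSREM maximizes the penalized
likelihood

    Φ(x) = Σᵢ yᵢ log ȳᵢ(x) − ȳᵢ(x) − β·R(x)

with the relative difference penalty
`R(x) = Σⱼ Σₖ w_jk (xⱼ−xₖ)²/(xⱼ+xₖ+γ|xⱼ−xₖ|+ε)` on the 26-neighbourhood.

**Metrics.** Per lesion: `a_max` (hottest voxel), `a_peak` (1-mL spherical
ROI), `a_apex` (0.26-mL spherical ROI at the max voxel — a hybrid metric
sized for focal sub-mL lesions), `a_mean` (weight-aware mask mean), MTV
(mask volume), TTU = `a_mean × MTV`, recovery coefficients
`RC = a_meas/a_true × 100`, and contrast/noise measures (C, CNR, SNR) from
five 0.5-mL background ROIs.

## Worked example

```python
from petquant import (build_phantom, forward_project, sample_counts,
                      Projector, ReconParams, reconstruct, SeedPoint,
                      segment_gradient, measure_lesion,
                      ground_truth_from_cold_scan, sphere_volume_ml)
from petquant.experiments import compact_recovery_phantom
from petquant.phantom import PhantomSpec
from dataclasses import replace

spec = compact_recovery_phantom(diameters=(14.0,))   # one 14-mm, 57.6 kBq/mL lesion
truth = build_phantom(spec, time=0.0)
proj = Projector(truth.grid, n_angles=96, psf_fwhm=4.7)
sino = sample_counts(forward_project(proj, truth, duration=850.0), seed=7)
params = ReconParams(algorithm="BSREM", subsets=32, iterations=25, beta=300.0)
recon = reconstruct(sino, proj, params)

les = spec.lesions[0]
cold = build_phantom(replace(spec, compartments=[replace(spec.compartments[0], concentration=0.0)]))
gt = ground_truth_from_cold_scan(cold, les.center, sphere_volume_ml(14.0), les.id)
mask = segment_gradient(recon, SeedPoint(les.center))
m = measure_lesion(recon, mask, gt)
print(f"RC_max {m.RC_max:.1f}%  RC_apex {m.RC_apex:.1f}%  "
      f"MTV {m.MTV:.2f} mL (true {gt.true_volume:.2f})  TTU {m.TTU:.1f} kBq")
```

Output:

```
RC_max 112.0%  RC_apex 92.5%  MTV 1.51 mL (true 1.44)  TTU 63.5 kBq
```

Read: the hottest voxel overshoots truth by ~12 % (Gibbs edge-ringing from
PSF modelling plus noise), the 0.26-mL apex ROI reads 92 % of the cast
concentration, and the gradient segmentation recovers the 14-mm sphere volume
to within about 5 %.

There is also a CLI mirroring the library
(`petquant phantom build / simulate / recon / segment / experiment run`);
run `petquant --help`.

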