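# hiemap

Quantitative MRI biomarkers for neonatal hypoxic-ischemic encephalopathy
(HIE): normative Z-score deviation mapping of apparent-diffusion-coefficient
(ADC) images, automated lesion detection with multi-rater consensus,
population lesion-frequency mapping with permutation-corrected
lesion-symptom statistics, lesion-based and lesion-free radiomics, wrapper
feature selection with cross-validated outcome prediction, and the study's
power/sample-size calculators — all exercisable end-to-end on synthetic
phantom cohorts with known ground truth.

## Who it is for

Researchers building imaging biomarkers for neonatal brain injury: the
package provides the full computational chain from a co-registered ADC
volume to a predicted 2-year neurodevelopmental outcome, plus the
simulation machinery to validate every stage without clinical data.

## The core measurement

Normal neonatal diffusivity varies strongly across brain regions, which
makes raw ADC thresholds unreliable. The package instead measures the
deviation from a voxel-wise normative atlas built from healthy controls:

    Z_ADC(u) = (y(u) − μ(v)) / σ(v)

where y(u) is the patient's ADC at voxel u and μ(v), σ(v) are the
per-voxel mean and sample standard deviation over the control cohort at
the anatomically corresponding atlas location v. Z ≈ −2 or below marks
abnormally low diffusivity (ischemic injury); Z ≥ 2 marks abnormally high
diffusivity (vasogenic edema). Because Z is invariant to any affine
intensity transform applied jointly to controls and patient, Z maps are
comparable across scanners and sites — a property the test suite enforces
to 1e-9.

Downstream of the Z map:

- **Detection** — thresholding (τ ∈ {−1, −1.5, −2, −2.5}) or a voxel-wise
  classifier on neighborhood features of ADC and Z, with morphological
  post-processing, lesion-frequency-atlas regularization, and a
  self-adaptive "silver standard" retraining step for images from unseen
  scanners.
- **Consensus** — binary STAPLE expectation-maximization fuses multiple
  expert annotations into a probabilistic reference and estimates each
  rater's sensitivity/specificity.
- **Population maps** — per-voxel lesion frequency over a cohort, and
  voxel-wise lesion-symptom mapping (VLSM) with max-statistic permutation
  correction (default 10,000 permutations, α = 0.05).
- **Features** — lesion-based anatomy/geometry/histogram/texture (GLCM,
  GLRLM) descriptors, and lesion-free per-region and per-tract statistics
  with left/right asymmetries for patients without a detectable lesion.
- **Prediction** — forward-inclusion/backward-elimination (FIBE) feature
  selection driven by inner cross-validated error, leave-one-out outcome
  prediction (sensitivity/specificity for binary outcomes, RMSE for
  Bayley scores), cross-site stability ranking, clinical-variable fusion,
  and comparison against NICHD–NRN expert severity scores.
- **Power** — the analytic sample sizes for the planned accuracy and
  correlation analyses, with Monte-Carlo verification, and the one-in-ten
  feature cap.

## Worked example

```python
from hiemap.synthetic import (PhantomSpec, LesionSpec, make_controls,
                              make_patient)
from hiemap.atlas import build_atlas, compute_z_map
from hiemap.detect import detect_by_threshold, score_detection
from hiemap.consensus import staple_fuse
from hiemap.synthetic import simulate_raters

spec = PhantomSpec()                       # 32x32x24 mm grid, 6 regions
controls, brain, labels = make_controls(spec, 13)
atlas = build_atlas(controls, brain)       # voxel-wise mu, sigma

lesion = LesionSpec(center=(16, 16, 12), radius_mm=4.0, z_offset=-3.0)
case = make_patient(spec, [lesion], seed=1)
zmap = compute_z_map(case.volume, atlas, patient_mask=brain)

mask = detect_by_threshold(zmap, tau=-2.0)
print("detection Dice:", round(score_detection(mask, case.true_mask).dice, 3))

raters = simulate_raters(case.true_mask, 3, sens=0.8, spec=0.99, seed=2,
                         brain_mask=brain)
fused = staple_fuse(raters)
print("consensus Dice:", round(score_detection(fused.consensus,
                                               case.true_mask).dice, 3))
print("estimated rater sensitivities:", fused.sensitivities.round(3))
```

Output:

```
detection Dice: 0.53
consensus Dice: 0.93
estimated rater sensitivities: [0.765 0.785 0.76 ]
```

The threshold Dice of 0.53 reflects the sampling noise of a 13-control
atlas (on a noise-free phantom the same threshold scores 1.0); the STAPLE
consensus of three imperfect raters reaches 0.93 against the planted
truth, and the estimated rater sensitivities sit near the simulated 0.8.

A command-line interface mirrors the stages (`hiemap simulate`,
`hiemap atlas build/zmap`, `hiemap detect threshold/score`,
`hiemap consensus`, `hiemap popmap freq`, `hiemap power ...`,
`hiemap pipeline`).

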