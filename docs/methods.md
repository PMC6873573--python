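# Methods

This note documents the models, parameter choices and numerical
conventions behind `hiemap`, and what the synthetic validation does and
does not demonstrate about real clinical data.

## The deviation model

A patient's ADC image is compared voxel-by-voxel to a normative atlas
built from healthy neonatal controls on the same grid:

    Z(u) = (y(u) − μ(u)) / σ(u)

- μ and σ are the per-voxel sample mean and **sample** standard
  deviation (divisor n−1) over n ≥ 2 controls. The sample-stdev
  convention is load-bearing: it is what makes Z-mapping the atlas's own
  controls give per-voxel mean exactly 0 and sample variance exactly 1,
  which the test suite asserts at 1e-9.
- Voxels whose σ falls below 1e-6 × (global mean μ) are removed from the
  atlas support and counted, rather than producing unbounded Z values.
  The threshold is far below any physiological variability; it only
  guards degenerate synthetic inputs.
- Z is invariant to any affine intensity transform v → a·v + b (a > 0)
  applied jointly to the controls and the patient. This is the formal
  reason Z maps transfer across scanners whose ADC scales drift, and it
  is asserted numerically rather than assumed.
- Patient-to-atlas spatial correspondence is a pluggable interface whose
  default is the identity: inputs are assumed already co-registered.
  Deformable registration is deliberately out of scope — it belongs to
  dedicated, validated external tools.
- One atlas covers the neonatal window; no age modulation. Whether the
  population or sample stdev convention is the "right" normative choice
  is open in the literature; the sample convention is fixed here and
  test-enforced.

## Lesion detection

Thresholding uses the strict inequality z < τ (τ negative for ischemic
lesions); a `high_side` flag selects z > |τ| for vasogenic edema, which
is kept out of the default detection mask. Morphological post-processing
is standard opening-then-closing with ball structuring elements followed
by removal of 26-connected components below a minimum size. Two
conventions worth noting:

- Closing is implemented as dilation followed by erosion with the
  *outside of the grid treated as foreground* during the erosion;
  scipy's stock closing is not extensive at array borders, which would
  break the set-inequality invariant (closing ⊇ input) the tests check.
- Connectivity is 26 and structuring elements are balls; these are
  conventional choices, configurable at the call sites.

The voxel-wise classifier characterizes each voxel by its ADC and/or Z
value plus the mean and standard deviation of each channel in a cubic
neighborhood (radius 1 by default). The default estimator is a
standardized, class-balanced logistic regression: the channels differ by
orders of magnitude (Z near unity, ADC near 10³) and lesion voxels are
rare, so unscaled, unweighted fits are poorly conditioned for the
adaptation step below. Any scikit-learn classifier exposing
`predict_proba` (calibrated SVM, random forest) can be substituted.

**Self-adaptation ("silver standard").** For a target image from an
unseen scanner, voxels the source model labels lesion with probability
above a confidence level (default 0.75) become provisional lesion
samples, voxels below 1−confidence become provisional background, and
the classifier is refit on the target's own features of those voxels
only, then re-predicts at 0.5. The symmetric background class is an
extension of the high-confidence-lesion idea — a two-class model cannot
be refit from positives alone. If either silver class is empty the
unadapted prediction is returned unchanged, with a flag. In the
simulated cross-site scenario (site scale 1.05–1.15 applied to the
patient while the atlas stays source-site), adaptation improved Dice on
10/10 seeds; without feature standardization and class balancing it did
not, which is why those are defaults rather than options.

**Scoring.** Dice = 2|P∩R|/(|P|+|R|), with the both-empty case defined
as Dice 1 and flagged: patients without detectable lesions are a normal
part of HIE cohorts and an undefined 0/0 must not poison cohort means.
ROC sweeps report operating points at the requested thresholds; the AUC
is the rank statistic of the continuous Z values (midranks for ties), so
it measures ranking quality rather than depending on the threshold grid.

## Consensus (STAPLE)

Classic binary STAPLE EM: latent true segmentation, per-rater
sensitivity p_j and specificity q_j, per-voxel posterior E-step,
closed-form M-step. Defaults: prior = mean positive fraction across
raters ("from-data"), p_j = q_j = 0.99 initialization, tolerance 1e-6 on
the summed parameter change, 100 iterations maximum, posterior ties at
0.5 labeled lesion. All-blank rater sets return a blank consensus with
the per-rater parameters reported missing — blank annotations are
legitimate input, not an error. The observed-data log-likelihood is
non-decreasing across iterations (property-tested), and with raters
simulated at known performance the estimates recover (p_j, q_j) within
±0.05 at ≥ 10⁴ voxels.

## Population maps and VLSM

The lesion-frequency atlas is the per-voxel mean of binary cohort masks.
VLSM tests each voxel lesioned in at least `min_lesion_count` patients
(default 5 — association is undefined at almost-never-lesioned voxels):

- binary outcome or group label: chi-square score statistic on the 2×2
  table of lesion presence × label;
- continuous outcome: absolute Welch t statistic, lesioned vs
  non-lesioned patients.

Family-wise correction is max-statistic permutation: labels are permuted
(default 10,000 times), each voxel's corrected p is
(1 + #{max over voxels of permuted statistic ≥ observed})/(1 + n_perms),
so p is never zero and corrected p dominates uncorrected p by
construction. Under a null with identical lesion statistics in both
groups, the measured family-wise error at nominal 0.05 was 0.005 over
200 replicates — conservative, as max-statistic correction on discrete
data tends to be. The per-voxel statistics are documented choices; the
VLSM literature uses several, and they are recorded in the result
metadata.

## Features

- First-order statistics: percentiles {0, 25, 50, 75, 100} with linear
  interpolation, mean, stdev, Fisher skewness, excess kurtosis, Shannon
  entropy (base 2, 32 equal-width bins over the region range) and
  uniformity (sum of squared bin probabilities). Constant regions define
  skewness/kurtosis as 0, entropy 0, uniformity 1 — NaN must not
  propagate into feature selection.
- Texture: symmetric GLCM over the 13 unique 3-D unit directions at 16
  gray levels (contrast, energy, homogeneity, correlation) and
  axis-wise GLRLM run statistics (short/long-run emphasis, run-length
  non-uniformity). All quantization parameters are configurable.
- Geometry: volume, axis-aligned maximum diameters, surface area by
  exposed-face counting, largest axial cross-section, compactness
  (volume / bounding box), surface-to-volume ratio, and **two**
  sphericity variants: `sphericity` from the face-counted area (exact
  closed forms on cubes: a single 1 mm voxel gives
  π^(1/3)·6^(2/3)/6 ≈ 0.806) and `sphericity_mesh` from a
  marching-cubes mesh area. The staircase bias of face counting
  overestimates a smooth sphere's area by roughly half, capping its
  sphericity near 0.67; the mesh variant restores ≥ 0.9 on a digital
  sphere. Both are emitted because each is the right answer to a
  different question.
- Anatomy: per-region and per-tract injured fractions, lesion mass
  center in world coordinates, raw left/right injured-volume ratios per
  declared region pair plus a bounded asymmetry index
  (L−R)/(L+R+1e-12).
- Lesion-free vectors: per-region and per-tract ADC/Z statistics, region
  volumes, and left/right asymmetry of every paired feature. An empty
  lesion mask yields an all-missing lesion-based row with the same
  feature inventory, which routes the patient to the lesion-free
  prediction branch.
- The NICHD–NRN encoder maps regional injury flags (deep gray, internal
  capsule, watershed, cerebral extent, hemispheric devastation) to the
  six ordinal levels {0, 1A, 1B, 2A, 2B, 3}; an exhaustiveness test
  enumerates all flag combinations. The minimal/extensive cerebral
  distinction is taken as categorical input rather than inferred from
  voxel counts, since its clinical definition is qualitative.
- Outcome derivation: developmental delay = any Bayley-III domain ≤ 85
  (boundary inclusive) OR documented delay; motor impairment = motor
  score ≤ 85 OR documented motor abnormality; missing inputs propagate
  to missing outputs — absence of documentation is never read as a
  negative finding.

## Prediction

**FIBE.** Greedy forward inclusion from the best single feature,
backward elimination, alternating until a full pass changes nothing or
the cap is reached (pass limit 50, flagged if hit). The selection
criterion is repeated stratified/K-fold cross-validated error inside the
training data (5 folds × 3 repeats), with ties broken lexicographically
by feature name so column order is irrelevant. A step is accepted only
when the error improves by more than one standard error of the
fold-error mean. This guard is essential, not cosmetic: with ~20
candidates, the minimum of a noisy CV estimate almost surely shows
*some* spurious decrease, and a literal any-decrease rule chained 5–8
noise features onto a perfectly recovered signal pair. With the one-SE
rule the planted-signal benchmark (60 samples, 2 signal + 18 noise
features) recovers exactly {x1, x2} on 10/10 seeds. Resubstitution
error as the criterion for the seed feature overfits for the same
reason and is replaced by the same inner CV.

**Leave-one-out evaluation.** N folds, each patient tested once.
Median imputation (with missingness indicator columns), standardization
and any FIBE selection are refit inside every training fold — no
leakage, verified by a canary: on outcome-shuffled data the mean Youden
index over 20 seeds stays within ±0.15 of zero. Binary outcomes report
sensitivity and specificity; continuous outcomes report RMSE. Default
learners are linear-kernel SVM / SVR; anything scikit-learn-compatible
plugs in.

**Cross-site stability.** Each feature is scored per site by
leave-one-site-out transfer: a univariate model trained on the other
sites, evaluated on the held-out site; stability = mean − λ·std across
sites (λ = 1). Within-site CV would be blind to per-site monotone
intensity shifts — any site-wise rescaling leaves within-site
separability untouched — so transfer scoring is what lets a
site-invariant Z feature outrank its raw-ADC counterpart, which it does
on ≥ 8/10 simulated seeds. Features missing at any site are flagged and
ranked last.

**Expert comparison.** The ordinal NICHD–NRN score becomes a family of
binary predictors (one per cut, five cuts for six levels); each cut's
sensitivity/specificity is tabulated next to the ML model's. No single
clinical cut is privileged because none is canonical.

## Power and sample size

Two-group comparison of means (normal approximation):
n = 2(z_{1−α/2} + z_{power})²·sd²/Δ² per group, **rounded up**; the Dice
designs (baseline 0.52, sd 0.15, α 0.05 two-sided, power 0.8) give
unrounded 55.2 and 12.2, hence 56 and 13 patients per group at target
means 0.60 and 0.69. Correlation detection (Fisher-z approximation):
n = ((z_{1−α/2} + z_{power})/atanh ρ)² + 3, **rounded to nearest**;
ρ = 0.5 gives unrounded 46.07 at power 0.95 and 71.18 at power 0.995,
hence 46 and 71 subjects. The two rounding conventions are exactly the
ones that reproduce these printed values and are reported alongside the
unrounded numbers. The one-in-ten rule caps predictors at ⌊n/10⌋
(0 below n = 10, with a warning). A Monte-Carlo oracle simulates each
design at its computed n and reproduces the nominal power within ±0.04
at 10⁴ simulations; under zero effect the rejection rate matches α.

## The synthetic phantom

Defaults (which are also the validation conditions): 32×32×24 grid at
1 mm isotropic, ellipsoidal brain, 6-region parcellation that is
mirror-symmetric about the x midline (3 left/right pairs), region mean
ADC 1050/1200/1350 ×10⁻⁶ mm²/s with stdev 60 — inside the plausible
neonatal band of 800–1800. Controls draw voxel-wise
Normal(region mean, region sd). Lesions are spheres (or stretched
blobs) specified in **σ units**: the voxel shift is z_offset·σ(region),
applied before the site transform v → scale·v + offset, so the
ground-truth Z inside a lesion is known by construction; a noise-free
mode sets tissue exactly at the region mean, making planted Z values
exact. Raters flip voxels independently (Bernoulli at the stated
sensitivity/specificity; defaults 0.8/0.999 are fixture choices, not
clinical estimates). Outcomes follow a logistic model in the lesion
fraction of a designated eloquent region (defaults: intercept −4,
slope 8) plus a linear Bayley motor score (base 100, slope −60,
noise sd 5, clipped to [50, 150]). All generators are deterministic
under a fixed seed.

What this phantom does **not** emulate: MRI noise spectra, partial
volume, motion artifacts, anatomically realistic parcellations,
age-dependent atlas drift, spatially correlated rater error, or
pseudo-normalization dynamics. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated generative
model — not clinical performance. The pilot-scale clinical accuracies
(algorithm-vs-expert Dice near 0.69, inter-expert 0.71) require real
cohorts and are intentionally not simulated; the phantom benchmarks
substitute exact, construction-known targets instead.

## Benchmark problem sizes

The acceptance benchmarks run at sizes chosen to give stable statistics
in minutes on one CPU: 200 null replicates × 500 permutations for VLSM
calibration (1000 permutations for effect recovery, 80 patients, 10
seeds), 10 seeds for the consensus and FIBE benchmarks, 20 seeds for
the leakage canary, 10⁴ simulations for the power oracle. The VLSM
effect-recovery cohort enriches half its lesions in the eloquent region
and uses logistic slope 16 (rather than the phantom default 8) so the
planted association has adequate contrast at the ~0.25–0.45 region
overlap fractions radius-6 lesions produce; this is a power decision
made at design time, documented here.

## Known limitations

- The identity registration restricts real-data use to pre-registered
  inputs.
- GLCM/GLRLM features assume a meaningful intensity range in the region;
  two-voxel regions are the accepted minimum and degenerate to flagged
  constants.
- STAPLE is the classic binary variant without spatial consistency
  terms.
- The FIBE one-SE rule trades a small amount of sensitivity (a weakly
  informative feature may be passed over) for a large specificity gain;
  at clinical effect sizes this is the right trade, but it is a rule the
  caller can see in the trajectory, not a hidden heuristic.
- Max-statistic VLSM correction is conservative on discrete data;
  observed family-wise error ran an order of magnitude below nominal.
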