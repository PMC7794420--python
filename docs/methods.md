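# Methods

`prm3d` implements a quantitative-CT pipeline for COPD: voxel-wise
parametric response mapping (PRM) of registered inspiration/expiration lung
CT, deformation metrics derived from the registration displacement field, a
9-layer volumetric CNN classifier with five-fold cross-validation, and 3-D
Grad-CAM saliency.  Because clinical paired-CT cohorts are not openly
available, the package ships a calibrated synthetic phantom generator that
exercises every stage end to end with known ground truth.  This note
records the models, the parameter choices, and what the synthetic results
do and do not demonstrate.

## Parametric response mapping

A registered voxel carries an inspiratory attenuation (at total lung
capacity) and an expiratory attenuation (at functional residual capacity),
both in Hounsfield units.  Two fixed cuts classify each lung voxel:

* **emphysema (code 64)** — IN ≤ −950 HU and EX ≤ −856 HU,
* **functional small-airway disease, fSAD (code 32)** — IN > −950 HU and
  EX ≤ −856 HU,
* **normal (code 8)** — EX > −856 HU.

Both comparisons are inclusive, so a voxel at exactly (−950, −856) codes as
emphysema.  The physiologically implausible quadrant (IN ≤ −950,
EX > −856) is folded into "normal", with a diagnostic count logged.
Per-subject summaries (Emph%, fSAD%, Normal%) are fractions of lung-mask
voxel *counts*, not physical volume — identical on the uniform grids used
here — and sum to 100 exactly.  TLC and FRC are obtained by integrating
the linear air-fraction model β(HU) = clamp((55 − HU)/1055, 0, 1) over the
mask (pure air −1000 HU, soft tissue +55 HU) at the two breath holds.

## Deformation metrics

The displacement field u maps the expiration grid to inspiration space
(x_insp = x_exp + u(x_exp), mm).  All metrics live on the expiration grid:

* **F = I + ∇u** by central differences in physical mm, second-order
  one-sided at the boundary (affine fields are therefore exact in the
  interior);
* **J = det F** — local expansion toward inspiration, J > 1 inflating;
* **principal stretches** λ1 ≥ λ2 ≥ λ3 from the eigenvalues of FᵀF;
* **ADI** = √(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²), zero for isotropic motion;
* **SRI** = (2/π)·atan2(λ2(λ1−λ2), λ3(λ2−λ3)) ∈ [0,1], 0 slab-like,
  1 rod-like;
* **ΔV_air^f** = J·β_IN(x + u(x)) − β_EX(x) per expiration voxel, the
  J-weighted air-volume change (the unweighted difference is the other
  defensible reading of "air-volume difference per voxel"; the J-weighted
  form is used because it measures the same material region at both breath
  holds).  Out-of-grid correspondences clamp to the nearest edge and are
  logged.

Per-subject scalars are voxel-*medians* over the lung mask — robust to
lesion outliers; the alternative (means) is trivially obtainable from the
returned maps.

## Synthetic phantom cohort

Each subject is an ellipsoidal "lung" (semi-axis fractions 0.30/0.35/0.42
of a 64³ grid at 4 mm isotropic spacing) inside +40 HU soft tissue.
Disease is planted as spherical blobs (radius uniform in 2–4.5 voxels),
accreted until the planted voxel count matches the drawn burden exactly
(the last blob is trimmed nearest-first).  Lesion centres are drawn 2:1 in
favour of the upper third of the lung for COPD subjects (uniform for
non-COPD), so saliency maps have a known spatial target.

Class HU levels (mean, SD; IN / EX):

| tissue     | IN            | EX            |
|------------|---------------|---------------|
| normal     | −870, 30      | −780, 28      |
| emphysema  | −975, 10      | −920, 15      |
| fSAD       | −900, 15      | −900, 15      |

These place each class safely on its side of the −950/−856 cuts while
leaving a small, testable misclassification tail: ~0.4% of normal voxels
fall below −950 at IN and ~0.3% below −856 at EX, biasing measured fSAD%
upward by ≈0.2 percentage points at COPD burdens — well inside the
recovery tolerances below.  HU volumes are rounded to int16 and clipped to
[−1100, 3100].

Group burden distributions default to the study cohort statistics
(mean, SD): Emph% 8.5/7.5 (COPD) vs 1.7/2.5 (non-COPD), fSAD% 23.7/13.6 vs
11.2/13.4, mean Jacobian 1.5/0.3 vs 1.7/0.4.  Draws are truncated to
[0, 60] (burdens; joint cap Emph+fSAD ≤ 80) and [1, 3] (J).  Plain
truncation would inflate the group means (for non-COPD Emph% from 1.7 to
≈2.75, since the SD exceeds the mean), so the generator root-solves the
pre-truncation location so that the *post*-truncation mean equals the
nominal mean.  A left-truncated normal cannot match both mean and SD when
SD/mean > 1; the mean — the quantity the recovery tests measure — is
matched exactly and the realised SD is somewhat smaller than nominal for
the non-COPD burdens.

The displacement field is u = w(x)·[(A − I)(x − c) + p(x)]: a global
anisotropic scaling A (axis ratios 1.15/1.00/0.87 normalised to det 1,
magnitude set by the subject's target J), a Gaussian-smoothed random
perturbation p (σ = 4 voxels, RMS 1 mm), and a factor w < 1 (0.7 inside
lesions, smoothed) that suppresses local expansion in diseased tissue —
air trapping, which gives the J/ADI/SRI network inputs a group signal.
Because F is linear in a global field scale, the voxel-median J over the
mask is calibrated to the drawn target by a bounded 1-D solve (the
anisotropy caps the achievable median when the target is near 1, hence
minimisation rather than root bracketing); the per-subject residual is
below 0.01.

What the phantoms do **not** model: airway trees, lobes and fissures,
vessels, reconstruction-kernel texture, registration error (the field is
the generator's own), or any correlation between burden and lung geometry.
Passing recovery tests therefore demonstrates that the *measurement*
pipeline is faithful, not that the classifier would reach the same
accuracy on clinical data.

## Network input preparation

Every input kind is trilinearly resampled to 32³ on the voxel-centred
lattice — including the PRM code map, accepting blended codes at class
borders — then mapped into [0, 1] with a fixed window per kind: HU
[−1024, 0]; PRM codes /64 (monotone in severity: 0, 0.125, 0.5, 1);
J [0.5, 3]; ADI [0, 2]; SRI identity; ΔV_air^f [−0.5, 1.5].  Fixed windows
rather than per-volume min–max, because per-volume scaling would erase the
between-group density differences the classifier must learn.  The IN+EX
concatenation stacks two channels; all other kinds are single-channel.

## Classifier

Three conv → batch-norm → ReLU → max-pool blocks (3×3×3 kernels, same
padding, filters 32/64/128, 2×2×2 pooling: 32³→16³→8³→4³), then fully
connected 128 → 128 → 2 with ReLU on the first two and a softmax output.
Weights (conv and dense) are initialised from a normal with mean 0 and
SD 0.1; biases start at zero.  One input channel
gives 1,343,490 trainable parameters.  Training minimises the binary
cross-entropy of the softmax pair with Adam at learning rate 1e-4;
"iterations" are optimizer steps over shuffled mini-batches.  The
study-scale schedule is 2500 iterations at batch 50; the desk-scale
default is a few hundred iterations at batch 25.

The layers are implemented directly on numpy (float32, one BLAS GEMM per
convolution pass via a column buffer; explicit backward passes verified
against finite differences and a scipy correlation oracle).

Batch normalization keeps running statistics with momentum 0.9 during
training.  At short desk-scale schedules those running averages lag the
rapidly changing weights badly enough to break eval-mode inference, so
after the last iteration the statistics are re-estimated in one pass over
the training set at fixed weights (mean of batch means; law-of-total-
variance combination of batch variances) — the standard "precise BN"
correction.  At long schedules the two coincide.

Cross-validation is stratified k-fold (default 5) with a fixed seed: a
disjoint cover, each subject tested exactly once, per-fold class ratio
within one subject of the global ratio.  The primary report pools all
held-out predictions; per-fold reports are available from the fold
results.  COPD is the positive class, ties at the 0.5 threshold count
positive, and ROC/AUC come from the full threshold sweep with trapezoidal
integration (equal to the Mann–Whitney concordance probability).

## Grad-CAM

Saliency for a target class is the ReLU of the gradient-weighted channel
sum of the third conv block's ReLU output (128 channels at 8³ — taken
before the final pool for the extra resolution), with channel weights from
global average pooling of the gradients of the class *log-odds* (its logit
minus the other class's logit — for a two-class softmax the shared
component of the logits carries no class evidence, and its gradients
swamp the discriminative signal at short training schedules), trilinearly
upsampled to 32³ and max-normalised per volume.  At desk-scale schedules
the localization contrast is real but modest; longer training sharpens the
maps.  Overlays export the heatmap volume
plus mid-plane (floor(shape/2)) axial/coronal/sagittal PNGs.

## Problem sizes used by the test suite and acceptance script

* Recovery of the group calibration: 500 subjects per single-group cohort;
  the tolerance is two standard errors of the measured cohort mean.
* Classifier check: a 300-subject cohort (150/150), five-fold
  cross-validation at 110 iterations, batch 25 — a schedule chosen as the
  desk-scale point where held-out accuracy has stabilised (well past the
  BN re-estimation knee); the pooled accuracy is required to reach 0.85.
* Saliency check: true positives of the first fold; mean heat in the upper
  third of the lung must exceed the lower third, matching the planted 2:1
  upper-lobe lesion bias.

## Known limitations

* The ADI/SRI formulas implement the principal-stretch definitions stated
  above; other anisotropy indices exist in the registration literature and
  differ in normalisation.
* ΔV_air^f is the J-weighted variant (see above).
* Phantom TLC/FRC are whatever the arbitrary geometry yields (~2–3 L);
  group air-volume statistics are not calibrated, only fractions and J.
* The CNN training loop is single-threaded CPU numpy: study-scale
  schedules (2500×50) run, but take hours, and no GPU path is provided.
* Evaluation reports treat undefined ratios (empty denominators) as 0
  with a warning rather than raising.
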