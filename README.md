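# prm3d

Parametric response mapping (PRM) and 3-D CNN classification of paired
inspiration/expiration lung CT, for quantitative-imaging researchers
studying COPD.

Chronic obstructive pulmonary disease shows up in CT as two voxel-level
phenotypes: emphysematous tissue, which stays abnormally dark (air-like) at
both breath holds, and functional small-airway disease (fSAD), which looks
normal at full inspiration but traps air at expiration.  With the
expiratory scan registered onto the inspiratory one, each lung voxel
carries a pair of attenuations and is classified by two thresholds:

| class          | rule                          | code |
|----------------|-------------------------------|------|
| emphysema      | IN ≤ −950 HU and EX ≤ −856 HU | 64   |
| fSAD           | IN > −950 HU and EX ≤ −856 HU | 32   |
| normal         | EX > −856 HU                  | 8    |

From the registration displacement field u (with F = I + ∇u) the package
also computes the functional variables J = det F (local volume change),
the anisotropic deformation index ADI, the slab–rod index SRI, and the
per-voxel air-volume change ΔV_air^f = J·β_IN(x+u) − β_EX, where β is the
linear air fraction of a voxel's attenuation.

On top of these inputs sits a 9-layer volumetric CNN (3 × [conv 3×3×3 →
batch norm → ReLU → max-pool], filters 32/64/128, then 128→128→2 fully
connected with softmax; Adam, binary cross-entropy, 32³ inputs normalised
to [0,1]) evaluated by stratified five-fold cross-validation, and a 3-D
Grad-CAM module that renders class-discriminative saliency over the lung.

Because clinical paired-CT cohorts are private, the package includes a
phantom generator that plants emphysema/fSAD lesions and smooth
displacement fields in synthetic lungs, with group burden distributions
calibrated so cohort statistics match the study population it models
(COPD: Emph% 8.5 ± 7.5, fSAD% 23.7 ± 13.6, J 1.5 ± 0.3; non-COPD:
1.7 ± 2.5, 11.2 ± 13.4, 1.7 ± 0.4).  Every stage of the pipeline is
testable end to end against this known ground truth.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import numpy as np
from prm3d.phantom import PhantomParams, SubjectTruth, generate_paired_scan, COPD
from prm3d.prm import classify_volume, summarize
from prm3d.deformation import functional_maps

truth = SubjectTruth(group=COPD, emph_pct=8.0, fsad_pct=22.0, mean_j=1.5)
pair, mask, field = generate_paired_scan(truth, PhantomParams(),
                                         np.random.default_rng(0))
s = summarize(classify_volume(pair), pair)
fm = functional_maps(pair, field)
print(f"Emph% {s.emph_pct:.2f}  fSAD% {s.fsad_pct:.2f}  "
      f"Normal% {s.normal_pct:.2f}  median J {fm.j_median:.3f}")
```

prints

```
Emph% 7.97  fSAD% 22.24  Normal% 69.79  median J 1.500
```

— the planted 8% emphysema and 22% fSAD are recovered to within voxel
quantization plus a ~0.2-point air-trapping noise tail, and the
displacement field's median Jacobian hits its 1.5 target.  The scripts in
`examples/` walk through each capability (PRM, deformation metrics,
training + Grad-CAM); the `prm3d` command exposes the same stages from the
shell (`prm3d run --config cfg.yaml` chains them).

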