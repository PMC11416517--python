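# csvdnet

A volumetric deep-learning pipeline for detecting **grade-1 cerebral
small vessel disease (cSVD)** — the mildest radiological grade of
white-matter hyperintensity burden — from brain MRI DICOM series.  It is
aimed at researchers who want a complete, reproducible, data-free
reference implementation of the classical small-cohort 3D-CNN workflow:

- **DICOM preprocessing** into fixed stacks: per-patient slices are
  sorted by instance number, filtered to axial T1W/T2W/FLAIR, small
  (64x64) matrices discarded, the rest shrunk to 128x128 by
  area-preserving downsampling, z-scored with pooled cohort statistics
  `x̂ = (x - μ)/σ`, and zero-padded along depth to a constant
  `(120, 128, 128, 1)` tensor.
- **A 3D CNN** of four convolutional blocks — Conv3D(3³, stride 1,
  valid, ELU) → batch norm → max-pool(2³) with 8/16/32/64 filters —
  followed by flatten → FC(40, ELU) → dropout(0.2) → FC(10, ELU) →
  dropout(0.2) → FC(1, sigmoid), He initialization
  `W ~ N(0, 2/n_in)`, and L2(0.05) on every conv/FC kernel:
  534,653 parameters (534,413 trainable, 240 non-trainable).  The
  network runs on a small NumPy reverse-mode engine whose gradients are
  finite-difference verified.
- **Training protocol**: stratified 80/20 test carve-out, class
  balancing by in-plane augmentation (translation / shear / rotation /
  affine), 80/20 train/val split, Adam (lr 1e-3) on binary
  cross-entropy + L2 with reduce-on-plateau, and k-fold cross-validated
  reporting (stratified 5-fold with augmentation, 6-fold inside a 90/10
  split without).
- **Metrics** computed from first principles: accuracy, precision and
  recall from TP/FP/TN/FN; AUC as the rank statistic
  `P(score⁺ > score⁻) + ½·P(tie)`; BCE
  `-(1/N) Σ yᵢ log ŷᵢ + (1-yᵢ) log(1-ŷᵢ)`.
- **3D Grad-CAM**: rectified, gradient-weighted feature-map sums from a
  convolutional block, upsampled trilinearly and rendered as per-slice
  heat overlays.
- **A synthetic MRI phantom cohort** (seeded, written as standard DICOM)
  that mimics the structure of a small clinical cohort and plants
  periventricular hyperintense lesions on T2W/FLAIR in the diseased
  class — so the entire pipeline is testable without any clinical data.

## Worked example

Run the full pipeline at the reduced desk-scale profile (24x32x32
stacks, three conv blocks) on the default 40-patient phantom cohort
(26 diseased : 14 control):

```bash
csvdnet run --seed 3 --epochs 2 --out run_output
```

which generates the DICOM cohort, preprocesses it, trains for two
epochs and prints the metrics on the 8 held-out test patients:

```json
{
  "accuracy": 0.75,
  "auc": 0.8666666666666667,
  "precision": 0.8,
  "recall": 0.8,
  "bce_loss": 0.7638762558702855
}
```

Two epochs only begin to separate the classes (AUC 0.87: 87% of
diseased/control test pairs are ranked correctly); the study below
trains the same setup to convergence.  Inspect the architecture against
its published summary:

```bash
csvdnet model summary
```

```
Layer                     Input Shape               Output Shape              Parameters
Input Layer               (None, 120, 128, 128, 1)  (None, 120, 128, 128, 1)  0
Conv Block1               (None, 120, 128, 128, 1)  (None, 59, 63, 63, 8)     256
Conv Block2               (None, 59, 63, 63, 8)     (None, 28, 30, 30, 16)    3536
Conv Block3               (None, 28, 30, 30, 16)    (None, 13, 14, 14, 32)    13984
Conv Block4               (None, 13, 14, 14, 32)    (None, 5, 6, 6, 64)       55616
Flatten                   (None, 5, 6, 6, 64)       (None, 11520)             0
Fully Connected           (None, 11520)             (None, 40)                460840
Dropout                   (None, 40)                (None, 40)                0
Fully Connected           (None, 40)                (None, 10)                410
Dropout                   (None, 10)                (None, 10)                0
Fully Connected           (None, 10)                (None, 1)                 11
Total Parameters                                                              534,653
Trainable Parameters                                                          534,413
Non-Trainable Parameters                                                      240
```

Other subcommands: `csvdnet phantom generate`, `csvdnet preprocess`,
`csvdnet explain` (Grad-CAM overlays for a saved model/stack), and
`csvdnet run --config run.yaml` for fully configured runs.

From Python, the desk-scale learnability study:

```python
from csvdnet.experiments import reduced_phantom_study

result = reduced_phantom_study(seed=1)   # ~3 minutes on one core
print(result.test_accuracy, result.test_auc)
print(result.cam_inside_mean, result.cam_outside_mean)
```

trains the reduced-profile model on a 40-patient high-contrast phantom
cohort (26 diseased : 14 control) with the headline recipe (Adam,
rotation + affine balancing).  At seed 1 this reaches held-out accuracy
1.0 and AUC 1.0 on the 8 test patients, with a Grad-CAM lesion-overlap
statistic of 0.33 mean relevance inside the planted lesion masks versus
0.12 outside, averaged over the 26 diseased phantoms.

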