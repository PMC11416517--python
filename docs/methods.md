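# Methods

## Problem and scope

`csvdnet` implements a computer-aided diagnostic pipeline for grade-1
cerebral small vessel disease (cSVD) from volumetric brain MRI.  Grade-1
cSVD manifests radiologically as periventricular white-matter
hyperintensities (WMH): bright ellipsoidal lesions adjacent to the
lateral ventricles on T2-weighted and FLAIR sequences.  The pipeline
turns a patient's raw DICOM slice series into a fixed-shape 3D stack,
classifies it with a small 3D convolutional network, and explains the
decision with gradient-weighted class activation maps (Grad-CAM).

Clinical MRI cohorts of this kind are rarely shareable, so the package
ships a seeded synthetic phantom cohort that reproduces the *structure*
of such data (class imbalance, variable slice counts, mixed matrix
sizes, multi-plane multi-sequence series) and carries a learnable,
biologically shaped class signal.  Everything downstream — reading,
preprocessing, training, evaluation, explanation — is exercised end to
end with no external data.

## Preprocessing

Per patient directory, in order:

1. **Load** every readable DICOM file (`pydicom`); corrupt files are
   skipped with a logged warning.  The imaging plane is recovered from
   the image-orientation direction cosines, the sequence tag from the
   series description.
2. **Sort** by the DICOM instance-number attribute (stable, so the
   on-disk file order is irrelevant).
3. **Filter** to axial T1W/T2W/FLAIR slices only.
4. **Discard** matrices smaller than 128x128 (the 64x64 localizer-scale
   images carry no diagnostic content at this resolution).
5. **Resize** the remaining 256/512 matrices to 128x128 by local-mean
   (area-preserving) downsampling — anti-aliased shrinking; upscaling is
   rejected rather than invented.
6. **Normalize** each pixel by the pooled z-score `(x - mu) / sigma`,
   with mu and sigma computed over *every pixel* of the qualifying,
   resized slices.  The *population* standard deviation is used (the
   z-score definition carries no Bessel correction).  By default the
   statistics come from the training patients only and are reused for
   validation/test (`stats_scope="train_only"`); a pooled-dataset mode
   (`"all"`) exists for protocol fidelity but leaks test statistics and
   is not the default.
7. **Zero-pad** the depth axis to 120 slices.  Real slices occupy depth
   indices `[0, n)`, zeros the tail — appending (rather than centring)
   preserves anatomical ordering from slice 0.  Normalizing *before*
   padding makes the pad value 0 coincide with the post-normalization
   mean.  A patient with more than 120 qualifying slices is rejected
   with an explicit error: the cohort maximum (115) left headroom and no
   truncation policy is defined, so silent truncation would be a bug
   masquerading as robustness.

The sequences of one patient are interleaved deterministically in the
stack: grouped T1W < T2W < FLAIR, instance order within each group.  The
acquisition protocol does not define a canonical interleaving; any fixed
deterministic rule works, and grouping keeps each sequence contiguous.

Output: a `(120, 128, 128, 1)` float tensor per patient, with
`n_real_slices` recorded.  A 23-slice patient gains exactly 97 zero
slices, a 115-slice patient exactly 5.

## Network

Input `(120, 128, 128, 1)`; four convolutional blocks with 8/16/32/64
filters, each Conv3D (3x3x3 kernel, stride 1, valid padding, ELU) ->
channel-wise batch normalization -> 2x2x2 max pooling; then flatten
(11520) -> dense 40 (ELU) -> dropout 0.2 -> dense 10 (ELU) -> dropout
0.2 -> dense 1 (sigmoid).  He initialization (zero-mean Gaussian,
variance 2/fan-in) on every weight tensor; biases zero; L2 penalty of
0.05 on every convolutional and dense kernel (not on batch-norm scale
and shift).

Kernel size, stride and padding are not free choices: they are uniquely
recovered from the layer-shape/parameter table the network must
reproduce.  Block 1 maps `(120,128,128,1) -> (59,63,63,8)` with 256
parameters; only kernel 3, stride 1, valid padding and pool 2 satisfy
`120 -> 118 -> 59` together with `8*(3^3*1 + 1) + 4*8 = 256`.  The same
arithmetic fixes every other block, the 11520-wide flatten, and the
totals 534,653 / 534,413 trainable / 240 non-trainable.  The test suite
enforces all of these numbers.

ELU uses alpha = 1 (the canonical default).  Dropout is placed after
the two hidden dense layers, where the summary table puts it.  The
decision threshold for binary accuracy is 0.5.

### Runtime

No autodiff framework is used: the network runs on a compact NumPy
reverse-mode engine written for this package (`csvdnet.nn`).  The 3D
convolution forward pass is a sum of 27 shifted GEMMs (one per kernel
offset); the backward pass accumulates the corresponding transposed
products, the exact adjoint of the forward map.  Max-pool backward
splits gradients equally across tied maxima (a valid subgradient; ties
have measure zero for continuous inputs).  Batch normalization keeps
running mean/variance (the two non-trainable parameters per channel)
with momentum 0.9; training mode uses mini-batch moments, inference the
running statistics.  A momentum of 0.9 rather than the larger values
common in long-schedule training is deliberate: with only ~15 optimizer
steps per epoch the running statistics must track the fast-moving
weights, and a long memory leaves inference statistics stale, shifting
every predicted probability away from its training-mode value.

Every layer's backward pass is verified against central finite
differences on a sub-1k-parameter model to 1e-4 relative error, with and
without the L2 term.

Training minimizes mean binary cross-entropy (computed from logits in
the overflow-safe form) plus the L2 penalty, with Adam at learning rate
1e-3 (SGD available), seeded shuffling, seeded dropout, and a
reduce-on-plateau schedule (factor 0.5, patience 5 epochs on validation
loss).  Batch size and epoch count are not protocol-fixed; the defaults
are batch 2 / 100 epochs for the full profile, and batch 4 / 50 epochs
for the reduced desk-scale study below.

## Splitting and augmentation

Patients are split 80/20 into pool/test first (stratified by class),
then the pool 80/20 into train/validation.  Augmentation is applied to
the training pool only: in-plane translation (up to 10% of the extent),
shear (up to 10 degrees), rotation (up to 15 degrees) and small affine
maps (scale +/-10%, rotation +/-10 degrees), all slice-wise with zero
fill so the padded tail stays exactly zero.  Magnitudes are package
defaults (the protocol states the operation names, not ranges) and are
configurable.

Two per-class presets balance the 2:1 class imbalance:

* `balance_shear`: shear on both classes, translation + affine
  additionally on the control class (30:15 -> 60:60);
* `balance_rotation`: rotation on both classes, affine additionally on
  the control class — the headline recipe, paired with Adam.

Every augmented copy keeps its source label and a provenance link to the
source patient.  Cross-validated reporting (`run_kfold`) supports 6-fold
CV inside a 90/10 split without augmentation and stratified 5-fold CV
after augmentation; `group_by_patient` (default on) keeps all copies of
a patient in one fold, because an original on one side and its rotated
copy on the other is leakage.  A mode without grouping exists for
protocol fidelity.

## Metrics

Accuracy, precision and recall from the confusion counts; AUC as the
Mann-Whitney rank statistic (the probability a random positive outscores
a random negative, ties 1/2 — identical to the area under the ROC
curve); BCE in nats with probabilities clipped to `[1e-7, 1 - 1e-7]`.
Ratios with zero denominators are reported as *undefined* (None), never
as zero, so fold means are not corrupted.  All implementations are
checked against exhaustive brute-force oracles (pairwise enumeration for
AUC, direct tallies for the rest) and against scikit-learn on small
instances.

## Grad-CAM

Gradients of the *pre-sigmoid logit* (not the probability, whose
gradient vanishes at confident predictions) are taken with respect to a
convolutional block's output feature map.  Channel weights are the
spatial mean of that gradient; the CAM is the rectified weighted sum of
feature maps, upsampled trilinearly to the input spatial shape and
normalized by its global (whole-volume) maximum.  Global rather than
per-slice normalization keeps uninformative slices dark, preserving
cross-slice relative importance; an all-zero map stays zero rather than
being rescaled.  The default target is the last convolutional block
(`conv_block4`, feature shape `(5, 6, 6, 64)` at the full profile).

At the reduced profile the final block's feature map is `(1, 2, 2, 32)`
— a single depth cell cannot resolve lesion location — so the
localization study targets the penultimate block (`conv_block2`,
`(4, 6, 6, 16)`).  The layer is a parameter everywhere.

## Synthetic phantom cohort

The generator emulates the *structure* of a 45-patient clinical cohort
(default 30 diseased : 15 control): per-patient total axial slice count
drawn uniformly from [23, 115] and partitioned near-evenly across the
T1W/T2W/FLAIR sequences; mixed square matrices 64/256/512 cycling per
slice; a few sagittal/coronal slices per patient that the filter stage
must remove.  Anatomy is analytic on normalized coordinates (a head
ellipsoid, two lateral-ventricle ellipsoids with sequence-appropriate
CSF intensity: dark on T1W/FLAIR, bright on T2W), so a patient is
coherent across matrix sizes and the ground-truth lesion mask can be
re-evaluated at any resolution.  Diseased patients carry
`lesion_count` (default 3) hyperintense ellipsoids abutting the
ventricle walls near mid-depth, visible on T2W/FLAIR only, brighter than
tissue by the factor `lesion_contrast` (default 1.8); controls share the
identical background and noise stream.  Voxel noise is Gaussian
(`noise_sigma` = 0.03 of the unit intensity scale), images are stored as
uint16 DICOM with plane encoded in the image orientation and sequence in
the series description.

The whole cohort is a pure function of the configuration, including the
seed: per-patient seeds derive from `(cohort seed, patient index)`, and
DICOM UIDs are generated deterministically.

What the phantom does **not** model: k-space physics, relaxometry, bias
fields, motion, skull/scalp anatomy, partial-volume effects, or any
realistic non-axial content (those slices exist only to be filtered
out).  Passing tests therefore demonstrate that the pipeline's
machinery — format handling, geometry, bookkeeping, optimization,
attribution — behaves correctly on data with a known planted signal;
they say nothing about clinical discrimination performance on real MRI.

## The reduced desk-scale study

The learnability experiment (`csvdnet.experiments.reduced_phantom_study`)
uses a 40-patient cohort (26:14, the clinical imbalance) at the reduced
profile: stacks of `(24, 32, 32, 1)` built from 64x64 phantom slices
(10–22 per patient, resized to 32), three conv blocks (8/16/32 filters,
the same block structure, ~23k parameters), lesion contrast 3.0
("high-contrast": the planted effect is strong so that failure indicates
a pipeline defect, not statistical bad luck), Adam with the
rotation + affine balancing preset, batch 4, 50 epochs.  Held-out
accuracy, AUC and the Grad-CAM lesion-overlap statistic (mean relevance
inside vs outside the planted lesion masks over all diseased patients)
are reported.  These sizes keep a full run to a few minutes on one CPU
core.

## Numerical and degenerate-input choices

- Constant-intensity cohorts are rejected at normalization (sigma = 0).
- A patient with no qualifying axial slices is an explicit error.
- Sigmoid and BCE are computed in overflow-safe forms; probabilities are
  clipped only inside BCE.
- Batch-norm epsilon is 1e-3; a constant channel maps to beta.
- Max-pool drops odd remainders (floor), matching the shape table.
- Stratified splits require at least one patient per class and preserve
  per-class proportions within one patient.
- Training aborts with a diagnostic on non-finite loss rather than
  continuing silently.

## Known limitations

- The NumPy runtime is single-threaded except for BLAS inside the GEMMs;
  full-profile (120x128x128) *training* is possible but slow — the full
  profile is primarily used for architecture verification and inference,
  the reduced profile for training studies.
- The phantom's class signal is simpler than real WMH heterogeneity;
  accuracy on phantoms does not transfer to clinical claims.
- `balance_shear` / `balance_rotation` reflect two differing published
  descriptions of the per-class augmentation recipe; no adjudication is
  attempted — both are available, the rotation preset is the default.
- AUC on tiny test sets (8 patients) is a coarse statistic; the
  acceptance study reports it alongside accuracy rather than instead of
  it.
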