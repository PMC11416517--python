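"""Self-contained desk-scale experiments on the synthetic phantom cohort.

The reduced phantom study is the package's stand-in for the clinical
evaluation: a 40-patient cohort (26 diseased : 14 control, the study's
2:1 imbalance) at the reduced profile (24x32x32 stacks), trained with
the headline recipe — Adam at learning rate 1e-3, rotation augmentation
on both classes plus affine on the control class — and scored on the
20% held-out patients, followed by a Grad-CAM lesion-localization
statistic over the diseased patients.

Problem sizes (40 patients, 3 conv blocks, 50 epochs) are chosen so a
full run completes in a few minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .core import LABEL_NAMES
from .explain import grad_cam, lesion_overlap_statistic
from .metrics import evaluate
from .phantom import PhantomConfig, cohort_patients, generate_patient_series, lesion_mask_stack
from .pipeline import RUN_PROFILES, build_model_for_profile
from .preprocessing import _ordered_qualifying, build_stack_from_records, compute_dataset_stats
from .training import (
    TrainConfig,
    balance_with_augmentation,
    make_split,
    policy_preset,
    train,
)
from .training import _predict_batched, _stack_tensor  # shared batched helpers

#: high lesion-to-tissue contrast used for the learnability study
HIGH_CONTRAST = 3.0


@dataclass
class StudyResult:
    test_accuracy: float
    test_auc: float
    test_recall: float
    cam_inside_mean: float
    cam_outside_mean: float
    n_patients: int
    n_diseased: int
    n_test: int
    final_train_loss: float


def reduced_phantom_study(
    seed: int,
    *,
    n_diseased: int = 26,
    n_control: int = 14,
    lesion_contrast: float = HIGH_CONTRAST,
    epochs: int = 50,
    batch_size: int = 4,
    cam_block: str = "conv_block2",
) -> StudyResult:
    """Train the reduced-profile model on a high-contrast phantom cohort
    and measure held-out accuracy plus the Grad-CAM lesion overlap."""
    profile = RUN_PROFILES["reduced"]
    cfg = PhantomConfig(
        n_diseased=n_diseased,
        n_control=n_control,
        slice_count_range=profile.phantom_slice_range,
        matrix_sizes=profile.phantom_matrix_sizes,
        lesion_radius_vox=profile.lesion_radius_vox,
        lesion_contrast=lesion_contrast,
        noise_sigma=0.03,
        seed=seed,
    )
    roster = cohort_patients(cfg)
    series = {pid: generate_patient_series(cfg, pid, lab, s) for pid, lab, s in roster}
    labels = {pid: LABEL_NAMES[lab] for pid, lab, _ in roster}
    split = make_split(
        [p for p, _, _ in roster], [labels[p] for p, _, _ in roster], seed=seed
    )
    stats = compute_dataset_stats(
        s for pid in split.train_ids
        for s in _ordered_qualifying(series[pid], profile.min_size, profile.size)
    )
    stacks = {
        pid: build_stack_from_records(
            series[pid], stats, min_size=profile.min_size, target=profile.size,
            depth=profile.depth, label=labels[pid],
        )
        for pid, _, _ in roster
    }
    pool = balance_with_augmentation(
        [stacks[p] for p in split.train_ids], policy_preset("balance_rotation", seed)
    )
    net = build_model_for_profile("reduced", seed=seed)
    config = TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    history = train(net, pool, [stacks[p] for p in split.val_ids], config)

    x_te, y_te = _stack_tensor([stacks[p] for p in split.test_ids])
    report = evaluate(y_te, _predict_batched(net, x_te), config.decision_threshold)

    inside: List[float] = []
    outside: List[float] = []
    for pid, lab, pseed in roster:
        if lab != "diseased":
            continue
        mask = lesion_mask_stack(
            cfg, lab, pseed, min_size=profile.min_size, target=profile.size,
            depth=profile.depth,
        )
        cam = grad_cam(net, stacks[pid], cam_block)
        i, o = lesion_overlap_statistic(cam, mask)
        inside.append(i)
        outside.append(o)

    return StudyResult(
        test_accuracy=report.accuracy,
        test_auc=report.auc if report.auc is not None else float("nan"),
        test_recall=report.recall if report.recall is not None else float("nan"),
        cam_inside_mean=float(np.mean(inside)),
        cam_outside_mean=float(np.mean(outside)),
        n_patients=len(roster),
        n_diseased=len(inside),
        n_test=len(split.test_ids),
        final_train_loss=history["loss"][-1],
    )
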