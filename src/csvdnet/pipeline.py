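"""End-to-end orchestration: phantom cohort -> stacks -> training -> CAM.

A single RunConfig drives every stage; each source of randomness derives
from the global seed, so re-running a config reproduces all metrics in
deterministic mode.  Two profiles are supported: ``paper`` (120x128x128
input, four conv blocks — the published geometry) and ``reduced``
(24x32x32, three conv blocks) for desk-scale training and CI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import preprocessing as pp
from .architecture import PROFILES, build_architecture, count_parameters, format_model_table
from .core import LABEL_NAMES, VolumeStack
from .metrics import evaluate
from .nn import Network, save_network
from .phantom import PhantomConfig, cohort_patients, write_cohort
from .training import (
    AugmentationPolicy,
    TrainConfig,
    balance_with_augmentation,
    make_split,
    policy_preset,
    train,
)
from .explain import grad_cam, render_overlays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Profile:
    """Consistent geometry across phantom, preprocessing and model."""

    name: str
    depth: int
    size: int
    min_size: int
    conv_filters: Tuple[int, ...]
    phantom_matrix_sizes: Tuple[int, ...]
    phantom_slice_range: Tuple[int, int]
    lesion_radius_vox: float

    @property
    def input_shape(self) -> Tuple[int, int, int, int]:
        return (self.depth, self.size, self.size, 1)


RUN_PROFILES: Dict[str, Profile] = {
    "paper": Profile(
        name="paper", depth=120, size=128, min_size=128,
        conv_filters=PROFILES["paper"]["conv_filters"],
        phantom_matrix_sizes=(64, 256, 512), phantom_slice_range=(23, 115),
        lesion_radius_vox=6.0,
    ),
    "reduced": Profile(
        name="reduced", depth=24, size=32, min_size=32,
        conv_filters=PROFILES["reduced"]["conv_filters"],
        phantom_matrix_sizes=(64,), phantom_slice_range=(10, 22),
        lesion_radius_vox=14.0,
    ),
}


@dataclass
class RunConfig:
    profile: str = "reduced"
    n_diseased: int = 26
    n_control: int = 14
    lesion_contrast: float = 1.8
    noise_sigma: float = 0.03
    stats_scope: str = "train_only"  # or "all" (pools test statistics)
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    augmentation_preset: str = "balance_rotation"
    train: TrainConfig = field(default_factory=TrainConfig)
    output_dir: str = "run_output"
    global_seed: int = 0
    n_cam_examples: int = 2

    def phantom_config(self) -> PhantomConfig:
        p = RUN_PROFILES[self.profile]
        return PhantomConfig(
            n_diseased=self.n_diseased,
            n_control=self.n_control,
            slice_count_range=p.phantom_slice_range,
            matrix_sizes=p.phantom_matrix_sizes,
            lesion_radius_vox=p.lesion_radius_vox,
            lesion_contrast=self.lesion_contrast,
            noise_sigma=self.noise_sigma,
            seed=self.global_seed,
        )


def build_model_for_profile(profile: str, seed: int = 0) -> Network:
    p = RUN_PROFILES[profile]
    spec = build_architecture(p.input_shape, p.conv_filters)
    return Network.from_spec(spec, seed=seed)


def print_model_table(profile: str = "paper") -> str:
    p = RUN_PROFILES[profile]
    return format_model_table(build_architecture(p.input_shape, p.conv_filters))


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom -> preprocess -> split -> augment -> train -> explain.

    Returns the run report (also written to ``<output_dir>/report.json``)
    with test metrics, the split, every derived seed and artifact paths.
    """
    profile = RUN_PROFILES[config.profile]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "phantom"
    try:
        pconf = config.phantom_config()
        cohort_dir = out / "cohort"
        manifest = write_cohort(pconf, cohort_dir)

        stage = "split"
        labels = [LABEL_NAMES[l] for l in manifest["label"]]
        split = make_split(
            list(manifest["patient_id"]), labels,
            test_fraction=config.test_fraction, val_fraction=config.val_fraction,
            seed=config.global_seed,
        )

        stage = "preprocessing"
        stats_ids = (
            list(manifest["patient_id"])
            if config.stats_scope == "all"
            else list(split.train_ids)
        )
        stats = pp.compute_cohort_stats(
            [cohort_dir / pid for pid in stats_ids],
            min_size=profile.min_size, target=profile.size,
        )
        label_of = dict(zip(manifest["patient_id"], labels))
        stacks = {
            pid: pp.build_stack(
                cohort_dir / pid, stats, min_size=profile.min_size,
                target=profile.size, depth=profile.depth, label=label_of[pid],
            )
            for pid in manifest["patient_id"]
        }

        stage = "augmentation"
        policy = policy_preset(config.augmentation_preset, seed=config.global_seed)
        train_pool = balance_with_augmentation(
            [stacks[p] for p in split.train_ids], policy
        )

        stage = "training"
        net = build_model_for_profile(config.profile, seed=config.global_seed)
        history = train(
            net, train_pool, [stacks[p] for p in split.val_ids], config.train
        )
        model_path = out / "model.npz"
        save_network(
            net, model_path,
            {"input_shape": list(profile.input_shape),
             "conv_filters": list(profile.conv_filters)},
        )

        stage = "evaluation"
        test_stacks = [stacks[p] for p in split.test_ids]
        y_te = np.array([s.label for s in test_stacks], dtype=float)
        p_te = np.concatenate([net.predict_proba(s.voxels[None]) for s in test_stacks])
        report = evaluate(y_te, p_te, config.train.decision_threshold)
        metrics_df = pd.DataFrame(
            [{"split": "test", **{k: v for k, v in report.as_dict().items()}}]
        )
        metrics_df.to_csv(out / "metrics.csv", index=False)

        stage = "explanation"
        cam_block = f"conv_block{len(profile.conv_filters)}"
        overlay_paths: List[str] = []
        diseased_test = [s for s in test_stacks if s.label == 1]
        for s in diseased_test[: config.n_cam_examples]:
            cam = grad_cam(net, s, cam_block)
            overlay_paths += [str(p) for p in
                              render_overlays(cam, s, out / "overlays")]

        run_report = {
            "profile": config.profile,
            "global_seed": config.global_seed,
            "split": {
                "train": list(split.train_ids),
                "val": list(split.val_ids),
                "test": list(split.test_ids),
            },
            "normalization": {"mean": stats.mean, "std": stats.std},
            "n_train_after_augmentation": len(train_pool),
            "test_metrics": report.as_dict(),
            "final_train_loss": history["loss"][-1] if history["loss"] else None,
            "patient_seeds": {pid: seed for pid, _, seed in cohort_patients(pconf)},
            "artifacts": {
                "cohort": str(cohort_dir),
                "model": str(model_path),
                "metrics": str(out / "metrics.csv"),
                "overlays": overlay_paths,
            },
        }
        (out / "report.json").write_text(json.dumps(run_report, indent=2))
        return run_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
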