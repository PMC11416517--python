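"""Seeded synthetic DICOM cohort mimicking a small cerebral-SVD MRI study.

The phantom reproduces the *structure* of the study data — two classes
(diseased = grade-1 cSVD, control), per-patient axial T1W/T2W/FLAIR slice
series with the per-patient filtered slice total varying in [23, 115],
mixed square matrix sizes (64/256/512), sagittal/coronal extras that the
pipeline must filter out — and gives the classifier a learnable,
biologically shaped signal: hyperintense ellipsoidal lesions adjacent to
a synthetic ventricle pair on T2W/FLAIR axial slices (periventricular
white-matter hyperintensities, the grade-1 imaging biomarker).  It is
NOT a physical MR simulation: no k-space, no relaxometry, stylized
per-sequence intensity constants.

Every image is evaluated analytically on a normalized [0,1]^3 coordinate
grid, so a patient's anatomy is coherent across matrix sizes and the
lesion mask can be re-evaluated at any target resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import LABEL_NAMES, PLANES, SEQUENCE_ORDER, SEQUENCES, SliceMeta, SliceRecord

logger = logging.getLogger(__name__)

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
UID_ROOT = "1.2.826.0.1.3680043.10.1463."

#: direction cosines (row, column) per imaging plane
PLANE_ORIENTATION = {
    "axial": [1, 0, 0, 0, 1, 0],
    "sagittal": [0, 1, 0, 0, 0, -1],
    "coronal": [1, 0, 0, 0, 0, -1],
}

#: stylized per-sequence tissue/CSF intensities (arbitrary units in [0, 1]);
#: lesions are visible (hyperintense) on T2W and FLAIR only
SEQUENCE_PROFILE = {
    "T1W": {"tissue": 0.60, "csf": 0.20, "lesion_visible": False},
    "T2W": {"tissue": 0.45, "csf": 0.90, "lesion_visible": True},
    "FLAIR": {"tissue": 0.50, "csf": 0.15, "lesion_visible": True},
}

INTENSITY_SCALE = 1000.0  # normalized units -> stored uint16
REFERENCE_GRID = 128  # voxel grid on which lesion_radius_vox is expressed
N_NONAXIAL_SLICES = 4  # per non-axial plane (tags-only realism)


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters.

    ``slice_count_range`` bounds each patient's total axial slice count
    across the selected sequences (the quantity the stack depth must
    accommodate); the total is partitioned near-evenly per sequence.
    """

    n_diseased: int = 30
    n_control: int = 15
    slice_count_range: Tuple[int, int] = (23, 115)
    matrix_sizes: Tuple[int, ...] = (64, 256, 512)
    sequences: Tuple[str, ...] = SEQUENCES
    planes: Tuple[str, ...] = PLANES
    lesion_count: int = 3
    lesion_radius_vox: float = 6.0
    lesion_contrast: float = 1.8
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseased < 0 or self.n_control < 0 or self.n_diseased + self.n_control < 1:
            raise ValueError("need n_diseased >= 0, n_control >= 0 and at least 1 patient")
        lo, hi = self.slice_count_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid slice_count_range {self.slice_count_range}")
        if not self.sequences:
            raise ValueError("sequences set must be non-empty")
        if not self.planes or "axial" not in self.planes:
            raise ValueError("planes must be non-empty and include 'axial'")
        if not self.lesion_contrast > 0:
            raise ValueError("lesion_contrast must be positive")
        if not self.matrix_sizes:
            raise ValueError("matrix_sizes must be non-empty")
        object.__setattr__(self, "matrix_sizes", tuple(sorted(self.matrix_sizes)))
        object.__setattr__(
            self,
            "sequences",
            tuple(sorted(self.sequences, key=lambda s: SEQUENCE_ORDER.get(s, 99))),
        )


# ---------------------------------------------------------------------------
# anatomy model (normalized coordinates z, y, x in [0, 1])
# ---------------------------------------------------------------------------

HEAD_CENTER = (0.5, 0.5, 0.5)
HEAD_RADII = (0.55, 0.44, 0.38)  # (z, y, x) semi-axes
VENTRICLES = (  # two lateral ventricles: center (z, y, x), radii (z, y, x)
    ((0.5, 0.48, 0.41), (0.20, 0.11, 0.05)),
    ((0.5, 0.48, 0.59), (0.20, 0.11, 0.05)),
)


def _ellipsoid(z, y, x, center, radii) -> np.ndarray:
    return (
        ((z - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((x - center[2]) / radii[2]) ** 2
    ) <= 1.0


@dataclass(frozen=True)
class _Lesion:
    center: Tuple[float, float, float]  # (z, y, x), normalized
    radius: float  # normalized isotropic radius (slightly anisotropic below)


def _patient_seed(config: PhantomConfig, index: int) -> int:
    return int(np.random.SeedSequence([config.seed, index]).generate_state(1)[0] % (2**31))


def _draw_geometry(config: PhantomConfig, rng: np.random.Generator, label: str):
    """Draw the per-patient axial slice budget and lesion geometry.

    Draw order is fixed so that pixel rendering and mask evaluation stay
    in lockstep for a given seed.
    """
    lo, hi = config.slice_count_range
    total_axial = int(rng.integers(lo, hi + 1))
    lesions: List[_Lesion] = []
    r_norm = config.lesion_radius_vox / REFERENCE_GRID
    for _ in range(config.lesion_count):
        vent = VENTRICLES[int(rng.integers(len(VENTRICLES)))]
        side = 1.0 if vent[0][2] > 0.5 else -1.0
        cz = float(np.clip(0.5 + rng.normal(0, 0.05), 0.35, 0.65))
        cy = float(np.clip(0.48 + rng.normal(0, 0.05), 0.3, 0.66))
        cx = float(vent[0][2] + side * (vent[1][2] + 0.8 * r_norm + abs(rng.normal(0, 0.01))))
        lesions.append(_Lesion((cz, cy, cx), r_norm))
    if label == "control":
        lesions = []
    return total_axial, lesions


def lesion_mask_slice(lesions: Sequence[_Lesion], z: float, size: int) -> np.ndarray:
    """Boolean in-plane lesion mask at axial position ``z`` on a size^2 grid."""
    y, x = np.meshgrid(
        (np.arange(size) + 0.5) / size, (np.arange(size) + 0.5) / size, indexing="ij"
    )
    mask = np.zeros((size, size), dtype=bool)
    for les in lesions:
        # lesions are mildly oblate in depth (half the in-plane radius)
        mask |= _ellipsoid(z, y, x, les.center, (les.radius * 2.0, les.radius, les.radius))
    return mask


def _render_axial(
    config: PhantomConfig,
    sequence: str,
    z: float,
    size: int,
    lesions: Sequence[_Lesion],
    rng: np.random.Generator,
) -> np.ndarray:
    prof = SEQUENCE_PROFILE.get(sequence, SEQUENCE_PROFILE["T1W"])
    y, x = np.meshgrid(
        (np.arange(size) + 0.5) / size, (np.arange(size) + 0.5) / size, indexing="ij"
    )
    img = np.zeros((size, size))
    head = _ellipsoid(z, y, x, HEAD_CENTER, HEAD_RADII)
    img[head] = prof["tissue"]
    for vc, vr in VENTRICLES:
        img[_ellipsoid(z, y, x, vc, vr) & head] = prof["csf"]
    if lesions and prof["lesion_visible"]:
        lm = lesion_mask_slice(lesions, z, size)
        img[lm & head] = prof["tissue"] * config.lesion_contrast
    img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    return np.clip(img * INTENSITY_SCALE, 0, 65535).astype(np.uint16)


def _render_nonaxial(size: int, rng: np.random.Generator, noise_sigma: float) -> np.ndarray:
    # tags-only realism: a plain elliptical mask plus noise
    y, x = np.meshgrid(
        (np.arange(size) + 0.5) / size, (np.arange(size) + 0.5) / size, indexing="ij"
    )
    img = np.where(((y - 0.5) / 0.45) ** 2 + ((x - 0.5) / 0.4) ** 2 <= 1, 0.5, 0.0)
    img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img * INTENSITY_SCALE, 0, 65535).astype(np.uint16)


def _split_total(total: int, n_groups: int) -> List[int]:
    base, rem = divmod(total, n_groups)
    return [base + (1 if i < rem else 0) for i in range(n_groups)]


def _axial_plan(config: PhantomConfig, total_axial: int) -> List[Tuple[str, int, float, int]]:
    """Deterministic per-slice plan: (sequence, instance, z, matrix size)."""
    plan: List[Tuple[str, int, float, int]] = []
    counts = _split_total(total_axial, len(config.sequences))
    k = 0
    for seq, n_seq in zip(config.sequences, counts):
        for i in range(n_seq):
            z = (i + 0.5) / n_seq
            size = config.matrix_sizes[k % len(config.matrix_sizes)]
            plan.append((seq, i + 1, z, size))
            k += 1
    return plan


def generate_patient_series(
    config: PhantomConfig, patient_id: str, label: str, seed: int
) -> List[SliceRecord]:
    """Generate one patient's multi-plane, multi-sequence slice series.

    Deterministic: identical (config, patient_id, label, seed) yields
    byte-identical pixel data.
    """
    if label not in LABEL_NAMES:
        raise ValueError(f"label must be one of {sorted(LABEL_NAMES)}, got {label!r}")
    rng = np.random.default_rng(seed)
    total_axial, lesions = _draw_geometry(config, rng, label)
    records: List[SliceRecord] = []
    for seq, inst, z, size in _axial_plan(config, total_axial):
        pixels = _render_axial(config, seq, z, size, lesions, rng)
        meta = SliceMeta(patient_id, inst, "axial", seq, size, size)
        records.append(SliceRecord(meta, pixels))
    for plane in config.planes:
        if plane == "axial":
            continue
        for i in range(N_NONAXIAL_SLICES):
            size = config.matrix_sizes[i % len(config.matrix_sizes)]
            pixels = _render_nonaxial(size, rng, config.noise_sigma)
            meta = SliceMeta(patient_id, i + 1, plane, config.sequences[0], size, size)
            records.append(SliceRecord(meta, pixels))
    return records


def lesion_mask_stack(
    config: PhantomConfig,
    label: str,
    seed: int,
    *,
    min_size: int = 128,
    target: int = 128,
    depth: int = 120,
) -> np.ndarray:
    """Ground-truth lesion mask aligned to the preprocessed volume stack.

    Re-evaluates the patient's lesion geometry on the stack geometry the
    preprocessing stage produces (axial slices with matrix size >=
    ``min_size``, ordered by (sequence, instance), resampled to
    ``target``^2, zero-padded to ``depth``).
    """
    rng = np.random.default_rng(seed)
    total_axial, lesions = _draw_geometry(config, rng, label)
    plan = [p for p in _axial_plan(config, total_axial) if p[3] >= min_size]
    plan.sort(key=lambda p: (SEQUENCE_ORDER.get(p[0], 99), p[1]))
    mask = np.zeros((depth, target, target), dtype=bool)
    for d, (seq, inst, z, size) in enumerate(plan):
        if seq in SEQUENCE_PROFILE and SEQUENCE_PROFILE[seq]["lesion_visible"]:
            mask[d] = lesion_mask_slice(lesions, z, target)
    return mask


# ---------------------------------------------------------------------------
# DICOM serialization
# ---------------------------------------------------------------------------


def _slice_to_dicom(rec: SliceRecord) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
    sop_uid = generate_uid(
        prefix=UID_ROOT,
        entropy_srcs=[rec.meta.patient_id, rec.meta.sequence, rec.meta.plane,
                      str(rec.meta.instance_number)],
    )
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = MR_IMAGE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "MR"
    ds.PatientID = rec.meta.patient_id
    ds.PatientName = rec.meta.patient_id
    ds.SeriesDescription = rec.meta.sequence
    ds.ProtocolName = f"{rec.meta.sequence} {rec.meta.plane}"
    ds.SeriesInstanceUID = generate_uid(
        prefix=UID_ROOT,
        entropy_srcs=[rec.meta.patient_id, rec.meta.sequence, rec.meta.plane],
    )
    ds.StudyInstanceUID = generate_uid(prefix=UID_ROOT, entropy_srcs=[rec.meta.patient_id])
    ds.InstanceNumber = rec.meta.instance_number
    ds.ImageOrientationPatient = PLANE_ORIENTATION[rec.meta.plane]
    ds.ImagePositionPatient = [0, 0, float(rec.meta.instance_number) * 5.0]
    ds.SliceThickness = 5.0
    ds.Rows = rec.meta.rows
    ds.Columns = rec.meta.cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(rec.pixels.astype(np.uint16)).tobytes()
    return ds


def cohort_patients(config: PhantomConfig) -> List[Tuple[str, str, int]]:
    """Deterministic (patient_id, label, per-patient seed) roster."""
    roster = []
    for i in range(config.n_diseased + config.n_control):
        label = "diseased" if i < config.n_diseased else "control"
        roster.append((f"sub-{i + 1:04d}", label, _patient_seed(config, i)))
    return roster


def write_cohort(config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write the full cohort as DICOM directories plus a manifest table.

    One subdirectory per patient, one DICOM file per slice; the manifest
    (``manifest.tsv``) lists patient_id, label, seed and slice counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient_id, label, seed in cohort_patients(config):
        records = generate_patient_series(config, patient_id, label, seed)
        pdir = out / patient_id
        pdir.mkdir(exist_ok=True)
        for rec in records:
            fname = (
                f"{rec.meta.sequence}_{rec.meta.plane}_{rec.meta.instance_number:03d}.dcm"
            )
            _slice_to_dicom(rec).save_as(pdir / fname, enforce_file_format=True)
        n_axial = sum(r.meta.plane == "axial" for r in records)
        rows.append(
            {
                "patient_id": patient_id,
                "label": label,
                "seed": seed,
                "n_slices": len(records),
                "n_axial": n_axial,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info("wrote %d patients to %s", len(manifest), out)
    return manifest


def read_manifest(cohort_dir) -> pd.DataFrame:
    return pd.read_csv(Path(cohort_dir) / "manifest.tsv", sep="\t")
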