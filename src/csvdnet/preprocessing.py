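"""DICOM series -> fixed normalized 3D stack.

Stage order for one patient directory: load -> sort by instance number ->
keep axial T1W/T2W/FLAIR -> discard small matrices (< 128) -> shrink to
128x128 (area-preserving) -> z-score with pooled cohort statistics ->
zero-pad the depth axis to 120 slices.  The output is always a
(120, 128, 128, 1) tensor (profile-dependent sizes are parameters).

Normalization is applied *before* padding so that the pad value 0
coincides with the post-normalization mean; statistics default to the
training portion of a cohort (``stats_scope="train_only"``) with an
``"all"`` mode pooling every patient.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pydicom
from skimage.transform import downscale_local_mean, resize

from .core import (
    SEQUENCE_ORDER,
    SEQUENCES,
    NormalizationStats,
    SliceMeta,
    SliceRecord,
    VolumeStack,
)

logger = logging.getLogger(__name__)

DEPTH = 120
TARGET_SIZE = 128
MIN_SIZE = 128


def _plane_from_orientation(iop: Sequence[float]) -> str:
    row, col = np.asarray(iop[:3], float), np.asarray(iop[3:6], float)
    normal = np.cross(row, col)
    axis = int(np.argmax(np.abs(normal)))
    return {0: "sagittal", 1: "coronal", 2: "axial"}[axis]


def _sequence_from_description(desc: str) -> str:
    d = (desc or "").upper()
    for seq in SEQUENCES:
        if seq in d or seq.replace("W", "") == d.strip():
            return seq
    if "FLAIR" in d:
        return "FLAIR"
    return "other"


def load_series(dir_path) -> List[SliceRecord]:
    """Read every DICOM file in a patient directory into SliceRecords.

    Unreadable or corrupt files are skipped with a logged warning; if no
    file is readable the patient is unusable and a ValueError is raised.
    """
    dir_path = Path(dir_path)
    records: List[SliceRecord] = []
    files = sorted(p for p in dir_path.iterdir() if p.is_file() and p.suffix != ".tsv")
    for path in files:
        try:
            ds = pydicom.dcmread(path)
            meta = SliceMeta(
                patient_id=str(getattr(ds, "PatientID", dir_path.name)),
                instance_number=int(ds.InstanceNumber),
                plane=_plane_from_orientation(ds.ImageOrientationPatient),
                sequence=_sequence_from_description(str(getattr(ds, "SeriesDescription", ""))),
                rows=int(ds.Rows),
                cols=int(ds.Columns),
            )
            records.append(SliceRecord(meta, ds.pixel_array))
        except Exception as exc:  # corrupt / truncated / non-DICOM
            logger.warning("skipping unreadable file %s: %s", path, exc)
    if not records:
        raise ValueError(f"no readable DICOM files in {dir_path}")
    return records


def sort_by_instance(slices: Sequence[SliceRecord]) -> List[SliceRecord]:
    """Ascending, stable sort by the DICOM instance-number attribute."""
    for rec in slices:
        if rec.meta.instance_number is None:
            raise ValueError(f"slice of patient {rec.meta.patient_id} lacks an instance number")
    return sorted(slices, key=lambda r: r.meta.instance_number)


def filter_axial_sequences(slices: Sequence[SliceRecord]) -> List[SliceRecord]:
    """Keep only axial T1W/T2W/FLAIR slices (pixels untouched, order kept)."""
    kept = [
        r for r in slices if r.meta.plane == "axial" and r.meta.sequence in SEQUENCES
    ]
    if not kept:
        raise ValueError("no axial T1W/T2W/FLAIR slices present; patient unusable")
    return kept


def discard_small(slices: Sequence[SliceRecord], min_size: int = MIN_SIZE) -> List[SliceRecord]:
    """Drop slices whose matrix is smaller than ``min_size`` pixels."""
    return [r for r in slices if r.meta.rows >= min_size]


def resize_slice(rec: SliceRecord, target: int = TARGET_SIZE) -> SliceRecord:
    """Shrink a square slice to target x target by area-preserving resampling.

    Upscaling is undefined for this pipeline and rejected.
    """
    n = rec.meta.rows
    if n < target:
        raise ValueError(f"cannot upscale {n}x{n} slice to {target}x{target}")
    if n == target:
        return rec
    if n % target == 0:
        pixels = downscale_local_mean(rec.pixels.astype(float), (n // target, n // target))
    else:
        pixels = resize(
            rec.pixels.astype(float), (target, target), anti_aliasing=True,
            preserve_range=True,
        )
    meta = SliceMeta(
        rec.meta.patient_id, rec.meta.instance_number, rec.meta.plane,
        rec.meta.sequence, target, target,
    )
    return SliceRecord(meta, pixels)


def compute_dataset_stats(slices: Iterable[SliceRecord]) -> NormalizationStats:
    """Pooled mean and population standard deviation over every pixel."""
    n = 0
    s = 0.0
    s2 = 0.0
    for rec in slices:
        px = rec.pixels.astype(float)
        n += px.size
        s += float(px.sum())
        s2 += float(np.square(px).sum())
    if n < 2:
        raise ValueError("need at least 2 pixels to compute statistics")
    mean = s / n
    var = max(s2 / n - mean * mean, 0.0)
    if var == 0.0:
        raise ValueError("constant cohort: standard deviation is zero")
    return NormalizationStats(mean=mean, std=float(np.sqrt(var)))


def normalize(rec: SliceRecord, stats: NormalizationStats) -> SliceRecord:
    """z-score every pixel: (x - mean) / std."""
    return SliceRecord(rec.meta, (rec.pixels.astype(float) - stats.mean) / stats.std)


def pad_stack(
    slices: Sequence[np.ndarray],
    depth: int = DEPTH,
    *,
    patient_id: str = "",
    label: Optional[int] = None,
) -> VolumeStack:
    """Zero-pad an ordered list of equal-size normalized slices to ``depth``.

    Real slices occupy depth indices [0, n); zero slices fill the tail.
    More than ``depth`` slices is rejected (truncation is deliberately
    undefined: the study maximum left headroom below the stack depth).
    """
    n = len(slices)
    if n < 1:
        raise ValueError("cannot build a stack from zero slices")
    if n > depth:
        raise ValueError(
            f"{n} slices exceed the stack depth {depth}; no truncation policy is defined"
        )
    size = slices[0].shape[0]
    vox = np.zeros((depth, size, size, 1), dtype=np.float32)
    for i, sl in enumerate(slices):
        if sl.shape != (size, size):
            raise ValueError(f"slice {i} has shape {sl.shape}, expected {(size, size)}")
        vox[i, :, :, 0] = sl
    return VolumeStack(voxels=vox, patient_id=patient_id, n_real_slices=n, label=label)


def _ordered_qualifying(
    records: Sequence[SliceRecord], min_size: int, target: int
) -> List[SliceRecord]:
    recs = sort_by_instance(records)
    recs = filter_axial_sequences(recs)
    recs = discard_small(recs, min_size=min_size)
    # deterministic sequence interleaving: group T1W < T2W < FLAIR,
    # instance order within each group (stable sort after instance sort)
    recs = sorted(recs, key=lambda r: SEQUENCE_ORDER[r.meta.sequence])
    return [resize_slice(r, target=target) for r in recs]


def build_stack_from_records(
    records: Sequence[SliceRecord],
    stats: NormalizationStats,
    *,
    min_size: int = MIN_SIZE,
    target: int = TARGET_SIZE,
    depth: int = DEPTH,
    label: Optional[int] = None,
) -> VolumeStack:
    """The full preprocessing composition on already-loaded slice records."""
    recs = _ordered_qualifying(records, min_size, target)
    if not recs:
        raise ValueError("no qualifying slices after filtering/discarding")
    norm = [normalize(r, stats).pixels for r in recs]
    pid = recs[0].meta.patient_id
    return pad_stack(norm, depth=depth, patient_id=pid, label=label)


def build_stack(
    dir_path,
    stats: NormalizationStats,
    *,
    min_size: int = MIN_SIZE,
    target: int = TARGET_SIZE,
    depth: int = DEPTH,
    label: Optional[int] = None,
) -> VolumeStack:
    """load -> sort -> filter -> discard -> resize -> normalize -> pad."""
    return build_stack_from_records(
        load_series(dir_path), stats, min_size=min_size, target=target,
        depth=depth, label=label,
    )


def compute_cohort_stats(
    patient_dirs: Iterable, *, min_size: int = MIN_SIZE, target: int = TARGET_SIZE
) -> NormalizationStats:
    """Pooled normalization statistics over the qualifying, resized slices
    of the given patients (pass training directories for leakage-free
    ``train_only`` scope, or all directories for the pooled-dataset mode)."""

    def _gen():
        for d in patient_dirs:
            yield from _ordered_qualifying(load_series(d), min_size, target)

    return compute_dataset_stats(_gen())


# ---------------------------------------------------------------------------
# stack serialization (HDF5)
# ---------------------------------------------------------------------------


def save_stack(stack: VolumeStack, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("voxels", data=stack.voxels, compression="gzip")
        d.attrs["patient_id"] = stack.patient_id
        d.attrs["n_real_slices"] = stack.n_real_slices
        d.attrs["label"] = -1 if stack.label is None else int(stack.label)


def load_stack(path) -> VolumeStack:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["voxels"]
        label = int(d.attrs["label"])
        return VolumeStack(
            voxels=d[...],
            patient_id=str(d.attrs["patient_id"]),
            n_real_slices=int(d.attrs["n_real_slices"]),
            label=None if label < 0 else label,
        )
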