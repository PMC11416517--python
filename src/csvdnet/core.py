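"""Shared domain types for the volumetric cSVD classification pipeline.

The pipeline's unit of data is a single MR slice (pixel matrix plus the
DICOM attributes the downstream stages need) and, after preprocessing, a
fixed-shape zero-padded volume stack per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PLANES = ("axial", "sagittal", "coronal")
SEQUENCES = ("T1W", "T2W", "FLAIR")
#: deterministic interleaving order of sequences inside a patient stack
SEQUENCE_ORDER = {"T1W": 0, "T2W": 1, "FLAIR": 2}

LABEL_CONTROL = 0
LABEL_DISEASED = 1
LABEL_NAMES = {"control": LABEL_CONTROL, "diseased": LABEL_DISEASED}


@dataclass(frozen=True)
class SliceMeta:
    """Per-slice acquisition metadata (the DICOM attributes used here)."""

    patient_id: str
    instance_number: int
    plane: str
    sequence: str
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.instance_number < 1:
            raise ValueError(f"instance_number must be >= 1, got {self.instance_number}")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if self.rows != self.cols:
            raise ValueError(f"only square matrices supported, got {self.rows}x{self.cols}")


@dataclass
class SliceRecord:
    """One MRI slice: pixel matrix plus its metadata."""

    meta: SliceMeta
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (self.meta.rows, self.meta.cols):
            raise ValueError(
                f"pixel shape {self.pixels.shape} != metadata "
                f"({self.meta.rows}, {self.meta.cols})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite pixel values")


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled intensity mean/std used for z-scoring every slice."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"std must be positive, got {self.std}")


@dataclass
class VolumeStack:
    """Fixed-shape, zero-padded, normalized patient volume.

    ``voxels`` has shape (depth, size, size, 1); slices at depth index
    >= ``n_real_slices`` are identically zero (the padding region).
    """

    voxels: np.ndarray
    patient_id: str
    n_real_slices: int
    label: Optional[int] = None
    source_id: Optional[str] = None  # provenance of augmented copies

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[-1] != 1:
            raise ValueError(f"expected (depth, h, w, 1) voxels, got {self.voxels.shape}")
        depth = self.voxels.shape[0]
        if not (1 <= self.n_real_slices <= depth):
            raise ValueError(
                f"n_real_slices={self.n_real_slices} outside [1, {depth}]"
            )
        if self.n_real_slices < depth and np.any(self.voxels[self.n_real_slices :]):
            raise ValueError("padding region of the stack is not identically zero")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape
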