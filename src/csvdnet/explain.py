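"""3D Grad-CAM: gradient-weighted class activation volumes.

The class score used for gradients is the pre-sigmoid logit (standard
practice; avoids vanishing sigmoid gradients).  Channel weights are the
spatial mean of the logit gradient over the chosen convolutional block's
output feature map; the CAM is the rectified weighted sum of feature
maps, upsampled trilinearly to the input spatial shape and normalized by
its global maximum (an all-zero map is left as zeros, so uninformative
volumes render dark).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import VolumeStack
from .nn import MaxPool3D, Network

DEFAULT_BLOCK = "conv_block4"


@dataclass
class CamMap:
    relevance: np.ndarray  # (depth, h, w) in [0, 1], aligned to the input stack
    source_layer: str
    predicted_class: int
    raw_feature_shape: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.relevance.min() < 0 or self.relevance.max() > 1:
            raise ValueError("CAM relevance must lie in [0, 1]")


def _resolve_block(net: Network, target_layer: str) -> int:
    """Index of the layer whose *output* is the requested block output."""
    names = [l.name for l in net.layers]
    if target_layer in names:
        return names.index(target_layer)
    pool_name = f"{target_layer}_pool"
    if pool_name in names:
        return names.index(pool_name)
    blocks = sorted({n.rsplit("_", 1)[0] for n in names if n.startswith("conv_block")})
    raise KeyError(
        f"unknown target layer {target_layer!r}; valid conv blocks: {blocks}"
    )


def grad_cam(net: Network, stack: VolumeStack, target_layer: str = DEFAULT_BLOCK) -> CamMap:
    """Compute the Grad-CAM relevance volume for one stack."""
    idx = _resolve_block(net, target_layer)
    x = stack.voxels[None].astype(np.float64)
    logits = net.forward(x, training=False)
    p = 1.0 / (1.0 + np.exp(-logits[0, 0]))
    # capture the block's activation from the layer cache by re-running
    # the forward prefix (layers cache inputs, so outputs are recomputed)
    h = x
    for lyr in net.layers[: idx + 1]:
        h = lyr.forward(h, training=False)
    fmap = h  # (1, d, h, w, c)
    grad = net.backward(np.ones((1, 1)), stop_at=idx + 1)  # d(logit)/d(fmap)
    weights = grad.mean(axis=(1, 2, 3))  # (1, c): spatial mean per channel
    cam = np.maximum((fmap * weights[:, None, None, None, :]).sum(axis=-1)[0], 0.0)
    target_shape = stack.voxels.shape[:3]
    zoom = [t / s for t, s in zip(target_shape, cam.shape)]
    cam_up = ndimage.zoom(cam, zoom, order=1)
    cam_up = np.maximum(cam_up, 0.0)
    # guard rounding of the resampled grid
    if cam_up.shape != target_shape:  # pragma: no cover
        cam_up = np.resize(cam_up, target_shape)
    m = cam_up.max()
    if m > 0:
        cam_up = cam_up / m
    return CamMap(
        relevance=cam_up,
        source_layer=net.layers[idx].name,
        predicted_class=int(p >= 0.5),
        raw_feature_shape=fmap.shape[1:],
    )


def lesion_overlap_statistic(cam: CamMap, lesion_mask: np.ndarray) -> Tuple[float, float]:
    """Mean CAM relevance inside vs outside a boolean lesion mask."""
    mask = lesion_mask.astype(bool)
    if mask.shape != cam.relevance.shape:
        raise ValueError(f"mask shape {mask.shape} != CAM shape {cam.relevance.shape}")
    inside = float(cam.relevance[mask].mean()) if mask.any() else float("nan")
    outside = float(cam.relevance[~mask].mean())
    return inside, outside


def render_overlays(
    cam: CamMap,
    stack: VolumeStack,
    out_dir,
    slice_indices: Optional[Sequence[int]] = None,
) -> List[Path]:
    """Write one PNG per requested slice: grayscale anatomy + heat overlay.

    Slices with an all-zero CAM render as plain grayscale (no overlay).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth = stack.voxels.shape[0]
    if slice_indices is None:
        slice_indices = [min(i, stack.n_real_slices - 1) for i in
                         (stack.n_real_slices // 4, stack.n_real_slices // 2)]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for i in slice_indices:
        if not 0 <= i < depth:
            raise IndexError(f"slice index {i} outside [0, {depth})")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(stack.voxels[i, :, :, 0], cmap="gray")
        sl = cam.relevance[i]
        if sl.max() > 0:
            ax.imshow(np.ma.masked_where(sl < 0.05, sl), cmap="jet", alpha=0.45,
                      vmin=0, vmax=1)
        ax.set_axis_off()
        path = out / f"{stack.patient_id}_slice{i:03d}.png"
        fig.savefig(path, bbox_inches="tight", dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
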