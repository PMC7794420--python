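"""3-D gradient-weighted class activation mapping for the volumetric CNN.

The gradient of the target-class *log-odds* (its logit minus the other
class's logit — for a two-class softmax the shared component of the two
logits carries no class evidence, so the log-odds is the discriminative
score) is taken with respect to the third conv block's ReLU output (128
feature volumes at 8³, *before* the final pooling for the extra
resolution), globally average-pooled into one weight per channel; the
heatmap is the ReLU of the weighted channel sum, trilinearly upsampled to
the 32³ input lattice and normalized to a maximum of 1 (identically-zero
maps stay zero).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cnn.model import CNN3D
from .io import CTVolume, write_volume
from .preprocess import NetworkInput, resample

CLASS_INDEX = {"noncopd": 0, "copd": 1}


class HeatmapVolume:
    """Normalized non-negative saliency volume aligned to the network input."""

    def __init__(self, values: np.ndarray, target_class: str):
        values = np.asarray(values, dtype=np.float32)
        if values.min() < 0:
            raise ValueError("heatmap must be non-negative")
        self.values = values
        self.target_class = target_class


def grad_cam(model: CNN3D, x: NetworkInput, target_class: str | int = "copd"
             ) -> HeatmapVolume:
    """Class-discriminative heatmap for one network input."""
    if isinstance(target_class, str):
        cls = CLASS_INDEX[target_class.lower().replace("-", "")]
        name = target_class
    else:
        cls = int(target_class)
        name = "copd" if cls == 1 else "noncopd"
    batch = np.ascontiguousarray(
        x.values.transpose(1, 2, 3, 0)[None], dtype=np.float32
    )
    logits = model.forward(batch, train=False, retain_activations=True)
    tap = model.cam_layer_index
    feats = model._activations[tap + 1][0]  # (8, 8, 8, 128)
    dlogits = np.zeros_like(logits)
    dlogits[0, cls] = 1.0
    dlogits[0, 1 - cls] = -1.0  # log-odds: remove the class-shared component
    dfeats = model.backward(dlogits, until_layer=tap + 1)[0]
    weights = dfeats.mean(axis=(0, 1, 2))  # GAP over space, one per channel
    cam = np.maximum(feats @ weights, 0.0)
    cam = resample(cam, x.values.shape[1:])
    cam = np.maximum(cam, 0.0)  # interpolation cannot introduce sign flips
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return HeatmapVolume(cam.astype(np.float32), name)


def export_overlay(heatmap: HeatmapVolume, background: CTVolume | np.ndarray,
                   out_dir: str | Path, prefix: str = "cam") -> dict[str, Path]:
    """Write the heatmap volume plus mid-plane axial/sagittal/coronal PNGs.

    The background (CT or PRM code volume) is resampled to the heatmap grid
    if needed; mid-planes are taken at ``floor(shape / 2)`` on each axis.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bg = background.voxels if isinstance(background, CTVolume) else np.asarray(background)
    bg = bg.astype(np.float64)
    if bg.shape != heatmap.values.shape:
        bg = resample(bg, heatmap.values.shape)
    paths = {"heatmap": out / f"{prefix}_heatmap.nii.gz"}
    write_volume(heatmap.values, paths["heatmap"])

    mids = [s // 2 for s in heatmap.values.shape]
    planes = {
        "axial": (bg[:, :, mids[2]], heatmap.values[:, :, mids[2]]),
        "coronal": (bg[:, mids[1], :], heatmap.values[:, mids[1], :]),
        "sagittal": (bg[mids[0], :, :], heatmap.values[mids[0], :, :]),
    }
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, (name, (b, h)) in zip(axes, planes.items()):
        ax.imshow(b.T, cmap="gray", origin="lower")
        ax.imshow(h.T, cmap="jet", alpha=0.4, origin="lower", vmin=0, vmax=1)
        ax.set_title(name)
        ax.axis("off")
    png = out / f"{prefix}_triptych.png"
    fig.savefig(png, dpi=100, bbox_inches="tight")
    plt.close(fig)
    paths["triptych"] = png
    return paths
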