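"""Grad-CAM heat maps over the final convolutional stage.

Channel weights are the spatial means of the class-score gradient at the
final stage feature map (the last convolutional representation before
global average pooling); the map is the rectified weighted channel sum,
bilinearly upsampled to the input size and max-normalised (an all-zero raw
map is preserved as zeros).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from brainnext.errors import ConfigurationError
from brainnext.patch_features import resize_image


@dataclass
class Heatmap:
    map: np.ndarray          # H x W in [0, 1], aligned to the input image
    raw: np.ndarray          # pre-normalisation map at feature-map resolution
    target_class: int


def grad_cam(net, image: np.ndarray, class_id: int) -> Heatmap:
    """Grad-CAM for one image and target class.

    Works on any model exposing ``forward_features``/``backward_head`` and a
    class count; evaluation-mode BN makes the map deterministic.
    """
    num_classes = net.fc.out_f
    if not 0 <= class_id < num_classes:
        raise ConfigurationError(
            f"class_id {class_id} out of range 0..{num_classes - 1}")
    size = net.spec.input_size if hasattr(net, "spec") else image.shape[0]
    x = resize_image(np.asarray(image), size)
    batch = np.transpose(x, (2, 0, 1))[None]

    fmap = net.forward_features(batch, train=False)       # 1 x C x h x w
    logits = net.fc.forward(net.gap.forward(fmap), train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_id] = 1.0
    net.fc.w.grad[:] = 0
    net.fc.b.grad[:] = 0
    dfmap = net.backward_head(dlogits)                    # 1 x C x h x w

    alpha = dfmap[0].mean(axis=(1, 2))                    # channel weights
    raw = np.maximum((alpha[:, None, None] * fmap[0]).sum(axis=0), 0.0)
    up = resize_image(raw.astype(np.float32), size)[:, :, 0]
    up = np.maximum(up, 0.0)
    peak = up.max()
    norm = up / peak if peak > 0 else up
    return Heatmap(map=norm.astype(np.float32), raw=raw.astype(np.float32),
                   target_class=class_id)


def save_overlay(heatmap: Heatmap, image: np.ndarray, path: str | Path,
                 alpha: float = 0.4, cmap: str = "jet") -> None:
    """Render the heat map over the image as a PNG (CLI artifact; the
    numeric map is the tested object)."""
    import matplotlib
    from PIL import Image

    size = heatmap.map.shape[0]
    base = resize_image(np.asarray(image), size)
    colored = matplotlib.colormaps[cmap](heatmap.map)[:, :, :3]
    blend = (1 - alpha) * base + alpha * colored
    arr = np.clip(np.round(blend * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def save_map_csv(heatmap: Heatmap, path: str | Path) -> None:
    np.savetxt(path, heatmap.raw, delimiter=",")
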