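"""Exemplar (fixed-size patch) deep feature extraction.

A 224x224 image is tiled into 49 non-overlapping 32x32 patches (row-major).
The trained network's global-average-pooling layer turns the raw image and
each patch into a length-C feature vector (C = final stage width, 768 by
default), giving 50 vectors per image that are concatenated into one
exemplar feature vector of length 50*C (38,400 by default).  Each patch is
bilinearly resized to the network input size before extraction, matching the
fixed-input pretrained-extractor convention.

Column provenance follows the merging law F[q + C*(t-1)] = fv_t[q] with
t in 1..50 (t=1 the raw image) and q in 1..C, both 1-based in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from brainnext.errors import GeometryError


@dataclass
class PatchGrid:
    """Ordered row-major tiling of a square image into fixed-size patches."""

    patches: list[np.ndarray]
    grid_shape: tuple[int, int]
    origins: list[tuple[int, int]]    # 1-based (i, j) top-left per patch
    source_size: int
    patch_size: int


@dataclass
class FeatureMatrix:
    """n x (vectors_per_image * feature_len) merged exemplar features."""

    values: np.ndarray
    feature_len: int                       # C, per-vector length
    n_vectors: int = 50                    # t range (raw + patches)
    row_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.values.ndim != 2:
            raise GeometryError("feature values must be 2-D")
        if self.values.shape[1] != self.feature_len * self.n_vectors:
            raise GeometryError(
                f"feature width {self.values.shape[1]} != "
                f"{self.feature_len} * {self.n_vectors}")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def column_provenance(self, col: int) -> tuple[int, int]:
        """0-based column -> 1-based (t, q) source block and channel."""
        if not 0 <= col < self.width:
            raise GeometryError(f"column {col} out of range")
        return col // self.feature_len + 1, col % self.feature_len + 1

    def column_names(self) -> list[str]:
        return [f"t{t}_q{q}" for t in range(1, self.n_vectors + 1)
                for q in range(1, self.feature_len + 1)]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.values, columns=self.column_names())
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        last = df.columns[-1]
        t, q = (int(s[1:]) for s in last.split("_"))
        return cls(df.to_numpy(dtype=np.float64), feature_len=q, n_vectors=t,
                   labels=labels)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an HxWx3 intensity image to size x size."""
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.shape[0] == size and image.shape[1] == size:
        return image.astype(np.float32, copy=False)
    out = _sk_resize(image, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def divide_patches(image: np.ndarray, patch_size: int = 32) -> PatchGrid:
    """Tile a square image into a row-major grid of pixel-exact patches."""
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    h, w = image.shape[:2]
    if h != w:
        raise GeometryError(f"image must be square, got {h}x{w}")
    if h % patch_size:
        raise GeometryError(
            f"image side {h} is not divisible by patch size {patch_size}")
    g = h // patch_size
    patches, origins = [], []
    for r in range(g):
        for c in range(g):
            i, j = r * patch_size, c * patch_size
            patches.append(image[i:i + patch_size, j:j + patch_size].copy())
            origins.append((i + 1, j + 1))
    return PatchGrid(patches, (g, g), origins, h, patch_size)


def reassemble(grid: PatchGrid) -> np.ndarray:
    """Inverse of divide_patches: stitch patches back in grid order."""
    g = grid.grid_shape[0]
    rows = [np.concatenate(grid.patches[r * g:(r + 1) * g], axis=1)
            for r in range(g)]
    return np.concatenate(rows, axis=0)


def extract_gap_features(net, image: np.ndarray) -> np.ndarray:
    """Global-average-pooling activation of the network for one image.

    The image is resized to the network input size; the returned vector has
    length equal to the final stage width.  Evaluation mode (running BN
    statistics) makes this deterministic.
    """
    x = resize_image(np.asarray(image), net.spec.input_size)
    batch = np.transpose(x, (2, 0, 1))[None]
    fmap = net.forward_features(batch, train=False)
    return fmap.mean(axis=(2, 3))[0]


def exemplar_features(net, image: np.ndarray,
                      patch_size: int = 32,
                      grid_size: int = 224) -> np.ndarray:
    """(1 + n_patches) x C feature array: row 1 the raw image, then patches
    in row-major grid order."""
    img = resize_image(np.asarray(image), grid_size)
    grid = divide_patches(img, patch_size)
    inputs = [img] + grid.patches
    c = net.feature_length()
    out = np.empty((len(inputs), c), dtype=np.float32)
    # fixed extraction order (raw, then patches row-major) for determinism
    for t, im in enumerate(inputs):
        out[t] = extract_gap_features(net, im)
    return out


def merge_features(per_image: list[np.ndarray] | np.ndarray,
                   row_ids: list[str] | None = None,
                   labels: np.ndarray | None = None) -> FeatureMatrix:
    """Merge per-image (n_vectors x C) arrays into the n x (n_vectors*C)
    exemplar feature matrix, block t occupying columns C*(t-1)..C*t-1."""
    arrs = [np.asarray(a) for a in per_image]
    if not arrs:
        raise GeometryError("no feature arrays given")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs) or len(shape) != 2:
        raise GeometryError("all per-image feature arrays must share one "
                            "(n_vectors, feature_len) shape")
    values = np.stack([a.reshape(-1) for a in arrs])
    if not np.all(np.isfinite(values)):
        raise GeometryError("non-finite feature values")
    return FeatureMatrix(values, feature_len=shape[1], n_vectors=shape[0],
                         row_ids=row_ids or [], labels=labels)


def unmerge_features(fm: FeatureMatrix) -> list[np.ndarray]:
    """Inverse of merge_features."""
    return [row.reshape(fm.n_vectors, fm.feature_len)
            for row in fm.values]


def dataset_features(net, image_set, patch_size: int = 32,
                     grid_size: int = 224) -> FeatureMatrix:
    """Exemplar feature matrix for every image in a LabeledImageSet."""
    per_image = [exemplar_features(net, it.image, patch_size, grid_size)
                 for it in image_set.items]
    ids = [it.path or str(i) for i, it in enumerate(image_set.items)]
    return merge_features(per_image, row_ids=ids, labels=image_set.labels())
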