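"""Render per-sample feature vectors as images under a pixel map.

Rendering is lossless: the intensity of a mapped pixel is exactly the
sample's feature value, empty pixels carry a configurable null value
(default 0, neutral for ReLU convolutions), and :func:`image_to_vector`
recovers the original vector bit-exactly.

Also provides the two baseline mappers used for comparison: a uniformly
random injective assignment and a PCA-loading layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureTable, ValidationError
from .gridmap import PixelMap, assign_to_grid, grid_side, rescale_to_unit_square
from .bmds import LocationSet

__all__ = [
    "SampleImage",
    "vectors_to_images",
    "images_to_array",
    "image_to_vector",
    "random_map",
    "pca_map",
    "write_image_archive",
    "read_image_archive",
    "write_pngs",
]


@dataclass
class SampleImage:
    """One rendered sample: a grid of pixel intensities."""

    sample_id: str
    pixels: np.ndarray
    null_value: float = 0.0


def vectors_to_images(
    t: FeatureTable, m: PixelMap, null_value: float = 0.0
) -> list:
    """Render one image per sample, feature values at their mapped pixels."""
    missing = [f for f in t.feature_names if f not in m.assignment]
    if missing:
        raise ValidationError(f"features missing from pixel map: {missing[:5]}")
    rows = np.array([m.assignment[f][0] for f in t.feature_names])
    cols = np.array([m.assignment[f][1] for f in t.feature_names])
    images = []
    for i, sid in enumerate(t.sample_ids):
        pix = np.full((m.grid_rows, m.grid_cols), null_value, dtype=float)
        pix[rows, cols] = t.values[i]
        images.append(SampleImage(sample_id=str(sid), pixels=pix, null_value=null_value))
    return images


def images_to_array(images: list) -> np.ndarray:
    """Stack images into an (n, rows, cols) array (training input)."""
    return np.stack([img.pixels for img in images])


def image_to_vector(img: SampleImage, m: PixelMap, feature_order=None) -> np.ndarray:
    """Read mapped pixels back in feature order (inverse of rendering)."""
    if img.pixels.shape != (m.grid_rows, m.grid_cols):
        raise ValidationError(
            f"image shape {img.pixels.shape} != grid ({m.grid_rows}, {m.grid_cols})"
        )
    order = m.features if feature_order is None else feature_order
    rows = np.array([m.assignment[f][0] for f in order])
    cols = np.array([m.assignment[f][1] for f in order])
    return img.pixels[rows, cols]


def random_map(feature_names, seed: int = 0) -> PixelMap:
    """Uniformly random injective assignment onto the smallest square grid."""
    names = list(feature_names)
    p = len(names)
    if p < 1:
        raise ValidationError("need at least one feature")
    side = grid_side(p)
    rng = np.random.default_rng(seed)
    cells = rng.permutation(side * side)[:p]
    assignment = {f: (int(c // side), int(c % side)) for f, c in zip(names, cells)}
    return PixelMap(side, side, assignment)


def pca_map(t: FeatureTable) -> PixelMap:
    """Layout features by their loadings on the first two principal components.

    PCA is run on the samples-by-features matrix; each feature's 2D
    coordinate is its loading pair on PC1/PC2, similarity-rescaled into the
    unit square and tessellated with the shared collision resolution.
    """
    if t.n < 2 or t.p < 2:
        raise ValidationError("pca_map needs n >= 2 and p >= 2")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2)
    pca.fit(t.values)
    if pca.components_.shape[0] < 2:
        raise ValidationError("covariance has fewer than 2 principal components")
    loadings = pca.components_.T  # (p, 2)
    loc = LocationSet(list(t.feature_names), rescale_to_unit_square(loadings))
    return assign_to_grid(loc)


def write_image_archive(images: list, path) -> None:
    """Write a numeric archive (one matrix per sample + manifest of ids)."""
    path = Path(path)
    arrays = {f"img_{i:06d}": img.pixels for i, img in enumerate(images)}
    np.savez_compressed(path, **arrays)
    manifest = pd.DataFrame({"index": range(len(images)), "sample_id": [i.sample_id for i in images]})
    manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def read_image_archive(path) -> list:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    manifest = pd.read_csv(path.with_suffix("").with_suffix(".manifest.csv"))
    images = []
    for row in manifest.itertuples():
        images.append(SampleImage(sample_id=str(row.sample_id), pixels=data[f"img_{row.index:06d}"]))
    return images


def write_pngs(images: list, directory) -> None:
    """16-bit grayscale PNG previews (quantized to 1/65535; inspection only)."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img in images:
        arr = np.clip(img.pixels, 0.0, 1.0)
        arr16 = np.round(arr * 65535).astype(np.uint16)
        Image.fromarray(arr16).save(directory / f"{img.sample_id}.png")  # uint16 -> 16-bit gray
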