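"""Green-target detection in RGB images.

A reaching workspace is photographed against a plain background with an
unknown number (typically 2-4) of green spherical targets.  Detection is a
three-stage pipeline:

1. colour-ratio segmentation: a pixel is foreground iff G / (R+G+B) exceeds
   a threshold (default 0.5);
2. noise filtering: 3x3 morphological erosion (a pixel survives only if its
   full 3x3 neighbourhood is foreground; borders are cleared);
3. divisive hierarchical clustering: all foreground pixels start as one
   cluster, and any cluster whose x- or y-standard deviation reaches the
   split threshold (default 20 px) is divided in two, recursively, until
   every cluster is compact.  This avoids fixing the number of targets in
   advance.

Pixel coordinates are (x, y) = (column, row), 0-based, throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "PixelCluster",
    "segment_green",
    "denoise",
    "divisive_cluster",
    "detect_targets",
    "read_rgb",
    "write_mask",
    "clusters_to_frame",
]

DEFAULT_RATIO_THRESHOLD = 0.5
DEFAULT_STD_THRESHOLD = 20.0
_MAX_SPLIT_DEPTH = 16
_KMEANS_TOL = 1e-6
_KMEANS_MAX_ITER = 100


class ClusteringError(RuntimeError):
    """Divisive clustering failed to converge within the depth guard."""


@dataclass(frozen=True)
class PixelCluster:
    """A compact group of foreground pixels attributed to one target.

    ``pixels`` is an (n, 2) integer array of (x, y) coordinates; ``centroid``
    is their arithmetic mean and ``std_x`` / ``std_y`` the population
    standard deviations per axis.
    """

    pixels: np.ndarray
    centroid: tuple[float, float]
    std_x: float
    std_y: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def _make_cluster(pixels: np.ndarray) -> PixelCluster:
    mean = pixels.mean(axis=0)
    std = pixels.std(axis=0)  # population std: stable down to single pixels
    return PixelCluster(
        pixels=pixels,
        centroid=(float(mean[0]), float(mean[1])),
        std_x=float(std[0]),
        std_y=float(std[1]),
    )


def segment_green(
    image: np.ndarray, threshold: float = DEFAULT_RATIO_THRESHOLD
) -> np.ndarray:
    """Binary mask of pixels whose green ratio G/(R+G+B) exceeds ``threshold``.

    A pure black pixel (0, 0, 0) has an undefined ratio and is defined as
    background.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    total = image.sum(axis=2, dtype=np.float64)
    green = image[:, :, 1].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, green / total, 0.0)
    return (ratio > threshold).astype(np.uint8)


def denoise(binary: np.ndarray) -> np.ndarray:
    """3x3 erosion: keep a pixel only when all 9 neighbours are foreground.

    Border pixels, whose 3x3 window leaves the image, are set to 0.
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValueError("expected a 2-D binary array")
    if binary.shape[0] < 3 or binary.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3 for the erosion filter")
    eroded = ndimage.binary_erosion(
        binary.astype(bool), structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    return eroded.astype(np.uint8)


def _lex_order(pixels: np.ndarray) -> np.ndarray:
    """Indices sorting pixels by (x, y) lexicographically."""
    return np.lexsort((pixels[:, 1], pixels[:, 0]))


def _split_two(pixels: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2-means split of pixel coordinates.

    Centroids are seeded with the two extreme pixels along ``axis`` (the axis
    whose spread triggered the split); ties broken lexicographically.
    Assignment ties go to the first centroid.
    """
    pts = pixels.astype(np.float64)
    coord = pixels[:, axis]
    lo_candidates = pixels[coord == coord.min()]
    hi_candidates = pixels[coord == coord.max()]
    c0 = lo_candidates[_lex_order(lo_candidates)[0]].astype(np.float64)
    c1 = hi_candidates[_lex_order(hi_candidates)[-1]].astype(np.float64)
    assign = None
    for _ in range(_KMEANS_MAX_ITER):
        d0 = ((pts - c0) ** 2).sum(axis=1)
        d1 = ((pts - c1) ** 2).sum(axis=1)
        assign = d1 < d0
        if not assign.any():  # second cluster emptied: reseed at farthest point
            assign = d0 == d0.max()
            assign &= np.cumsum(assign) == 1
        elif assign.all():
            inv = d1 == d1.max()
            inv &= np.cumsum(inv) == 1
            assign = ~inv
        new_c0 = pts[~assign].mean(axis=0)
        new_c1 = pts[assign].mean(axis=0)
        shift = max(np.abs(new_c0 - c0).max(), np.abs(new_c1 - c1).max())
        c0, c1 = new_c0, new_c1
        if shift < _KMEANS_TOL:
            break
    return pixels[~assign], pixels[assign]


def divisive_cluster(
    binary: np.ndarray, std_threshold: float = DEFAULT_STD_THRESHOLD
) -> list[PixelCluster]:
    """Divisively cluster foreground pixels until every cluster is compact.

    Starting from the single cluster of all 1-pixels, any cluster whose
    per-axis population standard deviation reaches ``std_threshold`` on x or
    y is split in two (deterministic 2-means); the returned clusters
    partition the foreground and are sorted by centroid (x, then y).

    An empty foreground returns an empty list.
    """
    if std_threshold <= 0:
        raise ValueError("std_threshold must be positive")
    binary = np.asarray(binary)
    rows, cols = np.nonzero(binary)
    if len(rows) == 0:
        return []
    pixels = np.column_stack([cols, rows]).astype(np.int64)  # (x, y)

    done: list[PixelCluster] = []
    stack: list[tuple[np.ndarray, int]] = [(pixels, 0)]
    while stack:
        pts, depth = stack.pop()
        cluster = _make_cluster(pts)
        if cluster.std_x < std_threshold and cluster.std_y < std_threshold:
            done.append(cluster)
            continue
        if depth >= _MAX_SPLIT_DEPTH:
            raise ClusteringError(
                f"cluster of {len(pts)} pixels (std_x={cluster.std_x:.1f}, "
                f"std_y={cluster.std_y:.1f}) not compact after "
                f"{_MAX_SPLIT_DEPTH} splits"
            )
        axis = 0 if cluster.std_x >= cluster.std_y else 1
        left, right = _split_two(pts, axis)
        stack.append((left, depth + 1))
        stack.append((right, depth + 1))
    done.sort(key=lambda c: c.centroid)
    return done


def detect_targets(
    image: np.ndarray,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
    std_threshold: float = DEFAULT_STD_THRESHOLD,
) -> list[PixelCluster]:
    """Full detection pipeline: segment, erode, cluster."""
    return divisive_cluster(denoise(segment_green(image, threshold)), std_threshold)


def read_rgb(path: str | Path) -> np.ndarray:
    """Load an RGB image (PNG/PPM, 8-bit) as an H x W x 3 uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def clusters_to_frame(clusters: list[PixelCluster]) -> pd.DataFrame:
    """Tabulate clusters (cluster_id, centroid_x, centroid_y, n_pixels, std_x, std_y)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": i,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "n_pixels": c.n_pixels,
                "std_x": c.std_x,
                "std_y": c.std_y,
            }
            for i, c in enumerate(clusters)
        ],
        columns=["cluster_id", "centroid_x", "centroid_y", "n_pixels", "std_x", "std_y"],
    )
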