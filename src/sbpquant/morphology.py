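"""Pre-skeletonisation morphology: components, coverage and homogeneity.

The first analysis stage treats the binary mask directly.  Connected
components of foreground pixels (8-connectivity) are interpreted as
individual nerve-fibre networks.  The stage yields the number of nerve
pixels, the percentage of the field they cover, the component count,
and a spatial-homogeneity score measuring how evenly nerve pixels are
spread over the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .image_io import SegmentedImage

#: 3x3 structuring element: foreground connectivity is 8-connected.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: Default tiling for the homogeneity measure.
DEFAULT_TILES_PER_AXIS = 8


@dataclass
class ComponentLabeling:
    """Partition of foreground pixels into maximal 8-connected sets.

    Labels are positive integers assigned in raster order of each
    component's first pixel; background is 0.
    """

    labels: np.ndarray
    n_components: int


@dataclass
class MorphoMetrics:
    component_pixels: int
    component_ratio: float  # percent of the field covered by fibres
    n_components: int
    homogeneity: float


def label_components(img: SegmentedImage) -> ComponentLabeling:
    """Label maximal 8-connected foreground sets 1..n in raster order."""
    labels, n = ndi.label(img.mask, structure=STRUCTURE_8)
    if n > 1:
        # relabel so label k is the k-th component encountered in a raster scan
        flat = labels.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so that the earliest index wins
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    return ComponentLabeling(labels=labels, n_components=int(n))


def component_pixels(img: SegmentedImage) -> int:
    """Number of pixels identified as nerve fibres."""
    return int(img.mask.sum())


def component_ratio(img: SegmentedImage) -> float:
    """Percentage of the image area covered by nerve-fibre pixels."""
    return 100.0 * component_pixels(img) / img.mask.size


def _tile_edges(size: int, k: int) -> list[tuple[int, int]]:
    # k near-equal tiles; the last tile absorbs the remainder
    step = size // k
    return [(i * step, (i + 1) * step if i < k - 1 else size) for i in range(k)]


def homogeneity(img: SegmentedImage, tiles_per_axis: int = DEFAULT_TILES_PER_AXIS) -> float:
    """Spatial-homogeneity score of the nerve-pixel distribution.

    The field is split into ``tiles_per_axis²`` near-equal rectangular
    tiles and the population variance of per-tile foreground fractions
    is returned.  Zero means perfectly uniform coverage (including the
    all-empty and all-full masks); larger values mean nerve pixels are
    concentrated in fewer tiles.
    """
    k = tiles_per_axis
    if not 2 <= k <= min(img.width_px, img.height_px):
        raise ValueError(f"tiles_per_axis {k} out of range for {img.mask.shape} image")
    fractions = np.empty((k, k))
    for i, (r0, r1) in enumerate(_tile_edges(img.height_px, k)):
        for j, (c0, c1) in enumerate(_tile_edges(img.width_px, k)):
            tile = img.mask[r0:r1, c0:c1]
            fractions[i, j] = tile.mean()
    return float(fractions.var())


def morpho_metrics(img: SegmentedImage, tiles_per_axis: int = DEFAULT_TILES_PER_AXIS) -> MorphoMetrics:
    """Run the full pre-skeletonisation stage on one mask."""
    labeling = label_components(img)
    n_px = component_pixels(img)
    return MorphoMetrics(
        component_pixels=n_px,
        component_ratio=100.0 * n_px / img.mask.size,
        n_components=labeling.n_components,
        homogeneity=homogeneity(img, tiles_per_axis),
    )
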