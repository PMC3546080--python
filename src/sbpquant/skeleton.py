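"""Topology-preserving skeletonisation of fibre masks.

Reduces a segmented fibre mask to its one-pixel-wide medial axis by
iterative boundary thinning (Zhang–Suen family, via scikit-image).
The mask is padded by edge replication before thinning so that fibres
cut off by the image border keep a stub reaching the outermost pixel
row/column — those stubs later become border-crossing ("connectivity")
terminals in the graph stage.  Thinning is iterated to a fixed point,
which makes the operation idempotent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .image_io import SegmentedImage

#: Edge-replication pad width (px) applied around the mask during thinning.
_PAD = 8

#: Safety cap on fixed-point iterations; thinning converges in 1-2 passes.
_MAX_PASSES = 10


@dataclass
class SkeletonImage:
    """One-pixel-wide medial-axis mask derived from a segmented image."""

    skeleton: np.ndarray
    pixel_pitch_um: float
    parent: SegmentedImage | None = None

    @property
    def skeleton_pixels(self) -> int:
        return int(self.skeleton.sum())

    @property
    def height_px(self) -> int:
        return self.skeleton.shape[0]

    @property
    def width_px(self) -> int:
        return self.skeleton.shape[1]


def _thin_once(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, _PAD, mode="edge")
    thin = _sk_skeletonize(padded)[_PAD:-_PAD, _PAD:-_PAD]
    # Replicate padding keeps border-crossing fibre stubs, but a blunt
    # shape flush against the border can thin into the pad region and
    # come back cropped away or disconnected.  Any mask component whose
    # thinned image is not exactly one connected piece is redone with a
    # plain (unpadded, topology-safe) thinning pass.
    structure = np.ones((3, 3), bool)
    labm, nm = ndi.label(mask, structure=structure)
    if nm == 0:
        return thin
    labt, _ = ndi.label(thin, structure=structure)
    pieces_per_comp = np.zeros(nm + 1, dtype=int)
    if thin.any():
        pairs = np.unique(np.stack([labm[thin], labt[thin]]), axis=1)
        np.add.at(pieces_per_comp, pairs[0], 1)
    bad = [k for k in range(1, nm + 1) if pieces_per_comp[k] != 1]
    if bad:
        plain = _sk_skeletonize(mask)
        for k in bad:
            comp = labm == k
            rescue = plain & comp
            if not rescue.any():
                rescue = np.zeros_like(mask)
                rescue[tuple(np.argwhere(comp)[0])] = True
            thin = (thin & ~comp) | rescue
    return thin


def thin_mask(mask: np.ndarray) -> np.ndarray:
    """Iterate boundary thinning to a fixed point (idempotent)."""
    current = np.asarray(mask, dtype=bool)
    for _ in range(_MAX_PASSES):
        thinned = _thin_once(current)
        if np.array_equal(thinned, current):
            break
        current = thinned
    return current


def skeletonize(img: SegmentedImage) -> SkeletonImage:
    """Compute the medial axis of a segmented fibre mask.

    Deterministic for a fixed input and idempotent: skeletonising an
    already-thin mask leaves it unchanged.  An empty mask yields an
    empty skeleton.  Component count (8-connectivity) is preserved.
    """
    return SkeletonImage(
        skeleton=thin_mask(img.mask), pixel_pitch_um=img.pixel_pitch_um, parent=img
    )


def skeleton_pixels(skel: SkeletonImage) -> int:
    """Number of pixels on the medial axes of the nerve fibres."""
    return skel.skeleton_pixels
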