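"""Synthetic subbasal-nerve-plexus phantoms with exact ground truth.

Real confocal nerve images are not redistributable, so validation of
the measurement pipeline rests on phantoms: binary masks of smooth
curvilinear fibres whose arc lengths and topology are known before
rasterisation.  A fibre is a straight chord between two field-border
points (or a border point and an interior ending) plus a sinusoidal
lateral displacement that emulates the regular tortuosity of subbasal
nerves; with some probability a fibre carries one branch event that
spawns a child curve.  Curves are rasterised at a configurable stroke
width.  By default fibres are kept disjoint by rejection sampling so
that the recorded truth (total analytic length, branch/endpoint/
border-crossing counts) is exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .image_io import DEFAULT_PIXEL_PITCH_UM, SegmentedImage

logger = logging.getLogger(__name__)

_MAX_ATTEMPTS = 100

#: Curve sampling density (samples per pixel of arc).
_SAMPLES_PER_PX = 4.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom mask.

    ``tortuosity_amp_um`` is the lateral sine amplitude in µm;
    ``branch_prob`` the per-fibre probability of one branch event;
    ``interior_end_prob`` the chance that a fibre terminates inside
    the field rather than crossing the far border.  The seed fixes
    the output bit for bit.
    """

    n_fibres: int = 8
    branch_prob: float = 0.5
    tortuosity_amp_um: float = 12.0
    stroke_width_px: int = 3
    width_px: int = 384
    height_px: int = 384
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    interior_end_prob: float = 0.2
    allow_intersections: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.branch_prob <= 1 or not 0 <= self.interior_end_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.stroke_width_px < 1 or self.stroke_width_px % 2 == 0:
            raise ValueError("stroke_width_px must be a positive odd integer")
        if self.n_fibres < 0:
            raise ValueError("n_fibres must be non-negative")


@dataclass
class PhantomTruth:
    """Analytic ground truth recorded while drawing a phantom.

    ``true_n_fibres`` counts the traced segments the measurement stage
    should find: each drawn parent curve is one segment, and every
    branch event adds two (the child plus the split of its parent).
    Lengths are arc lengths of the generating curves, computed before
    rasterisation.
    """

    true_total_length_um: float = 0.0
    true_n_fibres: int = 0
    true_n_branches: int = 0
    true_n_endpoints: int = 0
    true_n_border_crossings: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _span_points(u: float, v: float, h: int, w: int, vertical: bool) -> tuple[np.ndarray, np.ndarray]:
    """Entry and exit border points of a fibre crossing the field.

    ``u``/``v`` are fractional positions along the entry and exit
    sides; ``vertical`` selects top→bottom travel, else left→right.
    """
    if vertical:
        return np.array([0.0, u * (w - 1)]), np.array([h - 1.0, v * (w - 1)])
    return np.array([u * (h - 1), 0.0]), np.array([v * (h - 1), w - 1.0])


def _curve_points(a: np.ndarray, b: np.ndarray, amp_px: float, n_halfwaves: int) -> np.ndarray:
    """Dense samples of the sinusoidally displaced chord from a to b.

    The displacement ``amp·sin(π·m·t)`` vanishes at both ends, so the
    curve's endpoints stay exactly at a and b.
    """
    chord = b - a
    chord_len = float(np.hypot(*chord))
    n = max(64, int(_SAMPLES_PER_PX * (chord_len + 2 * np.pi * abs(amp_px) * n_halfwaves)))
    t = np.linspace(0.0, 1.0, n)
    normal = np.array([-chord[1], chord[0]]) / max(chord_len, 1e-9)
    return a + np.outer(t, chord) + np.outer(amp_px * np.sin(np.pi * n_halfwaves * t), normal)


def _arc_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _rasterize(points: np.ndarray, h: int, w: int, stroke_width_px: int) -> np.ndarray:
    rc = np.clip(np.round(points).astype(int), 0, [h - 1, w - 1])
    mask = np.zeros((h, w), dtype=bool)
    mask[rc[:, 0], rc[:, 1]] = True
    if stroke_width_px > 1:
        mask = ndi.binary_dilation(mask, structure=disk((stroke_width_px - 1) // 2))
    return mask


def _curve_admissible(
    pts: np.ndarray, h: int, w: int, stroke_width_px: int,
    border_start: bool, border_end: bool,
) -> bool:
    """True when the curve stays in the field and only approaches the
    border near its border endpoints.

    Interior stretches must keep a clearance of half a stroke plus two
    pixels from the border so that the dilated stroke never grazes the
    frame away from a genuine crossing.
    """
    r = np.round(pts)
    if (r[:, 0] < 0).any() or (r[:, 0] > h - 1).any() or (r[:, 1] < 0).any() or (r[:, 1] > w - 1).any():
        return False
    d = np.minimum.reduce([pts[:, 0], h - 1 - pts[:, 0], pts[:, 1], w - 1 - pts[:, 1]])
    clearance = stroke_width_px // 2 + 2
    # samples within ~15 px of arc of a border endpoint are exempt
    window = int(_SAMPLES_PER_PX * 5 * (stroke_width_px + 2))
    lo = window if border_start else 0
    hi = len(pts) - (window if border_end else 0)
    if lo >= hi:
        return False
    return bool((d[lo:hi] >= clearance).all())


def generate_phantom(spec: PhantomSpec) -> tuple[SegmentedImage, PhantomTruth]:
    """Draw a phantom mask and its exact ground truth.

    Deterministic per seed: the same spec always yields the same mask
    and truth.  Raises a generation error when a fibre cannot be
    placed without overlap after 100 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    sw = spec.stroke_width_px
    mask = np.zeros((h, w), dtype=bool)
    truth = PhantomTruth()
    # separation margin keeping skeletons of distinct fibres disjoint
    margin = disk(sw + 2)
    forbidden = np.zeros((h, w), dtype=bool)
    amp_px = spec.tortuosity_amp_um / spec.pixel_pitch_um

    def near_disk(center: np.ndarray) -> np.ndarray:
        rr, cc = np.indices((h, w))
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (2 * sw + 4) ** 2

    # fibres run roughly in parallel across the field, as subbasal
    # nerves do; stratified entry positions keep them apart
    vertical = bool(rng.uniform() < 0.5)
    n = max(spec.n_fibres, 1)
    bin_width = 0.9 / n
    entry_bins = rng.permutation(spec.n_fibres)

    # phase 1: main fibres
    parents: list[np.ndarray] = []
    for fibre_idx in range(spec.n_fibres):
        for _attempt in range(_MAX_ATTEMPTS):
            # late attempts fall back to straighter, better-aligned
            # fibres so that a crowded field can still be completed
            squeeze = 1.0 if _attempt < _MAX_ATTEMPTS // 2 else 0.25
            u = 0.05 + (entry_bins[fibre_idx] + rng.uniform(0.15, 0.85)) * bin_width
            v = float(np.clip(u + rng.normal(0.0, 0.08 * squeeze), 0.03, 0.97))
            a, b = _span_points(u, v, h, w, vertical)
            interior_end = rng.uniform() < spec.interior_end_prob
            if interior_end:
                # stop partway across the field instead of crossing it
                b = a + rng.uniform(0.35, 0.75) * (b - a)
            amp = amp_px * rng.uniform(0.5, 1.5) * squeeze
            n_halfwaves = int(rng.integers(1, 3))
            pts = _curve_points(a, b, amp, n_halfwaves)
            if not _curve_admissible(pts, h, w, sw, True, not interior_end):
                continue
            raster = _rasterize(pts, h, w, sw)
            if not spec.allow_intersections and (raster & forbidden).any():
                continue
            mask |= raster
            forbidden = ndi.binary_dilation(mask, structure=margin)
            parents.append(pts)
            truth.true_total_length_um += _arc_length(pts) * spec.pixel_pitch_um
            truth.true_n_fibres += 1
            truth.true_n_border_crossings += 2 - int(interior_end)
            truth.true_n_endpoints += int(interior_end)
            break
        else:
            raise RuntimeError(
                f"could not place fibre without overlap after {_MAX_ATTEMPTS} attempts "
                f"(n_fibres={spec.n_fibres} on {w}x{h})"
            )

    # phase 2: branch twigs, attached once all main fibres are down so
    # that a twig can never block a fibre corridor
    for pts in parents:
        if rng.uniform() >= spec.branch_prob:
            continue
        parent_raster = _rasterize(pts, h, w, sw)
        others_zone = forbidden & ~ndi.binary_dilation(parent_raster, structure=margin)
        for _c in range(_MAX_ATTEMPTS):
            t0 = rng.uniform(0.3, 0.7)
            i0 = int(t0 * (len(pts) - 1))
            bp = pts[i0]
            # short side twig fitting the inter-fibre gap
            tangent = pts[min(i0 + 3, len(pts) - 1)] - pts[max(i0 - 3, 0)]
            tangent = tangent / max(float(np.hypot(*tangent)), 1e-9)
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            theta = sign * np.deg2rad(rng.uniform(35.0, 80.0))
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            length = rng.uniform(15.0, 40.0)
            c_end = bp + length * (rot @ tangent)
            c_amp = amp_px * rng.uniform(0.1, 0.3)
            cand = _curve_points(bp, c_end, c_amp, 1)
            if not _curve_admissible(cand, h, w, sw, False, False):
                continue
            child_raster = _rasterize(cand, h, w, sw)
            # must clear every other fibre entirely and its own parent
            # beyond the immediate fork region
            parent_clash = child_raster & ndi.binary_dilation(parent_raster, structure=margin)
            clash = (child_raster & others_zone) | (parent_clash & ~near_disk(bp))
            if clash.any() and not spec.allow_intersections:
                continue
            mask |= child_raster
            forbidden = ndi.binary_dilation(mask, structure=margin)
            truth.true_total_length_um += _arc_length(cand) * spec.pixel_pitch_um
            truth.true_n_branches += 1
            truth.true_n_fibres += 2  # child + split of the parent
            truth.true_n_endpoints += 1  # twigs end inside the field
            break

    img = SegmentedImage(
        mask=mask, pixel_pitch_um=spec.pixel_pitch_um, source=f"phantom(seed={spec.seed})"
    )
    return img, truth


#: Generation presets emulating the density contrast between a normal
#: plexus (~0.02 µm/µm²) and a rarefied neuropathic one (~0.006 µm/µm²).
_PRESETS = {
    "healthy": PhantomSpec(
        n_fibres=8, branch_prob=0.5, tortuosity_amp_um=12.0, interior_end_prob=0.15
    ),
    "neuropathic": PhantomSpec(
        n_fibres=2, branch_prob=0.25, tortuosity_amp_um=15.0, interior_end_prob=0.3
    ),
}


def preset(group: str, seed: int = 0) -> PhantomSpec:
    """Phantom spec for a named condition: ``healthy`` or ``neuropathic``."""
    if group not in _PRESETS:
        raise ValueError(f"unknown preset {group!r}; expected one of {sorted(_PRESETS)}")
    return replace(_PRESETS[group], seed=seed)
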