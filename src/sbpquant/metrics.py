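"""Assembly of the per-image nerve-morphometry parameter vector.

Runs the full two-stage pipeline (morphology → skeletonisation →
graph topology) on one segmented image and collects the parameter
set used to characterise the subbasal nerve plexus:

==============================  =====================================
component_pixels (n)            pixels identified as nerve fibres
component_ratio (%)             field coverage by nerve pixels
n_components (n)                individual nerve-fibre networks
homogeneity                     spatial uniformity of nerve pixels
skeleton_pixels (n)             medial-axis pixels
single_nerve_fibres (n)         traced segments between nodes
fibres_per_component (n)        segments per network
total_fibre_length_um (µm)      summed centreline length
avg_single_fibre_length_um (µm) mean traced-segment length
fibre_density (µm/µm²)          total length / imaged area
n_branches (n)                  fibre bifurcations
n_connectivity_points (n)       fibres crossing the field border
n_endpoints (n)                 true nerve endings
==============================  =====================================

Density is stored in µm of fibre per µm² of tissue; on this scale a
healthy plexus is of order 0.02 and a severely rarefied one of order
0.006.  Extensive quantities can be rescaled to a reference area of
1 mm² with :func:`normalize_metrics`.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from .graph import DEFAULT_MIN_SEGMENT_UM, build_graph, prune_spurs
from .image_io import SegmentedImage
from .morphology import DEFAULT_TILES_PER_AXIS, morpho_metrics
from .skeleton import skeletonize

logger = logging.getLogger(__name__)

#: Extensive (area-proportional) fields rescaled by the 1 mm² normalisation.
EXTENSIVE_FIELDS = (
    "component_pixels",
    "n_components",
    "skeleton_pixels",
    "single_nerve_fibres",
    "total_fibre_length_um",
    "n_branches",
    "n_connectivity_points",
    "n_endpoints",
)

#: Column order of the metrics CSV.
CSV_COLUMNS = (
    "subject_id",
    "group",
    "component_pixels",
    "component_ratio_pct",
    "n_components",
    "homogeneity",
    "skeleton_pixels",
    "single_nerve_fibres",
    "fibres_per_component",
    "total_fibre_length_um",
    "avg_single_fibre_length_um",
    "fibre_density_um_per_um2",
    "n_branches",
    "n_connectivity_points",
    "n_endpoints",
    "normalized",
    "image_area_mm2",
)


@dataclass
class SBPMetrics:
    component_pixels: float
    component_ratio: float
    n_components: float
    homogeneity: float
    skeleton_pixels: float
    single_nerve_fibres: float
    fibres_per_component: float
    total_fibre_length_um: float
    avg_single_fibre_length_um: float
    fibre_density: float  # µm of fibre per µm² of imaged area
    n_branches: float
    n_connectivity_points: float
    n_endpoints: float
    normalized: bool
    image_area_mm2: float


def compute_metrics(
    img: SegmentedImage,
    *,
    tiles_per_axis: int = DEFAULT_TILES_PER_AXIS,
    min_segment_um: float = DEFAULT_MIN_SEGMENT_UM,
) -> SBPMetrics:
    """Quantify one segmented image (un-normalised, per-field values).

    Stage 1 measures the mask directly; stage 2 skeletonises it,
    prunes sub-threshold terminal spurs and analyses the resulting
    graph.  An empty image yields all-zero metrics; the ratio
    quantities that would be 0/0 are reported as 0 by convention.
    """
    morpho = morpho_metrics(img, tiles_per_axis)
    skel = prune_spurs(skeletonize(img), min_segment_um)
    g = build_graph(skel)

    n_fibres = len(g.edges)
    total_um = g.total_length_um
    if n_fibres == 0:
        logger.warning("image %s contains no measurable fibre segments", img.source or "<array>")
    avg_um = total_um / n_fibres if n_fibres else 0.0
    per_comp = n_fibres / morpho.n_components if morpho.n_components else 0.0

    return SBPMetrics(
        component_pixels=morpho.component_pixels,
        component_ratio=morpho.component_ratio,
        n_components=morpho.n_components,
        homogeneity=morpho.homogeneity,
        skeleton_pixels=skel.skeleton_pixels,
        single_nerve_fibres=n_fibres,
        fibres_per_component=per_comp,
        total_fibre_length_um=total_um,
        avg_single_fibre_length_um=avg_um,
        fibre_density=total_um / img.image_area_um2,
        n_branches=g.count_nodes("branch"),
        n_connectivity_points=g.count_nodes("connectivity"),
        n_endpoints=g.count_nodes("endpoint"),
        normalized=False,
        image_area_mm2=img.image_area_mm2,
    )


def normalize_metrics(m: SBPMetrics) -> SBPMetrics:
    """Rescale extensive quantities to a reference area of 1 mm².

    Counts and lengths are divided by the imaged area in mm² (×6.25
    for the default 0.16 mm² field); intensive quantities — ratio,
    homogeneity, density, per-segment and per-component averages —
    are area-free and stay unchanged.
    """
    if m.normalized:
        raise ValueError("metrics are already normalised to 1 mm²")
    if not m.image_area_mm2 > 0:
        raise ValueError("image area must be positive to normalise")
    scale = 1.0 / m.image_area_mm2
    updates = {f: getattr(m, f) * scale for f in EXTENSIVE_FIELDS}
    return dataclasses.replace(m, normalized=True, **updates)


def _to_row(subject_id: str, group: str, m: SBPMetrics) -> dict:
    return {
        "subject_id": subject_id,
        "group": group,
        "component_pixels": m.component_pixels,
        "component_ratio_pct": m.component_ratio,
        "n_components": m.n_components,
        "homogeneity": m.homogeneity,
        "skeleton_pixels": m.skeleton_pixels,
        "single_nerve_fibres": m.single_nerve_fibres,
        "fibres_per_component": m.fibres_per_component,
        "total_fibre_length_um": m.total_fibre_length_um,
        "avg_single_fibre_length_um": m.avg_single_fibre_length_um,
        "fibre_density_um_per_um2": m.fibre_density,
        "n_branches": m.n_branches,
        "n_connectivity_points": m.n_connectivity_points,
        "n_endpoints": m.n_endpoints,
        "normalized": int(m.normalized),
        "image_area_mm2": m.image_area_mm2,
    }


def write_metrics_csv(rows: list[tuple[str, str, SBPMetrics]], path: str | Path) -> None:
    """Write one CSV row per subject in the documented column order.

    All rows must share the same normalisation state; mixing per-field
    and per-mm² values in one table is refused.
    """
    states = {m.normalized for _, _, m in rows}
    if len(states) > 1:
        raise ValueError("cannot mix normalised and un-normalised metrics in one CSV")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for subject_id, group, m in rows:
            writer.writerow(_to_row(subject_id, group, m))
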