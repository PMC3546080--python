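"""Reading, writing and validation of pre-segmented nerve-fibre masks.

The quantification pipeline consumes binary masks in which foreground
pixels mark subbasal nerve fibres.  Masks are stored as single-channel
8-bit PNG or TIFF rasters (white fibres on black background by
convention).  Spatial calibration defaults to the HRT-II / Rostock
Cornea Module field: 384 px across a 400 µm field of view, i.e.
~1.0417 µm per pixel edge; it can be overridden per image with a JSON
sidecar ``{"pixel_pitch_um": ...}`` stored next to the raster.

Coordinates are row-major with the origin at the top-left corner; a
pixel is treated as a unit square of side ``pixel_pitch_um``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: µm per pixel edge of the default confocal field (400 µm over 384 px).
DEFAULT_PIXEL_PITCH_UM: float = 400.0 / 384.0

#: Default binarisation threshold on 8-bit intensities.
DEFAULT_THRESHOLD: int = 127

# ITU-R BT.601 luminance weights used to collapse RGB input.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration of a confocal field.

    Parameters
    ----------
    pixel_pitch_um:
        Physical size of a pixel edge in micrometres.
    field_width_um, field_height_um:
        Physical extent of the imaged field.  Must agree with
        ``pixels x pitch`` to within 0.5 %.
    """

    pixel_pitch_um: float
    field_width_um: float
    field_height_um: float

    def __post_init__(self) -> None:
        for name in ("pixel_pitch_um", "field_width_um", "field_height_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_pitch(cls, pixel_pitch_um: float, width_px: int, height_px: int) -> "Calibration":
        return cls(
            pixel_pitch_um=pixel_pitch_um,
            field_width_um=width_px * pixel_pitch_um,
            field_height_um=height_px * pixel_pitch_um,
        )

    def check_consistency(self, width_px: int, height_px: int) -> None:
        """Raise if the stated field size disagrees with pixels x pitch by >0.5 %."""
        for field_um, n_px in ((self.field_width_um, width_px), (self.field_height_um, height_px)):
            expected = n_px * self.pixel_pitch_um
            if abs(field_um - expected) > 0.005 * expected:
                raise ValueError(
                    f"field size {field_um} µm inconsistent with "
                    f"{n_px} px at {self.pixel_pitch_um} µm/px"
                )


@dataclass
class SegmentedImage:
    """A binary nerve-fibre mask with spatial calibration.

    ``mask`` is a 2-D boolean array: ``True`` marks nerve-fibre
    (foreground) pixels.  The imaged area in mm² is derived from the
    pixel grid and the pixel pitch.
    """

    mask: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        if m.shape[0] < 3 or m.shape[1] < 3:
            raise ValueError(f"mask must be at least 3x3, got {m.shape}")
        if m.dtype != bool:
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask cells must be exactly 0 or 1")
            m = m.astype(bool)
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        self.mask = m

    @property
    def height_px(self) -> int:
        return self.mask.shape[0]

    @property
    def width_px(self) -> int:
        return self.mask.shape[1]

    @property
    def image_area_um2(self) -> float:
        return self.width_px * self.height_px * self.pixel_pitch_um**2

    @property
    def image_area_mm2(self) -> float:
        return self.image_area_um2 / 1e6

    @property
    def calibration(self) -> Calibration:
        return Calibration.from_pitch(self.pixel_pitch_um, self.width_px, self.height_px)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_mask(
    path: str | Path,
    binarize_threshold: int = DEFAULT_THRESHOLD,
    *,
    invert: bool = False,
    pixel_pitch_um: float | None = None,
) -> SegmentedImage:
    """Read a raster mask and binarise it.

    Multi-channel input is collapsed to luminance before thresholding;
    foreground is ``intensity > binarize_threshold`` (flipped when
    ``invert`` is set).  Calibration is taken from ``pixel_pitch_um``
    if given, else from a JSON sidecar next to the image, else the
    default confocal pitch.
    """
    path = Path(path)
    if not 0 <= binarize_threshold <= 255:
        raise ValueError(f"binarize_threshold must be in [0, 255], got {binarize_threshold}")
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError(f"image {path} has a zero dimension")
    if raw.ndim == 3:
        raw = raw[..., :3] @ _LUMA
    mask = raw > binarize_threshold
    if invert:
        mask = ~mask

    if pixel_pitch_um is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                payload = json.load(fh)
            pitch = payload.get("pixel_pitch_um") if isinstance(payload, dict) else None
            if pitch is not None:
                pixel_pitch_um = float(pitch)
                logger.info(
                    "calibration for %s from sidecar: %.4f µm/px", path.name, pixel_pitch_um
                )
            else:
                logger.warning(
                    "sidecar %s has no pixel_pitch_um; using default", sidecar.name
                )
        if pixel_pitch_um is None:
            pixel_pitch_um = DEFAULT_PIXEL_PITCH_UM
            logger.debug(
                "assuming default 400 µm / 384 px field (%.4f µm/px) for %s",
                pixel_pitch_um,
                path.name,
            )
    return SegmentedImage(mask=mask, pixel_pitch_um=pixel_pitch_um, source=str(path))


def write_mask(img: SegmentedImage, path: str | Path, *, write_sidecar: bool = False) -> None:
    """Write a mask as a lossless single-channel 8-bit raster (0/255).

    ``read_mask(write_mask(x))`` reproduces ``x.mask`` bit for bit.
    """
    path = Path(path)
    data = np.where(img.mask, 255, 0).astype(np.uint8)
    try:
        iio.imwrite(path, data)
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
    if write_sidecar:
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"pixel_pitch_um": img.pixel_pitch_um}, fh)
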