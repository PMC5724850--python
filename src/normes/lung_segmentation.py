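"""Automatic lung extraction from chest CT.

The lungs are the large interior air-density regions of a thorax scan. The
segmenter thresholds at an air/tissue boundary, discards low-attenuation
components connected to the in-plane image border (exterior air), discards
components too small to be a lung, keeps the largest remaining components,
and smooths the result by morphological closing plus slice-wise hole
filling. Airways are not removed and the two lungs are not separated —
emphysema scores in this package are whole-lung quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LungMask

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when no plausible lung region can be found."""


@dataclass
class SegmentationConfig:
    """Parameters of the threshold-based lung segmenter.

    air_threshold_hu : voxels below this are air-like candidates (HU).
    min_component_volume_ml : components smaller than this are discarded.
    closing_radius_mm : radius of the spherical closing element.
    keep_components : number of largest interior components to keep
        (2 covers separate left/right lungs; merged lungs arrive as 1).
    """

    air_threshold_hu: float = -500.0
    min_component_volume_ml: float = 50.0
    closing_radius_mm: float = 2.0
    keep_components: int = 2

    def __post_init__(self) -> None:
        if not (-1000.0 < self.air_threshold_hu < 0.0):
            raise ValueError("air_threshold_hu must lie in (-1000, 0)")
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")
        if self.min_component_volume_ml < 0:
            raise ValueError("min_component_volume_ml must be >= 0")
        if self.keep_components < 1:
            raise ValueError("keep_components must be >= 1")


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element approximating a sphere of the given
    physical radius on an anisotropic grid."""
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    zz, yy, xx = np.ogrid[
        -radii[0] : radii[0] + 1, -radii[1] : radii[1] + 1, -radii[2] : radii[2] + 1
    ]
    return (
        (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    ) <= 1.0


def segment_lungs(volume: CTVolume, config: SegmentationConfig | None = None) -> LungMask:
    """Extract the lung region of a chest CT volume.

    Raises :class:`SegmentationError` when no interior air-density component
    survives the size filter ("no lung found").
    """
    config = config or SegmentationConfig()
    air = volume.voxels < config.air_threshold_hu
    if not air.any():
        raise SegmentationError("no lung found: no voxels below the air threshold")

    labels, n_labels = ndimage.label(air)

    # Exterior air touches the in-plane border of the field of view.
    border_labels = np.unique(
        np.concatenate(
            [
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = set(border_labels[border_labels > 0].tolist())

    voxel_ml = float(np.prod(volume.spacing)) / 1000.0
    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    candidates = [
        (counts[lab], lab)
        for lab in range(1, n_labels + 1)
        if lab not in border_labels
        and counts[lab] * voxel_ml >= config.min_component_volume_ml
    ]
    if not candidates:
        raise SegmentationError(
            "no lung found: every interior air component was below "
            f"{config.min_component_volume_ml} ml or touched the border"
        )
    candidates.sort(reverse=True)
    keep = [lab for _, lab in candidates[: config.keep_components]]
    mask = np.isin(labels, keep)

    if config.closing_radius_mm > 0:
        mask = ndimage.binary_closing(
            mask, structure=_ball_footprint(config.closing_radius_mm, volume.spacing)
        )

    # Hole filling is slice-wise so that through-going airways are not sealed
    # into solid tubes by a 3-D fill.
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])

    out = LungMask(mask.astype(np.uint8), volume.spacing, volume.origin)
    if out.is_empty:  # pragma: no cover - closing cannot empty a nonempty mask
        raise SegmentationError("no lung found")
    log.info(
        "segmented lungs: %d voxels (%.0f ml) from %d candidate components",
        out.n_voxels,
        out.n_voxels * voxel_ml,
        len(candidates),
    )
    return out
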