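"""Threshold-based tumor volumetry on T2-contrast images.

Mirrors a slice-wise semiautomatic segmentation chain: per slice, one to
five rectangular regions of interest are binarized with ROI-individual
lower/upper thresholds (gray intensity on T2 average images, milliseconds
on T2 maps), the largest 8-connected component of each binarized ROI is
retained, retained pixel counts are summed over ROIs and slices, and the
total is converted to mm^3 with the voxel volume.

The interactive ROI placement of the original procedure is replaced by
declarative :class:`ROISpec` records; :func:`auto_rois` derives specs from
phantom tissue statistics for testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "ROISpec",
    "VolumeMeasurement",
    "voxel_volume",
    "truncate_voxel_volume",
    "segment_roi",
    "measure_volume",
    "auto_rois",
]

MAX_ROIS_PER_SLICE = 5


def voxel_volume(fov_x_mm: float, fov_y_mm: float, nx: int, ny: int, slice_thickness_mm: float) -> float:
    """Volume of one voxel in mm^3 at full floating-point precision.

    The default acquisition geometry (20x20 mm FOV, 256x256 matrix, 0.8 mm
    slices) gives 0.0048828125 mm^3.
    """
    if min(fov_x_mm, fov_y_mm, nx, ny, slice_thickness_mm) <= 0:
        raise ValueError("all geometry arguments must be positive")
    return (fov_x_mm / nx) * (fov_y_mm / ny) * slice_thickness_mm


def truncate_voxel_volume(volume_mm3: float, decimals: int = 4) -> float:
    """Truncate (not round) a voxel volume to ``decimals`` places.

    Formatting helper only: reproduces the conventional 4-decimal printed
    constant (0.0048828125 -> 0.0048).  All computation in this module uses
    the full-precision value.
    """
    factor = 10.0 ** decimals
    return math.floor(volume_mm3 * factor) / factor


@dataclass(frozen=True)
class ROISpec:
    """One rectangular region of interest with its threshold band.

    Coordinates are 0-based (row, col) with half-open bounds: the box covers
    rows ``row0 <= r < row1`` and cols ``col0 <= c < col1``.  Thresholds are
    in image units — gray intensity for T2 average images, ms for T2 maps —
    and the band is closed on both ends.
    """

    slice_index: int
    row0: int
    col0: int
    row1: int
    col1: int
    lower_threshold: float
    upper_threshold: float

    def __post_init__(self) -> None:
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"empty bounding box ({self.row0},{self.col0},{self.row1},{self.col1})")
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError(
                f"lower_threshold ({self.lower_threshold}) must be < upper_threshold ({self.upper_threshold})"
            )

    def validate_for(self, image_shape: tuple[int, int]) -> None:
        nr, nc = image_shape
        if self.row0 < 0 or self.col0 < 0 or self.row1 > nr or self.col1 > nc:
            raise ValueError(
                f"ROI box ({self.row0},{self.col0},{self.row1},{self.col1}) "
                f"exceeds image bounds {image_shape}"
            )


@dataclass
class VolumeMeasurement:
    """One session's tumor volume with segmentation provenance.

    ``volume_mm3`` equals ``total_pixels * voxel_volume_mm3`` exactly.
    """

    animal_id: str
    week: int
    method: str
    total_pixels: int
    voxel_volume_mm3: float
    per_roi_pixels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_pixels < 0 or any(n < 0 for n in self.per_roi_pixels):
            raise ValueError("pixel counts must be >= 0")
        if self.method not in ("t2_average", "t2_map"):
            raise ValueError(f"unknown contrast method {self.method!r}")

    @property
    def volume_mm3(self) -> float:
        return self.total_pixels * self.voxel_volume_mm3


def segment_roi(image_slice: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Binarize one ROI and keep the largest 8-connected component.

    Returns a full-slice boolean mask that is True only on the retained
    component inside the ROI box.  Values equal to either threshold are
    in-band.  Ties for the largest component are broken by smallest centroid
    distance to the box center, then lowest label — deterministic.  An empty
    band triggers a warning and an all-False mask.
    """
    image_slice = np.asarray(image_slice, dtype=float)
    if image_slice.ndim != 2:
        raise ValueError("image_slice must be 2-D")
    roi.validate_for(image_slice.shape)

    box = image_slice[roi.row0 : roi.row1, roi.col0 : roi.col1]
    # NaN (undefined T2-map pixels) never falls in-band.
    with np.errstate(invalid="ignore"):
        band = (box >= roi.lower_threshold) & (box <= roi.upper_threshold)

    mask = np.zeros(image_slice.shape, dtype=bool)
    if not band.any():
        warnings.warn(
            f"ROI at slice {roi.slice_index} box ({roi.row0},{roi.col0},{roi.row1},{roi.col1}): "
            "threshold band matched no pixels",
            stacklevel=2,
        )
        return mask

    labeled = cc_label(band, connectivity=2)  # 8-connectivity in 2-D
    props = regionprops(labeled)
    center = ((roi.row1 - roi.row0 - 1) / 2.0, (roi.col1 - roi.col0 - 1) / 2.0)

    def sort_key(p):
        d = (p.centroid[0] - center[0]) ** 2 + (p.centroid[1] - center[1]) ** 2
        return (-p.area, d, p.label)

    best = min(props, key=sort_key)
    mask[roi.row0 : roi.row1, roi.col0 : roi.col1] = labeled == best.label
    return mask


def measure_volume(
    masks: Mapping[int, Sequence[np.ndarray]],
    voxel_volume_mm3: float,
    animal_id: str = "",
    week: int = 0,
    method: str = "t2_average",
) -> VolumeMeasurement:
    """Count retained pixels over all ROIs and slices and scale to mm^3.

    ``masks`` maps slice index to the per-ROI retained-component masks of
    that slice.  Pixels covered by several ROIs on the same slice are counted
    once (deduplicated union) with a warning naming the slice.
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel_volume_mm3 must be positive")
    per_roi: list[int] = []
    total = 0
    for slice_index in sorted(masks):
        slice_masks = list(masks[slice_index])
        if len(slice_masks) > MAX_ROIS_PER_SLICE:
            raise ValueError(
                f"slice {slice_index}: {len(slice_masks)} ROIs exceeds the {MAX_ROIS_PER_SLICE}-ROI limit"
            )
        if not slice_masks:
            continue
        shapes = {m.shape for m in slice_masks}
        if len(shapes) > 1:
            raise ValueError(f"slice {slice_index}: inconsistent mask shapes {shapes}")
        union = np.zeros(slice_masks[0].shape, dtype=bool)
        summed = 0
        for m in slice_masks:
            m = m.astype(bool)
            per_roi.append(int(m.sum()))
            summed += int(m.sum())
            union |= m
        n_union = int(union.sum())
        if n_union < summed:
            warnings.warn(
                f"slice {slice_index}: ROIs overlap; {summed - n_union} pixels deduplicated",
                stacklevel=2,
            )
        total += n_union
    return VolumeMeasurement(
        animal_id=animal_id,
        week=week,
        method=method,
        total_pixels=total,
        voxel_volume_mm3=voxel_volume_mm3,
        per_roi_pixels=per_roi,
    )


def auto_rois(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    lower_threshold: float,
    upper_threshold: float,
    pad: int = 2,
) -> list[ROISpec]:
    """Derive one ROI per tumor-containing slice from a reference mask.

    Test/pipeline helper standing in for interactive ROI placement: the box
    is the padded bounding box of the reference tumor pixels on each slice,
    and the supplied threshold band (derived from tissue statistics) applies
    to all slices.
    """
    if image.shape != tumor_mask.shape:
        raise ValueError("image and tumor_mask shapes differ")
    rois = []
    nr, nc = image.shape[1:]
    for slice_index in range(image.shape[0]):
        rows, cols = np.nonzero(tumor_mask[slice_index])
        if rows.size == 0:
            continue
        rois.append(
            ROISpec(
                slice_index=slice_index,
                row0=max(0, int(rows.min()) - pad),
                col0=max(0, int(cols.min()) - pad),
                row1=min(nr, int(rows.max()) + 1 + pad),
                col1=min(nc, int(cols.max()) + 1 + pad),
                lower_threshold=lower_threshold,
                upper_threshold=upper_threshold,
            )
        )
    return rois
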