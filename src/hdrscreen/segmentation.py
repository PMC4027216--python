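"""Nucleus detection from the DAPI channel and cytoplasmic-ring construction.

The screen's per-cell readouts all hang off the DAPI segmentation: nuclei are
found by a histogram threshold, touching nuclei are split by a
distance-transform watershed, and regions outside the configured size band or
touching the image border are discarded.  Around every retained nucleus an
annular "cytoplasmic ring" is drawn (a small gap, then a fixed-width band)
as the cytoplasm proxy for the nuclear/cytoplasmic translocation ratio.

Perimeters are estimated with the Crofton (smooth-contour) formula rather
than by counting boundary pixels: naive boundary counts inflate a digitized
disk's perimeter by >10%, which would distort the meaning of the 1.48
form-factor cutoff applied downstream.

Coordinates are 0-based row-major ``(row, column)``; label 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops_table
from skimage.segmentation import clear_border, expand_labels, relabel_sequential, watershed

__all__ = ["NucleusLabelMap", "RingMap", "segment_nuclei", "make_rings", "measure_geometry"]

#: floor for the Crofton perimeter so 1-pixel regions cannot divide by zero
_PERIMETER_FLOOR = 1e-3

_GEOMETRY_COLUMNS = [
    "label", "area", "perimeter", "centroid_r", "centroid_c",
    "bbox_min_r", "bbox_min_c", "bbox_max_r", "bbox_max_c",
]


@dataclass
class NucleusLabelMap:
    """Integer label image plus a per-label geometry table."""

    labels: np.ndarray
    regions: pd.DataFrame

    @property
    def n_nuclei(self) -> int:
        return len(self.regions)


@dataclass
class RingMap:
    """Per-nucleus cytoplasmic-ring labels (same ids as the nucleus map)."""

    rings: np.ndarray
    inner_gap: int
    ring_width: int
    ring_failed: set = field(default_factory=set)


def measure_geometry(labels: np.ndarray) -> pd.DataFrame:
    """Area, Crofton perimeter, centroid and bounding box per label.

    Area is the exact pixel count; the perimeter is floored at a small
    positive value so degenerate single-pixel regions stay finite downstream.
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        return pd.DataFrame(columns=_GEOMETRY_COLUMNS)
    props = regionprops_table(
        labels, properties=("label", "area", "perimeter_crofton", "centroid", "bbox")
    )
    df = pd.DataFrame(props).rename(columns={
        "perimeter_crofton": "perimeter",
        "centroid-0": "centroid_r", "centroid-1": "centroid_c",
        "bbox-0": "bbox_min_r", "bbox-1": "bbox_min_c",
        "bbox-2": "bbox_max_r", "bbox-3": "bbox_max_c",
    })
    df["area"] = df["area"].astype(float)
    df["perimeter"] = np.maximum(df["perimeter"].astype(float), _PERIMETER_FLOOR)
    return df[_GEOMETRY_COLUMNS]


def _empty_map(shape) -> NucleusLabelMap:
    return NucleusLabelMap(
        labels=np.zeros(shape, dtype=np.int32),
        regions=pd.DataFrame(columns=_GEOMETRY_COLUMNS),
    )


def segment_nuclei(
    dapi: np.ndarray,
    min_area: float = 80,
    max_area: float = 2000,
    min_distance: int = 8,
    smoothing_sigma: float = 1.0,
    distance_sigma: float = 2.0,
) -> NucleusLabelMap:
    """Detect nuclei in a DAPI image with size limits and border exclusion.

    Pipeline: Gaussian pre-smoothing, automatic Otsu threshold (histogram
    based, hence invariant to a constant additive offset), hole filling,
    distance-transform watershed to split touching nuclei, removal of
    border-touching regions and of regions outside ``[min_area, max_area]``.

    A blank (constant) image yields an empty label map, not an exception.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("DAPI image must be 2-D")
    if np.any(dapi < 0):
        raise ValueError("DAPI image must be non-negative")
    if min_area <= 0 or max_area < min_area:
        raise ValueError("need 0 < min_area <= max_area")

    img = ndi.gaussian_filter(dapi, smoothing_sigma) if smoothing_sigma > 0 else dapi
    if np.ptp(img) == 0:
        return _empty_map(dapi.shape)

    from skimage.filters import threshold_otsu

    mask = img > threshold_otsu(img)
    if not mask.any():
        return _empty_map(dapi.shape)
    mask = ndi.binary_fill_holes(mask)

    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, distance_sigma)
    peaks = peak_local_max(dist_s, min_distance=min_distance, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist_s, markers, mask=mask).astype(np.int32)

    labels = clear_border(labels)
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)
    return NucleusLabelMap(labels=labels, regions=measure_geometry(labels))


def make_rings(labels, inner_gap: int = 1, ring_width: int = 4) -> RingMap:
    """Cytoplasmic ring per nucleus: dilate by ``inner_gap + ring_width``,
    subtract the ``inner_gap`` dilation and every nucleus pixel.

    Pixels reachable from two nuclei are assigned to the nearer one
    (``expand_labels`` semantics).  A nucleus whose ring came out empty
    (fully crowded in by neighbours) is recorded in ``ring_failed`` so the
    caller can exclude it instead of dividing by a missing cytoplasm.
    """
    if isinstance(labels, NucleusLabelMap):
        labels = labels.labels
    labels = np.asarray(labels)
    if inner_gap < 0 or ring_width < 1:
        raise ValueError("need inner_gap >= 0 and ring_width >= 1")

    inner = expand_labels(labels, distance=inner_gap) if inner_gap > 0 else labels
    outer = expand_labels(labels, distance=inner_gap + ring_width)
    rings = np.where((inner == 0) & (labels == 0), outer, 0).astype(np.int32)

    present = set(np.unique(labels)) - {0}
    with_ring = set(np.unique(rings)) - {0}
    return RingMap(rings=rings, inner_gap=inner_gap, ring_width=ring_width,
                   ring_failed=present - with_ring)
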