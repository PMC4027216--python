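"""Per-cell features and the four-step selection cascade.

The screen keeps, per detected nucleus, exactly the features its published
thresholds act on:

* ``nc_ratio`` — mean nuclear mCherry over mean cytoplasmic-ring mCherry;
  cells with a ratio **higher than 1.05** are considered translocation
  responders (the endonuclease entered the nucleus).
* ``form_factor`` — perimeter^2 / (4*pi*area); 1 for a perfect circle,
  larger for irregular shapes.  Cells are kept while the value is strictly
  **below 1.48**.
* ``nuc_cv`` — coefficient of variation of the DAPI pixel intensities over
  the nuclear region (population SD / mean).  Cells **above 0.19** are
  excluded as condensed apoptotic nuclei.  Exactly 0.19 is kept.
* ``gfp_nuc_mean`` — nuclear GFP, thresholded into the per-cell HDR call.

Boundary strictness follows the published wording literally; each boundary
is locked in by tests.  The cascade order (translocation, then form factor,
then CV) only affects which rejection class a doomed cell is attributed to,
never the final selected set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import NucleusLabelMap, RingMap, make_rings, segment_nuclei

__all__ = [
    "Thresholds", "VERDICTS", "form_factor", "nuclear_cv", "nc_ratio",
    "classify_cell", "classify_cells", "gfp_threshold", "gfp_call",
    "measure_field",
]

VERDICTS = (
    "selected", "rejected_translocation", "rejected_form", "rejected_cv",
    "rejected_ring",
)


@dataclass(frozen=True)
class Thresholds:
    """Selection-cascade cutoffs; defaults are the published screen values."""

    nc_ratio_min: float = 1.05
    form_factor_max: float = 1.48
    cv_max: float = 0.19

    def __post_init__(self) -> None:
        if min(self.nc_ratio_min, self.form_factor_max, self.cv_max) <= 0:
            raise ValueError("thresholds must be strictly positive")


def form_factor(perimeter: float, area: float) -> float:
    """perimeter^2 / (4*pi*area); dimensionless, 1 for a perfect circle."""
    if area <= 0:
        raise ValueError(f"degenerate region: area={area} must be positive")
    if perimeter <= 0:
        raise ValueError(f"degenerate region: perimeter={perimeter} must be positive")
    return perimeter**2 / (4.0 * math.pi * area)


def nuclear_cv(intensities) -> float:
    """Population SD over mean of the nuclear pixel intensities."""
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("nuclear CV needs at least 2 pixels")
    mean = x.mean()
    if mean <= 0:
        raise ValueError(
            "nonpositive nuclear mean (background subtraction removed the signal)"
        )
    return float(x.std(ddof=0) / mean)


def nc_ratio(mcherry_nuc_mean: float, mcherry_ring_mean: float) -> float:
    """Nuclear-to-cytoplasmic mCherry ratio; requires a positive ring mean."""
    if mcherry_ring_mean <= 0:
        raise ValueError("ring mean must be positive for the N/C ratio")
    return mcherry_nuc_mean / mcherry_ring_mean


def classify_cell(record, thresholds: Thresholds = Thresholds()) -> str:
    """Apply the selection cascade to one cell record.

    ``record`` needs attributes/keys ``nc_ratio``, ``form_factor`` and
    ``nuc_cv``; a missing (None/NaN) ``nc_ratio`` marks an unusable ring.
    Order: translocation gate first, then form factor, then CV.
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    r, ff, cv = get("nc_ratio"), get("form_factor"), get("nuc_cv")
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return "rejected_ring"
    if not r > thresholds.nc_ratio_min:
        return "rejected_translocation"
    if not ff < thresholds.form_factor_max:
        return "rejected_form"
    if cv > thresholds.cv_max:
        return "rejected_cv"
    return "selected"


def classify_cells(cells: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.Series:
    """Vectorised cascade over a cells table; returns the verdict column."""
    r = cells["nc_ratio"].to_numpy(dtype=float)
    ff = cells["form_factor"].to_numpy(dtype=float)
    cv = cells["nuc_cv"].to_numpy(dtype=float)
    verdict = np.full(len(cells), "selected", dtype=object)
    verdict[cv > thresholds.cv_max] = "rejected_cv"
    verdict[~(ff < thresholds.form_factor_max)] = "rejected_form"
    verdict[~(r > thresholds.nc_ratio_min)] = "rejected_translocation"
    verdict[np.isnan(r)] = "rejected_ring"
    return pd.Series(verdict, index=cells.index, name="verdict")


def gfp_threshold(control_values, k: float = 3.0) -> float:
    """Robust GFP-positivity cutoff from a no-break control population.

    median + k * 1.4826 * MAD of the controls' nuclear GFP means; 1.4826
    scales the MAD to an SD under normality.
    """
    x = np.asarray(control_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError(
            "empty GFP calibration population: supply an explicit fixed threshold"
        )
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return float(med + k * 1.4826 * mad)


def gfp_call(gfp_nuc_means, control_values=None, k: float = 3.0,
             fixed: float | None = None) -> np.ndarray:
    """Per-cell HDR call: nuclear GFP strictly above the threshold.

    Either ``fixed`` is given, or the threshold is calibrated from
    ``control_values`` via :func:`gfp_threshold`.
    """
    thr = fixed if fixed is not None else gfp_threshold(control_values, k=k)
    return np.asarray(gfp_nuc_means, dtype=float) > thr


def _field_background(channel: np.ndarray, labels: np.ndarray, rings: np.ndarray) -> float:
    free = (labels == 0) & (rings == 0)
    if not free.any():
        return 0.0
    return float(np.median(channel[free]))


def measure_field(
    dapi: np.ndarray,
    mcherry: np.ndarray,
    gfp: np.ndarray,
    thresholds: Thresholds = Thresholds(),
    min_area: float = 80,
    max_area: float = 2000,
    min_distance: int = 8,
    smoothing_sigma: float = 1.0,
    inner_gap: int = 1,
    ring_width: int = 4,
    label_map: NucleusLabelMap | None = None,
) -> pd.DataFrame:
    """Segment one field and compute the full per-cell feature table.

    Per-field background (median of pixels outside every nucleus and ring)
    is subtracted from each channel's region means before ratios, so the
    N/C ratio is comparable across fields with different baselines.  The
    returned table has one row per retained nucleus with its features and
    cascade verdict; GFP positivity is *not* called here because the robust
    threshold needs plate-level control cells (see :func:`gfp_call`).
    """
    if label_map is None:
        label_map = segment_nuclei(dapi, min_area=min_area, max_area=max_area,
                                   min_distance=min_distance,
                                   smoothing_sigma=smoothing_sigma)
    labels = label_map.labels
    regions = label_map.regions
    ring_map: RingMap = make_rings(labels, inner_gap=inner_gap, ring_width=ring_width)
    rings = ring_map.rings

    if regions.empty:
        return pd.DataFrame(columns=[
            "label", "area", "perimeter", "centroid_r", "centroid_c",
            "form_factor", "nuc_cv", "mcherry_nuc_mean", "mcherry_ring_mean",
            "nc_ratio", "gfp_nuc_mean", "ring_failed", "verdict",
        ])

    ids = regions["label"].to_numpy()
    bg = {
        "dapi": _field_background(np.asarray(dapi, float), labels, rings),
        "mcherry": _field_background(np.asarray(mcherry, float), labels, rings),
        "gfp": _field_background(np.asarray(gfp, float), labels, rings),
    }

    dapi_bs = np.asarray(dapi, float) - bg["dapi"]
    nuc_mean_dapi = ndi.mean(dapi_bs, labels, ids)
    nuc_sd_dapi = ndi.standard_deviation(dapi_bs, labels, ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(nuc_mean_dapi > 0, nuc_sd_dapi / nuc_mean_dapi, np.inf)

    mch = np.asarray(mcherry, float) - bg["mcherry"]
    mch_nuc = ndi.mean(mch, labels, ids)
    has_ring = ~np.isin(ids, list(ring_map.ring_failed))
    mch_ring = np.full(ids.shape, np.nan)
    if has_ring.any():
        mch_ring[has_ring] = ndi.mean(mch, rings, ids[has_ring])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mch_ring > 0, mch_nuc / mch_ring, np.nan)

    gfp_nuc = ndi.mean(np.asarray(gfp, float) - bg["gfp"], labels, ids)

    cells = regions[["label", "area", "perimeter", "centroid_r", "centroid_c"]].copy()
    cells["form_factor"] = [form_factor(p, a) for p, a in
                            zip(cells["perimeter"], cells["area"])]
    cells["nuc_cv"] = cv
    cells["mcherry_nuc_mean"] = mch_nuc
    cells["mcherry_ring_mean"] = mch_ring
    cells["nc_ratio"] = ratio
    cells["gfp_nuc_mean"] = gfp_nuc
    cells["ring_failed"] = ~has_ring
    cells["verdict"] = classify_cells(cells, thresholds)
    return cells
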