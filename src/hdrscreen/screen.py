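"""Well aggregation, control-based plate normalization and 4-SD hit calling.

Per well, the HDR frequency is the fraction of translocation-selected cells
scored GFP-positive.  Each plate is normalized to the mean HDR frequency of
its own vehicle (DMSO) control wells (100 = control level), which removes
plate-to-plate efficiency differences.  Compound wells are averaged across
replicate plates, and a compound is called an activator (repressor) when its
mean normalized value lies strictly more than ``k = 4`` standard deviations
above (below) the DMSO mean; a 3-SD "near-hit" band is reported alongside.

By default the SD is taken over the individual normalized DMSO well values
pooled across all plates of the run; ``dmso_values(..., mode="dots")``
instead averages each control well position over its replicate plates first,
mirroring a per-dot reading of the screen's scatter plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "QCError", "ScreenResult", "well_hdr_frequency", "wells_from_counts",
    "summarize_wells", "normalize_plate", "average_replicates",
    "dmso_values", "call_hits", "edge_effect_qc",
]


class QCError(RuntimeError):
    """A plate failed a quality-control precondition."""


_WELL_COLUMNS = [
    "plate_id", "well_id", "role", "compound_id", "concentration_uM",
    "n_detected", "n_selected", "n_gfp_positive", "hdr_frequency", "low_count",
]


def well_hdr_frequency(n_detected: int, n_selected: int, n_gfp_positive: int,
                       min_cells: int = 50) -> dict:
    """Counts -> HDR frequency for one well, with the low-count flag.

    ``hdr_frequency = n_gfp_positive / n_selected``; wells with fewer than
    ``min_cells`` selected cells are flagged ``low_count`` (frequency NaN
    when nothing was selected) and excluded from control statistics.
    """
    if not 0 <= n_gfp_positive <= n_selected <= n_detected:
        raise ValueError("need 0 <= n_gfp_positive <= n_selected <= n_detected")
    freq = n_gfp_positive / n_selected if n_selected > 0 else float("nan")
    return dict(n_detected=n_detected, n_selected=n_selected,
                n_gfp_positive=n_gfp_positive, hdr_frequency=freq,
                low_count=n_selected < min_cells)


def wells_from_counts(counts: pd.DataFrame, min_cells: int = 50) -> pd.DataFrame:
    """Apply :func:`well_hdr_frequency` to a per-well counts table."""
    out = counts.copy()
    n_sel = out["n_selected"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["hdr_frequency"] = np.where(
            n_sel > 0, out["n_gfp_positive"] / n_sel, np.nan)
    out["low_count"] = out["n_selected"] < min_cells
    return out


def summarize_wells(cells: pd.DataFrame, layout: pd.DataFrame,
                    min_cells: int = 50) -> pd.DataFrame:
    """Aggregate a per-cell table (verdict + gfp_positive) to wells.

    Every well in the layout appears exactly once, with zero counts for
    wells that produced no cells.
    """
    rows = []
    for lay in layout.itertuples(index=False):
        sub = cells[cells["well_id"] == lay.well_id]
        sel = sub[sub["verdict"] == "selected"]
        counts = well_hdr_frequency(
            len(sub), len(sel), int(sel["gfp_positive"].sum()), min_cells)
        rows.append(dict(
            plate_id=sub["plate_id"].iloc[0] if len(sub) else "",
            well_id=lay.well_id, role=lay.role, compound_id=lay.compound_id,
            concentration_uM=lay.concentration_uM, **counts))
    return pd.DataFrame(rows, columns=_WELL_COLUMNS)


def normalize_plate(wells: pd.DataFrame, min_controls: int = 2) -> pd.DataFrame:
    """Add ``normalized_hdr`` = 100 x hdr / mean(vehicle-control hdr).

    ``wells`` must be a single plate; a plate with fewer than
    ``min_controls`` usable (unflagged, finite) vehicle wells is rejected.
    """
    if wells["plate_id"].nunique() > 1:
        raise ValueError("normalize_plate expects wells of a single plate")
    ctrl = wells[(wells["role"] == "vehicle_control") & ~wells["low_count"]]
    ctrl = ctrl[np.isfinite(ctrl["hdr_frequency"])]
    if len(ctrl) < min_controls:
        raise QCError(
            f"plate {wells['plate_id'].iloc[0]!r}: only {len(ctrl)} usable "
            f"vehicle-control wells (need >= {min_controls})")
    mean = ctrl["hdr_frequency"].mean()
    if mean <= 0:
        raise QCError("vehicle-control mean HDR frequency is not positive")
    out = wells.copy()
    out["normalized_hdr"] = 100.0 * out["hdr_frequency"] / mean
    return out


def average_replicates(wells: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Per-compound mean/SD of ``normalized_hdr`` across replicate wells.

    Only ``role == "compound"`` wells that are not low-count contribute;
    compounds with fewer than ``min_replicates`` usable wells are flagged
    ``under_replicated`` (their mean is still reported).
    """
    ok = wells[(wells["role"] == "compound") & ~wells["low_count"]]
    ok = ok[np.isfinite(ok["normalized_hdr"])]
    grp = ok.groupby("compound_id", sort=True)["normalized_hdr"]
    out = grp.agg(mean_normalized_hdr="mean", sd_normalized_hdr="std",
                  n_replicates="size").reset_index()
    out["under_replicated"] = out["n_replicates"] < min_replicates
    return out


def dmso_values(wells: pd.DataFrame, mode: str = "pooled") -> np.ndarray:
    """Normalized vehicle-control values used for the hit-calling SD.

    ``mode="pooled"`` (default): every usable DMSO well of every plate.
    ``mode="dots"``: each control well position averaged over its replicate
    plates first (one value per position, like one scatter dot per control).
    """
    ctrl = wells[(wells["role"] == "vehicle_control") & ~wells["low_count"]]
    ctrl = ctrl[np.isfinite(ctrl["normalized_hdr"])]
    if mode == "pooled":
        return ctrl["normalized_hdr"].to_numpy(dtype=float)
    if mode == "dots":
        return ctrl.groupby("well_id")["normalized_hdr"].mean().to_numpy(dtype=float)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ScreenResult:
    """Hit table plus the control statistics it was called against."""

    compounds: pd.DataFrame
    dmso_mean: float
    dmso_sd: float
    n_dmso: int
    k: float

    @property
    def hits(self) -> pd.DataFrame:
        return self.compounds[self.compounds["hit_class"] != "none"]


def call_hits(compounds: pd.DataFrame, dmso: np.ndarray, k: float = 4.0,
              near_k: float = 3.0) -> ScreenResult:
    """Classify compounds against the DMSO distribution at the k-SD rule.

    ``z = (mean_normalized_hdr - mean(dmso)) / sd(dmso)``; activator iff
    ``z > k``, repressor iff ``z < -k`` (strict — a compound exactly at
    k SD is not a hit), and a ``near_hit`` column marks the 3-SD band.
    """
    dmso = np.asarray(dmso, dtype=float)
    if dmso.size < 2:
        raise ValueError("need at least 2 DMSO values for hit calling")
    mean = float(dmso.mean())
    sd = float(dmso.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate controls: DMSO SD is zero")
    out = compounds.copy()
    out["z"] = (out["mean_normalized_hdr"] - mean) / sd
    z = out["z"].to_numpy(dtype=float)
    out["hit_class"] = np.select([z > k, z < -k], ["activator", "repressor"],
                                 default="none")
    out["near_hit"] = np.select([z > near_k, z < -near_k], ["up", "down"],
                                default="none")
    return ScreenResult(compounds=out, dmso_mean=mean, dmso_sd=sd,
                        n_dmso=int(dmso.size), k=float(k))


def _is_edge(well_id: str) -> bool:
    row, col = well_id[0], int(well_id[1:])
    return row in ("A", "H") or col in (1, 12)


def edge_effect_qc(wells: pd.DataFrame, alpha: float = 0.01,
                   value: str = "normalized_hdr") -> dict:
    """Rank-based check for plate edge effects on control wells.

    Compares edge vs interior vehicle-control values with a two-sided
    Mann-Whitney U test; the plate is flagged when ``p < alpha``.  With no
    interior (or no edge) controls the check is skipped with a warning.
    """
    ctrl = wells[(wells["role"] == "vehicle_control") & ~wells["low_count"]]
    ctrl = ctrl[np.isfinite(ctrl[value])]
    edge = ctrl[ctrl["well_id"].map(_is_edge)][value].to_numpy()
    interior = ctrl[~ctrl["well_id"].map(_is_edge)][value].to_numpy()
    if edge.size == 0 or interior.size == 0:
        warnings.warn("edge-effect QC skipped: need edge and interior "
                      "control wells", stacklevel=2)
        return dict(flagged=None, p_value=float("nan"),
                    n_edge=int(edge.size), n_interior=int(interior.size))
    stat, p = mannwhitneyu(edge, interior, alternative="two-sided")
    return dict(flagged=bool(p < alpha), p_value=float(p),
                n_edge=int(edge.size), n_interior=int(interior.size))
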