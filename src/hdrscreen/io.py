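"""Manifest/table IO and the end-to-end screen runner.

`run_screen` chains the whole analysis: load each field's three channel
TIFFs, segment nuclei and build rings, measure the per-cell features and
apply the selection cascade, calibrate the GFP threshold per plate, score
wells, normalize to in-plate vehicle controls, average replicate plates and
call hits.  All tables are written atomically (temp file + rename) under the
configured output directory; input files are never touched.

A field with a missing or unreadable channel file is skipped with a logged
warning; an imaged well that has no layout row is a hard error.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import screen as scr
from .config import RunConfig
from .features import gfp_threshold, measure_field

__all__ = ["read_manifest", "read_layout", "write_table", "run_screen"]

log = logging.getLogger("hdrscreen")

_MANIFEST_COLUMNS = ["plate", "well", "field", "channel", "path"]
_LAYOUT_COLUMNS = ["well_id", "role", "compound_id", "concentration_uM"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_manifest(path) -> pd.DataFrame:
    """Read and validate an image manifest CSV.

    Columns: plate, well, field, channel, path (extras preserved).
    Duplicate (plate, well, field, channel) rows are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, _MANIFEST_COLUMNS, path)
    dup = df.duplicated(subset=["plate", "well", "field", "channel"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate manifest entry for plate={row['plate']} "
            f"well={row['well']} field={row['field']} channel={row['channel']}")
    return df


def read_layout(path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV (well_id, role, compound_id,
    concentration_uM; extras preserved)."""
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"well_id": str, "role": str, "compound_id": str})
    _require_columns(df, _LAYOUT_COLUMNS, path)
    df["concentration_uM"] = pd.to_numeric(df["concentration_uM"])
    dup = df.duplicated(subset=["well_id"])
    if dup.any():
        raise ValueError(f"{path}: duplicate layout row for well "
                         f"{df[dup]['well_id'].iloc[0]!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Atomic CSV write: temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _load_field(image_dir: Path, group: pd.DataFrame) -> dict | None:
    """Load the three channels of one field, or None if any is unusable."""
    channels = {}
    for row in group.itertuples(index=False):
        fp = image_dir / row.path
        try:
            channels[row.channel] = np.asarray(tifffile.imread(fp), dtype=float)
        except (FileNotFoundError, OSError, ValueError) as exc:
            log.warning("skipping field %s/%s/f%s: cannot read %s (%s)",
                        row.plate, row.well, row.field, fp.name, exc)
            return None
    missing = set(("DAPI", "mCherry", "GFP")) - set(channels)
    if missing:
        row = group.iloc[0]
        log.warning("skipping field %s/%s/f%s: missing channel(s) %s",
                    row["plate"], row["well"], row["field"], sorted(missing))
        return None
    return channels


def _analyze_plate_cells(plate_id: str, manifest: pd.DataFrame,
                         layout: pd.DataFrame, image_dir: Path,
                         cfg: RunConfig) -> tuple[pd.DataFrame, int]:
    """Per-cell table for one plate; returns (cells, n_skipped_fields)."""
    seg = cfg.segmentation
    known_wells = set(layout["well_id"])
    parts = []
    skipped = 0
    for (well, field_idx), group in manifest.groupby(["well", "field"], sort=True):
        if well not in known_wells:
            raise ValueError(f"imaged well {well!r} of plate {plate_id!r} "
                             f"has no layout row")
        channels = _load_field(image_dir, group)
        if channels is None:
            skipped += 1
            continue
        cells = measure_field(
            channels["DAPI"], channels["mCherry"], channels["GFP"],
            thresholds=cfg.thresholds, min_area=seg.min_area,
            max_area=seg.max_area, min_distance=seg.min_distance,
            smoothing_sigma=seg.smoothing_sigma, inner_gap=seg.inner_gap,
            ring_width=seg.ring_width)
        cells.insert(0, "plate_id", plate_id)
        cells.insert(1, "well_id", well)
        cells.insert(2, "field", field_idx)
        parts.append(cells)
    cells = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["plate_id", "well_id", "field", "label", "verdict",
                 "gfp_nuc_mean"])
    return cells, skipped


def _call_plate_gfp(cells: pd.DataFrame, layout: pd.DataFrame,
                    cfg: RunConfig) -> pd.DataFrame:
    """Set per-cell gfp_positive using the configured rule (per plate)."""
    rule = cfg.gfp_rule
    if rule.method == "fixed":
        thr = rule.fixed
    else:
        calib_wells = set(
            layout[layout["role"].isin(rule.calibration_roles)]["well_id"])
        calib = cells[(cells["well_id"].isin(calib_wells))
                      & (cells["verdict"] == "selected")]
        thr = gfp_threshold(calib["gfp_nuc_mean"], k=rule.k)
    out = cells.copy()
    out["gfp_positive"] = (out["gfp_nuc_mean"] > thr) \
        & (out["verdict"] == "selected")
    out.attrs["gfp_threshold"] = float(thr)
    return out


def run_screen(cfg: RunConfig) -> scr.ScreenResult:
    """Execute the full pipeline described by ``cfg`` and write artifacts.

    Writes cells.csv, wells.csv, compounds.csv, qc.csv and the resolved
    config (run_config.yaml) under ``cfg.output_dir``, logging per-stage
    counts, and returns the :class:`~hdrscreen.screen.ScreenResult`.
    """
    image_dir = Path(cfg.image_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(cfg.manifest_path)
    layout = read_layout(cfg.layout_path)

    all_cells, all_wells, qc_rows = [], [], []
    for plate_id, plate_manifest in manifest.groupby("plate", sort=True):
        cells, skipped = _analyze_plate_cells(
            str(plate_id), plate_manifest, layout, image_dir, cfg)
        cells = _call_plate_gfp(cells, layout, cfg)
        wells = scr.summarize_wells(cells, layout, min_cells=cfg.min_cells)
        wells["plate_id"] = str(plate_id)
        wells = scr.normalize_plate(wells)
        qc = scr.edge_effect_qc(wells, alpha=cfg.edge_alpha)
        qc_rows.append(dict(plate_id=str(plate_id), skipped_fields=skipped,
                            gfp_threshold=cells.attrs.get("gfp_threshold"),
                            **qc))
        rej = cells["verdict"].value_counts().to_dict()
        log.info("plate %s: %d cells detected, %d selected, %d GFP+, "
                 "rejections=%s, %d fields skipped", plate_id, len(cells),
                 int(wells["n_selected"].sum()),
                 int(wells["n_gfp_positive"].sum()),
                 {k: v for k, v in rej.items() if k != "selected"}, skipped)
        all_cells.append(cells)
        all_wells.append(wells)

    cells = pd.concat(all_cells, ignore_index=True)
    wells = pd.concat(all_wells, ignore_index=True)
    compounds = scr.average_replicates(wells, min_replicates=cfg.min_replicates)
    dmso = scr.dmso_values(wells, mode=cfg.dmso_sd_mode)
    result = scr.call_hits(compounds, dmso, k=cfg.k_sd)

    write_table(cells, outdir / "cells.csv")
    write_table(wells, outdir / "wells.csv")
    write_table(result.compounds, outdir / "compounds.csv")
    write_table(pd.DataFrame(qc_rows), outdir / "qc.csv")
    cfg.to_yaml(outdir / "run_config.yaml")
    log.info("screen: %d compounds, DMSO %.2f +/- %.2f (n=%d), %d hits",
             len(result.compounds), result.dmso_mean, result.dmso_sd,
             result.n_dmso, len(result.hits))
    return result
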