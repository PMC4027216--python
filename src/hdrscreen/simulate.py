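"""Synthetic three-channel plate images with per-cell ground truth.

The generator emulates the statistical structure the screen analysis
assumes, at the scale of a 96-well plate imaged in multiple fields per well:

* **DAPI** — elliptical nuclei.  Healthy nuclei have mean radius 8-14 px and
  mild chromatin texture; apoptotic nuclei are condensed (radius 4-6 px),
  brighter, with 3x the texture SD so their intra-nuclear intensity CV falls
  above the 0.19 exclusion cutoff.  Dead cells are rendered as irregular
  low-DAPI debris with broadband signal in every channel.
* **mCherry** — a cytoplasm ellipse around every nucleus; translocated cells
  have a nuclear mean above the cytoplasmic level, resident cells the
  reverse, so the 1.05 nuclear/ring ratio gate separates them.
* **GFP** — nuclear signal only in cells that are both translocated and
  drawn HDR-positive with the well's ``true_hdr_fraction`` (no repair event
  without nuclear endonuclease).

Noise is Gaussian read noise plus an intensity-proportional (shot-like)
term, applied last; rendering is float internally with 16-bit unsigned
output on disk.  All randomness flows from a single plate seed; per-well and
per-field seeds are derived by a stable CRC32 hash so partial regeneration
is reproducible.

Besides images, the module generates plate layouts, per-cell/per-well ground
truth (the test oracle), a count-level screen simulator for statistics at
scales where rendering every field would be pointless, and noisy 4PL
titration tables for the dose-response fitter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse

from .dose_response import FourPL

__all__ = [
    "CHANNELS", "WELL_IDS", "ROLES", "CellSpec", "WellSpec", "NoiseModel",
    "PlateSpec", "FieldImage", "PlateData", "derive_seed", "generate_field",
    "generate_plate", "write_plate", "simulate_well_counts",
    "build_screen_plates", "generate_dose_response",
]

CHANNELS = ("DAPI", "mCherry", "GFP")
ROWS = "ABCDEFGH"
WELL_IDS = tuple(f"{r}{c}" for r in ROWS for c in range(1, 13))
ROLES = ("compound", "vehicle_control", "up_control", "down_control", "mock_no_break")
PHENOTYPES = ("healthy", "apoptotic", "dead")


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary parts (CRC32, < 2^31)."""
    key = ":".join(str(p) for p in parts).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth draw for one simulated cell."""

    center: tuple[float, float]
    radii: tuple[float, float]  # (major, minor), pixels
    orientation: float  # radians
    phenotype: str
    translocated: bool
    gfp_positive: bool
    dapi_level: float
    mcherry_nuc_level: float
    mcherry_cyto_level: float
    gfp_nuc_level: float

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.gfp_positive and not self.translocated:
            raise ValueError("gfp_positive requires translocated (no break "
                             "without nuclear endonuclease)")


@dataclass(frozen=True)
class WellSpec:
    """Condition of one well: role, compound, and true per-cell rates."""

    well_id: str
    role: str = "compound"
    compound_id: str = ""
    concentration_uM: float = 0.0
    true_hdr_fraction: float = 0.03
    n_cells: int = 60
    translocation_fraction: float = 0.8
    apoptotic_fraction: float = 0.05
    dead_fraction: float = 0.03

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for well {self.well_id}")
        for name in ("true_hdr_fraction", "translocation_fraction",
                     "apoptotic_fraction", "dead_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] in well {self.well_id}")
        if self.apoptotic_fraction + self.dead_fraction > 1.0:
            raise ValueError("phenotype fractions exceed 1")


@dataclass(frozen=True)
class NoiseModel:
    """Additive background, Gaussian read noise and shot-like noise."""

    background: Mapping[str, float] = dc_field(
        default_factory=lambda: {"DAPI": 100.0, "mCherry": 120.0, "GFP": 90.0}
    )
    read_noise_sd: float = 40.0
    shot_scale: float = 2.0


@dataclass(frozen=True)
class PlateSpec:
    plate_id: str
    wells: tuple[WellSpec, ...]
    fields_per_well: int = 12
    image_shape: tuple[int, int] = (512, 512)
    noise: NoiseModel = dc_field(default_factory=NoiseModel)
    rng_seed: int = 0
    overlap_fraction: float = 0.0  # allowed fractional overlap of radii

    def __post_init__(self) -> None:
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        seen = set()
        for w in self.wells:
            if w.well_id in seen:
                raise ValueError(f"duplicate well_id {w.well_id!r} in plate "
                                 f"{self.plate_id!r}")
            seen.add(w.well_id)


@dataclass
class FieldImage:
    """One imaging field: three co-registered channels plus pixel size."""

    dapi: np.ndarray
    mcherry: np.ndarray
    gfp: np.ndarray
    pixel_size_um: float = 0.65

    def channels(self) -> dict[str, np.ndarray]:
        return {"DAPI": self.dapi, "mCherry": self.mcherry, "GFP": self.gfp}

    def to_uint16(self) -> dict[str, np.ndarray]:
        return {name: np.clip(np.round(img), 0, 65535).astype(np.uint16)
                for name, img in self.channels().items()}


# rendering defaults (arbitrary intensity units, chosen so that the printed
# thresholds are exercised from both sides at default noise)
_RENDER = dict(
    dapi_level=3000.0, dapi_level_sd=300.0,
    apoptotic_gain=1.6,
    healthy_texture=0.06, apoptotic_texture=0.24,  # 4x the healthy SD
    mcherry_cyto_range=(800.0, 1200.0),
    nc_gain_translocated=(1.4, 2.2),
    nc_gain_resident=(0.4, 0.8),
    gfp_level=1500.0, gfp_level_sd=150.0,
    cyto_scale=2.2,
    healthy_radius=(8.0, 14.0), apoptotic_radius=(4.0, 6.0),
    axis_ratio_max=1.6,
    edge_sigma=0.5,
    placement_margin=3.0,
)


def _draw_cell(rng: np.random.Generator, well: WellSpec) -> dict:
    u = rng.random()
    if u < well.dead_fraction:
        phenotype = "dead"
    elif u < well.dead_fraction + well.apoptotic_fraction:
        phenotype = "apoptotic"
    else:
        phenotype = "healthy"
    if phenotype == "apoptotic":
        r = rng.uniform(*_RENDER["apoptotic_radius"])
        dapi = rng.normal(_RENDER["dapi_level"] * _RENDER["apoptotic_gain"],
                          _RENDER["dapi_level_sd"])
    else:
        r = rng.uniform(*_RENDER["healthy_radius"])
        dapi = rng.normal(_RENDER["dapi_level"], _RENDER["dapi_level_sd"])
    ratio = rng.uniform(1.0, _RENDER["axis_ratio_max"])
    radii = (r * np.sqrt(ratio), r / np.sqrt(ratio))

    translocated = bool(rng.random() < well.translocation_fraction) \
        if phenotype != "dead" else False
    gfp_positive = bool(translocated and rng.random() < well.true_hdr_fraction)
    cyto = rng.uniform(*_RENDER["mcherry_cyto_range"])
    gain = rng.uniform(*(_RENDER["nc_gain_translocated"] if translocated
                         else _RENDER["nc_gain_resident"]))
    return dict(
        radii=radii,
        orientation=rng.uniform(0, np.pi),
        phenotype=phenotype,
        translocated=translocated,
        gfp_positive=gfp_positive,
        dapi_level=max(float(dapi), 500.0),
        mcherry_nuc_level=cyto * gain,
        mcherry_cyto_level=cyto,
        gfp_nuc_level=(max(float(rng.normal(_RENDER["gfp_level"],
                                            _RENDER["gfp_level_sd"])), 200.0)
                       if gfp_positive else 0.0),
    )


def _place_cells(rng, drafts, shape, overlap_fraction):
    """Rejection-sample non-overlapping centers (optionally allowing a
    fractional radius overlap); cells that cannot be placed are dropped."""
    placed: list[CellSpec] = []
    centers: list[tuple[float, float]] = []
    maxr: list[float] = []
    h, w = shape
    for d in drafts:
        rmax = d["radii"][0]
        margin = rmax + _RENDER["placement_margin"]
        if 2 * margin >= min(h, w):
            continue
        ok = False
        for _ in range(200):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            ok = True
            for (rr, cc), other_r in zip(centers, maxr):
                min_sep = (rmax + other_r + _RENDER["placement_margin"]) \
                    * (1.0 - overlap_fraction)
                if (r0 - rr) ** 2 + (c0 - cc) ** 2 < min_sep**2:
                    ok = False
                    break
            if ok:
                break
        if not ok:
            continue
        centers.append((r0, c0))
        maxr.append(rmax)
        placed.append(CellSpec(center=(r0, c0), **d))
    return placed


def _paint(img, cell, radii_scale, value, shape, rotation=None):
    rr, cc = _draw_ellipse(
        cell.center[0], cell.center[1],
        cell.radii[0] * radii_scale, cell.radii[1] * radii_scale,
        shape=shape,
        rotation=cell.orientation if rotation is None else rotation,
    )
    img[rr, cc] = value
    return rr, cc


def render_field(cells: Sequence[CellSpec], shape, noise: NoiseModel,
                 rng: np.random.Generator, apply_noise: bool = True) -> FieldImage:
    """Render a cell list into the three channels.

    Painting order: cytoplasm ellipses first, then nuclei (so a neighbour's
    cytoplasm never overwrites a nucleus), then debris for dead cells; soft
    edges by a small Gaussian blur; chromatin texture after the blur (it is
    structure, not optics); background and noise last.
    """
    dapi = np.zeros(shape)
    mch = np.zeros(shape)
    gfp = np.zeros(shape)

    live = [c for c in cells if c.phenotype != "dead"]
    for c in live:
        _paint(mch, c, _RENDER["cyto_scale"], c.mcherry_cyto_level, shape)
    nuc_px = []
    for c in live:
        rr, cc = _paint(dapi, c, 1.0, c.dapi_level, shape)
        mch[rr, cc] = c.mcherry_nuc_level
        if c.gfp_positive:
            gfp[rr, cc] = c.gfp_nuc_level
        nuc_px.append((rr, cc))
    for c in (c for c in cells if c.phenotype == "dead"):
        for _ in range(int(rng.integers(3, 7))):
            dr, dc = rng.normal(0, 5, size=2)
            frag = replace(c, center=(float(np.clip(c.center[0] + dr, 1, shape[0] - 2)),
                                      float(np.clip(c.center[1] + dc, 1, shape[1] - 2))),
                           radii=(float(rng.uniform(1.5, 3.5)),) * 2)
            lvl = rng.uniform(300, 900)
            _paint(dapi, frag, 1.0, lvl, shape)
            _paint(mch, frag, 1.0, lvl * rng.uniform(0.5, 1.2), shape)
            _paint(gfp, frag, 1.0, lvl * rng.uniform(0.3, 0.8), shape)

    sig = _RENDER["edge_sigma"]
    dapi = ndi.gaussian_filter(dapi, sig)
    mch = ndi.gaussian_filter(mch, sig)
    gfp = ndi.gaussian_filter(gfp, sig)

    for c, (rr, cc) in zip(live, nuc_px):
        tex = _RENDER["apoptotic_texture"] if c.phenotype == "apoptotic" \
            else _RENDER["healthy_texture"]
        dapi[rr, cc] *= np.clip(1.0 + tex * rng.standard_normal(rr.size), 0.0, None)

    out = []
    for name, img in (("DAPI", dapi), ("mCherry", mch), ("GFP", gfp)):
        img = img + noise.background[name]
        if apply_noise:
            img = img + rng.normal(0.0, noise.read_noise_sd, shape)
            img = img + rng.standard_normal(shape) * noise.shot_scale \
                * np.sqrt(np.clip(img, 0.0, None))
        out.append(np.clip(img, 0.0, 65535.0))
    return FieldImage(dapi=out[0], mcherry=out[1], gfp=out[2])


_TRUTH_COLUMNS = [
    "cell_index", "center_r", "center_c", "radius_major", "radius_minor",
    "orientation", "phenotype", "translocated", "gfp_positive", "dapi_level",
    "mcherry_nuc_level", "mcherry_cyto_level", "gfp_nuc_level",
]


def _truth_rows(cells: Sequence[CellSpec]) -> pd.DataFrame:
    rows = [
        dict(cell_index=i, center_r=c.center[0], center_c=c.center[1],
             radius_major=c.radii[0], radius_minor=c.radii[1],
             orientation=c.orientation, phenotype=c.phenotype,
             translocated=c.translocated, gfp_positive=c.gfp_positive,
             dapi_level=c.dapi_level, mcherry_nuc_level=c.mcherry_nuc_level,
             mcherry_cyto_level=c.mcherry_cyto_level,
             gfp_nuc_level=c.gfp_nuc_level)
        for i, c in enumerate(cells)
    ]
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def generate_field(
    well_spec: WellSpec,
    plate_noise: NoiseModel = NoiseModel(),
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    overlap_fraction: float = 0.0,
    apply_noise: bool = True,
) -> tuple[FieldImage, pd.DataFrame]:
    """One field for one well: rendered channels plus per-cell ground truth.

    ``n_cells <= 0`` yields a valid background-only field and an empty truth
    table.  The same spec and seed always reproduce identical pixels.
    """
    rng = np.random.default_rng(seed)
    drafts = [_draw_cell(rng, well_spec) for _ in range(max(well_spec.n_cells, 0))]
    cells = _place_cells(rng, drafts, shape, overlap_fraction)
    image = render_field(cells, shape, plate_noise, rng, apply_noise=apply_noise)
    return image, _truth_rows(cells)


@dataclass
class PlateData:
    """In-memory product of :func:`generate_plate`."""

    plate_id: str
    images: dict  # (well_id, field_index) -> FieldImage
    manifest: pd.DataFrame
    layout: pd.DataFrame
    cell_truth: pd.DataFrame
    well_truth: pd.DataFrame


def generate_plate(spec: PlateSpec) -> PlateData:
    """All fields of a plate, with layout table and ground truth.

    Per-field seeds are ``derive_seed(plate_seed, well_id, field_index)``,
    so any single field can be regenerated in isolation.
    """
    images = {}
    manifest_rows = []
    truth_parts = []
    for well in spec.wells:
        for f in range(spec.fields_per_well):
            seed = derive_seed(spec.rng_seed, well.well_id, f)
            img, truth = generate_field(
                well, spec.noise, spec.image_shape, seed,
                overlap_fraction=spec.overlap_fraction,
            )
            images[(well.well_id, f)] = img
            truth.insert(0, "plate_id", spec.plate_id)
            truth.insert(1, "well_id", well.well_id)
            truth.insert(2, "field", f)
            truth_parts.append(truth)
            for channel in CHANNELS:
                manifest_rows.append(dict(
                    plate=spec.plate_id, well=well.well_id, field=f,
                    channel=channel,
                    path=f"{spec.plate_id}_{well.well_id}_f{f}_{channel}.tif",
                ))

    cell_truth = pd.concat(truth_parts, ignore_index=True) if truth_parts \
        else pd.DataFrame(columns=["plate_id", "well_id", "field"] + _TRUTH_COLUMNS)
    grp = cell_truth.groupby("well_id", sort=False)
    well_truth = pd.DataFrame({
        "well_id": [w.well_id for w in spec.wells],
        "role": [w.role for w in spec.wells],
        "true_hdr_fraction": [w.true_hdr_fraction for w in spec.wells],
    })
    counts = grp.agg(
        n_cells=("cell_index", "size"),
        n_translocated=("translocated", "sum"),
        n_gfp_positive=("gfp_positive", "sum"),
    ).reindex(well_truth["well_id"])
    counts = counts.apply(lambda s: pd.to_numeric(s, errors="coerce")) \
        .fillna(0).astype(int)
    well_truth = well_truth.join(counts.reset_index(drop=True))

    layout = pd.DataFrame({
        "well_id": [w.well_id for w in spec.wells],
        "role": [w.role for w in spec.wells],
        "compound_id": [w.compound_id for w in spec.wells],
        "concentration_uM": [w.concentration_uM for w in spec.wells],
    })
    manifest = pd.DataFrame(manifest_rows)
    return PlateData(plate_id=spec.plate_id, images=images, manifest=manifest,
                     layout=layout, cell_truth=cell_truth, well_truth=well_truth)


def write_plate(plate: PlateData, outdir) -> Path:
    """Write a plate to disk: one 16-bit grayscale TIFF per channel per
    field, plus manifest, layout and ground-truth CSVs."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row in plate.manifest.itertuples(index=False):
        img = plate.images[(row.well, row.field)]
        tifffile.imwrite(outdir / row.path, img.to_uint16()[row.channel])
    plate.manifest.to_csv(outdir / "manifest.csv", index=False)
    plate.layout.to_csv(outdir / "layout.csv", index=False)
    plate.cell_truth.to_csv(outdir / "cell_truth.csv", index=False)
    plate.well_truth.to_csv(outdir / "well_truth.csv", index=False)
    return outdir


def simulate_well_counts(wells: Sequence[WellSpec], seed: int = 0,
                         plate_id: str = "P1") -> pd.DataFrame:
    """Count-level simulation of one plate (no images).

    Draws, per well, the number of translocation-selected cells
    ``Binomial(n_cells, translocation_fraction)`` and the number of
    GFP-positive cells among them ``Binomial(n_selected, true_hdr_fraction)``
    — the same stochastic structure the rendered pipeline measures, for
    statistical experiments at scales where rendering is pointless.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for w in wells:
        n_sel = int(rng.binomial(w.n_cells, w.translocation_fraction))
        n_pos = int(rng.binomial(n_sel, w.true_hdr_fraction))
        rows.append(dict(
            plate_id=plate_id, well_id=w.well_id, role=w.role,
            compound_id=w.compound_id, concentration_uM=w.concentration_uM,
            n_detected=w.n_cells, n_selected=n_sel, n_gfp_positive=n_pos,
            true_hdr_fraction=w.true_hdr_fraction,
        ))
    return pd.DataFrame(rows)


#: control columns of the default screen layout: 10 vehicle (DMSO) wells,
#: 2 up-shifting and 2 down-shifting control-compound wells, 2 no-break
#: (nuclease-dead) wells for GFP calibration; 80 wells remain for compounds.
_CONTROL_LAYOUT = {
    "A1": "vehicle_control", "B1": "vehicle_control",
    "C1": "vehicle_control", "D1": "vehicle_control",
    "E1": "up_control", "F1": "up_control",
    "G1": "down_control", "H1": "down_control",
    "A12": "mock_no_break", "B12": "mock_no_break",
    "C12": "vehicle_control", "D12": "vehicle_control",
    "E12": "vehicle_control", "F12": "vehicle_control",
    "D6": "vehicle_control", "E7": "vehicle_control",
}

_CONTROL_HDR = {  # vehicle 3% baseline; shifted controls mimic NU7026/KU55933
    "vehicle_control": 0.03, "up_control": 0.045,
    "down_control": 0.015, "mock_no_break": 0.0,
}


def build_screen_plates(
    compound_hdr: Mapping[str, float],
    vehicle_hdr: float = 0.03,
    n_cells: int = 2500,
    translocation_fraction: float = 0.8,
    **well_kwargs,
) -> list[list[WellSpec]]:
    """Chunk a compound -> true-HDR map into 96-well plate layouts.

    Each plate carries the fixed control columns (1 and 12) and up to 80
    compounds; compound order follows the mapping's iteration order.
    Returns one list of :class:`WellSpec` per plate.
    """
    control_hdr = dict(_CONTROL_HDR, vehicle_control=vehicle_hdr)
    items = list(compound_hdr.items())
    compound_wells = [w for w in WELL_IDS if w not in _CONTROL_LAYOUT]
    plates = []
    for start in range(0, len(items), len(compound_wells)):
        chunk = items[start:start + len(compound_wells)]
        wells = []
        for wid in WELL_IDS:
            if wid in _CONTROL_LAYOUT:
                role = _CONTROL_LAYOUT[wid]
                wells.append(WellSpec(
                    well_id=wid, role=role, compound_id=role,
                    true_hdr_fraction=control_hdr[role], n_cells=n_cells,
                    translocation_fraction=translocation_fraction,
                    **well_kwargs))
            elif chunk:
                cid, hdr = chunk.pop(0)
                wells.append(WellSpec(
                    well_id=wid, role="compound", compound_id=cid,
                    concentration_uM=20.0, true_hdr_fraction=hdr,
                    n_cells=n_cells,
                    translocation_fraction=translocation_fraction,
                    **well_kwargs))
            else:
                wells.append(WellSpec(
                    well_id=wid, role="vehicle_control",
                    compound_id="vehicle_control",
                    true_hdr_fraction=vehicle_hdr, n_cells=n_cells,
                    translocation_fraction=translocation_fraction,
                    **well_kwargs))
        plates.append(wells)
    return plates


def generate_dose_response(
    params: FourPL,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy titration table from a known 4PL curve.

    Responses are ``params.predict(c) + Normal(0, noise_sd)``; one row per
    concentration x replicate with columns ``concentration_uM``,
    ``replicate``, ``response``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (log-scale fitting)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        resp = params.predict(conc) + rng.normal(0.0, noise_sd, conc.size)
        for c, y in zip(conc, resp):
            rows.append(dict(concentration_uM=float(c), replicate=rep,
                             response=float(y)))
    return pd.DataFrame(rows)
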