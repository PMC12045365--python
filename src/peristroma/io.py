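"""Reading, writing and assembly of tissue samples.

A *tissue sample* is one whole tumor cross-section as exported by a
segmentation platform: a table of cell centroids (tumor vs. other classes,
marker-positive vs. -negative), a stroma mask or polygon set, and an
optional necrosis-exclusion mask.  Coordinates follow the image convention:
origin at the top-left corner, ``x`` rightward, ``y`` downward, and pixel
``(row i, column j)`` spanning ``[j, j+1) x [i, i+1)`` with its center at
``(j + 0.5, i + 0.5)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

#: default column names for cell tables
DEFAULT_COLUMNS = {"x": "x", "y": "y", "cell_class": "class", "marker": "marker"}
#: default vocabulary mapping raw class strings to {"tumor", "other"}
DEFAULT_CLASS_VOCAB = {"tumor": "tumor", "other": "other"}
#: default vocabulary mapping raw marker strings to booleans
DEFAULT_MARKER_VOCAB = {"pos": True, "neg": False}

RASTER_EXTENSIONS = {".png", ".tif", ".tiff"}
POLYGON_EXTENSIONS = {".geojson", ".json", ".wkt", ".txt"}


@dataclass
class StromaGeometry:
    """Binary stroma raster, optionally retaining the source polygons."""

    raster: np.ndarray
    polygons: list | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster).astype(bool)
        if self.raster.ndim != 2 or self.raster.size == 0:
            raise ValueError("stroma raster must be a non-empty 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    @property
    def area_fraction(self) -> float:
        return float(self.raster.mean())


@dataclass
class TissueSample:
    """One analyzed tumor cross-section.

    ``cells`` holds tumor cells only (non-tumor classes are dropped at
    assembly) with columns ``x``, ``y`` (continuous image coordinates) and
    ``marker`` (bool, True = marker-positive, e.g. BrdU+).  ``exclusion``
    marks necrotic pixels removed from every analysis.
    """

    cells: pd.DataFrame
    stroma: StromaGeometry
    exclusion: np.ndarray
    pixel_size: float
    sample_id: str = ""
    treatment: str = ""
    host_model: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_positive(self) -> int:
        return int(self.cells["marker"].sum())


def read_cell_table(
    path,
    columns: dict | None = None,
    class_vocab: dict | None = None,
    marker_vocab: dict | None = None,
) -> pd.DataFrame:
    """Parse a delimited cell-centroid export into a standard cell table.

    Returns a DataFrame with columns ``x``, ``y`` (float), ``cell_class``
    ("tumor"/"other") and ``marker`` (bool).  Non-tumor classes are retained
    (flagged via ``cell_class``); rows with non-finite coordinates are
    rejected with their row numbers logged.

    Raises
    ------
    ValueError
        If a mapped column is missing, or a class/marker value is not in
        its vocabulary (all offending values are listed).
    """
    columns = {**DEFAULT_COLUMNS, **(columns or {})}
    class_vocab = dict(class_vocab or DEFAULT_CLASS_VOCAB)
    marker_vocab = dict(marker_vocab or DEFAULT_MARKER_VOCAB)

    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing mapped column(s): {missing}")

    x = pd.to_numeric(raw[columns["x"]], errors="coerce")
    y = pd.to_numeric(raw[columns["y"]], errors="coerce")
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if bad.any():
        rows = (raw.index[bad] + 2).tolist()  # 1-based, +1 for header
        logger.warning(
            "rejected %d malformed row(s) in %s (file rows %s)", bad.sum(), path, rows
        )

    cls_raw = raw[columns["cell_class"]].astype(str).str.strip()
    unknown_cls = sorted(set(cls_raw) - set(class_vocab))
    if unknown_cls:
        raise ValueError(f"unmappable cell-class value(s) in {path}: {unknown_cls}")
    marker_raw = raw[columns["marker"]].astype(str).str.strip()
    unknown_marker = sorted(set(marker_raw) - set(marker_vocab))
    if unknown_marker:
        raise ValueError(f"unmappable marker value(s) in {path}: {unknown_marker}")

    table = pd.DataFrame(
        {
            "x": x.astype(float),
            "y": y.astype(float),
            "cell_class": cls_raw.map(class_vocab),
            "marker": marker_raw.map(marker_vocab).astype(bool),
        }
    )
    return table.loc[~bad].reset_index(drop=True)


def _load_mask(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    return arr > 0


def _polygons_from_geometry(geom, path) -> list:
    geoms = getattr(geom, "geoms", [geom])
    polys = []
    for g in geoms:
        if g.geom_type != "Polygon":
            raise ValueError(f"{path}: unsupported geometry type {g.geom_type!r}")
        if not g.is_valid:
            raise ValueError(f"{path}: invalid (e.g. self-intersecting) polygon; not repaired")
        polys.append(g)
    return polys


def read_geometry(path):
    """Read stroma/exclusion geometry, auto-detecting the format by extension.

    PNG/TIFF masks are thresholded at ``> 0`` and returned as a boolean
    raster.  GeoJSON (Polygon/MultiPolygon features) and WKT files return a
    list of shapely Polygons in image coordinates.  Self-intersecting
    polygons are an error; no silent repair is attempted.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in RASTER_EXTENSIONS:
        return _load_mask(path)
    if ext not in POLYGON_EXTENSIONS:
        raise ValueError(f"unsupported geometry extension {ext!r} ({path})")

    text = path.read_text()
    if ext in {".geojson", ".json"}:
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            geoms = [shapely.geometry.shape(f["geometry"]) for f in obj["features"]]
        elif obj.get("type") == "Feature":
            geoms = [shapely.geometry.shape(obj["geometry"])]
        else:
            geoms = [shapely.geometry.shape(obj)]
    else:
        geoms = [shapely.from_wkt(text.strip())]
    polys: list = []
    for geom in geoms:
        polys.extend(_polygons_from_geometry(geom, path))
    return polys


def rasterize(polygons, shape: tuple[int, int], pixel_size: float | None = None) -> np.ndarray:
    """Rasterize polygons onto a grid: a pixel is foreground iff its center
    ``(j + 0.5, i + 0.5)`` lies inside (or on the boundary of) any polygon.

    A polygon that covers no pixel center at all raises a warning and
    contributes nothing.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("grid shape must be positive")
    mask = np.zeros((h, w), dtype=bool)
    if not polygons:
        return mask
    jj, ii = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    for poly in polygons:
        # boundary-center ties count as inside, hence intersects not contains
        hit = shapely.intersects_xy(poly, jj.ravel(), ii.ravel()).reshape(h, w)
        if not hit.any():
            warnings.warn(
                f"polygon with bounds {poly.bounds} covers no pixel center on "
                f"a {h}x{w} grid; it contributes no pixels",
                stacklevel=2,
            )
        mask |= hit
    return mask


def assemble_sample(
    cells: pd.DataFrame,
    stroma: StromaGeometry | np.ndarray,
    exclusion: np.ndarray | None = None,
    pixel_size: float = 1.0,
    sample_id: str = "",
    treatment: str = "",
    host_model: str = "",
    exclude_necrotic_stroma: bool = True,
) -> TissueSample:
    """Validate and assemble a :class:`TissueSample`.

    Non-tumor-class cells are dropped, as are cells lying on excluded
    (necrotic) pixels; both counts are logged.  Cells coincident with stroma
    pixels are retained (they receive distance 0 downstream) and counted.
    By default, stroma pixels inside the exclusion mask are removed from the
    stroma raster so necrotic stroma never acts as a distance target; pass
    ``exclude_necrotic_stroma=False`` to keep them.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if not isinstance(stroma, StromaGeometry):
        stroma = StromaGeometry(np.asarray(stroma))
    h, w = stroma.shape
    if exclusion is None:
        exclusion = np.zeros((h, w), dtype=bool)
    exclusion = np.asarray(exclusion).astype(bool)
    if exclusion.shape != (h, w):
        raise ValueError(
            f"exclusion shape {exclusion.shape} != stroma shape {(h, w)}"
        )

    cells = cells.reset_index(drop=True)
    n_input = len(cells)
    tumor = cells[cells["cell_class"] == "tumor"] if "cell_class" in cells else cells
    n_non_tumor = n_input - len(tumor)
    if n_non_tumor:
        logger.info("%s: dropped %d non-tumor cell(s)", sample_id, n_non_tumor)
    if len(tumor) == 0:
        raise ValueError(f"{sample_id}: zero tumor cells after class filtering")

    xs = tumor["x"].to_numpy(float)
    ys = tumor["y"].to_numpy(float)
    oob = ~((xs >= 0) & (xs < w) & (ys >= 0) & (ys < h))
    if oob.any():
        raise ValueError(
            f"{sample_id}: {int(oob.sum())} cell(s) outside the {h}x{w} grid, "
            f"e.g. rows {tumor.index[oob][:5].tolist()}"
        )
    ii = ys.astype(np.intp)
    jj = xs.astype(np.intp)

    on_excluded = exclusion[ii, jj]
    if on_excluded.any():
        logger.info(
            "%s: dropped %d cell(s) on excluded (necrotic) pixels",
            sample_id,
            int(on_excluded.sum()),
        )
    tumor = tumor.loc[~on_excluded]
    if len(tumor) == 0:
        raise ValueError(f"{sample_id}: zero tumor cells after exclusion filtering")

    raster = stroma.raster
    if exclude_necrotic_stroma:
        raster = raster & ~exclusion
    if not (raster & ~exclusion).any():
        raise ValueError(
            f"{sample_id}: no stroma pixel outside the exclusion mask; "
            "distance to nearest stroma is undefined"
        )
    n_on_stroma = int(raster[ii[~on_excluded], jj[~on_excluded]].sum())
    if n_on_stroma:
        logger.info(
            "%s: %d cell(s) coincide with stroma pixels (kept, distance 0)",
            sample_id,
            n_on_stroma,
        )

    out_cells = tumor[["x", "y", "marker"]].reset_index(drop=True)
    return TissueSample(
        cells=out_cells,
        stroma=StromaGeometry(raster, polygons=stroma.polygons),
        exclusion=exclusion,
        pixel_size=float(pixel_size),
        sample_id=sample_id,
        treatment=treatment,
        host_model=host_model,
    )


def _write_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def write_sample(sample: TissueSample, directory) -> Path:
    """Write a sample bundle: ``cells.csv``, ``stroma.png``, optional
    ``exclusion.png`` and a ``sample.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "x": sample.cells["x"],
            "y": sample.cells["y"],
            "class": "tumor",
            "marker": np.where(sample.cells["marker"], "pos", "neg"),
        }
    )
    table.to_csv(directory / "cells.csv", index=False)
    _write_mask(sample.stroma.raster, directory / "stroma.png")
    if sample.exclusion.any():
        _write_mask(sample.exclusion, directory / "exclusion.png")
    meta = {
        "pixel_size": sample.pixel_size,
        "sample_id": sample.sample_id,
        "treatment": sample.treatment,
        "host_model": sample.host_model,
    }
    (directory / "sample.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_sample(directory, exclude_necrotic_stroma: bool = True) -> TissueSample:
    """Read a sample bundle written by :func:`write_sample` (or hand-built
    in the same layout) and assemble it."""
    directory = Path(directory)
    meta = json.loads((directory / "sample.json").read_text())
    cells = read_cell_table(directory / "cells.csv")
    stroma = _load_mask(directory / "stroma.png")
    excl_path = directory / "exclusion.png"
    exclusion = _load_mask(excl_path) if excl_path.exists() else None
    return assemble_sample(
        cells,
        StromaGeometry(stroma),
        exclusion,
        pixel_size=meta["pixel_size"],
        sample_id=meta.get("sample_id", directory.name),
        treatment=meta.get("treatment", ""),
        host_model=meta.get("host_model", ""),
        exclude_necrotic_stroma=exclude_necrotic_stroma,
    )
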