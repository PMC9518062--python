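"""Raster/vector data model, file I/O and class-area accounting.

Rasters are single-band numeric grids with a cell size (km), a nodata
sentinel and a lower-left origin.  All multi-raster operations require
alignment (same shape, cell size and origin).  Supported on-disk formats
are single-band GeoTIFF (georeference stored in the image description)
and ESRI ASCII grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Raster",
    "CategoricalRaster",
    "ClassTable",
    "VectorSet",
    "read_raster",
    "write_raster",
    "classify_raster",
    "class_area_table",
    "rate_statistics",
    "erosion_budget",
    "rasterize",
    "burn_distance",
]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """Single-band numeric grid.

    ``values`` is row-major with row 0 at the *top* of the map; ``origin``
    is the (x, y) of the lower-left corner in km.  ``cell_size`` is the
    edge length of one square cell in km, so one cell covers
    ``cell_size**2`` km².
    """

    values: np.ndarray
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.values[self.values != self.nodata]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-nodata values must be finite")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.values != self.nodata

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def aligned_with(self, other: "Raster | CategoricalRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """New raster sharing this raster's georeference."""
        return Raster(
            values,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            origin=self.origin,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int((x - x0) / self.cell_size)
        row = self.nrows - 1 - int((y - y0) / self.cell_size)
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        return (
            x0 <= x < x0 + self.ncols * self.cell_size
            and y0 <= y < y0 + self.nrows * self.cell_size
        )


def require_aligned(*rasters: "Raster | CategoricalRaster") -> None:
    first = rasters[0]
    for other in rasters[1:]:
        ok = (
            first.shape == other.shape
            and np.isclose(first.cell_size, other.cell_size)
            and np.allclose(first.origin, other.origin)
        )
        if not ok:
            raise ValueError(
                f"rasters are not aligned: {first.shape}@{first.origin} vs "
                f"{other.shape}@{other.origin}"
            )


@dataclass
class CategoricalRaster:
    """Integer-coded class raster with an ordered label list.

    Code ``i`` (0-based) maps to ``labels[i]``; the nodata code is -1.
    """

    labels: list[str]
    values: np.ndarray
    cell_size: float = 1.0
    nodata_code: int = -1
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        codes = np.unique(self.values[self.values != self.nodata_code])
        if codes.size and (codes.min() < 0 or codes.max() >= len(self.labels)):
            raise ValueError("class code without a label")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def class_mask(self, label: str) -> np.ndarray:
        return self.values == self.labels.index(label)

    def class_counts(self) -> np.ndarray:
        """Cell count per class, ordered as ``labels``."""
        valid = self.values[self.mask]
        return np.bincount(valid, minlength=len(self.labels))

    def to_raster(self) -> Raster:
        vals = self.values.astype(np.float64)
        vals[~self.mask] = DEFAULT_NODATA
        return Raster(vals, self.cell_size, DEFAULT_NODATA, self.origin)


@dataclass
class ClassTable:
    """Per-class accounting table (areas, shares, counts, densities).

    Mirrors the layout of graded-result report tables: one row per class
    plus share columns that sum to 100 within rounding tolerance.
    """

    table: pd.DataFrame

    ROUND = 2  # print precision for km² and %

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def row(self, label: str) -> pd.Series:
        return self.table.set_index("label").loc[label]

    def rounded(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in out.columns:
            if col != "label" and pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(self.ROUND)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.rounded().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "ecopattern:"


def _format_of(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f in {"geotiff", "gtiff", "tif", "tiff"}:
            return "geotiff"
        if f in {"ascii", "aaigrid", "asc", "esri_ascii"}:
            return "ascii"
        raise ValueError(f"unsupported raster format: {fmt}")
    suffix = Path(path).suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    if suffix in {".asc", ".txt"}:
        return "ascii"
    raise ValueError(f"cannot infer raster format from {path!r}")


def write_raster(raster: Raster, path: str | Path, fmt: str | None = None) -> None:
    """Write a raster as GeoTIFF or ESRI ASCII grid (inferred from suffix)."""
    kind = _format_of(path, fmt)
    if kind == "ascii":
        _write_ascii(raster, path)
    else:
        _write_geotiff(raster, path)


def read_raster(path: str | Path, fmt: str | None = None) -> Raster:
    kind = _format_of(path, fmt)
    if kind == "ascii":
        return _read_ascii(path)
    return _read_geotiff(path)


def _write_ascii(raster: Raster, path: str | Path) -> None:
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.origin[0]!r}\n"
        f"yllcorner {raster.origin[1]!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values.astype(np.float32), fmt="%.7g")


def _read_ascii(path: str | Path) -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in meta:
            raise ValueError(f"malformed ESRI ASCII header: missing {key}")
    values = np.loadtxt(lines[n_header:], dtype=np.float64, ndmin=2)
    if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(
            f"ASCII grid body {values.shape} does not match header "
            f"({int(meta['nrows'])}, {int(meta['ncols'])})"
        )
    return Raster(
        values,
        cell_size=meta["cellsize"],
        nodata=meta.get("nodata_value", DEFAULT_NODATA),
        origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
    )


def _write_geotiff(raster: Raster, path: str | Path) -> None:
    import tifffile

    meta = {
        "cell_size": raster.cell_size,
        "nodata": raster.nodata,
        "origin": list(raster.origin),
    }
    tifffile.imwrite(
        path,
        raster.values.astype(np.float32),
        description=_META_PREFIX + json.dumps(meta),
    )


def _read_geotiff(path: str | Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.description or ""
    if values.ndim != 2:
        raise ValueError("expected a single-band GeoTIFF")
    cell_size, nodata, origin = 1.0, DEFAULT_NODATA, (0.0, 0.0)
    if desc.startswith(_META_PREFIX):
        meta = json.loads(desc[len(_META_PREFIX):])
        cell_size = float(meta["cell_size"])
        nodata = float(meta["nodata"])
        origin = tuple(meta["origin"])
    return Raster(values.astype(np.float64), cell_size, nodata, origin)


def write_categorical(cat: CategoricalRaster, path: str | Path) -> None:
    """Persist a class raster; labels ride along in a JSON sidecar."""
    write_raster(cat.to_raster(), path)
    Path(str(path) + ".labels.json").write_text(json.dumps(cat.labels))


def read_categorical(path: str | Path) -> CategoricalRaster:
    rast = read_raster(path)
    labels = json.loads(Path(str(path) + ".labels.json").read_text())
    codes = np.where(rast.mask, rast.values, -1).astype(np.int32)
    return CategoricalRaster(labels, codes, rast.cell_size, -1, rast.origin)


# ---------------------------------------------------------------------------
# Classification and accounting
# ---------------------------------------------------------------------------

def classify_raster(
    raster: Raster,
    breaks: Sequence[float],
    labels: Sequence[str],
    closure: str = "left",
) -> CategoricalRaster:
    """Grade a continuous raster into labelled intervals.

    ``breaks`` are the ``len(labels) + 1`` interval edges, strictly
    increasing (``±inf`` allowed at the ends).  The default ``left``
    closure assigns ``[a, b)`` with the last class closed on the right,
    so touching printed bounds like "0–500 / 500–2500" are deterministic.
    """
    edges = np.asarray(breaks, dtype=np.float64)
    if edges.ndim != 1 or len(edges) != len(labels) + 1:
        raise ValueError("need len(labels) + 1 break edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("breaks must be strictly increasing")
    if closure not in {"left", "right"}:
        raise ValueError("closure must be 'left' or 'right'")

    vals = raster.values
    valid = raster.mask
    if closure == "left":
        codes = np.searchsorted(edges, vals, side="right") - 1
        codes[vals == edges[-1]] = len(labels) - 1  # last class closed
    else:
        codes = np.searchsorted(edges, vals, side="left") - 1
        codes[vals == edges[0]] = 0
    out_of_range = valid & ((codes < 0) | (codes >= len(labels)))
    if np.any(out_of_range):
        bad = vals[out_of_range][0]
        raise ValueError(f"value {bad} outside classification range "
                         f"[{edges[0]}, {edges[-1]}]")
    codes = codes.astype(np.int32)
    codes[~valid] = -1
    return CategoricalRaster(
        list(labels), codes, raster.cell_size, -1, raster.origin
    )


def class_area_table(
    categorical: CategoricalRaster | None = None,
    total_area: float | None = None,
    *,
    labels: Sequence[str] | None = None,
    areas: Sequence[float] | None = None,
) -> ClassTable:
    """Per-class area and share-of-total table.

    Either pass a class raster (areas = cell counts × cell area) or
    supply ``labels``/``areas`` directly, e.g. from a printed table.
    """
    if categorical is not None:
        labels = list(categorical.labels)
        counts = categorical.class_counts()
        areas_arr = counts * categorical.cell_area
    else:
        if labels is None or areas is None:
            raise ValueError("need a categorical raster or labels + areas")
        areas_arr = np.asarray(areas, dtype=np.float64)
    if np.any(areas_arr < 0):
        raise ValueError("negative class area")
    total = float(np.sum(areas_arr)) if total_area is None else float(total_area)
    if total <= 0:
        raise ValueError("total area must be positive")
    shares = 100.0 * areas_arr / total
    return ClassTable(pd.DataFrame({
        "label": list(labels),
        "area_km2": areas_arr,
        "share_pct": shares,
    }))


def rate_statistics(
    labels: Sequence[str],
    counts: Sequence[float],
    areas: Sequence[float],
) -> ClassTable:
    """Per-class event counts, count shares and densities per km²."""
    counts_arr = np.asarray(counts, dtype=np.float64)
    areas_arr = np.asarray(areas, dtype=np.float64)
    if counts_arr.shape != areas_arr.shape or len(labels) != counts_arr.size:
        raise ValueError("labels, counts and areas must have equal length")
    if np.any((areas_arr == 0) & (counts_arr > 0)):
        raise ValueError("nonzero count on zero area")
    total_count = counts_arr.sum()
    count_share = (
        100.0 * counts_arr / total_count if total_count > 0
        else np.zeros_like(counts_arr)
    )
    density = np.divide(
        counts_arr, areas_arr,
        out=np.zeros_like(counts_arr), where=areas_arr > 0,
    )
    total_area = areas_arr.sum()
    area_share = (
        100.0 * areas_arr / total_area if total_area > 0
        else np.zeros_like(areas_arr)
    )
    return ClassTable(pd.DataFrame({
        "label": list(labels),
        "area_km2": areas_arr,
        "area_share_pct": area_share,
        "count": counts_arr,
        "count_share_pct": count_share,
        "density_per_km2": density,
    }))


def erosion_budget(
    labels: Sequence[str],
    areas_km2: Sequence[float],
    mean_modulus: Sequence[float],
) -> ClassTable:
    """Per-class erosion amounts: area (km²) × mean modulus (t/(km²·a))."""
    areas_arr = np.asarray(areas_km2, dtype=np.float64)
    mod_arr = np.asarray(mean_modulus, dtype=np.float64)
    if np.any(areas_arr < 0) or np.any(mod_arr < 0):
        raise ValueError("areas and moduli must be non-negative")
    amounts = areas_arr * mod_arr
    total = amounts.sum()
    shares = 100.0 * amounts / total if total > 0 else np.zeros_like(amounts)
    return ClassTable(pd.DataFrame({
        "label": list(labels),
        "area_km2": areas_arr,
        "mean_modulus": mod_arr,
        "amount_t_per_a": amounts,
        "amount_share_pct": shares,
    }))


# ---------------------------------------------------------------------------
# Vectors
# ---------------------------------------------------------------------------

@dataclass
class VectorSet:
    """Points, polylines or polygons in raster coordinates (km).

    ``coordinates`` holds one coordinate array per feature: shape (2,)
    for points, (n, 2) for polylines/polygon rings.
    """

    kind: str  # "points" | "polylines" | "polygons"
    coordinates: list[np.ndarray]
    attributes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in {"points", "polylines", "polygons"}:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        self.coordinates = [np.asarray(c, dtype=np.float64) for c in self.coordinates]
        if not self.attributes:
            self.attributes = [{} for _ in self.coordinates]

    def __len__(self) -> int:
        return len(self.coordinates)

    def flag_out_of_domain(self, template: Raster) -> np.ndarray:
        """Per-feature flag: True if any vertex falls outside the extent."""
        out = np.zeros(len(self), dtype=bool)
        for i, coords in enumerate(self.coordinates):
            pts = np.atleast_2d(coords)
            for x, y in pts:
                if not template.contains(x, y):
                    out[i] = True
                    break
        return out

    def to_geojson(self, path: str | Path) -> None:
        gtype = {"points": "Point", "polylines": "LineString",
                 "polygons": "Polygon"}[self.kind]
        features = []
        for coords, attrs in zip(self.coordinates, self.attributes):
            if self.kind == "points":
                geometry = {"type": gtype, "coordinates": list(map(float, coords))}
            elif self.kind == "polylines":
                geometry = {"type": gtype,
                            "coordinates": np.atleast_2d(coords).tolist()}
            else:
                geometry = {"type": gtype,
                            "coordinates": [np.atleast_2d(coords).tolist()]}
            features.append({
                "type": "Feature",
                "geometry": geometry,
                "properties": {k: _jsonable(v) for k, v in attrs.items()},
            })
        Path(path).write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "VectorSet":
        data = json.loads(Path(path).read_text())
        coords: list[np.ndarray] = []
        attrs: list[dict] = []
        kind = None
        for feat in data["features"]:
            geom = feat["geometry"]
            if geom["type"] == "Point":
                kind = kind or "points"
                coords.append(np.asarray(geom["coordinates"]))
            elif geom["type"] == "LineString":
                kind = kind or "polylines"
                coords.append(np.asarray(geom["coordinates"]))
            elif geom["type"] == "Polygon":
                kind = kind or "polygons"
                coords.append(np.asarray(geom["coordinates"][0]))
            else:
                raise ValueError(f"unsupported geometry {geom['type']}")
            attrs.append(feat.get("properties") or {})
        if kind is None:
            raise ValueError("empty GeoJSON feature collection")
        return cls(kind, coords, attrs)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def rasterize(vectors: VectorSet, template: Raster) -> Raster:
    """Binary mask raster: 1 on cells intersected by any feature."""
    if len(vectors) == 0:
        raise ValueError("empty vector set")
    mask = np.zeros(template.shape, dtype=np.float64)
    for coords in vectors.coordinates:
        pts = np.atleast_2d(coords)
        if vectors.kind == "points":
            for x, y in pts:
                if template.contains(x, y):
                    r, c = template.cell_of(x, y)
                    mask[r, c] = 1.0
        else:
            for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
                _burn_segment(mask, template, x0, y0, x1, y1)
    return template.like(mask, nodata=-1.0)


def _burn_segment(mask, template, x0, y0, x1, y1):
    # Dense sampling at quarter-cell steps marks every traversed cell.
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(2, int(np.ceil(length / (template.cell_size / 4))) + 1)
    for t in np.linspace(0.0, 1.0, n):
        x = x0 + t * (x1 - x0)
        y = y0 + t * (y1 - y0)
        if template.contains(x, y):
            r, c = template.cell_of(x, y)
            mask[r, c] = 1.0


def burn_distance(vectors: VectorSet, template: Raster) -> Raster:
    """Euclidean distance (km) from each cell center to the nearest
    cell intersected by the vectors."""
    mask = rasterize(vectors, template)
    dist = ndimage.distance_transform_edt(
        mask.values == 0, sampling=template.cell_size
    )
    return template.like(dist, nodata=-1.0)
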