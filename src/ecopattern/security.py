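"""Comprehensive security surface and ecological-security-pattern
construction: sources and points, corrected resistance surface, minimum
cumulative resistance (MCR) corridors, and typed ecological nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure

from . import flow
from .grid import CategoricalRaster, Raster, VectorSet, classify_raster, rasterize, require_aligned

SECURITY_LEVELS = ["lowest", "lower", "medium", "higher", "highest"]

# base resistance coefficient per land-use class
RESISTANCE_TABLE = {"forest": 1.0, "grassland": 10.0, "farmland": 30.0,
                    "water": 50.0, "unutilized": 300.0, "construction": 500.0}


# ---------------------------------------------------------------------------
# Security surface
# ---------------------------------------------------------------------------

@dataclass
class SecuritySurface:
    score: Raster
    classes: CategoricalRaster


def security_index(
    importance: CategoricalRaster,
    sensitivity: CategoricalRaster,
    connectivity: CategoricalRaster,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> SecuritySurface:
    """score = w₁·norm(imp) + w₂·(1 − norm(sens)) + w₃·norm(conn), cut
    into five equal intervals on [0, 1].  Sensitivity enters with
    flipped polarity: highly sensitive means less secure."""
    require_aligned(importance, sensitivity, connectivity)
    w = np.asarray(weights, dtype=np.float64)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("security weights must sum to 1")

    def norm_rank(cat: CategoricalRaster) -> np.ndarray:
        return cat.values / max(cat.n_classes - 1, 1)

    score = (w[0] * norm_rank(importance)
             + w[1] * (1.0 - norm_rank(sensitivity))
             + w[2] * norm_rank(connectivity))
    valid = importance.mask & sensitivity.mask & connectivity.mask
    score = np.where(valid, score, -9999.0)
    raster = Raster(score, importance.cell_size, -9999.0, importance.origin)
    classes = classify_raster(raster, np.linspace(0, 1, 6), SECURITY_LEVELS)
    return SecuritySurface(raster, classes)


# ---------------------------------------------------------------------------
# Sources and points
# ---------------------------------------------------------------------------

@dataclass
class SourcePatch:
    id: int
    level: str  # "primary" | "secondary"
    cells: np.ndarray
    area: float
    point: tuple[float, float]  # in-patch centroid (x, y km)


@dataclass
class SourceSet:
    primary: list[SourcePatch]
    secondary: list[SourcePatch]
    min_area: float

    @property
    def all_patches(self) -> list[SourcePatch]:
        return self.primary + self.secondary

    def points(self) -> VectorSet:
        coords = [np.asarray(p.point) for p in self.all_patches]
        attrs = [{"id": p.id, "level": p.level, "area_km2": p.area}
                 for p in self.all_patches]
        return VectorSet("points", coords, attrs)

    def table(self) -> pd.DataFrame:
        rows = []
        for level, patches in (("primary", self.primary),
                               ("secondary", self.secondary)):
            rows.append({"level": level, "n_patches": len(patches),
                         "area_km2": sum(p.area for p in patches)})
        return pd.DataFrame(rows)


def _components(mask: np.ndarray, security: CategoricalRaster,
                min_area: float, level: str, start_id: int) -> list[SourcePatch]:
    labeled = measure.label(mask, connectivity=2)
    template = security.to_raster()
    patches = []
    pid = start_id
    for region in measure.regionprops(labeled):
        area = region.num_pixels * security.cell_area
        if area < min_area:
            continue
        cells = np.asarray(region.coords)
        rr, cc = region.centroid
        r0, c0 = int(round(rr)), int(round(cc))
        if not mask[min(r0, mask.shape[0] - 1), min(c0, mask.shape[1] - 1)]:
            # concave patch: snap to the nearest in-patch cell
            d2 = (cells[:, 0] - rr) ** 2 + (cells[:, 1] - cc) ** 2
            r0, c0 = cells[int(np.argmin(d2))]
        patches.append(SourcePatch(pid, level, cells, area,
                                   template.cell_center(r0, c0)))
        pid += 1
    return patches


def identify_sources(security: SecuritySurface | CategoricalRaster,
                     min_area: float = 10.0,
                     max_per_level: int | None = None) -> SourceSet:
    """Highest-class components become primary sources, higher-class
    components secondary; both filtered by ``min_area`` (km²).

    ``max_per_level`` keeps only the largest N patches per level — the
    practical "key source" cut when the top classes are fragmented.
    """
    classes = security.classes if isinstance(security, SecuritySurface) else security
    top = classes.n_classes - 1
    primary = _components(classes.values == top, classes, min_area, "primary", 1)
    if max_per_level is not None:
        primary = sorted(primary, key=lambda p: -p.area)[:max_per_level]
    secondary = _components(classes.values == top - 1, classes, min_area,
                            "secondary", len(primary) + 1)
    if max_per_level is not None:
        secondary = sorted(secondary, key=lambda p: -p.area)[:max_per_level]
    for i, patch in enumerate(primary + secondary, start=1):
        patch.id = i
    if not primary and not secondary:
        raise ValueError(f"no source patch survives the {min_area} km² threshold")
    return SourceSet(primary, secondary, min_area)


# ---------------------------------------------------------------------------
# Resistance surface
# ---------------------------------------------------------------------------

@dataclass
class ResistanceSurface:
    base: Raster  # land-use lookup
    nightlight_corrected: Raster  # R_i = NL_i / NL_a · R
    elevation_corrected: Raster  # R_j = DEM_i / DEM_a · R_i
    class_means: pd.DataFrame  # per-class NL_a and DEM_a


def resistance_surface(landuse: CategoricalRaster, nightlight: Raster,
                       dem: Raster,
                       table: dict[str, float] | None = None) -> ResistanceSurface:
    """Base resistance from the land-use lookup, then two multiplicative
    corrections: by the cell's nightlight relative to its class mean, and
    by its elevation relative to its class mean.  A class with zero mean
    nightlight keeps its base resistance (the correction is undefined)."""
    require_aligned(landuse, nightlight, dem)
    table = table if table is not None else RESISTANCE_TABLE
    missing = [c for c in landuse.labels if c not in table]
    if missing:
        raise KeyError(f"no resistance coefficient for classes {missing}")
    base = np.zeros(landuse.shape)
    r_i = np.zeros(landuse.shape)
    r_j = np.zeros(landuse.shape)
    means = []
    for code, cls in enumerate(landuse.labels):
        sel = landuse.values == code
        if not sel.any():
            means.append({"class": cls, "NL_a": np.nan, "DEM_a": np.nan})
            continue
        r = table[cls]
        base[sel] = r
        nl_a = nightlight.values[sel].mean()
        dem_a = dem.values[sel].mean()
        means.append({"class": cls, "NL_a": nl_a, "DEM_a": dem_a})
        ri_vals = (nightlight.values[sel] / nl_a) * r if nl_a > 0 else r
        r_i[sel] = ri_vals
        rj_vals = (dem.values[sel] / dem_a) * r_i[sel] if dem_a > 0 else r_i[sel]
        r_j[sel] = rj_vals
    # keep the surface strictly traversable
    floor = 1e-6
    r_i = np.maximum(r_i, floor)
    r_j = np.maximum(r_j, floor)
    like = landuse.to_raster()
    return ResistanceSurface(like.like(base), like.like(r_i), like.like(r_j),
                             pd.DataFrame(means))


# ---------------------------------------------------------------------------
# Cost distance and corridors
# ---------------------------------------------------------------------------

_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
          (0, 1), (1, -1), (1, 0), (1, 1)]


def _cost_graph(resistance: Raster):
    """Sparse 8-neighbor graph; edge weight = mean cell resistance × step
    length (√2·cell for diagonals)."""
    res = resistance.values
    if np.any(res <= 0):
        raise ValueError("resistance must be positive everywhere")
    nr, nc = res.shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows, cols, weights = [], [], []
    cell = resistance.cell_size
    for dr, dc in _STEPS[4:]:  # undirected: E, SW, S, SE cover all pairs once
        step = cell * np.sqrt(2) if dr and dc else cell
        src = idx[max(0, -dr):nr - max(0, dr), max(0, -dc):nc - max(0, dc)]
        dst = idx[max(0, dr):nr + min(0, dr), max(0, dc):nc + min(0, dc)]
        w = 0.5 * (res.ravel()[src.ravel()] + res.ravel()[dst.ravel()]) * step
        rows.append(src.ravel())
        cols.append(dst.ravel())
        weights.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = nr * nc
    return coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()


def cost_distance(resistance: Raster,
                  source_cells: list[tuple[int, int]]) -> Raster:
    """Accumulated MCR cost from the nearest source cell to every cell."""
    if not source_cells:
        raise ValueError("need at least one source cell")
    g = _cost_graph(resistance)
    nc = resistance.ncols
    sources = [r * nc + c for r, c in source_cells]
    dist = dijkstra(g, directed=False, indices=sources, min_only=True)
    return resistance.like(dist.reshape(resistance.shape), nodata=-1.0)


@dataclass
class Corridor:
    id: int
    endpoints: tuple[int, int]  # source point ids
    level: str  # "primary" | "secondary" | "river"
    cells: list[tuple[int, int]]
    cost: float  # MCR cost
    length: float  # km

    def polyline(self, template: Raster) -> np.ndarray:
        return np.asarray([template.cell_center(r, c) for r, c in self.cells])


@dataclass
class CorridorSet:
    corridors: list[Corridor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.corridors)

    def cell_set(self) -> set[tuple[int, int]]:
        cells: set[tuple[int, int]] = set()
        for cor in self.corridors:
            cells.update(cor.cells)
        return cells

    def to_vectors(self, template: Raster) -> VectorSet:
        coords = [c.polyline(template) for c in self.corridors]
        attrs = [{"id": c.id, "level": c.level, "cost": c.cost,
                  "length_km": c.length, "from": c.endpoints[0],
                  "to": c.endpoints[1]} for c in self.corridors]
        return VectorSet("polylines", coords, attrs)

    def table(self) -> pd.DataFrame:
        rows = []
        for level in ("primary", "secondary", "river"):
            sel = [c for c in self.corridors if c.level == level]
            rows.append({"level": level, "count": len(sel),
                         "total_length_km": sum(c.length for c in sel)})
        return pd.DataFrame(rows)


def _path_cells(predecessors: np.ndarray, src: int, dst: int,
                ncols: int) -> list[tuple[int, int]]:
    path = []
    node = dst
    while node != -9999 and node != src:
        path.append((node // ncols, node % ncols))
        node = predecessors[node]
    if node == src:
        path.append((src // ncols, src % ncols))
    return path[::-1]


def _path_length(cells: list[tuple[int, int]], cell_size: float) -> float:
    length = 0.0
    for (r0, c0), (r1, c1) in zip(cells[:-1], cells[1:]):
        length += cell_size * (np.sqrt(2) if r0 != r1 and c0 != c1 else 1.0)
    return length


def least_cost_path(resistance: Raster, a: tuple[int, int],
                    b: tuple[int, int]) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost 8-neighbor path between two cells and its MCR cost."""
    g = _cost_graph(resistance)
    nc = resistance.ncols
    src, dst = a[0] * nc + a[1], b[0] * nc + b[1]
    dist, pred = dijkstra(g, directed=False, indices=src,
                          return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise ValueError(f"cells {a} and {b} are not connected")
    return _path_cells(pred, src, dst, nc), float(dist[dst])


def least_cost_corridors(resistance: Raster, sources: SourceSet,
                         overlap_threshold: float = 0.8) -> CorridorSet:
    """MCR corridors between source points.

    Primary corridors connect every primary-point pair; each secondary
    point additionally connects to its cheapest neighbor (primary or
    secondary).  Corridors sharing more than ``overlap_threshold`` of
    their cells with an already-kept cheaper corridor are dropped.
    """
    patches = sources.all_patches
    pts = {p.id: resistance.cell_of(*p.point) for p in patches}
    level_of = {p.id: p.level for p in patches}
    g = _cost_graph(resistance)
    ncols = resistance.ncols
    node_of = {pid: r * ncols + c for pid, (r, c) in pts.items()}
    ids = sorted(pts)
    dist_rows: dict[int, np.ndarray] = {}
    pred_rows: dict[int, np.ndarray] = {}
    for pid in ids:
        d, p = dijkstra(g, directed=False, indices=node_of[pid],
                        return_predecessors=True)
        dist_rows[pid], pred_rows[pid] = d, p

    candidates: list[tuple[float, int, int, str]] = []
    primary_ids = [pid for pid in ids if level_of[pid] == "primary"]
    secondary_ids = [pid for pid in ids if level_of[pid] == "secondary"]
    for i, u in enumerate(primary_ids):
        for v in primary_ids[i + 1:]:
            candidates.append((dist_rows[u][node_of[v]], u, v, "primary"))
    for u in secondary_ids:
        others = [v for v in ids if v != u]
        if not others:
            continue
        costs = {v: dist_rows[u][node_of[v]] for v in others}
        v = min(costs, key=costs.get)
        pair = (min(u, v), max(u, v))
        candidates.append((costs[v], pair[0], pair[1], "secondary"))

    seen_pairs: set[tuple[int, int]] = set()
    corridors: list[Corridor] = []
    kept_cells: list[set[tuple[int, int]]] = []
    cid = 0
    for cost, u, v, level in sorted(candidates):
        if not np.isfinite(cost) or (u, v) in seen_pairs:
            continue
        seen_pairs.add((u, v))
        cells = _path_cells(pred_rows[u], node_of[u], node_of[v], ncols)
        cset = set(cells)
        dominated = any(
            len(cset & kept) / max(min(len(cset), len(kept)), 1) > overlap_threshold
            for kept in kept_cells)
        if dominated:
            continue
        cid += 1
        corridors.append(Corridor(
            cid, (u, v), level, cells, float(cost),
            _path_length(cells, resistance.cell_size)))
        kept_cells.append(cset)
    return CorridorSet(corridors)


def river_corridors(rivers: VectorSet, template: Raster,
                    start_id: int = 0) -> CorridorSet:
    """River polylines carried over as corridors of level "river"."""
    corridors = []
    for i, coords in enumerate(rivers.coordinates):
        pts = np.atleast_2d(coords)
        if len(pts) < 2:
            continue
        cells = [template.cell_of(x, y) for x, y in pts
                 if template.contains(x, y)]
        length = float(np.hypot(*(np.diff(pts, axis=0).T)).sum())
        corridors.append(Corridor(start_id + i + 1, (-1, -1), "river",
                                  cells, 0.0, length))
    return CorridorSet(corridors)


# ---------------------------------------------------------------------------
# Ridge/valley lines and nodes
# ---------------------------------------------------------------------------

def ridge_valley_lines(resistance: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Ridge mask (zero D8 inflow on the resistance surface) and valley
    mask (same on the sign-inverted surface, thinned to 1-cell lines)."""
    return flow.ridge_mask(resistance), flow.valley_mask(resistance)


@dataclass
class Node:
    id: int
    type: str  # "strategic" | "breaking" | "respite"
    cell: tuple[int, int]
    corridor_id: int


@dataclass
class NodeSet:
    nodes: list[Node] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def by_type(self, kind: str) -> list[Node]:
        return [n for n in self.nodes if n.type == kind]

    def to_vectors(self, template: Raster) -> VectorSet:
        coords = [np.asarray(template.cell_center(*n.cell)) for n in self.nodes]
        attrs = [{"id": n.id, "type": n.type, "corridor": n.corridor_id}
                 for n in self.nodes]
        return VectorSet("points", coords, attrs)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"type": kind, "count": len(self.by_type(kind))}
            for kind in ("strategic", "breaking", "respite")])


def _merge_intersections(corridor_cells: dict[tuple[int, int], int],
                         mask: np.ndarray) -> list[tuple[tuple[int, int], int]]:
    """8-connected runs of corridor∩mask cells collapse to one node each."""
    hits = np.zeros(mask.shape, dtype=bool)
    for cell in corridor_cells:
        if mask[cell]:
            hits[cell] = True
    if not hits.any():
        return []
    labeled = measure.label(hits, connectivity=2)
    out = []
    for region in measure.regionprops(labeled):
        rr, cc = region.coords[len(region.coords) // 2]
        out.append(((int(rr), int(cc)), corridor_cells[(int(rr), int(cc))]))
    return out


def ecological_nodes(corridors: CorridorSet, ridge: np.ndarray,
                     valley: np.ndarray,
                     roads: VectorSet | None, rivers: VectorSet | None,
                     template: Raster) -> NodeSet:
    """strategic = corridor ∩ ridge, breaking = corridor ∩ (roads ∪
    rivers), respite = corridor ∩ valley; adjacent hits merge."""
    cell_owner: dict[tuple[int, int], int] = {}
    for cor in corridors.corridors:
        if cor.level == "river":
            continue
        for cell in cor.cells:
            cell_owner.setdefault(cell, cor.id)
    barrier = np.zeros(template.shape, dtype=bool)
    for vec in (roads, rivers):
        if vec is not None and len(vec):
            barrier |= rasterize(vec, template).values > 0
    nodes: list[Node] = []
    nid = 0
    for kind, mask in (("strategic", ridge), ("breaking", barrier),
                       ("respite", valley)):
        for cell, cor_id in _merge_intersections(cell_owner, mask):
            nid += 1
            nodes.append(Node(nid, kind, cell, cor_id))
    return NodeSet(nodes)
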