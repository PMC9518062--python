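"""Habitat patches and graph-based landscape connectivity indices.

IIC weights patch-pair area products by 1/(1 + topological distance);
PC weights them by the maximum product of per-link dispersal
probabilities; both are normalized by the squared landscape area.
Per-patch importance is the percent drop of each index when the patch
is removed, and PI is the mean of the two drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .breaks import grade
from .grid import CategoricalRaster, Raster

CONNECTIVITY_LEVELS = ["lowest", "lower", "medium", "higher", "highest"]


@dataclass
class Patch:
    id: int
    cells: np.ndarray  # (n, 2) row/col indices
    area: float  # km²
    centroid: tuple[float, float]  # x, y in km


@dataclass
class PatchGraph:
    patches: list[Patch]
    graph: nx.Graph  # nodes = patch ids; edge attr: distance, p
    total_area: float  # A_L, km²
    kernel_k: float  # dispersal decay rate per km

    @property
    def n(self) -> int:
        return len(self.patches)

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches])

    def topo_distances(self) -> np.ndarray:
        """l_ij link counts; inf for disconnected pairs; l_ii = 0."""
        ids = [p.id for p in self.patches]
        idx = {pid: i for i, pid in enumerate(ids)}
        n = len(ids)
        l = np.full((n, n), np.inf)
        np.fill_diagonal(l, 0.0)
        for src, lengths in nx.all_pairs_shortest_path_length(self.graph):
            for dst, d in lengths.items():
                l[idx[src], idx[dst]] = d
        return l

    def max_product_probabilities(self) -> np.ndarray:
        """p*_ij: maximum product of link probabilities over all paths
        (shortest path on −log p); p*_ii = 1, 0 when disconnected."""
        ids = [p.id for p in self.patches]
        idx = {pid: i for i, pid in enumerate(ids)}
        n = len(ids)
        logg = nx.Graph()
        logg.add_nodes_from(ids)
        for u, v, data in self.graph.edges(data=True):
            p = data["p"]
            if p > 0:
                logg.add_edge(u, v, w=-np.log(p))
        pstar = np.zeros((n, n))
        np.fill_diagonal(pstar, 1.0)
        for src, lengths in nx.all_pairs_dijkstra_path_length(logg, weight="w"):
            for dst, d in lengths.items():
                pstar[idx[src], idx[dst]] = np.exp(-d)
        return pstar


def extract_patches(habitat: np.ndarray | Raster, cell_size: float | None = None,
                    min_area: float = 0.0, connectivity: int = 8,
                    origin: tuple[float, float] = (0.0, 0.0)) -> list[Patch]:
    """Connected components of a binary habitat mask, area-filtered.

    ``connectivity`` 8 joins diagonal neighbors; 4 does not.
    """
    if isinstance(habitat, Raster):
        cell_size = habitat.cell_size
        origin = habitat.origin
        mask = habitat.values > 0
    else:
        mask = np.asarray(habitat) > 0
        if cell_size is None:
            cell_size = 1.0
    if not mask.any():
        raise ValueError("empty habitat mask")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = measure.label(mask, connectivity=2 if connectivity == 8 else 1)
    template = Raster(np.zeros(mask.shape), cell_size, -1.0, origin)
    patches = []
    pid = 0
    for region in measure.regionprops(labeled):
        area = region.num_pixels * cell_size**2
        if area < min_area:
            continue
        pid += 1
        rr, cc = region.centroid
        cx, cy = template.cell_center(int(round(rr)), int(round(cc)))
        patches.append(Patch(pid, np.asarray(region.coords), area, (cx, cy)))
    return patches


def patch_distance(a: Patch, b: Patch, cell_size: float) -> float:
    """Edge-to-edge distance: minimum center distance over cell pairs."""
    ta = cKDTree(a.cells * cell_size)
    d, _ = ta.query(b.cells * cell_size)
    return float(d.min())


def build_graph(patches: list[Patch], total_area: float, cell_size: float,
                threshold: float = 5.0,
                median_distance: float = 2.0,
                p_at_median: float = 0.5) -> PatchGraph:
    """Link patches closer than ``threshold`` km; direct dispersal
    probability p = exp(−k·d) with k calibrated so p(median_distance) =
    p_at_median."""
    if not patches:
        raise ValueError("need at least one patch")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not 0 < p_at_median < 1 or median_distance <= 0:
        raise ValueError("invalid dispersal calibration")
    k = -np.log(p_at_median) / median_distance
    g = nx.Graph()
    g.add_nodes_from(p.id for p in patches)
    for i, a in enumerate(patches):
        for b in patches[i + 1:]:
            d = patch_distance(a, b, cell_size)
            if d <= threshold:
                g.add_edge(a.id, b.id, distance=d, p=float(np.exp(-k * d)))
    return PatchGraph(patches, g, total_area, k)


def iic(graph: PatchGraph) -> float:
    """IIC = ΣΣ aᵢaⱼ / (1 + l_ij) / A_L²; disconnected pairs contribute 0."""
    if graph.total_area <= 0:
        raise ValueError("landscape area must be positive")
    a = graph.areas()
    l = graph.topo_distances()
    with np.errstate(divide="ignore"):
        terms = np.outer(a, a) / (1.0 + l)
    terms[~np.isfinite(l)] = 0.0
    return float(terms.sum() / graph.total_area**2)


def pc(graph: PatchGraph) -> float:
    """PC = ΣΣ aᵢaⱼ p*_ij / A_L²."""
    if graph.total_area <= 0:
        raise ValueError("landscape area must be positive")
    a = graph.areas()
    pstar = graph.max_product_probabilities()
    return float((np.outer(a, a) * pstar).sum() / graph.total_area**2)


def _without(graph: PatchGraph, patch_id: int) -> PatchGraph:
    kept = [p for p in graph.patches if p.id != patch_id]
    sub = graph.graph.subgraph([p.id for p in kept]).copy()
    return PatchGraph(kept, sub, graph.total_area, graph.kernel_k)


def patch_importance(graph: PatchGraph) -> pd.DataFrame:
    """Leave-one-out dIIC, dPC (% drops) and PI = (dIIC + dPC)/2."""
    iic_full = iic(graph)
    pc_full = pc(graph)
    rows = []
    for patch in graph.patches:
        if graph.n == 1:
            diic = dpc = 100.0
        else:
            reduced = _without(graph, patch.id)
            diic = 100.0 * (iic_full - iic(reduced)) / iic_full
            dpc = 100.0 * (pc_full - pc(reduced)) / pc_full
        rows.append({"patch": patch.id, "area_km2": patch.area,
                     "dIIC": diic, "dPC": dpc,
                     "PI": 0.5 * (diic + dpc)})
    return pd.DataFrame(rows)


def connectivity_surface(patches: list[Patch], importance: pd.DataFrame,
                         template: Raster,
                         method: str = "jenks") -> tuple[Raster, CategoricalRaster]:
    """Rasterize per-patch PI (0 off-habitat) and grade into five levels."""
    pi = importance.set_index("patch")["PI"]
    surface = np.zeros(template.shape)
    for patch in patches:
        surface[patch.cells[:, 0], patch.cells[:, 1]] = pi.loc[patch.id]
    raster = template.like(surface, nodata=-9999.0)
    if np.ptp(surface) == 0:
        codes = np.zeros(template.shape, dtype=np.int32)
        return raster, CategoricalRaster(CONNECTIVITY_LEVELS, codes,
                                         template.cell_size, -1, template.origin)
    classes = grade(raster, CONNECTIVITY_LEVELS, method=method)
    return raster, classes


# ---------------------------------------------------------------------------
# Conefor-style plain-text node/connection interchange
# ---------------------------------------------------------------------------

def write_conefor(graph: PatchGraph, node_path, conn_path) -> None:
    with open(node_path, "w") as fh:
        for p in graph.patches:
            fh.write(f"{p.id} {p.area:.6f}\n")
    with open(conn_path, "w") as fh:
        for u, v, data in graph.graph.edges(data=True):
            fh.write(f"{u} {v} {data['distance']:.6f}\n")


def read_conefor(node_path, conn_path, total_area: float,
                 median_distance: float = 2.0,
                 p_at_median: float = 0.5) -> PatchGraph:
    patches = []
    for line in open(node_path):
        if line.strip():
            pid, area = line.split()
            patches.append(Patch(int(pid), np.zeros((0, 2), dtype=int),
                                 float(area), (0.0, 0.0)))
    k = -np.log(p_at_median) / median_distance
    g = nx.Graph()
    g.add_nodes_from(p.id for p in patches)
    for line in open(conn_path):
        if line.strip():
            u, v, d = line.split()
            g.add_edge(int(u), int(v), distance=float(d),
                       p=float(np.exp(-k * float(d))))
    return PatchGraph(patches, g, total_area, k)
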