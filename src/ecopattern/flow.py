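"""Deterministic eight-direction (D8) flow routing on a grid.

Used to derive rivers from a DEM, flow-accumulation-based slope lengths,
and ridge/valley line masks on resistance surfaces.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import skeletonize

from .grid import Raster

# neighbor offsets (dr, dc) and their step lengths in cell units
_D8 = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)])
_D8_LEN = np.array([np.sqrt(2), 1, np.sqrt(2), 1, 1, np.sqrt(2), 1, np.sqrt(2)])


def d8_receivers(surface: np.ndarray) -> np.ndarray:
    """Steepest-descent receiver per cell.

    Returns an (nrows, ncols, 2) int array of (row, col) of the neighbor
    each cell drains to; pits and flat cells point to themselves.
    """
    nr, nc = surface.shape
    best_drop = np.zeros((nr, nc))
    recv_r, recv_c = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    recv_r, recv_c = recv_r.copy(), recv_c.copy()
    padded = np.pad(surface, 1, mode="constant", constant_values=np.inf)
    for (dr, dc), step in zip(_D8, _D8_LEN):
        nb = padded[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
        drop = (surface - nb) / step
        better = drop > best_drop
        best_drop = np.where(better, drop, best_drop)
        rr, cc = np.meshgrid(np.arange(nr) + dr, np.arange(nc) + dc, indexing="ij")
        recv_r = np.where(better, rr, recv_r)
        recv_c = np.where(better, cc, recv_c)
    return np.stack([recv_r, recv_c], axis=-1)


def flow_accumulation(surface: np.ndarray) -> np.ndarray:
    """Number of cells draining through each cell (self included).

    Cells are processed from highest to lowest so every donor is settled
    before its receiver.
    """
    recv = d8_receivers(surface)
    nr, nc = surface.shape
    acc = np.ones((nr, nc), dtype=np.float64)
    order = np.argsort(surface, axis=None)[::-1]
    rows, cols = np.unravel_index(order, surface.shape)
    for r, c in zip(rows, cols):
        rr, cc = recv[r, c]
        if (rr, cc) != (r, c):
            acc[rr, cc] += acc[r, c]
    return acc


def inflow_count(surface: np.ndarray) -> np.ndarray:
    """Number of neighbors draining into each cell."""
    recv = d8_receivers(surface)
    nr, nc = surface.shape
    count = np.zeros((nr, nc), dtype=np.int32)
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    for r, c in zip(rows.ravel(), cols.ravel()):
        rr, cc = recv[r, c]
        if (rr, cc) != (r, c):
            count[rr, cc] += 1
    return count


def ridge_mask(surface: Raster) -> np.ndarray:
    """Cells with zero upstream contribution under D8: local crest lines."""
    return inflow_count(surface.values) == 0


def valley_mask(surface: Raster, thin: bool = True) -> np.ndarray:
    """Crest lines of the sign-inverted surface = trough lines, thinned."""
    mask = inflow_count(-surface.values) == 0
    if thin:
        mask = skeletonize(mask)
    return mask


def trace_downstream(surface: np.ndarray, start: tuple[int, int],
                     stop_mask: np.ndarray | None = None,
                     max_steps: int | None = None) -> list[tuple[int, int]]:
    """Follow steepest descent from ``start`` until a pit (or stop mask)."""
    recv = d8_receivers(surface)
    path = [start]
    seen = {start}
    r, c = start
    steps = max_steps if max_steps is not None else surface.size
    for _ in range(steps):
        rr, cc = recv[r, c]
        if (rr, cc) == (r, c) or (rr, cc) in seen:
            break
        path.append((int(rr), int(cc)))
        seen.add((int(rr), int(cc)))
        r, c = int(rr), int(cc)
        if stop_mask is not None and stop_mask[r, c]:
            break
    return path


def river_network(dem: Raster, percentile: float = 97.0) -> np.ndarray:
    """River mask: cells whose flow accumulation exceeds a percentile."""
    acc = flow_accumulation(dem.values)
    thresh = np.percentile(acc, percentile)
    return acc >= max(thresh, 2.0)


def river_polylines(dem: Raster, river: np.ndarray) -> list[np.ndarray]:
    """Trace river cells downstream into centre-line polylines (xy km).

    Head cells (river cells with no upstream river neighbor under D8)
    seed a downstream trace that stops when it leaves the river mask or
    merges into an already-traced channel.
    """
    recv = d8_receivers(dem.values)
    nr, nc = dem.shape
    inflow = np.zeros((nr, nc), dtype=np.int32)
    for r in range(nr):
        for c in range(nc):
            if not river[r, c]:
                continue
            rr, cc = recv[r, c]
            if (rr, cc) != (r, c) and river[rr, cc]:
                inflow[rr, cc] += 1
    heads = [(r, c) for r in range(nr) for c in range(nc)
             if river[r, c] and inflow[r, c] == 0]
    visited = np.zeros((nr, nc), dtype=bool)
    lines: list[np.ndarray] = []
    for head in sorted(heads):
        path = []
        r, c = head
        while river[r, c]:
            path.append(dem.cell_center(r, c))
            if visited[r, c]:
                break
            visited[r, c] = True
            rr, cc = recv[r, c]
            if (rr, cc) == (r, c):
                break
            r, c = int(rr), int(cc)
        if len(path) >= 2:
            lines.append(np.asarray(path))
    return lines
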