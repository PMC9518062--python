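"""Break finders for graded five-level surfaces.

Jenks natural breaks (1-D dynamic programming, optionally on a value
sample), quantile breaks, and equal-interval breaks.  All return the
``k + 1`` interval edges expected by :func:`ecopattern.grid.classify_raster`.
"""

from __future__ import annotations

import numpy as np

from .grid import CategoricalRaster, Raster, classify_raster

FIVE_LEVELS = ["level_1", "level_2", "level_3", "level_4", "level_5"]


def jenks_breaks(values: np.ndarray, k: int, max_sample: int = 1200) -> np.ndarray:
    """Natural-breaks edges minimizing within-class sum of squared deviation.

    Exact Fisher-style dynamic programming on the sorted (sub)sample;
    deterministic sub-sampling keeps the O(k·n²) DP tractable on rasters.
    """
    vals = np.sort(np.asarray(values, dtype=np.float64).ravel())
    if vals.size == 0:
        raise ValueError("no values to classify")
    if vals.size > max_sample:
        idx = np.linspace(0, vals.size - 1, max_sample).astype(int)
        vals = vals[idx]
    n = vals.size
    if np.ptp(vals) == 0:
        # Degenerate constant input: widen to k trivial bins.
        lo, hi = vals[0], vals[0] + 1.0
        return np.linspace(lo, hi, k + 1)

    csum = np.concatenate(([0.0], np.cumsum(vals)))
    csum2 = np.concatenate(([0.0], np.cumsum(vals**2)))

    def ssd(i: int, j: np.ndarray) -> np.ndarray:
        # within-class SSD of vals[i:j] (vectorized over j)
        cnt = j - i
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        return s2 - s**2 / np.maximum(cnt, 1)

    # cost[c, j] = optimal SSD of first j values split into c classes
    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    j_all = np.arange(n + 1)
    cost[1] = ssd(0, j_all)
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            cand = cost[c - 1, i] + ssd_single(vals, csum, csum2, i, j)
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            split[c, j] = i[best]

    edges = [vals[-1]]
    j = n
    for c in range(k, 1, -1):
        i = split[c, j]
        edges.append(vals[i - 1] if i > 0 else vals[0])
        j = i
    edges.append(vals[0])
    edges = np.array(edges[::-1])
    # Guard against coincident edges in heavy-tied data.
    for t in range(1, len(edges)):
        if edges[t] <= edges[t - 1]:
            edges[t] = np.nextafter(edges[t - 1], np.inf)
    edges[0] = min(edges[0], vals[0])
    edges[-1] = max(edges[-1], vals[-1])
    return edges


def ssd_single(vals, csum, csum2, i: np.ndarray, j: int) -> np.ndarray:
    cnt = j - i
    s = csum[j] - csum[i]
    s2 = csum2[j] - csum2[i]
    return s2 - s**2 / np.maximum(cnt, 1)


def quantile_breaks(values: np.ndarray, k: int) -> np.ndarray:
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("no values to classify")
    edges = np.quantile(vals, np.linspace(0, 1, k + 1))
    for t in range(1, len(edges)):
        if edges[t] <= edges[t - 1]:
            edges[t] = np.nextafter(edges[t - 1], np.inf)
    return edges


def equal_interval_breaks(lo: float, hi: float, k: int) -> np.ndarray:
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, k + 1)


def grade(
    raster: Raster,
    labels: list[str] | None = None,
    method: str = "jenks",
    k: int | None = None,
    bounds: tuple[float, float] | None = None,
) -> CategoricalRaster:
    """Classify a continuous raster into ``k`` graded levels."""
    labels = labels if labels is not None else FIVE_LEVELS
    k = k if k is not None else len(labels)
    if len(labels) != k:
        raise ValueError("labels must match k")
    vals = raster.valid_values()
    if method == "jenks":
        edges = jenks_breaks(vals, k)
    elif method == "quantile":
        edges = quantile_breaks(vals, k)
    elif method == "equal":
        lo, hi = bounds if bounds is not None else (vals.min(), vals.max())
        edges = equal_interval_breaks(lo, hi, k)
    else:
        raise ValueError(f"unknown break method {method!r}")
    edges[0] = min(edges[0], vals.min()) if vals.size else edges[0]
    edges[-1] = max(edges[-1], vals.max()) if vals.size else edges[-1]
    return classify_raster(raster, edges, labels)
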