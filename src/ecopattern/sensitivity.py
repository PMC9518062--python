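"""Eco-environmental sensitivity: RUSLE soil erosion and certainty-factor
geohazard susceptibility, fused into a five-level surface.

Soil loss A = R·K·LS·C·P is computed in t/(hm²·a) and graded on the
t/(km²·a) scale (×100).  Geohazard susceptibility scores each cell by the
sum, over ten factor layers, of the certainty factor of the bin the cell
falls in; the certainty factor compares a bin's hazard density with the
study-wide prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import flow
from .breaks import grade
from .grid import CategoricalRaster, Raster, classify_raster, require_aligned

EROSION_LABELS = ["micro", "mild", "moderate", "serious", "polar", "severe"]
# class bounds on the t/(km²·a) scale
EROSION_BREAKS = [0.0, 500.0, 2500.0, 5000.0, 8000.0, 15000.0, np.inf]

SENSITIVITY_LEVELS = ["least_sensitive", "less_sensitive", "medium_sensitive",
                      "more_sensitive", "most_sensitive"]

HM2_PER_KM2 = 100.0  # 1 km² = 100 hm²


# ---------------------------------------------------------------------------
# RUSLE factors
# ---------------------------------------------------------------------------

def rainfall_erosivity(monthly_precip: np.ndarray,
                       template: Raster) -> Raster:
    """R = 0.1833 · [N⁻¹ Σ_years (Σ_m P²) / (Σ_m P)]^1.9957.

    ``monthly_precip`` has shape (n_years, 12, nrows, ncols) in mm;
    all-zero years contribute 0 to the mean (zero-rain convention).
    """
    p = np.asarray(monthly_precip, dtype=np.float64)
    if p.ndim != 4 or p.shape[1] != 12:
        raise ValueError("monthly precipitation must be (years, 12, rows, cols)")
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    annual_sum = p.sum(axis=1)
    annual_sq = (p**2).sum(axis=1)
    ratio = np.divide(annual_sq, annual_sum,
                      out=np.zeros_like(annual_sum), where=annual_sum > 0)
    inner = ratio.mean(axis=0)
    r = 0.1833 * inner**1.9957
    return template.like(r)


def soil_erodibility(w_g: Raster, w_p: Raster, w_c: Raster,
                     w_o: Raster) -> Raster:
    """EPIC-style erodibility K (t·h/(MJ·mm)) from texture percentages.

    K = [0.2 + 0.3·exp(−0.0256·W_g·(1 − W_p/100))]
        · [W_p/(W_c + W_p)]^0.3
        · [1 − 0.25·W_o/(W_o + exp(3.72 − 2.95·W_o))]
        · [1 − 0.7·β/(β + exp(22.9·β − 5.51))],  β = 1 − W_g/100.
    """
    require_aligned(w_g, w_p, w_c, w_o)
    wg, wp, wc, wo = (r.values for r in (w_g, w_p, w_c, w_o))
    for arr, name in ((wg, "W_g"), (wp, "W_p"), (wc, "W_c")):
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"{name} must lie in [0, 100]")
    if np.any(wc + wp <= 0):
        raise ValueError("W_c + W_p must be positive")
    beta = 1.0 - wg / 100.0
    term1 = 0.2 + 0.3 * np.exp(-0.0256 * wg * (1.0 - wp / 100.0))
    term2 = (wp / (wc + wp)) ** 0.3
    term3 = 1.0 - 0.25 * wo / (wo + np.exp(3.72 - 2.95 * wo))
    term4 = 1.0 - 0.7 * beta / (beta + np.exp(22.9 * beta - 5.51))
    return w_g.like(term1 * term2 * term3 * term4)


@dataclass
class LSParams:
    """Constants of the flow-accumulation LS form (all overridable)."""

    ref_length: float = 22.13  # m, unit-plot slope length
    s_low: tuple[float, float] = (10.8, 0.03)  # S = a·sinθ + b below cutoff
    s_high: tuple[float, float] = (16.8, -0.5)
    slope_cutoff: float = 0.09  # tanθ cutoff between the two S branches
    max_length: float = 300.0  # m, cap on accumulated slope length


def ls_factor(dem: Raster, params: LSParams | None = None) -> Raster:
    """Slope length–steepness factor from DEM slope and D8 flow accumulation.

    L = (λ/22.13)^m with m = β/(1+β), β = (sinθ/0.0896)/(3·sin^0.8 θ + 0.56);
    S piecewise-linear in sinθ with a break at 9 % slope.
    """
    params = params or LSParams()
    cell_m = dem.cell_size * 1000.0
    gy, gx = np.gradient(dem.values, cell_m)
    slope = np.arctan(np.hypot(gx, gy))
    sin_t = np.sin(slope)
    acc = flow.flow_accumulation(dem.values)
    lam = np.minimum(acc * cell_m, params.max_length)
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)
    l_fac = (lam / params.ref_length) ** m
    a_lo, b_lo = params.s_low
    a_hi, b_hi = params.s_high
    s_fac = np.where(np.tan(slope) < params.slope_cutoff,
                     a_lo * sin_t + b_lo, a_hi * sin_t + b_hi)
    return dem.like(np.maximum(l_fac * s_fac, 0.0))


@dataclass
class RusleFactors:
    r: Raster
    k: Raster
    ls: Raster
    c: Raster
    p: Raster

    def __post_init__(self) -> None:
        require_aligned(self.r, self.k, self.ls, self.c, self.p)
        for name in ("r", "k", "ls", "c", "p"):
            vals = getattr(self, name).valid_values()
            if vals.size and vals.min() < 0:
                raise ValueError(f"RUSLE factor {name} has negative values")


# per-land-use cover-management C and practice P defaults
DEFAULT_C = {"forest": 0.006, "grassland": 0.05, "farmland": 0.22,
             "water": 0.0, "unutilized": 0.6, "construction": 0.15}
DEFAULT_P = {"forest": 1.0, "grassland": 1.0, "farmland": 0.5,
             "water": 1.0, "unutilized": 1.0, "construction": 0.0}


def lookup_raster(landuse: CategoricalRaster, table: dict[str, float]) -> Raster:
    """Per-class value lookup burned onto the land-use grid."""
    missing = [c for c in landuse.labels if c not in table]
    if missing:
        raise KeyError(f"no lookup value for classes {missing}")
    out = np.zeros(landuse.shape)
    for i, cls in enumerate(landuse.labels):
        out[landuse.values == i] = table[cls]
    out[~landuse.mask] = -9999.0
    return Raster(out, landuse.cell_size, -9999.0, landuse.origin)


def soil_loss(factors: RusleFactors) -> tuple[Raster, Raster, CategoricalRaster]:
    """A = R·K·LS·C·P in t/(hm²·a); also returned ×100 on the t/(km²·a)
    grading scale together with the six-class erosion intensity raster."""
    a_hm2 = (factors.r.values * factors.k.values * factors.ls.values
             * factors.c.values * factors.p.values)
    template = factors.r
    a_km2 = a_hm2 * HM2_PER_KM2
    modulus = template.like(a_km2)
    classes = classify_raster(modulus, EROSION_BREAKS, EROSION_LABELS)
    return template.like(a_hm2), modulus, classes


# ---------------------------------------------------------------------------
# Certainty-factor geohazard model
# ---------------------------------------------------------------------------

@dataclass
class CFFactor:
    """Per-bin certainty factors for one evaluation factor layer."""

    name: str
    edges: np.ndarray | None  # None for categorical factors
    bin_ids: np.ndarray  # per-bin identifier (edge index or class code)
    areas: np.ndarray  # km² per bin
    counts: np.ndarray  # hazard points per bin
    p_a: np.ndarray  # conditional per-bin probability
    p_s: float  # study-wide prior
    cf: np.ndarray  # certainty factor per bin, in [-1, 1]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.name, "bin": self.bin_ids,
            "area_km2": self.areas, "count": self.counts,
            "Pa": self.p_a, "CF": self.cf,
        })


def certainty_factor(p_a: np.ndarray, p_s: float) -> np.ndarray:
    """CF = (Pa−Ps)/(Pa(1−Ps)) if Pa ≥ Ps else (Pa−Ps)/(Ps(1−Pa)),
    clipped to [−1, 1]."""
    p_a = np.asarray(p_a, dtype=np.float64)
    hi = p_a >= p_s
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        cf_hi = (p_a - p_s) / (p_a * (1.0 - p_s))
        cf_lo = (p_a - p_s) / (p_s * (1.0 - p_a))
    cf = np.where(hi, cf_hi, cf_lo)
    cf = np.where(np.isfinite(cf), cf, 0.0)
    return np.clip(cf, -1.0, 1.0)


def _points_to_cells(points: np.ndarray, template: Raster) -> np.ndarray:
    cells = []
    for x, y in np.atleast_2d(points):
        if template.contains(x, y):
            cells.append(template.cell_of(x, y))
    return np.asarray(cells, dtype=int).reshape(-1, 2)


def cf_factor(hazard_xy: np.ndarray, factor: Raster,
              bins: int | np.ndarray = 8,
              categorical: bool = False) -> CFFactor:
    """Fit per-bin certainty factors for one factor layer.

    Probabilities are per-cell event probabilities: Pa = points-in-bin /
    cells-in-bin, Ps = all-points / all-cells, so a regular inventory of
    at most one event per cell keeps them in [0, 1].
    """
    pts = np.atleast_2d(np.asarray(hazard_xy, dtype=np.float64))
    if pts.size == 0:
        raise ValueError("need at least one hazard point")
    cells = _points_to_cells(pts, factor)
    valid = factor.mask
    vals = factor.values
    if categorical:
        bin_ids = np.unique(vals[valid])
        cell_bin = np.searchsorted(bin_ids, vals)
        edges = None
    else:
        if np.isscalar(bins):
            qs = np.quantile(vals[valid], np.linspace(0, 1, int(bins) + 1))
            edges = np.unique(qs)
        else:
            edges = np.asarray(bins, dtype=np.float64)
        if len(edges) < 2:
            edges = np.array([vals[valid].min(), vals[valid].max() + 1.0])
        cell_bin = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                           0, len(edges) - 2)
        bin_ids = np.arange(len(edges) - 1)
    n_bins = len(bin_ids)
    cell_counts = np.zeros(n_bins)
    for b in range(n_bins):
        cell_counts[b] = np.sum(valid & (cell_bin == b))
    if np.any(cell_counts == 0):
        keep = cell_counts > 0
        bin_ids, cell_counts = bin_ids[keep], cell_counts[keep]
        n_bins = len(bin_ids)
        remap = -np.ones(int(cell_bin.max()) + 1, dtype=int)
        kept_positions = np.flatnonzero(keep)
        for new, old in enumerate(kept_positions):
            remap[old] = new
        cell_bin = np.where(cell_bin < len(remap), remap[cell_bin], -1)
    point_counts = np.zeros(n_bins)
    for r, c in cells:
        b = cell_bin[r, c]
        if b >= 0 and valid[r, c]:
            point_counts[b] += 1
    areas = cell_counts * factor.cell_area
    total_cells = valid.sum()
    p_a = point_counts / cell_counts
    p_s = point_counts.sum() / total_cells
    if p_s <= 0:
        raise ValueError("no hazard point falls on a valid cell")
    cf = certainty_factor(p_a, min(p_s, 1.0 - 1e-12))
    return CFFactor(getattr(factor, "name", "factor"), edges, bin_ids,
                    areas, point_counts, p_a, p_s, cf)


def cf_score_layer(factor: Raster, model: CFFactor) -> np.ndarray:
    """Broadcast a fitted factor's per-bin CF back onto the grid."""
    vals = factor.values
    if model.edges is None:
        score = np.zeros(factor.shape)
        for b, code in enumerate(model.bin_ids):
            score[vals == code] = model.cf[b]
        return score
    cell_bin = np.clip(np.searchsorted(model.edges, vals, side="right") - 1,
                       0, len(model.edges) - 2)
    # bins dropped for zero area fall back to CF 0
    lookup = np.zeros(len(model.edges) - 1)
    for b, idx in enumerate(model.bin_ids):
        lookup[idx] = model.cf[b]
    return lookup[cell_bin]


@dataclass
class CFModel:
    """One fitted CFFactor per evaluation layer plus the layers themselves."""

    factors: dict[str, tuple[Raster, CFFactor]] = field(default_factory=dict)

    def add(self, name: str, factor: Raster, fitted: CFFactor) -> None:
        fitted.name = name
        self.factors[name] = (factor, fitted)

    def table(self) -> pd.DataFrame:
        return pd.concat([f.table() for _, f in self.factors.values()],
                         ignore_index=True)


def fit_cf_model(hazard_xy: np.ndarray,
                 continuous: dict[str, Raster],
                 categorical: dict[str, Raster] | None = None,
                 bins: int = 8) -> CFModel:
    model = CFModel()
    for name, rast in continuous.items():
        model.add(name, rast, cf_factor(hazard_xy, rast, bins=bins))
    for name, rast in (categorical or {}).items():
        model.add(name, rast, cf_factor(hazard_xy, rast, categorical=True))
    return model


def geohazard_sensitivity(model: CFModel,
                          method: str = "jenks") -> tuple[Raster, CategoricalRaster]:
    """Per-cell sum of factor CFs, graded into five sensitivity levels."""
    if not model.factors:
        raise ValueError("empty CF model")
    first = next(iter(model.factors.values()))[0]
    score = np.zeros(first.shape)
    for factor, fitted in model.factors.values():
        score += cf_score_layer(factor, fitted)
    score_raster = first.like(score, nodata=-9999.0)
    if np.ptp(score_raster.valid_values()) == 0:
        codes = np.zeros(first.shape, dtype=np.int32)
        return score_raster, CategoricalRaster(
            SENSITIVITY_LEVELS, codes, first.cell_size, -1, first.origin)
    classes = grade(score_raster, SENSITIVITY_LEVELS, method=method)
    return score_raster, classes


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def combined_sensitivity(
    erosion: CategoricalRaster,
    geohazard: CategoricalRaster,
    weights: tuple[float, float] = (0.5, 0.5),
) -> tuple[Raster, CategoricalRaster]:
    """Weighted mean of normalized class ranks, re-graded to five levels.

    Each input's class code is mapped to a rank in [0, 1]; the weighted
    mean is cut into five equal intervals so rank-symmetric inputs give
    symmetric outputs.
    """
    require_aligned(erosion, geohazard)
    w = np.asarray(weights, dtype=np.float64)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("sensitivity weights must sum to 1")

    def ranks(cat: CategoricalRaster) -> np.ndarray:
        denom = max(cat.n_classes - 1, 1)
        return cat.values / denom

    score = w[0] * ranks(erosion) + w[1] * ranks(geohazard)
    valid = erosion.mask & geohazard.mask
    score = np.where(valid, score, -9999.0)
    score_raster = Raster(score, erosion.cell_size, -9999.0, erosion.origin)
    edges = np.linspace(0.0, 1.0, 6)
    classes = classify_raster(score_raster, edges, SENSITIVITY_LEVELS)
    return score_raster, classes
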