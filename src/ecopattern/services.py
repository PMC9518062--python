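"""Ecosystem-service layers and the five-level importance surface.

Four per-cell services — water conservation, soil conservation, carbon
sequestration and habitat quality — are computed from NPP, terrain and
land-use inputs, min-max normalized, fused by weighted mean and graded
into five importance levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .breaks import grade
from .grid import CategoricalRaster, Raster, require_aligned

log = logging.getLogger(__name__)

IMPORTANCE_LEVELS = ["least_important", "less_important", "medium_importance",
                     "more_important", "most_important"]

# carbon constants: 1 g dry matter fixes 1.63 g CO2 and releases 1.2 g O2;
# NPP (g C) converts to dry matter at 45 % carbon content
CARBON_CONTENT = 0.45
CO2_PER_G = 1.63
O2_PER_G = 1.2


@dataclass
class ServiceInputs:
    npp_mean: Raster
    f_sic: Raster  # soil infiltration factor in [0, 1]
    f_pre: Raster  # normalized annual precipitation factor in [0, 1]
    f_slo: Raster  # slope factor in [0, 1]
    k: Raster  # soil erodibility, normalized to [0, 1] before use

    def __post_init__(self) -> None:
        require_aligned(self.npp_mean, self.f_sic, self.f_pre, self.f_slo, self.k)
        for name in ("f_sic", "f_pre", "f_slo"):
            vals = getattr(self, name).valid_values()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Threat:
    source_class: str
    max_distance: float  # km
    weight: float  # in [0, 1]
    decay: str = "linear"  # "linear" | "exponential"

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("threat weight must lie in [0, 1]")
        if self.max_distance <= 0:
            raise ValueError("threat distance must be positive")


@dataclass
class HabitatModel:
    """Habitat suitability plus half-saturation threat decay parameters."""

    suitability: dict[str, float]  # land-use class -> H in [0, 1]
    threats: list[Threat] = field(default_factory=lambda: [
        Threat("construction", max_distance=3.0, weight=1.0),
        Threat("farmland", max_distance=1.5, weight=0.6),
    ])
    half_saturation: float = 0.5
    # sensitivity[habitat class][threat source class] in [0, 1]
    sensitivity: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        for cls, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability for {cls!r} outside [0, 1]")
        if self.half_saturation <= 0:
            raise ValueError("half-saturation constant must be positive")

    def sens(self, habitat: str, threat: str) -> float:
        if self.sensitivity is None:
            return 1.0 if self.suitability.get(habitat, 0) > 0 else 0.0
        return self.sensitivity.get(habitat, {}).get(threat, 0.0)


DEFAULT_HABITAT_MODEL = HabitatModel(
    suitability={"forest": 1.0, "grassland": 0.7, "farmland": 0.4,
                 "water": 0.8, "unutilized": 0.2, "construction": 0.0},
)


@dataclass
class ImportanceResult:
    wc: Raster
    sc: Raster
    cs: Raster
    hq: Raster
    composite: Raster
    classes: CategoricalRaster


def water_conservation(inputs: ServiceInputs) -> Raster:
    """WC = NPP_mean · F_sic · F_pre · (1 − F_slo)."""
    out = (inputs.npp_mean.values * inputs.f_sic.values
           * inputs.f_pre.values * (1.0 - inputs.f_slo.values))
    out[~inputs.npp_mean.mask] = inputs.npp_mean.nodata
    return inputs.npp_mean.like(out)


def soil_conservation(inputs: ServiceInputs) -> Raster:
    """SC = NPP_mean · (1 − K) · (1 − F_slo), with K pre-normalized to [0, 1]."""
    k = inputs.k.values
    k_valid = inputs.k.valid_values()
    if k_valid.size and (k_valid.min() < 0 or k_valid.max() > 1):
        rng = np.ptp(k_valid)
        k = (k - k_valid.min()) / rng if rng > 0 else np.zeros_like(k)
    out = inputs.npp_mean.values * (1.0 - k) * (1.0 - inputs.f_slo.values)
    out[~inputs.npp_mean.mask] = inputs.npp_mean.nodata
    return inputs.npp_mean.like(out)


def carbon_sequestration(npp_mean: Raster) -> Raster:
    """CS = (NPP_mean / 0.45) · (1.2 + 1.63): dry matter times fixed
    CO2 + released O2 per gram."""
    vals = npp_mean.valid_values()
    if vals.size and vals.min() < 0:
        raise ValueError("NPP must be non-negative")
    out = npp_mean.values / CARBON_CONTENT * (O2_PER_G + CO2_PER_G)
    out[~npp_mean.mask] = npp_mean.nodata
    return npp_mean.like(out)


def threat_level(landuse: CategoricalRaster,
                 model: HabitatModel) -> np.ndarray:
    """Accumulated threat D per cell: weighted, distance-decayed and
    sensitivity-scaled sum over threat sources."""
    d_total = np.zeros(landuse.shape)
    sens_per_cell = {t.source_class: np.zeros(landuse.shape) for t in model.threats}
    code_of = {cls: i for i, cls in enumerate(landuse.labels)}
    for threat in model.threats:
        for cls in landuse.labels:
            s = model.sens(cls, threat.source_class)
            sens_per_cell[threat.source_class][landuse.values == code_of[cls]] = s
    for threat in model.threats:
        src = landuse.class_mask(threat.source_class)
        if not src.any():
            continue
        d = ndimage.distance_transform_edt(~src, sampling=landuse.cell_size)
        if threat.decay == "exponential":
            decay = np.exp(-2.99 * d / threat.max_distance)
            decay[d > threat.max_distance] = 0.0
        else:
            decay = np.clip(1.0 - d / threat.max_distance, 0.0, 1.0)
        d_total += threat.weight * decay * sens_per_cell[threat.source_class]
    return d_total


def habitat_quality(landuse: CategoricalRaster,
                    model: HabitatModel = DEFAULT_HABITAT_MODEL,
                    threat: np.ndarray | None = None) -> Raster:
    """Q = H_j · (1 − D² / (D² + k²)) per cell.

    ``threat`` overrides the computed D field (useful for tests and
    user-supplied stress layers).
    """
    missing = [c for c in landuse.labels if c not in model.suitability]
    if missing:
        raise KeyError(f"no habitat suitability for classes {missing}")
    d = threat_level(landuse, model) if threat is None else np.asarray(threat)
    h = np.zeros(landuse.shape)
    for i, cls in enumerate(landuse.labels):
        h[landuse.values == i] = model.suitability[cls]
    k = model.half_saturation
    q = h * (1.0 - d**2 / (d**2 + k**2))
    q[~landuse.mask] = -9999.0
    return Raster(q, landuse.cell_size, -9999.0, landuse.origin)


def _minmax(raster: Raster, name: str = "layer") -> np.ndarray:
    vals = raster.valid_values()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        log.warning("constant %s: contributes 0.5 to the composite", name)
        return np.full(raster.shape, 0.5)
    return (raster.values - lo) / (hi - lo)


def importance_index(
    wc: Raster, sc: Raster, cs: Raster, hq: Raster,
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    method: str = "jenks",
) -> ImportanceResult:
    """Min-max normalize the four service layers, fuse by weighted mean
    and grade into five importance levels."""
    require_aligned(wc, sc, cs, hq)
    w = np.asarray(weights, dtype=np.float64)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("importance weights must sum to 1")
    layers = [_minmax(r, n) for r, n in
              zip((wc, sc, cs, hq), ("WC", "SC", "CS", "HQ"))]
    composite_vals = sum(wi * li for wi, li in zip(w, layers))
    valid = wc.mask & sc.mask & cs.mask & hq.mask
    composite_vals = np.where(valid, composite_vals, -9999.0)
    composite = Raster(composite_vals, wc.cell_size, -9999.0, wc.origin)
    classes = grade(composite, IMPORTANCE_LEVELS, method=method)
    return ImportanceResult(wc, sc, cs, hq, composite, classes)
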