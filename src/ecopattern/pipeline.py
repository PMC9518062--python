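"""End-to-end runner: synthetic scene → importance, sensitivity,
connectivity → security surface → sources, resistance, corridors, nodes.

Holds the stage wiring the CLI and the acceptance checks share.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import connectivity as conn
from . import security, sensitivity, services
from .grid import (CategoricalRaster, Raster, class_area_table,
                   write_categorical, write_raster)
from .synth import SceneConfig, SyntheticScene, generate_scene, slope_degrees

log = logging.getLogger(__name__)

# land-use -> infiltration factor lookup used when F_sic is not supplied
DEFAULT_INFILTRATION = {"forest": 0.9, "grassland": 0.7, "farmland": 0.5,
                        "water": 1.0, "unutilized": 0.3, "construction": 0.1}

HABITAT_CLASSES = ["forest", "grassland"]


@dataclass
class PipelineResult:
    scene: SyntheticScene
    importance: services.ImportanceResult
    erosion_modulus: Raster
    erosion_classes: CategoricalRaster
    geohazard_classes: CategoricalRaster
    sensitivity_classes: CategoricalRaster
    connectivity_classes: CategoricalRaster
    patch_importance: pd.DataFrame
    security: security.SecuritySurface
    sources: security.SourceSet
    resistance: security.ResistanceSurface
    corridors: security.CorridorSet
    nodes: security.NodeSet


def _normalized(arr: np.ndarray) -> np.ndarray:
    rng = np.ptp(arr)
    return (arr - arr.min()) / rng if rng > 0 else np.zeros_like(arr)


def run_importance(scene: SyntheticScene) -> services.ImportanceResult:
    slope_n = _normalized(scene.slope.values)
    annual_precip = scene.rainfall.sum(axis=1).mean(axis=0)
    k_raw = sensitivity.soil_erodibility(
        scene.soil["W_g"], scene.soil["W_p"],
        scene.soil["W_c"], scene.soil["W_o"])
    inputs = services.ServiceInputs(
        npp_mean=scene.npp,
        f_sic=sensitivity.lookup_raster(scene.landuse, DEFAULT_INFILTRATION),
        f_pre=scene.npp.like(_normalized(annual_precip)),
        f_slo=scene.npp.like(slope_n),
        k=scene.npp.like(_normalized(k_raw.values)),
    )
    wc = services.water_conservation(inputs)
    sc = services.soil_conservation(inputs)
    cs = services.carbon_sequestration(scene.npp)
    hq = services.habitat_quality(scene.landuse)
    return services.importance_index(wc, sc, cs, hq)


def run_sensitivity(scene: SyntheticScene, cf_bins: int = 8):
    r = sensitivity.rainfall_erosivity(scene.rainfall, scene.dem)
    k = sensitivity.soil_erodibility(
        scene.soil["W_g"], scene.soil["W_p"],
        scene.soil["W_c"], scene.soil["W_o"])
    ls = sensitivity.ls_factor(scene.dem)
    c = sensitivity.lookup_raster(scene.landuse, sensitivity.DEFAULT_C)
    p = sensitivity.lookup_raster(scene.landuse, sensitivity.DEFAULT_P)
    _, modulus, erosion_classes = sensitivity.soil_loss(
        sensitivity.RusleFactors(r, k, ls, c, p))

    hazards = np.vstack(scene.hazard_points.coordinates)
    dem = scene.dem
    river_dist = ndimage.distance_transform_edt(
        ~scene.river_mask, sampling=dem.cell_size)
    aspect = np.degrees(np.arctan2(*np.gradient(dem.values)[::-1])) % 360.0
    continuous = {
        "slope": scene.slope,
        "elevation": dem,
        "river_distance": dem.like(river_dist),
        "ndvi": scene.ndvi,
        "rainfall": dem.like(scene.rainfall.sum(axis=1).mean(axis=0)),
        "aspect": dem.like(aspect),
    }
    categorical = {"landuse": scene.landuse.to_raster()}
    model = sensitivity.fit_cf_model(hazards, continuous, categorical,
                                     bins=cf_bins)
    score, geo_classes = sensitivity.geohazard_sensitivity(model)
    _, combined = sensitivity.combined_sensitivity(erosion_classes, geo_classes)
    return modulus, erosion_classes, model, score, geo_classes, combined


def run_connectivity(scene: SyntheticScene, min_patch_area: float = 0.5,
                     threshold: float = 5.0):
    habitat = np.isin(
        scene.landuse.values,
        [scene.landuse.labels.index(c) for c in HABITAT_CLASSES])
    total_area = scene.dem.values.size * scene.dem.cell_area
    patches = conn.extract_patches(habitat, scene.dem.cell_size,
                                   min_area=min_patch_area,
                                   origin=scene.dem.origin)
    graph = conn.build_graph(patches, total_area, scene.dem.cell_size,
                             threshold=threshold)
    importance = conn.patch_importance(graph)
    surface, classes = conn.connectivity_surface(patches, importance, scene.dem)
    return patches, graph, importance, surface, classes


def run_pipeline(config: SceneConfig | None = None,
                 scene: SyntheticScene | None = None,
                 min_source_area: float = 10.0,
                 max_sources: int = 15,
                 security_weights=(1 / 3, 1 / 3, 1 / 3),
                 outdir: str | Path | None = None) -> PipelineResult:
    t0 = time.time()
    if scene is None:
        config = config or SceneConfig()
        log.info("generating scene: %dx%d seed=%d", config.nrows,
                 config.ncols, config.seed)
        scene = generate_scene(config)
    log.info("scene ready (%.1fs); importance stage", time.time() - t0)
    importance = run_importance(scene)
    log.info("importance done (%.1fs); sensitivity stage", time.time() - t0)
    modulus, erosion_classes, _, _, geo_classes, combined = run_sensitivity(scene)
    log.info("sensitivity done (%.1fs); connectivity stage", time.time() - t0)
    _, _, pimp, _, conn_classes = run_connectivity(scene)
    log.info("connectivity done (%.1fs); security stage", time.time() - t0)

    sec = security.security_index(importance.classes, combined, conn_classes,
                                  security_weights)
    # relax the area threshold until a usable pattern emerges (at least
    # two primary and one secondary source), capping patch counts
    sources = None
    threshold = min_source_area
    while True:
        try:
            candidate = security.identify_sources(sec, threshold,
                                                  max_per_level=max_sources)
        except ValueError:
            candidate = None
        if candidate is not None and (
                len(candidate.primary) >= 2 and len(candidate.secondary) >= 1):
            sources = candidate
            break
        if threshold <= 1e-6:
            if candidate is None:
                raise ValueError("no source patch anywhere in the surface")
            sources = candidate
            break
        threshold = threshold / 4 if threshold / 4 > 1e-6 else 0.0
        log.warning("sparse sources; relaxing threshold to %.3g km²", threshold)
    resistance = security.resistance_surface(scene.landuse, scene.nightlight,
                                             scene.dem)
    corridors = security.least_cost_corridors(resistance.elevation_corrected,
                                              sources)
    rivers = security.river_corridors(scene.rivers, scene.dem,
                                      start_id=len(corridors))
    corridors.corridors.extend(rivers.corridors)
    ridge, valley = security.ridge_valley_lines(resistance.elevation_corrected)
    nodes = security.ecological_nodes(corridors, ridge, valley,
                                      scene.roads, scene.rivers, scene.dem)
    log.info("pattern done (%.1fs): %d corridors, %d nodes",
             time.time() - t0, len(corridors), len(nodes))

    result = PipelineResult(scene, importance, modulus, erosion_classes,
                            geo_classes, combined, conn_classes, pimp,
                            sec, sources, resistance, corridors, nodes)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dem = result.scene.dem
    write_raster(result.security.score, outdir / "security_score.tif")
    write_categorical(result.security.classes, outdir / "security_classes.tif")
    write_raster(result.resistance.base, outdir / "resistance_base.tif")
    write_raster(result.resistance.nightlight_corrected,
                 outdir / "resistance_nl.tif")
    write_raster(result.resistance.elevation_corrected,
                 outdir / "resistance_dem.tif")
    write_categorical(result.importance.classes, outdir / "importance_classes.tif")
    write_categorical(result.sensitivity_classes, outdir / "sensitivity_classes.tif")
    write_categorical(result.connectivity_classes, outdir / "connectivity_classes.tif")
    result.sources.points().to_geojson(outdir / "points.geojson")
    result.corridors.to_vectors(dem).to_geojson(outdir / "corridors.geojson")
    result.nodes.to_vectors(dem).to_geojson(outdir / "nodes.geojson")
    result.sources.table().to_csv(outdir / "sources.csv", index=False)
    result.corridors.table().to_csv(outdir / "corridors.csv", index=False)
    result.nodes.table().to_csv(outdir / "nodes.csv", index=False)
    for name, cat in (("security", result.security.classes),
                      ("importance", result.importance.classes),
                      ("sensitivity", result.sensitivity_classes),
                      ("connectivity", result.connectivity_classes)):
        class_area_table(cat).to_csv(outdir / f"{name}_areas.csv")
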