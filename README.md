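# ecopattern

A raster pipeline for evaluating regional ecological security and
constructing an ecological security pattern — the spatial network of
sources, corridors and nodes that keeps a landscape connected and
functioning. It targets mountainous scenes and is exercised end-to-end
on synthetic landscapes, so nothing needs downloading.

The pipeline has three evaluation axes fused into a comprehensive
security surface, followed by pattern construction:

1. **Ecosystem-service importance** (`ecopattern.services`) — water
   conservation, soil conservation, carbon sequestration and a
   half-saturation habitat-quality model, min-max normalized, fused and
   graded into five levels.
2. **Eco-environmental sensitivity** (`ecopattern.sensitivity`) — RUSLE
   soil loss (rainfall erosivity, EPIC erodibility, flow-accumulation LS,
   per-land-use C/P), graded on the t/(km²·a) scale, plus a
   certainty-factor (CF) geohazard susceptibility model fitted to a
   hazard-point inventory over ten factor layers.
3. **Landscape connectivity** (`ecopattern.connectivity`) — habitat
   patches, a dispersal graph, IIC/PC indices with leave-one-out
   patch importance (dIIC, dPC, PI), rasterized to five levels.

Pattern construction (`ecopattern.security`): the five-level security
surface selects primary/secondary source patches above an area
threshold; a land-use resistance surface is corrected by nightlight and
elevation ratios; minimum-cumulative-resistance corridors link source
points over the 8-neighbour cost graph; strategic/breaking/respite
nodes are corridor intersections with resistance-surface ridge lines,
roads/rivers and valley lines.

`ecopattern.synth` generates seeded mountainous scenes (fractal DEM,
D8-derived rivers, elevation-structured land use, hazard points whose
density follows slope and river proximity, nightlight decaying from
construction) with ground-truth coefficients for recovery tests.

## CLI

One `esp` entry point with a subcommand per stage. All stages generate
their scene from a seed/YAML config, so each is runnable standalone:

```sh
esp synth        --outdir scene/   --seed 1 --size 200
esp services     --outdir svc/     --seed 1
esp sensitivity  --outdir sens/    --seed 1
esp connectivity --outdir conn/    --seed 1
esp pattern      --outdir pattern/ --seed 1 --min-source-area 10
```

Outputs are GeoTIFF/ESRI-ASCII rasters, GeoJSON vectors (sources,
points, corridors with level/cost/length, typed nodes), Conefor-style
node/connection text files, and CSV report tables (class areas and
shares, corridor counts and lengths, node counts by type).

## Layout

```
src/ecopattern/
  grid.py          raster/vector model, GeoTIFF + ESRI ASCII I/O,
                   classification, class-area/share/density tables
  breaks.py        Jenks / quantile / equal-interval break finders
  flow.py          D8 receivers, flow accumulation, ridge/valley masks
  synth.py         seeded synthetic scene generator
  services.py      four service layers + importance surface
  sensitivity.py   RUSLE + CF model + combined sensitivity
  connectivity.py  patches, IIC/PC/dIIC/dPC/PI, Conefor text I/O
  security.py      security index, sources, resistance, MCR corridors, nodes
  pipeline.py      end-to-end wiring
  cli.py           click CLI (`esp`)
```
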