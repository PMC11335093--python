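# plotpheno

Plot-level phenotypic trait extraction from multitemporal UAV orthomosaics.

Given georeferenced rasters (RGB and multispectral orthomosaics, surface
elevation models), plot regions of interest as polygon shapefiles, and an
extraction strategy, `plotpheno` produces a long-format plot × date × trait
table plus shapefile, CSV/XLSX and SQLite outputs. It covers the full
workflow of a field-trial phenotyping campaign:

- **geodata_io** — GeoTIFF raster I/O (via `tifffile` geo tags), band maps,
  polygon clipping with a pixel-center containment rule.
- **roi_manager** — plot ROI creation, grid replication of a template plot,
  shapefile persistence (self-contained `.shp`/`.shx`/`.dbf`/`.prj`
  reader/writer, polygons only).
- **calibration** — empirical-line radiometric calibration: per-band OLS of
  known panel reflectance against panel-mean digital numbers.
- **formula_engine** — parser/evaluator for arithmetic trait formulas over
  canonical band variables (`r g b re nir dsm`), with 21 preset vegetation
  indices (10 RGB/MS, 11 MS-only) and NaN-propagating missing-value
  semantics.
- **extraction** — per-plot zonal statistics (per-pixel-then-aggregate by
  default, band-mean-first as an option), surface-minus-ground canopy
  height, empirical biomass formulas over previously computed traits, and
  external feature scripts via a subprocess protocol
  (`interpreter script clip.tif plot_id …`, last stdout line is the value).
- **batch_store** — multitemporal batch runs with per-date
  `output_root/YYYYMMDD/<task>_<timestamp>/` folders, fault isolation per
  plot, throughput accounting (plots/min), and CSV/XLSX/shapefile/SQLite
  outputs.
- **analysis** — five-family curve fitting (linear, quadratic, exponential,
  power, logarithmic) with best-set selection and 4-decimal RMSE tie
  reporting, pairwise-complete Pearson correlation screening, per-date
  trait dynamics, box statistics with 1.5·IQR outliers, and prediction
  accuracy metrics (R², RMSE, rRMSE).
- **synthetic_fixtures** — seeded synthetic fields with known per-plot
  reflectance/height truth, calibration panels, and stub external scripts,
  so everything is testable offline.

## CLI

```sh
# generate a seeded synthetic field (78 x 3 = 234 plots)
plotpheno synth field --seed 1 --rows 78 --reps 3 --gsd 2 --out field/

# replicate a template plot ROI onto a grid
plotpheno roi replicate --template plot.shp --cols 3 --rows 78 \
    --dx 1.5 --dy 1.5 --out rois.shp

# run a batch task (dates, images, ROIs, strategy in a YAML file)
plotpheno batch run --task task.yaml

# statistics over the results table
plotpheno analyze fit  --x height --y fresh_weight --table ground_truth.csv
plotpheno analyze corr --table results.csv --variables NDVI,EXG,lrs --truth lrs
plotpheno analyze curve --table results.csv --trait NDVI
plotpheno analyze dist  --table results.csv --trait NDVI
```

A task file looks like:

```yaml
task_name: demo
roi_path: rois.shp
output_root: out
dates:
  - {date: 2026-06-01, rgb: d1/rgb.tif, ms: d1/ms.tif, dsm: d1/dsm.tif,
     panels_shp: panels.shp, panels_csv: panels.csv}
strategy:
  features:
    - {kind: formula, name: NDVI, preset: NDVI, source: ms}
    - {kind: formula, name: EXG, preset: EXG, source: rgb}
    - {kind: height, name: height, ground: 20.0}
    - {kind: biomass, name: biomass, expression: "0.5*height"}
    - {kind: external, name: lrs, interpreter: /usr/bin/python3,
       script: predict.py, source: rgb}
```

## Conventions worth knowing

- Band indices are 1-based in configs and band maps.
- Raster and ROI CRS must match exactly; there is no silent reprojection.
- A pixel belongs to a plot iff its center is inside (or on the boundary
  of) the plot polygon.
- Nodata in any referenced band makes that pixel missing for every
  downstream formula; zonal statistics are over contributing pixels only.
- `MSAVI` is registered exactly as tabulated upstream (no ÷2); the
  conventional form is available as `MSAVI_std`.
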