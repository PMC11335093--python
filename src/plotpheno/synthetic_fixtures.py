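"""Seeded synthetic test fields with known per-plot ground truth.

Generates a rectangular grid of plots (the default layout mirrors a
78 × 3 = 234-plot trial) as a set of co-registered products: a 5-band
multispectral image in digital numbers (synthesized by *inverting* a known
gain/offset calibration so the full DN → reflectance → index chain is
exercised), a 3-band visible image in reflectance, a surface-elevation
model, calibration panels in an alley, the plot ROI shapefile and a truth
CSV holding every per-plot value including closed-form index values.

All randomness comes from one seed; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

import csv
import stat
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box

from .calibration import CalibrationPanel
from .geodata_io import CANONICAL_BANDS, GeoTransform, RasterGrid, write_raster
from .roi_manager import PlotROI, write_rois

__all__ = [
    "FieldProducts",
    "FieldTruth",
    "generate_field",
    "generate_stub_script",
    "load_panels",
]

_BAND_RANGES = {  # plausible canopy reflectance ranges per band
    "r": (0.04, 0.12),
    "g": (0.08, 0.20),
    "b": (0.03, 0.08),
    "re": (0.20, 0.35),
    "nir": (0.35, 0.60),
}


@dataclass
class FieldTruth:
    """Layout, per-plot truth and noise model of a synthetic field."""

    seed: int = 0
    n_rows: int = 78
    n_cols: int = 3
    plot_width: float = 1.0  # meters
    plot_height: float = 1.0
    alley: float = 0.5
    noise_sigma: float = 0.0  # per-pixel Gaussian σ on reflectance/height
    gain: float = 0.001  # DN synthesis: DN = (ρ − offset) / gain + noise
    offset: float = 0.02
    ground_elevation: float = 20.0
    height_range: tuple[float, float] = (0.3, 1.5)
    panel_reflectances: tuple[float, ...] = (0.12, 0.32, 0.56)
    crs_id: str = "EPSG:32649"

    # filled by resolve(); per-plot truth tables keyed by plot_id
    reflectance: dict = field(default_factory=dict)
    height: dict = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_cols

    def plot_ids(self) -> list[str]:
        return [f"P{serial:04d}" for serial in range(1, self.n_plots + 1)]

    def resolve(self) -> "FieldTruth":
        """Draw per-plot reflectances and heights from the seed."""
        rng = np.random.default_rng(self.seed)
        lo, hi = self.height_range
        for plot_id in self.plot_ids():
            self.reflectance[plot_id] = {
                band: float(rng.uniform(*_BAND_RANGES[band]))
                for band in CANONICAL_BANDS
            }
            self.height[plot_id] = float(rng.uniform(lo, hi))
        return self

    def plot_box(self, serial: int) -> tuple[float, float, float, float]:
        """World bounds (minx, miny, maxx, maxy) of plot #serial (1-based)."""
        index = serial - 1
        row, col = divmod(index, self.n_cols)
        x0 = self.alley + col * (self.plot_width + self.alley)
        y1 = self.field_height - self.alley - row * (self.plot_height + self.alley)
        return x0, y1 - self.plot_height, x0 + self.plot_width, y1

    @property
    def field_width(self) -> float:
        return self.alley + self.n_cols * (self.plot_width + self.alley)

    @property
    def field_height(self) -> float:
        # extra bottom strip hosts the calibration panels
        return (self.alley + self.n_rows * (self.plot_height + self.alley)
                + self.plot_height + self.alley)

    def panel_box(self, index: int) -> tuple[float, float, float, float]:
        side = min(self.plot_height, 0.5)
        x0 = self.alley + index * (side + self.alley)
        y0 = self.alley
        return x0, y0, x0 + side, y0 + side


@dataclass
class FieldProducts:
    """Paths of everything :func:`generate_field` wrote."""

    ms: Path
    rgb: Path
    dsm: Path
    rois: Path
    panels: Path
    panels_csv: Path
    truth_csv: Path


def _snap(value: float, pixel: float) -> float:
    return round(value / pixel) * pixel


def generate_field(truth: FieldTruth, gsd: float, out_dir) -> FieldProducts:
    """Render the field at ``gsd`` cm/pixel and write all products.

    Plot and panel rectangles are snapped to the pixel grid so that at
    σ = 0 the pixel-center mask recovers per-plot means exactly. Every
    plot must contain at least 25 pixels.
    """
    pixel = gsd / 100.0  # meters
    if (truth.plot_width / pixel) * (truth.plot_height / pixel) < 25:
        raise ValueError("gsd too coarse: plots must contain ≥ 25 pixels")
    if not truth.reflectance:
        truth.resolve()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 1)

    width = int(np.ceil(truth.field_width / pixel - 1e-9))
    height = int(np.ceil(truth.field_height / pixel - 1e-9))
    origin_y = height * pixel  # grid-aligned top edge
    transform = GeoTransform(0.0, origin_y, pixel, pixel)

    reflectance = np.zeros((5, height, width))
    for band_i, band in enumerate(CANONICAL_BANDS):
        reflectance[band_i] = 0.05 if band != "nir" else 0.15  # soil background
    dsm = np.full((height, width), truth.ground_elevation)

    def pixel_block(bounds):
        x0, y0, x1, y1 = (_snap(v, pixel) for v in bounds)
        c0, c1 = int(round(x0 / pixel)), int(round(x1 / pixel))
        r0 = int(round((origin_y - y1) / pixel))
        r1 = int(round((origin_y - y0) / pixel))
        return (slice(r0, r1), slice(c0, c1)), (x0, y0, x1, y1)

    rois = []
    for serial, plot_id in enumerate(truth.plot_ids(), start=1):
        (rows, cols), snapped = pixel_block(truth.plot_box(serial))
        for band_i, band in enumerate(CANONICAL_BANDS):
            reflectance[band_i, rows, cols] = truth.reflectance[plot_id][band]
        dsm[rows, cols] = truth.ground_elevation + truth.height[plot_id]
        rois.append(PlotROI(plot_id, box(*snapped),
                            {"row": (serial - 1) // truth.n_cols + 1,
                             "col": (serial - 1) % truth.n_cols + 1},
                            truth.crs_id))

    panel_polys, panel_rows = [], []
    for index, rho in enumerate(truth.panel_reflectances):
        (rows, cols), snapped = pixel_block(truth.panel_box(index))
        reflectance[:, rows, cols] = rho
        panel_polys.append(box(*snapped))
        panel_rows.append({"panel_id": f"B{index + 1}", "rho": float(rho)})

    if truth.noise_sigma > 0:
        reflectance = reflectance + rng.normal(
            0.0, truth.noise_sigma, reflectance.shape)
        dsm = dsm + rng.normal(0.0, truth.noise_sigma, dsm.shape)

    dn = (reflectance - truth.offset) / truth.gain

    products = FieldProducts(
        ms=out_dir / "ms.tif",
        rgb=out_dir / "rgb.tif",
        dsm=out_dir / "dsm.tif",
        rois=out_dir / "rois.shp",
        panels=out_dir / "panels.shp",
        panels_csv=out_dir / "panels.csv",
        truth_csv=out_dir / "truth.csv",
    )
    write_raster(RasterGrid(dn, transform, truth.crs_id), products.ms)
    write_raster(RasterGrid(reflectance[:3], transform, truth.crs_id),
                 products.rgb)
    write_raster(RasterGrid(dsm, transform, truth.crs_id), products.dsm)
    write_rois(rois, products.rois)
    write_rois(
        [PlotROI(row["panel_id"], poly, {"rho": row["rho"]}, truth.crs_id)
         for poly, row in zip(panel_polys, panel_rows)],
        products.panels,
    )
    with open(products.panels_csv, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=["panel_id", "rho"])
        writer.writeheader()
        writer.writerows(panel_rows)

    with open(products.truth_csv, "w", newline="") as f:
        fieldnames = ["plot_id", *CANONICAL_BANDS, "height", "ndvi", "exg"]
        writer = csv.DictWriter(f, fieldnames=fieldnames)
        writer.writeheader()
        for plot_id in truth.plot_ids():
            rho = truth.reflectance[plot_id]
            ndvi = (rho["nir"] - rho["r"]) / (rho["nir"] + rho["r"])
            exg = ((rho["g"] * 2 - rho["r"] - rho["b"])
                   / (rho["r"] + rho["g"] + rho["b"]))
            writer.writerow({"plot_id": plot_id, **{b: repr(rho[b]) for b in
                                                    CANONICAL_BANDS},
                             "height": repr(truth.height[plot_id]),
                             "ndvi": repr(ndvi), "exg": repr(exg)})
    return products


def load_panels(panels_shp, panels_csv) -> list[CalibrationPanel]:
    """Rebuild :class:`CalibrationPanel` objects from the written sidecars."""
    from .roi_manager import load_rois

    rois = load_rois(panels_shp, id_field="plot_id")
    rho_by_id = {}
    with open(panels_csv, newline="") as f:
        for row in csv.DictReader(f):
            rho_by_id[row["panel_id"]] = float(row["rho"])
    return [CalibrationPanel(roi.polygon, rho_by_id[roi.plot_id])
            for roi in rois]


_STUB_TEMPLATES = {
    "constant": """\
import sys

# protocol: argv = [image_path, plot_id, ...]; last stdout line = value
print("plot", sys.argv[2])
print({value!r})
""",
    "fail": """\
import sys

sys.stderr.write("simulated failure for plot %s\\n" % sys.argv[2])
sys.exit(1)
""",
    "mean": """\
import sys

import numpy as np

from plotpheno.geodata_io import load_raster

raster = load_raster(sys.argv[1])
values = raster.band_masked(1)
print("plot", sys.argv[2])
print(float(np.nanmean(values)))
""",
}


def generate_stub_script(out_path, behavior: str = "constant",
                         value: float = 2.5) -> Path:
    """Write an executable stand-in for an external feature script.

    Behaviors: ``constant`` prints ``value``, ``fail`` exits nonzero,
    ``mean`` echoes the mean first-band pixel value of the clip it is
    handed.
    """
    if behavior not in _STUB_TEMPLATES:
        raise ValueError(f"unknown stub behavior {behavior!r}")
    out_path = Path(out_path)
    out_path.write_text(_STUB_TEMPLATES[behavior].format(value=value))
    out_path.chmod(out_path.stat().st_mode | stat.S_IXUSR)
    return out_path
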