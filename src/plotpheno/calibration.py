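"""Empirical-line radiometric calibration from digital numbers to reflectance.

Per band, an ordinary least-squares line ``reflectance = gain * DN + offset``
is fit through the (panel-mean DN, known panel reflectance) points of the
calibration panels, and then applied pixel-wise. Reflectance is regressed on
DN (the operational direction), the intercept is fitted rather than forced
through the origin, and out-of-range reflectances are retained by default
(with a warning count) so downstream normalized indices stay linear.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .geodata_io import BandMap, RasterGrid, clip_plot

__all__ = [
    "CalibrationPanel",
    "EmpiricalLineModel",
    "apply_calibration",
    "fit_empirical_line",
    "write_calibration_report",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationPanel:
    """A reference panel of known reflectance.

    ``reflectance`` is either a single value applying to every band (the
    usual grey panel) or a mapping of canonical band name to value.
    """

    polygon: Polygon
    reflectance: float | dict[str, float]

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area == 0:
            raise ValueError("panel polygon has zero area")
        values = (
            [self.reflectance]
            if isinstance(self.reflectance, (int, float))
            else list(self.reflectance.values())
        )
        for v in values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"panel reflectance {v} outside [0, 1]")

    def reflectance_for(self, band: str) -> float:
        if isinstance(self.reflectance, (int, float)):
            return float(self.reflectance)
        return float(self.reflectance[band])


@dataclass
class EmpiricalLineModel:
    """Fitted per-band linear DN→reflectance transforms."""

    gain: dict[str, float]
    offset: dict[str, float]
    r_squared: dict[str, float | None] = field(default_factory=dict)
    n_panels: int = 0

    def bands(self) -> list[str]:
        return list(self.gain)


def _panel_mean_dn(image: RasterGrid, band_index: int, polygon: Polygon) -> float:
    clip = clip_plot(image, polygon)
    values = clip.band_masked(band_index)
    n = int(np.isfinite(values).sum())
    if n == 0:
        raise ValueError("calibration panel contains no pixel centers")
    return float(np.nanmean(values))


def fit_empirical_line(
    image: RasterGrid,
    band_map: BandMap,
    panels: list[CalibrationPanel],
) -> EmpiricalLineModel:
    """Fit the empirical line per band from ≥ 2 panels.

    With exactly 2 panels the line interpolates them exactly; with more,
    OLS. All panels sharing one mean DN is a singular fit and an error.
    ``r_squared`` is ``None`` when undefined (zero reflectance variance).
    """
    if len(panels) < 2:
        raise ValueError(f"empirical line needs ≥ 2 panels, got {len(panels)}")
    band_map.validate_against(image)
    gains: dict[str, float] = {}
    offsets: dict[str, float] = {}
    r2s: dict[str, float | None] = {}
    for name, index in band_map.bindings.items():
        dn = np.array([_panel_mean_dn(image, index, p.polygon) for p in panels])
        rho = np.array([p.reflectance_for(name) for p in panels])
        if np.ptp(dn) == 0:
            raise ValueError(
                f"singular calibration: all panels share mean DN {dn[0]} "
                f"in band {name!r}"
            )
        gain, offset = np.polyfit(dn, rho, 1)
        predicted = gain * dn + offset
        ss_res = float(np.sum((rho - predicted) ** 2))
        ss_tot = float(np.sum((rho - rho.mean()) ** 2))
        r2s[name] = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
        gains[name] = float(gain)
        offsets[name] = float(offset)
    return EmpiricalLineModel(gains, offsets, r2s, n_panels=len(panels))


def apply_calibration(
    image: RasterGrid,
    model: EmpiricalLineModel,
    band_map: BandMap,
    clamp: bool = False,
) -> RasterGrid:
    """Convert DN to reflectance band-wise; nodata pixels stay missing.

    No clamping by default; ``clamp=True`` clips to [0, 1]. The count of
    out-of-range reflectances is logged either way.
    """
    band_map.validate_against(image)
    missing = [b for b in band_map.bindings if b not in model.gain]
    if missing:
        raise ValueError(f"no calibration model entry for bands {sorted(missing)}")
    nodata_mask = image.mask()
    out = image.values.astype(float).copy()
    n_outside = 0
    for name, index in band_map.bindings.items():
        band = out[index - 1]
        band = model.gain[name] * band + model.offset[name]
        n_outside += int(((band < 0) | (band > 1))[~nodata_mask].sum())
        if clamp:
            band = np.clip(band, 0.0, 1.0)
        out[index - 1] = band
    out[:, nodata_mask] = np.nan
    if n_outside:
        logger.warning(
            "calibration produced %d out-of-range reflectance values%s",
            n_outside,
            " (clamped)" if clamp else "",
        )
    return RasterGrid(out, image.transform, crs_id=image.crs_id, nodata=float("nan"))


def write_calibration_report(model: EmpiricalLineModel, path) -> None:
    """CSV report: one row per band with gain, offset and fit accuracy."""
    with open(Path(path), "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["band", "gain", "offset", "r_squared", "n_panels"])
        for band in model.bands():
            r2 = model.r_squared.get(band)
            writer.writerow(
                [band, repr(model.gain[band]), repr(model.offset[band]),
                 "" if r2 is None else repr(r2), model.n_panels]
            )
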