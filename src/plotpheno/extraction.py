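"""Per-plot trait extraction: zonal statistics, canopy height, biomass and
external-script image features.

The unit of work is :func:`extract_plot`: clip each required source image
to the plot ROI, evaluate the strategy's formulas (per pixel by default,
optionally on band means), reduce with a zonal statistic, derive height
from the surface model minus a ground reference, evaluate biomass formulas
over previously computed traits, and hand saved plot clips to external
scripts over a simple subprocess protocol.
"""

from __future__ import annotations

import datetime as _dt
import logging
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formula_engine import FeatureFormula, evaluate_formula
from .geodata_io import BandMap, RasterGrid, clip_plot, write_raster
from .roi_manager import PlotROI

__all__ = [
    "BiomassSpec",
    "ExternalFeatureSpec",
    "ExternalSpec",
    "ExtractionStrategy",
    "FormulaSpec",
    "HeightSpec",
    "PlotRecord",
    "SourceImage",
    "ZONAL_STATISTICS",
    "compute_biomass",
    "extract_height",
    "extract_plot",
    "run_external_feature",
    "zonal_stat",
]

logger = logging.getLogger(__name__)

#: plots contributing fewer pixels than this are flagged (value still reported)
MIN_PIXEL_SUPPORT = 5

ZONAL_STATISTICS = {
    "mean": np.nanmean,
    "median": np.nanmedian,
    "min": np.nanmin,
    "max": np.nanmax,
    "std": np.nanstd,
    "sum": np.nansum,
    "count": None,  # handled explicitly
}


@dataclass(frozen=True)
class FormulaSpec:
    """A formula trait: evaluate over a clipped source image, then reduce."""

    name: str
    formula: FeatureFormula
    source: str = "ms"  # image role: rgb | ms | dsm
    statistic: str = "mean"
    aggregate: str = "pixel"  # "pixel" (per-pixel then reduce) or "band_mean"

    def __post_init__(self) -> None:
        if self.statistic not in ZONAL_STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.aggregate not in ("pixel", "band_mean"):
            raise ValueError(f"unknown aggregate mode {self.aggregate!r}")


@dataclass(frozen=True)
class HeightSpec:
    """Canopy height: mean of (surface model − ground reference) in the ROI."""

    name: str = "height"
    source: str = "dsm"
    ground: float | RasterGrid | None = None


@dataclass(frozen=True)
class BiomassSpec:
    """Empirical biomass formula over previously computed scalar traits."""

    name: str
    formula: FeatureFormula


@dataclass(frozen=True)
class ExternalFeatureSpec:
    """How to invoke an external feature script."""

    interpreter: str
    script: str
    extra_args: tuple[str, ...] = ()
    timeout: float = 60.0

    def __post_init__(self) -> None:
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")

    def validate(self) -> None:
        if not Path(self.interpreter).exists():
            raise FileNotFoundError(f"interpreter not found: {self.interpreter}")
        if not Path(self.script).exists():
            raise FileNotFoundError(f"script not found: {self.script}")


@dataclass(frozen=True)
class ExternalSpec:
    """An external-script trait bound to a source image role."""

    name: str
    spec: ExternalFeatureSpec
    source: str = "rgb"


@dataclass
class ExtractionStrategy:
    """Ordered recipe of trait features extracted for every plot."""

    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        duplicates = sorted({n for n in names if names.count(n) > 1})
        if duplicates:
            raise ValueError(f"duplicate feature names: {duplicates}")
        defined: set[str] = set()
        for feature in self.features:
            if isinstance(feature, BiomassSpec):
                missing = sorted(feature.formula.variables - defined)
                if missing:
                    raise ValueError(
                        f"biomass feature {feature.name!r} references traits "
                        f"not defined earlier: {missing}"
                    )
            defined.add(feature.name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def required_roles(self) -> set[str]:
        roles = set()
        for feature in self.features:
            source = getattr(feature, "source", None)
            if source is not None:
                roles.add(source)
        return roles


@dataclass(frozen=True)
class SourceImage:
    """A raster plus the band map describing its spectral layout."""

    raster: RasterGrid
    band_map: BandMap | None = None


@dataclass
class PlotRecord:
    """All trait values extracted for one plot on one date."""

    plot_id: str
    date: _dt.date
    values: dict[str, float] = field(default_factory=dict)
    pixel_counts: dict[str, int] = field(default_factory=dict)


def zonal_stat(clip: RasterGrid, statistic: str = "mean",
               band: int = 1) -> tuple[float, int]:
    """Statistic over the non-missing pixels of a clipped band.

    Returns ``(value, n_contributing_pixels)``; value is NaN (and a
    warning is logged) when no pixels contribute.
    """
    if statistic not in ZONAL_STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    values = clip.band_masked(band)
    # compact to the contributing pixels (row-major) so the statistic is
    # exactly the statistic of that vector, bit-for-bit
    kept = values[np.isfinite(values)]
    n = int(kept.size)
    if n == 0:
        logger.warning("zonal_stat: no contributing pixels")
        return float("nan"), 0
    if statistic == "count":
        return float(n), n
    plain = {"mean": np.mean, "median": np.median, "min": np.min,
             "max": np.max, "std": np.std, "sum": np.sum}
    return float(plain[statistic](kept)), n


def extract_height(dsm: RasterGrid, roi: PlotROI,
                   ground: float | RasterGrid | None) -> tuple[float, int]:
    """Mean within-plot height above the ground reference.

    ``ground`` is a scalar elevation or a terrain-model raster on the same
    grid as the surface model; it is required — there is no way to infer
    bare-soil height from the surface model alone.
    """
    if ground is None:
        raise ValueError("no soil reference: supply a scalar ground elevation "
                         "or a terrain-model raster")
    clip = clip_plot(dsm, roi)
    surface = clip.band_masked(1)
    if isinstance(ground, RasterGrid):
        if ground.values.shape != dsm.values.shape:
            raise ValueError("terrain model must share the surface model grid")
        ground_clip = clip_plot(ground, roi)
        surface = surface - ground_clip.band_masked(1)
    else:
        surface = surface - float(ground)
    n = int(np.isfinite(surface).sum())
    if n == 0:
        logger.warning("extract_height: no contributing pixels")
        return float("nan"), 0
    return float(np.nanmean(surface)), n


def compute_biomass(formula: FeatureFormula, traits: dict[str, float]) -> float:
    """Scalar evaluation of an empirical formula over available traits.

    A missing or undefined input yields NaN (logged), never an exception —
    one bad plot must not abort a batch.
    """
    missing = sorted(formula.variables - set(traits))
    if missing:
        logger.warning("biomass %r: missing trait inputs %s", formula.name, missing)
        return float("nan")
    bindings = {k: float(traits[k]) for k in formula.variables}
    if any(np.isnan(v) for v in bindings.values()):
        logger.warning("biomass %r: NaN trait inputs", formula.name)
        return float("nan")
    return float(evaluate_formula(formula, bindings))


def run_external_feature(spec: ExternalFeatureSpec, plot_image_path,
                         plot_id: str) -> float:
    """Invoke an external feature script for one plot.

    Protocol: ``interpreter script image_path plot_id [extra_args...]``;
    the last non-empty line of stdout must be a single numeric literal.
    Nonzero exit, timeout or unparsable output yields NaN and a logged
    failure for this plot.
    """
    command = [spec.interpreter, spec.script, str(plot_image_path), plot_id,
               *spec.extra_args]
    try:
        proc = subprocess.run(command, capture_output=True, text=True,
                              timeout=spec.timeout)
    except subprocess.TimeoutExpired:
        logger.error("external feature timed out for plot %s", plot_id)
        return float("nan")
    if proc.returncode != 0:
        logger.error("external feature failed for plot %s (exit %d): %s",
                     plot_id, proc.returncode, proc.stderr.strip()[:500])
        return float("nan")
    lines = [line for line in proc.stdout.splitlines() if line.strip()]
    if not lines:
        logger.error("external feature produced no output for plot %s", plot_id)
        return float("nan")
    try:
        return float(lines[-1].strip())
    except ValueError:
        logger.error("external feature output not numeric for plot %s: %r",
                     plot_id, lines[-1].strip())
        return float("nan")


def _formula_value(spec: FormulaSpec, image: SourceImage,
                   roi: PlotROI) -> tuple[float, int]:
    clip = clip_plot(image.raster, roi)
    bindings: dict[str, np.ndarray] = {}
    if image.band_map is not None:
        for name, index in image.band_map.bindings.items():
            bindings[name] = clip.band_masked(index)
    if spec.source == "dsm":
        bindings.setdefault("dsm", clip.band_masked(1))
    unbound = sorted(spec.formula.variables - set(bindings))
    if unbound:
        raise ValueError(
            f"feature {spec.name!r}: variables {unbound} not provided by "
            f"source {spec.source!r}"
        )
    if spec.aggregate == "band_mean":
        scalar_bindings = {}
        n = 0
        for name in spec.formula.variables:
            values = bindings[name]
            n = int(np.isfinite(values).sum())
            scalar_bindings[name] = (float(np.nanmean(values)) if n else
                                     float("nan"))
        return float(evaluate_formula(spec.formula, scalar_bindings)), n
    grid = evaluate_formula(spec.formula, bindings)
    result = RasterGrid(np.asarray(grid, dtype=float), clip.transform,
                        crs_id=clip.crs_id, nodata=float("nan"))
    return zonal_stat(result, spec.statistic)


def extract_plot(
    images: dict[str, SourceImage],
    roi: PlotROI,
    strategy: ExtractionStrategy,
    date: _dt.date,
    workdir=None,
) -> PlotRecord:
    """Run a full extraction strategy for one plot on one date.

    ``images`` maps role names (``rgb``/``ms``/``dsm``) to source images.
    When the strategy includes external features, the relevant clip is
    written to ``workdir/{plot_id}.tif`` (and retained). Per-feature
    failures are recorded as NaN; a missing image role is an error naming
    the blocked features.
    """
    blocked = [f.name for f in strategy.features
               if getattr(f, "source", None) not in (None, *images)]
    if blocked:
        missing_roles = sorted(strategy.required_roles() - set(images))
        raise ValueError(
            f"missing image roles {missing_roles} block features {blocked}"
        )
    record = PlotRecord(roi.plot_id, date)
    clip_paths: dict[str, Path] = {}
    for feature in strategy.features:
        if isinstance(feature, FormulaSpec):
            value, n = _formula_value(feature, images[feature.source], roi)
            record.values[feature.name] = value
            record.pixel_counts[feature.name] = n
            if 0 < n < MIN_PIXEL_SUPPORT:
                logger.warning("plot %s feature %s: only %d pixels contribute",
                               roi.plot_id, feature.name, n)
        elif isinstance(feature, HeightSpec):
            value, n = extract_height(images[feature.source].raster, roi,
                                      feature.ground)
            record.values[feature.name] = value
            record.pixel_counts[feature.name] = n
        elif isinstance(feature, BiomassSpec):
            record.values[feature.name] = compute_biomass(feature.formula,
                                                          record.values)
        elif isinstance(feature, ExternalSpec):
            role = feature.source
            if role not in clip_paths:
                if workdir is None:
                    raise ValueError("external features require a workdir")
                clip = clip_plot(images[role].raster, roi)
                clip_path = Path(workdir) / f"{roi.plot_id}.tif"
                write_raster(clip, clip_path)
                clip_paths[role] = clip_path
            record.values[feature.name] = run_external_feature(
                feature.spec, clip_paths[role], roi.plot_id
            )
        else:
            raise TypeError(f"unknown feature spec {type(feature).__name__}")
    return record
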