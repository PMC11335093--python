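"""Multitemporal batch extraction, result persistence and throughput accounting.

A batch task walks an ordered list of flight dates, optionally calibrates
the multispectral image per date, extracts every plot, and writes per-date
outputs under ``output_root/<YYYYMMDD>/<task>_<UTC timestamp>/``: a CSV
(always) and optionally XLSX wide table, a copy of the ROI shapefile with
trait attribute columns appended, and the retained plot clips. The
aggregated product is a long-format :class:`PhenotypeTable`; per-plot
failures become missing values, never dropped rows.
"""

from __future__ import annotations

import datetime as _dt
import logging
import sqlite3
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationPanel, apply_calibration, fit_empirical_line
from .extraction import ExtractionStrategy, SourceImage, extract_plot
from .geodata_io import BandMap, load_raster
from .roi_manager import PlotROI, load_rois, write_rois

__all__ = [
    "BatchTask",
    "DateInputs",
    "PhenotypeTable",
    "TimingReport",
    "append_shapefile_attributes",
    "compute_efficiency",
    "read_table",
    "run_batch",
    "write_database",
    "write_table",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["task", "date", "plot_id", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Long-format plot × date × trait records."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        keys = self.data[["date", "plot_id", "trait"]]
        if keys.duplicated().any():
            dupes = keys[keys.duplicated()].head(5).to_dict("records")
            raise ValueError(f"duplicate (date, plot_id, trait) keys, e.g. {dupes}")

    def __len__(self) -> int:
        return len(self.data)

    def wide(self, date=None) -> pd.DataFrame:
        """Wide view: one row per plot, one column per trait."""
        data = self.data
        if date is not None:
            data = data[data["date"] == _coerce_date(date)]
        if data.empty:
            return pd.DataFrame(columns=["date", "plot_id"])
        # pivot (not pivot_table): missing cells must survive as NaN
        wide = data.pivot(index=["date", "plot_id"], columns="trait",
                          values="value").reset_index()
        wide.columns.name = None
        return wide

    def dates(self) -> list:
        return sorted(self.data["date"].unique())

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())


@dataclass
class TimingReport:
    """Wall-clock accounting of an extraction batch.

    Durations cover the extraction loop only (input mosaic I/O excluded).
    Efficiency is plots processed per minute across all periods.
    """

    per_date_minutes: dict
    n_plots: int
    n_periods: int

    @property
    def total_minutes(self) -> float:
        return float(sum(self.per_date_minutes.values()))

    @property
    def efficiency(self) -> float:
        return self.n_plots * self.n_periods / self.total_minutes


@dataclass
class DateInputs:
    """Image roles available for one flight date."""

    date: _dt.date
    rgb: str | Path | None = None
    ms: str | Path | None = None
    dsm: str | Path | None = None
    panels: list[CalibrationPanel] | None = None

    def roles(self) -> dict[str, Path]:
        out = {}
        for role in ("rgb", "ms", "dsm"):
            path = getattr(self, role)
            if path is not None:
                out[role] = Path(path)
        return out


@dataclass
class BatchTask:
    """Everything needed to run one multitemporal extraction."""

    task_name: str
    dates: list[DateInputs]
    roi_path: str | Path
    strategy: ExtractionStrategy
    output_root: str | Path
    band_maps: dict[str, BandMap] = field(default_factory=dict)
    database: str | Path | None = None
    write_xlsx: bool = False
    ground: float | None = None

    def __post_init__(self) -> None:
        if not self.dates:
            raise ValueError("batch task needs at least one date")


def _coerce_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def _default_band_map(role: str, raster) -> BandMap | None:
    if role == "rgb":
        return BandMap.rgb()
    if role == "ms":
        return BandMap.ms() if raster.n_bands >= 5 else BandMap.rgb()
    return None


def _preflight(task: BatchTask) -> None:
    problems = []
    if not Path(task.roi_path).with_suffix(".shp").exists():
        problems.append(f"ROI shapefile missing: {task.roi_path}")
    needed = task.strategy.required_roles()
    for inputs in task.dates:
        available = inputs.roles()
        for role in sorted(needed - set(available)):
            problems.append(f"{inputs.date}: missing {role} image")
        for role, path in available.items():
            if not path.exists():
                problems.append(f"{inputs.date}: unreadable {role} image {path}")
    if problems:
        raise ValueError("pre-flight failed:\n" + "\n".join(problems))


def run_batch(task: BatchTask) -> tuple[PhenotypeTable, TimingReport]:
    """Execute a batch task over all dates.

    Returns the aggregated long table and the timing report. The long
    table always has ``n_dates × n_plots × n_traits`` rows; failed cells
    hold NaN.
    """
    _preflight(task)
    rois = load_rois(task.roi_path)
    rows = []
    per_date_minutes: dict = {}
    trait_names = task.strategy.names
    for inputs in task.dates:
        date = _coerce_date(inputs.date)
        run_dir = _run_directory(task, date)
        clips_dir = run_dir / "clips"
        clips_dir.mkdir(parents=True, exist_ok=True)
        images: dict[str, SourceImage] = {}
        for role, path in inputs.roles().items():
            raster = load_raster(path)
            band_map = task.band_maps.get(role) or _default_band_map(role, raster)
            if role == "ms" and inputs.panels:
                model = fit_empirical_line(raster, band_map, inputs.panels)
                raster = apply_calibration(raster, model, band_map)
            images[role] = SourceImage(raster, band_map)

        records = []
        started = time.perf_counter()
        for roi in rois:
            try:
                record = extract_plot(images, roi, task.strategy, date,
                                      workdir=clips_dir)
            except Exception:  # fault isolation: one plot never kills a batch
                logger.exception("extraction failed for plot %s on %s",
                                 roi.plot_id, date)
                record = None
            records.append((roi, record))
        per_date_minutes[date] = (time.perf_counter() - started) / 60.0

        for roi, record in records:
            for trait in trait_names:
                value = float("nan")
                if record is not None:
                    value = record.values.get(trait, float("nan"))
                rows.append((task.task_name, date, roi.plot_id, trait, value))

        date_table = PhenotypeTable(pd.DataFrame(
            [r for r in rows if r[1] == date], columns=LONG_COLUMNS))
        write_table(date_table, run_dir / "results.csv", "csv")
        if task.write_xlsx:
            write_table(date_table, run_dir / "results.xlsx", "xlsx")
        date_records = {roi.plot_id: rec for roi, rec in records
                        if rec is not None}
        if date_records:
            append_shapefile_attributes(rois, list(date_records.values()),
                                        run_dir / "results.shp")

    table = PhenotypeTable(pd.DataFrame(rows, columns=LONG_COLUMNS))
    if task.database is not None:
        write_database(table, task.database)
    timing = TimingReport(per_date_minutes, n_plots=len(rois),
                          n_periods=len(task.dates))
    return table, timing


def _run_directory(task: BatchTask, date: _dt.date) -> Path:
    stamp = _dt.datetime.now(_dt.timezone.utc).strftime("%Y%m%dT%H%M%S%f")
    root = Path(task.output_root) / date.strftime("%Y%m%d")
    run_dir = root / f"{task.task_name}_{stamp}"
    while run_dir.exists():  # never overwrite a previous run
        stamp += "x"
        run_dir = root / f"{task.task_name}_{stamp}"
    return run_dir


def write_table(table: PhenotypeTable, path, format: str = "csv") -> None:
    """Write the wide view (one sheet/segment per date) at full precision.

    Missing values are empty cells, never zeros. CSV stacks dates with a
    leading date column; XLSX uses one sheet per date.
    """
    path = Path(path)
    wide = table.wide()
    if format == "csv":
        # shortest exact round-trip form of each float
        wide.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    elif format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            if wide.empty:
                wide.to_excel(writer, sheet_name="results", index=False)
            for date, chunk in wide.groupby("date"):
                sheet = _coerce_date(date).strftime("%Y%m%d")
                chunk.drop(columns="date").to_excel(writer, sheet_name=sheet,
                                                    index=False)
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table` (wide view)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if "date" in frame.columns:
        frame["date"] = frame["date"].map(_coerce_date)
    return frame


def append_shapefile_attributes(rois: list[PlotROI], records, path) -> None:
    """Copy the ROI set with one attribute column appended per trait."""
    by_id = {}
    for record in records:
        by_id[record.plot_id] = record.values
    orphans = sorted(set(by_id) - {roi.plot_id for roi in rois})
    if orphans:
        raise ValueError(f"records reference unknown plot ids: {orphans}")
    augmented = []
    for roi in rois:
        attrs = dict(roi.attributes)
        for trait, value in by_id.get(roi.plot_id, {}).items():
            attrs[trait] = None if value is None or (
                isinstance(value, float) and np.isnan(value)) else float(value)
        augmented.append(PlotROI(roi.plot_id, roi.polygon, attrs, roi.crs_id))
    write_rois(augmented, path)


def write_database(table: PhenotypeTable, target) -> None:
    """Append the long table to a SQLite database.

    The ``phenotype`` table enforces (date, plot_id, trait) uniqueness;
    re-inserting existing keys raises ``sqlite3.IntegrityError``.
    """
    conn = sqlite3.connect(str(target))
    try:
        conn.execute(
            """CREATE TABLE IF NOT EXISTS phenotype (
                   task TEXT NOT NULL,
                   date TEXT NOT NULL,
                   plot_id TEXT NOT NULL,
                   trait TEXT NOT NULL,
                   value REAL,
                   UNIQUE (date, plot_id, trait)
               )"""
        )
        rows = [
            (task, _coerce_date(date).isoformat(), plot_id, trait,
             None if pd.isna(value) else float(value))
            for task, date, plot_id, trait, value
            in table.data[LONG_COLUMNS].itertuples(index=False)
        ]
        with conn:
            conn.executemany(
                "INSERT INTO phenotype (task, date, plot_id, trait, value) "
                "VALUES (?, ?, ?, ?, ?)", rows)
    finally:
        conn.close()


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class EfficiencyResult:
    """Throughput summary of replicated batch runs."""

    mean_minutes: float
    efficiency: float  # plots per minute

    @property
    def mean_minutes_2dp(self) -> float:
        return _round2(self.mean_minutes)

    @property
    def efficiency_2dp(self) -> float:
        return _round2(self.efficiency)


def compute_efficiency(n_plots: int, n_periods: int,
                       run_minutes: list[float]) -> EfficiencyResult:
    """Throughput from replicate run times.

    ``efficiency = n_plots × n_periods / mean(run_minutes)`` in plots per
    minute, computed on the full-precision mean; 2-decimal roundings are
    exposed alongside.
    """
    if not run_minutes:
        raise ValueError("need at least one run duration")
    if any(m <= 0 for m in run_minutes):
        raise ValueError("run durations must be positive")
    mean_minutes = float(np.mean(run_minutes))
    efficiency = n_plots * n_periods / mean_minutes
    return EfficiencyResult(mean_minutes, efficiency)
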