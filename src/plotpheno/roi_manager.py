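"""Plot ROI creation, replication, labeling and persistence."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from shapely.affinity import translate
from shapely.geometry import Polygon

from . import shapefile

__all__ = ["PlotROI", "load_rois", "replicate_roi", "write_rois"]

DEFAULT_LABEL_PATTERN = "P{serial:04d}"
ID_FIELD = "plot_id"


@dataclass
class PlotROI:
    """One plot's labeled region of interest."""

    plot_id: str
    polygon: Polygon
    attributes: dict = field(default_factory=dict)
    crs_id: str | None = None

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area == 0:
            raise ValueError(f"ROI {self.plot_id!r}: polygon has zero area")
        if len(self.polygon.exterior.coords) < 4:  # closed ring: n+1 coords
            raise ValueError(f"ROI {self.plot_id!r}: ring needs ≥ 3 vertices")


def load_rois(path, id_field: str | None = ID_FIELD) -> list[PlotROI]:
    """Read plot ROIs from a polygon shapefile, order preserved.

    Features are keyed by ``id_field``; when the field is absent (or
    ``None``) sequential ids ``P0001``… are assigned. Duplicate ids are
    an error listing the offenders.
    """
    geometries, records, crs_id = shapefile.read_shapefile(path)
    rois = []
    for i, (geom, attrs) in enumerate(zip(geometries, records), start=1):
        attrs = dict(attrs)
        if id_field is not None and id_field in attrs:
            plot_id = str(attrs.pop(id_field))
        else:
            plot_id = DEFAULT_LABEL_PATTERN.format(serial=i, row=1, col=i)
        rois.append(PlotROI(plot_id, geom, attrs, crs_id))
    seen: dict[str, int] = {}
    for roi in rois:
        seen[roi.plot_id] = seen.get(roi.plot_id, 0) + 1
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    if duplicates:
        raise ValueError(f"duplicate plot ids: {duplicates}")
    return rois


def replicate_roi(
    template: PlotROI,
    n_cols: int,
    n_rows: int,
    dx: float,
    dy: float,
    label_pattern: str = DEFAULT_LABEL_PATTERN,
) -> list[PlotROI]:
    """Replicate a template ROI on a regular grid by pure translation.

    Copy ``(i, j)`` (column i, row j, both 0-based) is the template
    shifted by ``(i*dx, -j*dy)``; labels are assigned row-major with
    ``{row}``/``{col}`` (1-based) and ``{serial}`` placeholders.
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("replication counts must be ≥ 1")
    rois = []
    serial = 0
    for j in range(n_rows):
        for i in range(n_cols):
            serial += 1
            label = label_pattern.format(serial=serial, row=j + 1, col=i + 1)
            poly = translate(template.polygon, xoff=i * dx, yoff=-j * dy)
            rois.append(PlotROI(label, poly, dict(template.attributes),
                                template.crs_id))
    return rois


def write_rois(rois: list[PlotROI], path) -> dict[str, str]:
    """Persist ROIs as a polygon shapefile; returns DBF field-name mapping.

    ``load_rois(write_rois(x))`` round-trips ids, geometry and attributes
    up to DBF field-name sanitization.
    """
    if not rois:
        raise ValueError("shapefile requires at least one feature")
    ids = [roi.plot_id for roi in rois]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plot ids in ROI set")
    crs_ids = {roi.crs_id for roi in rois}
    if len(crs_ids) > 1:
        raise ValueError(f"mixed CRS in ROI set: {sorted(map(str, crs_ids))}")
    records = [{ID_FIELD: roi.plot_id, **roi.attributes} for roi in rois]
    return shapefile.write_shapefile(
        Path(path), [roi.polygon for roi in rois], records, crs_id=rois[0].crs_id
    )
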