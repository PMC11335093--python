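"""Minimal ESRI shapefile (.shp/.shx/.dbf/.prj) reader and writer.

Only polygon shapefiles (shape type 5) with simple attribute tables are
needed here, so this module implements exactly that subset of the format:
multi-ring polygons with ring orientation (outer clockwise, holes
counter-clockwise), and DBF attributes of character, integer and float
type. The CRS identifier is stored verbatim in the ``.prj`` sidecar.

DBF field names are limited to 10 bytes; :func:`sanitize_field_names`
implements the truncate-plus-suffix rule used by every writer in this
package and logs the mapping.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

_SHAPE_POLYGON = 5


def sanitize_field_names(names: list[str]) -> dict[str, str]:
    """Map attribute names to unique DBF-legal (≤10 char) field names."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        candidate = name[:10]
        if candidate in used:
            i = 1
            while f"{name[:7]}_{i:02d}" in used:
                i += 1
            candidate = f"{name[:7]}_{i:02d}"
        if candidate != name:
            logger.warning("DBF field name %r sanitized to %r", name, candidate)
        mapping[name] = candidate
        used.add(candidate)
    return mapping


def _rings(polygon: Polygon) -> list[list[tuple[float, float]]]:
    """Closed rings with shapefile winding: exterior CW, holes CCW."""
    def oriented(ring, clockwise: bool):
        pts = list(ring.coords)
        if ring.is_ccw == clockwise:
            pts = pts[::-1]
        return [(float(x), float(y)) for x, y, *_ in pts]

    out = [oriented(polygon.exterior, clockwise=True)]
    out.extend(oriented(hole, clockwise=False) for hole in polygon.interiors)
    return out


def _polygon_record(polygon: Polygon) -> bytes:
    rings = _rings(polygon)
    points = [pt for ring in rings for pt in ring]
    parts, offset = [], 0
    for ring in rings:
        parts.append(offset)
        offset += len(ring)
    minx, miny, maxx, maxy = polygon.bounds
    buf = struct.pack("<i4d2i", _SHAPE_POLYGON, minx, miny, maxx, maxy,
                      len(rings), len(points))
    buf += struct.pack(f"<{len(parts)}i", *parts)
    for x, y in points:
        buf += struct.pack("<2d", x, y)
    return buf


def _parse_polygon(content: bytes) -> Polygon:
    shape_type = struct.unpack_from("<i", content, 0)[0]
    if shape_type != _SHAPE_POLYGON:
        raise ValueError(f"unsupported shape type {shape_type} (need polygon)")
    n_parts, n_points = struct.unpack_from("<2i", content, 36)
    parts = list(struct.unpack_from(f"<{n_parts}i", content, 44))
    pts_off = 44 + 4 * n_parts
    coords = struct.unpack_from(f"<{2 * n_points}d", content, pts_off)
    points = list(zip(coords[0::2], coords[1::2]))
    parts.append(n_points)
    rings = [points[parts[i]:parts[i + 1]] for i in range(n_parts)]
    # CW rings are exteriors, CCW rings are holes of the preceding exterior
    shell, holes = None, []
    polys = []
    for ring in rings:
        area2 = sum((x2 - x1) * (y2 + y1) for (x1, y1), (x2, y2)
                    in zip(ring, ring[1:]))
        is_cw = area2 > 0
        if is_cw or shell is None:
            if shell is not None:
                polys.append((shell, holes))
            shell, holes = ring, []
        else:
            holes.append(ring)
    polys.append((shell, holes))
    if len(polys) > 1:
        raise ValueError("multi-part polygons are not supported")
    return Polygon(polys[0][0], polys[0][1])


def _dbf_fields(records: list[dict]) -> list[tuple[str, str, int, int]]:
    """(name, type, length, decimals) per attribute, types inferred."""
    names: list[str] = []
    for rec in records:
        for k in rec:
            if k not in names:
                names.append(k)
    fields = []
    for name in names:
        values = [rec.get(name) for rec in records]
        if all(v is None or isinstance(v, bool) is False and isinstance(v, int)
               for v in values):
            fields.append((name, "N", 19, 0))
        elif all(v is None or isinstance(v, (int, float)) for v in values):
            # 'F' with %.17g round-trips doubles exactly
            fields.append((name, "F", 25, 0))
        else:
            width = max((len(str(v)) for v in values if v is not None), default=1)
            fields.append((name, "C", min(max(width, 1), 254), 0))
    return fields


def write_shapefile(path, geometries: list[Polygon], records: list[dict],
                    crs_id: str | None = None) -> dict[str, str]:
    """Write polygons + attributes; returns the field-name mapping used."""
    if len(geometries) != len(records):
        raise ValueError("geometry/record count mismatch")
    if not geometries:
        raise ValueError("shapefile requires at least one feature")
    path = Path(path)
    base = path.with_suffix("")

    shp_records = [_polygon_record(g) for g in geometries]
    bounds = [g.bounds for g in geometries]
    minx = min(b[0] for b in bounds)
    miny = min(b[1] for b in bounds)
    maxx = max(b[2] for b in bounds)
    maxy = max(b[3] for b in bounds)

    def header(total_words: int) -> bytes:
        return (struct.pack(">i5i i", 9994, 0, 0, 0, 0, 0, total_words)
                + struct.pack("<2i", 1000, _SHAPE_POLYGON)
                + struct.pack("<4d", minx, miny, maxx, maxy)
                + struct.pack("<4d", 0, 0, 0, 0))

    shp_len = 50 + sum(4 + len(r) // 2 for r in shp_records)
    with open(base.with_suffix(".shp"), "wb") as f:
        f.write(header(shp_len))
        for i, rec in enumerate(shp_records, start=1):
            f.write(struct.pack(">2i", i, len(rec) // 2))
            f.write(rec)

    with open(base.with_suffix(".shx"), "wb") as f:
        f.write(header(50 + 4 * len(shp_records)))
        offset = 50
        for rec in shp_records:
            f.write(struct.pack(">2i", offset, len(rec) // 2))
            offset += 4 + len(rec) // 2

    fields = _dbf_fields(records)
    mapping = sanitize_field_names([f[0] for f in fields])
    _write_dbf(base.with_suffix(".dbf"), fields, mapping, records)

    if crs_id:
        base.with_suffix(".prj").write_text(crs_id)
    return mapping


def _write_dbf(path: Path, fields, mapping, records) -> None:
    n_fields = len(fields)
    header_size = 32 + 32 * n_fields + 1
    record_size = 1 + sum(f[2] for f in fields)
    with open(path, "wb") as f:
        f.write(struct.pack("<B3Bi2H20x", 0x03, 26, 1, 1, len(records),
                            header_size, record_size))
        for name, ftype, length, decimals in fields:
            f.write(struct.pack("<11sc4xBB14x", mapping[name].encode()[:11],
                                ftype.encode(), length, decimals))
        f.write(b"\x0d")
        for rec in records:
            f.write(b" ")
            for name, ftype, length, _dec in fields:
                value = rec.get(name)
                if value is None:
                    text = ""
                elif ftype == "N":
                    text = str(int(value))
                elif ftype == "F":
                    text = format(float(value), ".17g")
                else:
                    text = str(value)
                raw = text.encode("utf-8")[:length]
                if ftype in "NF":
                    f.write(raw.rjust(length))
                else:
                    f.write(raw.ljust(length))
        f.write(b"\x1a")


def read_shapefile(path):
    """Read a polygon shapefile.

    Returns ``(geometries, records, crs_id)`` where records are dicts of
    attribute values converted back to str/int/float.
    """
    path = Path(path)
    base = path.with_suffix("")
    shp_path = base.with_suffix(".shp")
    if not shp_path.exists():
        raise FileNotFoundError(str(shp_path))

    data = shp_path.read_bytes()
    file_code, = struct.unpack_from(">i", data, 0)
    if file_code != 9994:
        raise ValueError(f"{shp_path}: not a shapefile")
    shape_type, = struct.unpack_from("<i", data, 32)
    if shape_type != _SHAPE_POLYGON:
        raise ValueError(f"{shp_path}: shape type {shape_type}, need polygon (5)")
    geometries = []
    pos = 100
    while pos < len(data):
        _rec_no, content_words = struct.unpack_from(">2i", data, pos)
        content = data[pos + 8:pos + 8 + content_words * 2]
        geometries.append(_parse_polygon(content))
        pos += 8 + content_words * 2

    records = _read_dbf(base.with_suffix(".dbf"), len(geometries))

    prj = base.with_suffix(".prj")
    crs_id = prj.read_text().strip() if prj.exists() else None
    return geometries, records, crs_id


def _read_dbf(path: Path, n_expected: int) -> list[dict]:
    if not path.exists():
        return [{} for _ in range(n_expected)]
    data = path.read_bytes()
    n_records, header_size, record_size = struct.unpack_from("<iHH", data, 4)
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        name = data[pos:pos + 11].split(b"\x00")[0].decode()
        ftype = chr(data[pos + 11])
        length = data[pos + 16]
        fields.append((name, ftype, length))
        pos += 32
    records = []
    pos = header_size
    for _ in range(n_records):
        rec = {}
        offset = pos + 1  # skip deletion flag
        for name, ftype, length in fields:
            raw = data[offset:offset + length].decode("utf-8", "replace").strip()
            offset += length
            if raw == "":
                rec[name] = None
            elif ftype == "N":
                rec[name] = int(raw)
            elif ftype == "F":
                rec[name] = float(raw)
            else:
                rec[name] = raw
        records.append(rec)
        pos += record_size
    return records
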