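import numpy as np
import pytest
from shapely.geometry import Polygon, box

from plotpheno.geodata_io import GeoTransform, RasterGrid
from plotpheno.roi_manager import PlotROI


@pytest.fixture
def transform():
    return GeoTransform(100.0, 200.0, 0.5, 0.5)


@pytest.fixture
def raster(transform):
    """3-band 8x8 float raster with no nodata."""
    rng = np.random.default_rng(42)
    return RasterGrid(rng.uniform(0.1, 0.9, (3, 8, 8)), transform,
                      crs_id="EPSG:32649")


@pytest.fixture
def square_roi(transform):
    """ROI exactly covering the 4x4 pixel block at rows/cols 2..5."""
    t = transform
    x0 = t.origin_x + 2 * t.pixel_width
    y1 = t.origin_y - 2 * t.pixel_height
    return PlotROI("P0001",
                   box(x0, y1 - 4 * t.pixel_height, x0 + 4 * t.pixel_width, y1),
                   crs_id="EPSG:32649")


def ray_cast_contains(polygon: Polygon, x: float, y: float) -> bool:
    """Independent point-in-polygon oracle (crossing number, closed boundary).

    Implemented from scratch on raw coordinates so it shares no code with
    the shapely-based production path.
    """
    def on_segment(ax, ay, bx, by):
        cross = (bx - ax) * (y - ay) - (by - ay) * (x - ax)
        if abs(cross) > 1e-12:
            return False
        return (min(ax, bx) - 1e-12 <= x <= max(ax, bx) + 1e-12
                and min(ay, by) - 1e-12 <= y <= max(ay, by) + 1e-12)

    def ring_crossings(coords):
        inside = False
        for (ax, ay), (bx, by) in zip(coords, coords[1:]):
            if on_segment(ax, ay, bx, by):
                return None  # boundary
            if (ay > y) != (by > y):
                x_int = ax + (y - ay) * (bx - ax) / (by - ay)
                if x_int > x:
                    inside = not inside
        return inside

    rings = [list(polygon.exterior.coords)]
    rings += [list(hole.coords) for hole in polygon.interiors]
    result = ring_crossings(rings[0])
    if result is None:
        return True  # on outer boundary counts as inside
    if not result:
        return False
    for hole in rings[1:]:
        hole_side = ring_crossings(hole)
        if hole_side is None:
            return True  # on hole boundary counts as inside
        if hole_side:
            return False
    return True
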