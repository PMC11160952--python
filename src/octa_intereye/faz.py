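"""Foveal avascular zone area, perimeter and circularity.

The FAZ is represented by its manually traced boundary polygon (pixel-center
vertex coordinates, implicit closure), mirroring freehand tracing in ImageJ.
Metrics:

    FAZA = shoelace area * pitch^2          [mm^2]
    FAZP = closed polyline length * pitch   [mm]
    FAZC = 4*pi*FAZA / FAZP^2               [dimensionless, (0, 1]]

Circularity equals 1 for a circle (isoperimetric bound) and decreases as the
boundary becomes more irregular; being a ratio it is invariant to scale, so
it is robust to axial-length magnification differences between eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Polygon
from skimage import measure


@dataclass(frozen=True)
class FazTrace:
    """Closed FAZ boundary polygon in pixel coordinates (x = column, y = row)."""

    polygon: np.ndarray  # (n, 2) array of (x, y) vertices, implicit closure
    pixel_pitch: float

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("FAZ trace needs >=3 (x, y) vertices")
        # drop an explicitly repeated closing vertex
        if np.allclose(poly[0], poly[-1]) and poly.shape[0] > 3:
            poly = poly[:-1]
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if not LinearRing(poly).is_simple:
            raise ValueError("FAZ trace polygon is self-intersecting")
        object.__setattr__(self, "polygon", poly)


@dataclass(frozen=True)
class FazMetrics:
    faza: float  # mm^2
    fazp: float  # mm
    fazc: float  # 4*pi*A/P^2

    def __post_init__(self) -> None:
        if not (self.faza > 0 and self.fazp > 0):
            raise ValueError("FAZ area and perimeter must be positive")


def faz_metrics(trace: FazTrace) -> FazMetrics:
    """Area, perimeter and circularity of a traced FAZ boundary."""
    ring = Polygon(trace.polygon)
    area = ring.area * trace.pixel_pitch ** 2
    perim = ring.exterior.length * trace.pixel_pitch
    return FazMetrics(faza=area, fazp=perim, fazc=4.0 * np.pi * area / perim ** 2)


def trace_from_mask(mask: np.ndarray, pixel_pitch: float) -> FazTrace:
    """Extract a FAZ boundary trace from a filled binary mask.

    Uses marching squares at level 0.5 and keeps the longest closed contour;
    intended for synthetic or software-segmented FAZ masks, where no manual
    trace exists.
    """
    mask = np.asarray(mask, dtype=float)
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ValueError("no FAZ boundary found in mask")
    boundary = max(contours, key=len)
    # find_contours returns (row, col); the trace convention is (x, y)
    return FazTrace(polygon=boundary[:, ::-1], pixel_pitch=pixel_pitch)


def read_faz_trace(path, pixel_pitch: float) -> FazTrace:
    """Read a FAZ polygon CSV (``x_px,y_px``, one vertex per row)."""
    import csv
    from pathlib import Path

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FAZ trace not found: {path}")
    verts = []
    with open(path, newline="") as fh:
        for record in csv.reader(fh):
            record = [c.strip() for c in record if c.strip()]
            if not record:
                continue
            try:
                verts.append((float(record[0]), float(record[1])))
            except ValueError:
                if not verts and record[0].lower() in {"x", "x_px"}:
                    continue
                raise ValueError(f"malformed FAZ trace row {record!r} in {path}")
    return FazTrace(polygon=np.asarray(verts), pixel_pitch=pixel_pitch)


def write_faz_trace(trace: FazTrace, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_px", "y_px"])
        for x, y in trace.polygon:
            writer.writerow([f"{x:.6f}", f"{y:.6f}"])
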