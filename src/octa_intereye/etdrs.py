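"""Fovea-centered ETDRS sector masks in pixel space.

Standard ETDRS macular grid: central subfield (1 mm diameter), inner ring
(1-3 mm) and outer ring (3-6 mm), centered on the manually annotated FAZ
center.  Each pixel is assigned by the Euclidean distance of its center from
the grid center, in mm, using half-open radial bins [0, 0.5), [0.5, 1.5),
[1.5, 3.0]; coordinates are 0-based with x = column, y = row.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

CENTRAL_RADIUS_MM = 0.5
INNER_RADIUS_MM = 1.5
OUTER_RADIUS_MM = 3.0


@dataclass(frozen=True)
class EtdrsGrid:
    """Sector masks of the ETDRS grid for one image.

    ``central``, ``inner_ring`` and ``outer_ring`` are pairwise disjoint and
    their union equals ``total`` (the full 6-mm disc) exactly by construction.
    ``clipped`` flags a grid whose 6-mm disc extends past the image border.
    """

    center: tuple[float, float]
    pixel_pitch: float
    central: np.ndarray
    inner_ring: np.ndarray
    outer_ring: np.ndarray
    total: np.ndarray
    clipped: bool

    def sector(self, name: str) -> np.ndarray:
        try:
            return {"central": self.central, "inner_ring": self.inner_ring,
                    "outer_ring": self.outer_ring, "total": self.total}[name]
        except KeyError:
            raise KeyError(f"unknown ETDRS sector {name!r}") from None


def build_grid(center: tuple[float, float], pixel_pitch: float, image_size: int) -> EtdrsGrid:
    """Build ETDRS sector masks for a square ``image_size`` x ``image_size`` image.

    ``center`` is the FAZ center in 0-based pixel coordinates (x, y).  The
    grid need not fit inside the image; a clipped grid raises a warning and
    sets ``clipped`` on the result.
    """
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx < image_size and 0 <= cy < image_size):
        raise ValueError(f"grid center {center} outside {image_size}x{image_size} image")
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r_mm = np.hypot(xx - cx, yy - cy) * pixel_pitch

    central = r_mm < CENTRAL_RADIUS_MM
    inner = (r_mm >= CENTRAL_RADIUS_MM) & (r_mm < INNER_RADIUS_MM)
    outer = (r_mm >= INNER_RADIUS_MM) & (r_mm <= OUTER_RADIUS_MM)
    total = central | inner | outer

    r_px = OUTER_RADIUS_MM / pixel_pitch
    clipped = (cx - r_px < -0.5 or cy - r_px < -0.5
               or cx + r_px > image_size - 0.5 or cy + r_px > image_size - 0.5)
    if clipped:
        warnings.warn(
            f"ETDRS 6-mm disc clipped at image border (center={center}, "
            f"radius={r_px:.1f} px, image={image_size} px)", stacklevel=2)

    return EtdrsGrid(center=(cx, cy), pixel_pitch=pixel_pitch, central=central,
                     inner_ring=inner, outer_ring=outer, total=total, clipped=clipped)


def read_faz_center(path: str | Path) -> tuple[float, float]:
    """Read a FAZ center annotation from CSV.

    Accepts either a single ``x,y`` coordinate pair (with or without an
    ``x_px,y_px`` header) or a FAZ boundary polygon (one vertex per row), in
    which case the polygon centroid is returned.  Coordinates are 0-based
    pixel positions, x = column, y = row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FAZ annotation not found: {path}")
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for record in csv.reader(fh):
            record = [c.strip() for c in record if c.strip()]
            if not record:
                continue
            try:
                x, y = float(record[0]), float(record[1])
            except (ValueError, IndexError):
                # tolerate a single header line
                if not rows and record[0].lower().lstrip("#") in {"x", "x_px"}:
                    continue
                raise ValueError(f"malformed FAZ annotation row {record!r} in {path}")
            rows.append((x, y))
    if not rows:
        raise ValueError(f"FAZ annotation {path} contains no coordinates")
    if len(rows) == 1:
        return rows[0]
    centroid = Polygon(rows).centroid
    logger.info("FAZ center %s: centroid of %d-vertex polygon", path.name, len(rows))
    return (centroid.x, centroid.y)
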