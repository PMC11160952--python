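"""Vessel density per ETDRS sector.

VD is the fraction of the measured area occupied by flow-positive capillary
pixels.  Excluded pixels (big vessels in the SCP, projection artifacts in the
DCP) are removed from numerator *and* denominator: "total area measured" is
the sector area remaining after exclusion, so density reflects the
microcirculation of the area actually assessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .etdrs import EtdrsGrid


@dataclass(frozen=True)
class SectorVD:
    """Per-sector vessel density, stored as fractions in [0, 1].

    ``measured_area_px`` / ``excluded_area_px`` give, per sector, the pixel
    counts of the denominator and of the exclusion region, for QC and exact
    pixel accounting.
    """

    vd_total: float
    vd_ir: float
    vd_or: float
    vd_central: float
    measured_area_px: dict[str, int]
    excluded_area_px: dict[str, int]


def vessel_density(capillary_mask: np.ndarray, excluded_area_mask: np.ndarray | None,
                   grid: EtdrsGrid) -> SectorVD:
    """Compute VD in the central subfield, inner ring, outer ring and 6-mm total.

    For each sector S: ``vd_S = |capillary ∩ S| / |S \\ excluded|``.  A sector
    whose measured area is empty after exclusion cannot be reported and
    raises ``ValueError`` naming the sector.
    """
    cap = np.asarray(capillary_mask, dtype=bool)
    if excluded_area_mask is None:
        excl = np.zeros_like(cap)
    else:
        excl = np.asarray(excluded_area_mask, dtype=bool)
    if cap.shape != grid.total.shape or excl.shape != grid.total.shape:
        raise ValueError("capillary/exclusion masks must match the grid image shape")
    if (cap & excl).any():
        raise ValueError("capillary mask overlaps the excluded area")

    vd: dict[str, float] = {}
    measured: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for name in ("central", "inner_ring", "outer_ring", "total"):
        sector = grid.sector(name)
        n_excl = int((sector & excl).sum())
        n_meas = int(sector.sum()) - n_excl
        if n_meas <= 0:
            raise ValueError(f"sector {name!r} has zero measured area after exclusion")
        vd[name] = int((cap & sector).sum()) / n_meas
        measured[name] = n_meas
        excluded[name] = n_excl

    return SectorVD(vd_total=vd["total"], vd_ir=vd["inner_ring"],
                    vd_or=vd["outer_ring"], vd_central=vd["central"],
                    measured_area_px=measured, excluded_area_px=excluded)
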