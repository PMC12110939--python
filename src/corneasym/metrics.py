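"""Interocular difference maps and the VBS symmetry index.

After registration, the two elevation matrices are subtracted point by point
(registered left minus right).  The VBS ("volume between spheres") index is
the arithmetic mean of the absolute elevation differences over the lattice
points of a chosen central zone, reported in micrometers.  Ring summaries
partition the zone into concentric annuli.

The volume reading of the index (mean x zone area) is exposed as the derived
``volume_mm3`` field of :class:`ZoneReport` but plays no role in thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CoverageError, DimensionError
from .grid import ElevationGrid, Zone, physical_coords, zone_lattice_mask

DEFAULT_MIN_COVERAGE = 0.90
DEFAULT_RING_WIDTH_MM = 0.5


@dataclass
class DifferenceMap:
    """Point-wise interocular elevation differences (micrometers)."""

    signed: np.ndarray  # left_registered - right, NaN outside joint mask
    mask: np.ndarray  # joint validity
    spacing_mm: float
    center: tuple

    @property
    def absolute(self) -> np.ndarray:
        return np.abs(self.signed)

    def as_grid(self) -> ElevationGrid:
        """View the signed map as an ElevationGrid for zone geometry."""
        return ElevationGrid(
            values=self.signed, spacing_mm=self.spacing_mm, center=self.center
        )


@dataclass(frozen=True)
class RingSummary:
    inner_mm: float
    outer_mm: float
    mean_abs_um: float
    max_abs_um: float
    n_points: int


@dataclass
class ZoneReport:
    zone: Zone
    vbs_um: float
    n_points: int
    coverage: float
    rings: Sequence[RingSummary] = field(default_factory=tuple)

    @property
    def volume_mm3(self) -> float:
        """Derived volume reading: mean |difference| x zone area."""
        r = self.zone.radius_mm
        return self.vbs_um * 1e-3 * np.pi * r * r


def difference_map(left_registered: ElevationGrid, right: ElevationGrid) -> DifferenceMap:
    """Signed and absolute point-wise differences with joint validity mask."""
    if left_registered.values.shape != right.values.shape:
        raise DimensionError(
            f"grid shapes differ: {left_registered.values.shape} vs {right.values.shape}"
        )
    if left_registered.spacing_mm != right.spacing_mm:
        raise DimensionError(
            f"grid spacings differ: {left_registered.spacing_mm} vs {right.spacing_mm} mm"
        )
    if tuple(left_registered.center) != tuple(right.center):
        raise DimensionError(
            f"grid centers differ: {left_registered.center} vs {right.center}"
        )
    mask = left_registered.mask & right.mask
    signed = np.where(mask, left_registered.values - right.values, np.nan)
    return DifferenceMap(
        signed=signed,
        mask=mask,
        spacing_mm=left_registered.spacing_mm,
        center=tuple(left_registered.center),
    )


def _rings(
    absolute: np.ndarray,
    r_mm: np.ndarray,
    in_zone: np.ndarray,
    zone: Zone,
    ring_width_mm: float,
) -> tuple:
    edges = np.arange(0.0, zone.radius_mm + 1e-9, ring_width_mm)
    if edges[-1] < zone.radius_mm - 1e-9:
        edges = np.append(edges, zone.radius_mm)
    elif abs(edges[-1] - zone.radius_mm) > 1e-9:
        edges[-1] = zone.radius_mm
    rings = []
    for inner, outer in zip(edges[:-1], edges[1:]):
        if inner == 0.0:
            sel = in_zone & (r_mm <= outer + 1e-12)
        else:
            sel = in_zone & (r_mm > inner + 1e-12) & (r_mm <= outer + 1e-12)
        vals = absolute[sel]
        if vals.size:
            rings.append(
                RingSummary(
                    inner_mm=float(inner),
                    outer_mm=float(outer),
                    mean_abs_um=float(vals.mean()),
                    max_abs_um=float(vals.max()),
                    n_points=int(vals.size),
                )
            )
        else:
            rings.append(
                RingSummary(float(inner), float(outer), float("nan"), float("nan"), 0)
            )
    return tuple(rings)


def vbs(
    diff: DifferenceMap,
    zone: Zone,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    ring_width_mm: float = DEFAULT_RING_WIDTH_MM,
) -> ZoneReport:
    """Mean absolute interocular difference over the zone, with ring summaries.

    Raises :class:`CoverageError` when fewer than ``min_coverage`` of the
    zone's lattice points carry a valid difference.
    """
    g = diff.as_grid()
    lattice = zone_lattice_mask(g, zone)
    n_lattice = int(lattice.sum())
    if n_lattice == 0:
        raise CoverageError(f"zone {zone} contains no lattice points")
    valid = lattice & diff.mask
    n_points = int(valid.sum())
    coverage = n_points / n_lattice
    if coverage < min_coverage:
        raise CoverageError(
            f"zone coverage {coverage:.3f} below required {min_coverage:.3f} "
            f"({n_points}/{n_lattice} points)"
        )
    absolute = diff.absolute
    vbs_val = float(absolute[valid].mean())
    x, y = physical_coords(g)
    r_mm = np.sqrt((x - zone.center_x_mm) ** 2 + (y - zone.center_y_mm) ** 2)
    rings = _rings(absolute, r_mm, valid, zone, ring_width_mm)
    return ZoneReport(
        zone=zone, vbs_um=vbs_val, n_points=n_points, coverage=coverage, rings=rings
    )
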