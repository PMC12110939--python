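"""Core data model for corneal elevation grids.

A Scheimpflug tomographer exports one square matrix of surface elevation per
corneal surface (anterior/posterior) per eye.  Elevation is stored internally
in micrometers relative to a reference (best-fit) sphere; missing points —
outside the measured footprint or dropped by the device — are NaN, never a
sentinel.

Physical coordinate convention (millimeters, origin at the grid center):

    x = (col - center_col) * spacing_mm
    y = (row - center_row) * spacing_mm   (positive superior)

The laterality of the x axis is whatever the device exported; the mirror flip
in :mod:`corneasym.transforms` makes the convention self-canceling for
symmetry analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .errors import DimensionError, ZoneExtentError

DEFAULT_N = 140
DEFAULT_SPACING_MM = 0.1


def default_center(n: int) -> Tuple[int, int]:
    """Geometric grid center, (n-1)/2 rounded to the nearest integer index."""
    c = int(round((n - 1) / 2))
    return (c, c)


@dataclass
class ElevationGrid:
    """One eye/surface elevation matrix.

    Parameters
    ----------
    values
        (n, n) float array of elevation in micrometers; NaN marks missing
        points.  Any other value must be finite.
    spacing_mm
        Grid step in millimeters (isotropic).
    center
        (row, col) index of the corneal apex / grid center.  Defaults to the
        geometric center.
    side
        "OD" (right) or "OS" (left).
    layer
        "anterior" or "posterior".
    meta
        Free-form source tags (file path, applied transforms, ...).
    """

    values: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    center: Tuple[int, int] | None = None
    side: str = "OD"
    layer: str = "anterior"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DimensionError(
                f"elevation grid must be square 2-D, got shape {self.values.shape}"
            )
        if not self.spacing_mm > 0:
            raise DimensionError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if self.center is None:
            self.center = default_center(self.n)
        if np.isinf(self.values).any():
            raise DimensionError("elevation values must be finite or NaN")
        if self.side not in ("OD", "OS"):
            raise DimensionError(f"side must be 'OD' or 'OS', got {self.side!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask: True where a measurement exists."""
        return np.isfinite(self.values)

    def copy(self, **overrides) -> "ElevationGrid":
        kwargs = dict(
            values=self.values.copy(),
            spacing_mm=self.spacing_mm,
            center=self.center,
            side=self.side,
            layer=self.layer,
            meta=dict(self.meta),
        )
        kwargs.update(overrides)
        return ElevationGrid(**kwargs)


@dataclass(frozen=True)
class Zone:
    """A circular analysis zone given by its diameter and center offset (mm)."""

    diameter_mm: float
    center_x_mm: float = 0.0
    center_y_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ZoneExtentError(f"zone diameter must be > 0, got {self.diameter_mm}")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


def physical_coords(grid: ElevationGrid) -> Tuple[np.ndarray, np.ndarray]:
    """Per-point physical coordinates (x_mm, y_mm) as two (n, n) arrays."""
    cr, cc = grid.center
    idx = np.arange(grid.n, dtype=float)
    x = (idx - cc) * grid.spacing_mm
    y = (idx - cr) * grid.spacing_mm
    return np.meshgrid(x, y)  # x varies along columns, y along rows


def _check_zone_fits(grid: ElevationGrid, zone: Zone) -> None:
    cr, cc = grid.center
    half = grid.spacing_mm * (grid.n - 1)
    x_min, x_max = -cc * grid.spacing_mm, (grid.n - 1 - cc) * grid.spacing_mm
    y_min, y_max = -cr * grid.spacing_mm, (grid.n - 1 - cr) * grid.spacing_mm
    r = zone.radius_mm
    if (
        zone.center_x_mm - r < x_min - 1e-9
        or zone.center_x_mm + r > x_max + 1e-9
        or zone.center_y_mm - r < y_min - 1e-9
        or zone.center_y_mm + r > y_max + 1e-9
    ):
        raise ZoneExtentError(
            f"zone (diameter {zone.diameter_mm} mm at "
            f"({zone.center_x_mm}, {zone.center_y_mm})) exceeds grid extent "
            f"x in [{x_min:.2f}, {x_max:.2f}] mm, y in [{y_min:.2f}, {y_max:.2f}] mm"
        )
    del half


def zone_lattice_mask(grid: ElevationGrid, zone: Zone) -> np.ndarray:
    """Lattice membership only: True where the point lies inside the zone
    circle, ignoring validity.  Used as the coverage denominator."""
    _check_zone_fits(grid, zone)
    x, y = physical_coords(grid)
    r2 = (x - zone.center_x_mm) ** 2 + (y - zone.center_y_mm) ** 2
    return r2 <= zone.radius_mm**2 + 1e-12


def zone_mask(grid: ElevationGrid, zone: Zone) -> np.ndarray:
    """Boolean (n, n) mask: inside the zone circle AND measured."""
    return zone_lattice_mask(grid, zone) & grid.mask
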