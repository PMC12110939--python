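"""The four registration adjustments: flip, shift, rotate, tilt.

Fellow eyes are enantiomorphs, so the left-eye map is mirrored (flip) before
comparison.  The remaining adjustments absorb acquisition misalignment:

* shift — in-plane decentration (dx, dy, millimeters) and a uniform elevation
  offset (dz, micrometers);
* rotate — cyclotorsion / head roll about the map center (degrees, in the
  frontal plane);
* tilt — head pitch/yaw, modeled as a planar elevation term
  ``tilt_x * x + tilt_y * y`` (micrometers per millimeter).  For the few
  degrees of tilt seen in practice on a ~tens-of-micrometers elevation range
  the planar small-angle term dominates a full 3-D rotation of the surface,
  and it makes the offset/tilt subproblem linear (see registration).

Resampling is bilinear and mask-aware: a target point is valid only when all
four supporting lattice points carry data, so transforms never invent data
across the missing-data boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError
from .grid import ElevationGrid, physical_coords


@dataclass(frozen=True)
class TransformBounds:
    """Configured limits on registration parameters."""

    shift_mm: float = 2.0
    dz_um: float = 200.0
    rot_deg: float = 15.0
    tilt_um_per_mm: float = 30.0


@dataclass(frozen=True)
class RegistrationParams:
    """Flip/shift/rotate/tilt parameter vector.

    flip is a discrete mirror-vs-direct switch; the six continuous parameters
    are what auto-registration optimizes.
    """

    flip: bool = False
    dx_mm: float = 0.0
    dy_mm: float = 0.0
    dz_um: float = 0.0
    rot_deg: float = 0.0
    tilt_x_um_per_mm: float = 0.0
    tilt_y_um_per_mm: float = 0.0

    def check_bounds(self, bounds: TransformBounds = TransformBounds()) -> None:
        vals = [
            self.dx_mm,
            self.dy_mm,
            self.dz_um,
            self.rot_deg,
            self.tilt_x_um_per_mm,
            self.tilt_y_um_per_mm,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise BoundsError(f"non-finite registration parameter in {self}")
        if abs(self.dx_mm) > bounds.shift_mm or abs(self.dy_mm) > bounds.shift_mm:
            raise BoundsError(
                f"|dx|,|dy| = ({abs(self.dx_mm)}, {abs(self.dy_mm)}) mm "
                f"exceed bound {bounds.shift_mm} mm"
            )
        if abs(self.dz_um) > bounds.dz_um:
            raise BoundsError(f"|dz| = {abs(self.dz_um)} um exceeds bound {bounds.dz_um} um")
        if abs(self.rot_deg) > bounds.rot_deg:
            raise BoundsError(
                f"|rot| = {abs(self.rot_deg)} deg exceeds bound {bounds.rot_deg} deg"
            )
        if (
            abs(self.tilt_x_um_per_mm) > bounds.tilt_um_per_mm
            or abs(self.tilt_y_um_per_mm) > bounds.tilt_um_per_mm
        ):
            raise BoundsError(
                f"tilt slopes ({self.tilt_x_um_per_mm}, {self.tilt_y_um_per_mm}) "
                f"um/mm exceed bound {bounds.tilt_um_per_mm} um/mm"
            )

    def is_identity(self) -> bool:
        return (
            not self.flip
            and self.dx_mm == self.dy_mm == self.dz_um == 0.0
            and self.rot_deg == 0.0
            and self.tilt_x_um_per_mm == self.tilt_y_um_per_mm == 0.0
        )


def apply_flip(grid: ElevationGrid) -> ElevationGrid:
    """Mirror the map about the y axis (x -> -x), reflecting about the center
    column.  A column whose mirror image falls outside the matrix becomes
    missing; for circular-footprint exports no measured point is lost."""
    n = grid.n
    _, cc = grid.center
    out = np.full_like(grid.values, np.nan)
    cols = np.arange(n)
    src = 2 * cc - cols
    ok = (src >= 0) & (src < n)
    out[:, cols[ok]] = grid.values[:, src[ok]]
    g = grid.copy(values=out)
    g.meta = dict(grid.meta, flipped=not grid.meta.get("flipped", False))
    return g


def flip_values(values: np.ndarray, center_col: int) -> np.ndarray:
    """Array-level mirror about ``center_col`` (helper for the optimizer)."""
    n = values.shape[1]
    out = np.full_like(values, np.nan)
    cols = np.arange(n)
    src = 2 * center_col - cols
    ok = (src >= 0) & (src < n)
    out[:, cols[ok]] = values[:, src[ok]]
    return out


def bilinear_sample(values: np.ndarray, row_f: np.ndarray, col_f: np.ndarray) -> np.ndarray:
    """Mask-aware bilinear sampling at fractional indices.

    Returns NaN where any of the four supporting lattice points is missing or
    the location falls outside the lattice.  Exactly-on-lattice queries return
    the lattice value untouched.
    """
    n_r, n_c = values.shape
    snap = 1e-9  # coordinate round-trip residue, well below any physical scale
    row_f = np.where(np.abs(row_f - np.round(row_f)) < snap, np.round(row_f), row_f)
    col_f = np.where(np.abs(col_f - np.round(col_f)) < snap, np.round(col_f), col_f)
    r0 = np.floor(row_f).astype(int)
    c0 = np.floor(col_f).astype(int)
    fr = row_f - r0
    fc = col_f - c0

    # on-lattice queries: collapse to a single supporting point so that a
    # valid lattice point next to the missing boundary stays usable
    exact_r = fr == 0.0
    exact_c = fc == 0.0

    r1 = np.where(exact_r, r0, r0 + 1)
    c1 = np.where(exact_c, c0, c0 + 1)

    inside = (r0 >= 0) & (r1 <= n_r - 1) & (c0 >= 0) & (c1 <= n_c - 1)
    r0c = np.clip(r0, 0, n_r - 1)
    r1c = np.clip(r1, 0, n_r - 1)
    c0c = np.clip(c0, 0, n_c - 1)
    c1c = np.clip(c1, 0, n_c - 1)

    v00 = values[r0c, c0c]
    v01 = values[r0c, c1c]
    v10 = values[r1c, c0c]
    v11 = values[r1c, c1c]

    w00 = (1 - fr) * (1 - fc)
    w01 = (1 - fr) * fc
    w10 = fr * (1 - fc)
    w11 = fr * fc

    out = w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11
    # NaN * 0 is NaN, so zero-weight missing corners must be healed explicitly
    zero_contrib = (
        ((w01 == 0) & ~np.isfinite(v01))
        | ((w10 == 0) & ~np.isfinite(v10))
        | ((w11 == 0) & ~np.isfinite(v11))
    )
    if np.any(zero_contrib):
        alt = (
            w00 * v00
            + np.where(w01 == 0, 0.0, w01 * v01)
            + np.where(w10 == 0, 0.0, w10 * v10)
            + np.where(w11 == 0, 0.0, w11 * v11)
        )
        out = np.where(zero_contrib, alt, out)
    out = np.where(inside, out, np.nan)
    return out


def source_coords(
    x: np.ndarray, y: np.ndarray, params: RegistrationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Physical source location sampled for each target point (x, y):
    the inverse in-plane motion R_{-rot}(x - dx, y - dy)."""
    th = np.deg2rad(params.rot_deg)
    c, s = np.cos(th), np.sin(th)
    xs = x - params.dx_mm
    ys = y - params.dy_mm
    u = c * xs + s * ys
    v = -s * xs + c * ys
    return u, v


def apply_transform(
    grid: ElevationGrid,
    params: RegistrationParams,
    bounds: TransformBounds = TransformBounds(),
) -> ElevationGrid:
    """Resample ``grid`` under the registration parameters.

    Output elevation at physical point (x, y):

        E(R_{-rot}(x - dx, y - dy)) + dz + tilt_x * x + tilt_y * y

    where E is the mask-aware bilinear interpolant of the (flipped, if
    ``params.flip``) input.  Points whose source location lacks valid data are
    missing in the output.
    """
    params.check_bounds(bounds)
    src = apply_flip(grid) if params.flip else grid
    if params.is_identity():
        return src.copy()

    x, y = physical_coords(src)
    u, v = source_coords(x, y, params)
    cr, cc = src.center
    row_f = v / src.spacing_mm + cr
    col_f = u / src.spacing_mm + cc
    sampled = bilinear_sample(src.values, row_f, col_f)
    plane = params.dz_um + params.tilt_x_um_per_mm * x + params.tilt_y_um_per_mm * y
    out = sampled + plane
    g = src.copy(values=out)
    g.meta = dict(src.meta, registered=True)
    return g
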