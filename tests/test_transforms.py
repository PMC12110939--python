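"""Flip/shift/rotate/tilt transforms and their contracts."""

import numpy as np
import pytest

from corneasym.errors import BoundsError
from corneasym.grid import ElevationGrid, physical_coords
from corneasym.transforms import (
    RegistrationParams,
    TransformBounds,
    apply_flip,
    apply_transform,
)


def gaussian_field(x, y, cx, cy, amp=10.0, sigma=0.8):
    return amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))


class TestFlip:
    def test_marker_mirrors_about_y_axis(self, footprint_grid):
        g = footprint_grid()
        x, y = physical_coords(g)
        g.values[np.isfinite(g.values)] = 0.0
        marker = (np.abs(x - 2.0) < 1e-9) & (np.abs(y) < 1e-9)
        g.values[marker] = 5.0
        f = apply_flip(g)
        xi, yi = physical_coords(f)
        assert f.values[(np.abs(xi + 2.0) < 1e-9) & (np.abs(yi) < 1e-9)] == 5.0

    def test_involution_on_footprint(self, footprint_grid):
        rng = np.random.default_rng(3)
        g = footprint_grid(values=rng.normal(size=(140, 140)))
        gg = apply_flip(apply_flip(g))
        assert np.array_equal(g.mask, gg.mask)
        assert np.array_equal(g.values[g.mask], gg.values[gg.mask])

    def test_rotationally_symmetric_grid_unchanged(self, footprint_grid):
        g = footprint_grid()
        x, y = physical_coords(g)
        g.values[:] = np.where(g.mask, x**2 + y**2, np.nan)
        f = apply_flip(g)
        assert np.allclose(f.values[f.mask], g.values[f.mask])


class TestTransform:
    def test_identity_params_exact(self, footprint_grid):
        rng = np.random.default_rng(5)
        g = footprint_grid(values=rng.normal(size=(140, 140)))
        out = apply_transform(g, RegistrationParams())
        assert np.array_equal(g.mask, out.mask)
        assert np.max(np.abs(out.values[out.mask] - g.values[g.mask])) < 1e-9

    def test_dz_pure_offset(self, footprint_grid):
        rng = np.random.default_rng(6)
        g = footprint_grid(values=rng.normal(size=(140, 140)))
        out = apply_transform(g, RegistrationParams(dz_um=5.0))
        assert np.allclose(out.values[out.mask], g.values[out.mask] + 5.0)

    def test_tilt_exactly_linear(self, footprint_grid):
        rng = np.random.default_rng(8)
        g = footprint_grid(values=rng.normal(size=(140, 140)))
        params = RegistrationParams(dz_um=2.0, tilt_x_um_per_mm=3.0,
                                    tilt_y_um_per_mm=-1.5)
        out = apply_transform(g, params)
        x, y = physical_coords(g)
        both = g.mask & out.mask
        plane = 2.0 + 3.0 * x + -1.5 * y
        assert np.allclose(out.values[both] - g.values[both], plane[both])

    def test_rotation_moves_gaussian_bump(self, footprint_grid):
        # oracle: evaluate the analytic Gaussian at rotated coordinates
        g = footprint_grid()
        x, y = physical_coords(g)
        g.values[:] = np.where(g.mask, gaussian_field(x, y, 2.0, 0.0), np.nan)
        out = apply_transform(g, RegistrationParams(rot_deg=90.0),
                              TransformBounds(rot_deg=90.0))
        # bump should now sit at (0, 2): rotating the map by +90 deg carries
        # the feature from (2, 0) to the 90-deg-rotated location
        th = np.pi / 2
        expect = gaussian_field(x * np.cos(th) + y * np.sin(th),
                                -x * np.sin(th) + y * np.cos(th), 2.0, 0.0)
        both = out.mask
        assert np.max(np.abs(out.values[both] - expect[both])) < 0.1 * 10.0 * 0.01 + 0.05
        peak_idx = np.unravel_index(np.nanargmax(out.values), out.values.shape)
        assert abs(x[peak_idx]) < 0.11 and abs(y[peak_idx] - 2.0) < 0.11
        assert np.nanmax(out.values) > 10.0 * 0.99

    def test_shift_then_unshift_restores_interior(self, footprint_grid):
        g = footprint_grid()
        x, y = physical_coords(g)
        g.values[:] = np.where(g.mask, gaussian_field(x, y, 0.5, -0.5, sigma=1.5), np.nan)
        fwd = apply_transform(g, RegistrationParams(dx_mm=0.37, dy_mm=-0.21))
        back = apply_transform(fwd, RegistrationParams(dx_mm=-0.37, dy_mm=0.21))
        both = back.mask & g.mask
        central = (x**2 + y**2) < 4.0
        err = np.abs(back.values - g.values)[both & central]
        assert err.max() < 0.05  # two bilinear resamples of a smooth field

    def test_mask_shrinkage_only(self, footprint_grid):
        g = footprint_grid()
        x, y = physical_coords(g)
        hole = (x - 1.0) ** 2 + y**2 < 1.0
        g.values[hole] = np.nan
        params = RegistrationParams(dx_mm=0.25, dy_mm=0.15, rot_deg=2.0)
        out = apply_transform(g, params)
        # every valid output point must map back to a fully valid bilinear cell
        from corneasym.transforms import source_coords
        u, v = source_coords(x, y, params)
        inside_hole_src = (u - 1.0) ** 2 + v**2 < (1.0 - 0.15) ** 2
        assert not (out.mask & inside_hole_src).any()

    def test_out_of_bounds_named(self):
        g = ElevationGrid(np.zeros((20, 20)))
        with pytest.raises(BoundsError, match="15.0 deg"):
            apply_transform(g, RegistrationParams(rot_deg=20.0))
        with pytest.raises(BoundsError, match="2.0 mm"):
            apply_transform(g, RegistrationParams(dx_mm=3.0))

    def test_params_at_bounds_evaluated(self):
        g = ElevationGrid(np.zeros((20, 20)))
        out = apply_transform(g, RegistrationParams(rot_deg=15.0, dx_mm=0.1))
        assert out is not None
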