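"""Auto-registration: inner L1 solver, convergence, determinism, symmetry."""

import itertools

import numpy as np
import pytest

from corneasym.grid import Zone
from corneasym.registration import (
    RegistrationConfig,
    auto_register,
    evaluate,
    l1_plane_fit,
)
from corneasym.synthetic import PairSpec, make_pair
from corneasym.transforms import RegistrationParams, apply_flip


@pytest.fixture(scope="module")
def twin_pair(realistic_base):
    return make_pair(PairSpec(base=realistic_base))


class TestInnerSolver:
    def test_l1_fit_beats_parameter_lattice(self):
        """The IRLS plane fit must reach at least the best mean absolute
        residual found by brute force over a 3-D (dz, tx, ty) lattice."""
        rng = np.random.default_rng(13)
        x = rng.uniform(-2, 2, 400)
        y = rng.uniform(-2, 2, 400)
        signed = 3.0 - 1.5 * x + 0.8 * y + rng.laplace(scale=0.7, size=400)
        dz, tx, ty, best = l1_plane_fit(signed, x, y)
        grid = np.linspace(-4, 4, 21)
        brute = min(
            np.mean(np.abs(signed + a + b * x + c * y))
            for a, b, c in itertools.product(grid, grid, grid)
        )
        assert best <= brute + 1e-9

    def test_recovers_exact_plane(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(-2, 2, 200)
        y = rng.uniform(-2, 2, 200)
        signed = -2.0 + 0.5 * x - 1.25 * y
        dz, tx, ty, resid = l1_plane_fit(signed, x, y)
        assert resid < 1e-8
        assert (dz, tx, ty) == pytest.approx((2.0, -0.5, 1.25), abs=1e-6)


class TestEvaluate:
    def test_mirror_twin_zero(self, twin_pair):
        od, osg, _ = twin_pair
        _, rep = evaluate(osg, od, RegistrationParams(flip=True), Zone(4.0))
        assert rep.vbs_um < 1e-9

    def test_dz_cancels_constant_offset(self, twin_pair):
        od, osg, _ = twin_pair
        od_up = od.copy(values=od.values + 4.0)
        _, rep = evaluate(
            osg, od_up, RegistrationParams(flip=True, dz_um=4.0), Zone(4.0)
        )
        assert rep.vbs_um < 1e-9

    def test_pure_function(self, twin_pair):
        od, osg, _ = twin_pair
        p = RegistrationParams(flip=True, dx_mm=0.1, rot_deg=1.0)
        _, r1 = evaluate(osg, od, p, Zone(4.0))
        _, r2 = evaluate(osg, od, p, Zone(4.0))
        assert r1.vbs_um == r2.vbs_um


class TestAutoRegister:
    def test_mirror_twin_reaches_global_minimum(self, twin_pair):
        od, osg, _ = twin_pair
        res = auto_register(osg, od)
        assert res.report.vbs_um < 1e-6
        assert abs(res.params.dx_mm) < 0.01
        assert abs(res.params.dy_mm) < 0.01
        assert abs(res.params.rot_deg) < 0.05
        assert res.params.flip

    def test_recovers_injected_misalignment_noiseless(self, realistic_base):
        mis = RegistrationParams(
            flip=True, dx_mm=0.3, dy_mm=-0.15, rot_deg=4.0, dz_um=5.0,
            tilt_x_um_per_mm=6.0, tilt_y_um_per_mm=-2.0,
        )
        od, osg, truth = make_pair(PairSpec(base=realistic_base, misalignment=mis))
        res = auto_register(osg, od)
        assert res.report.vbs_um < 0.1
        assert res.params.dx_mm == pytest.approx(mis.dx_mm, abs=0.05 * 0.3 + 0.01)
        assert res.params.dy_mm == pytest.approx(mis.dy_mm, abs=0.05 * 0.15 + 0.01)
        assert res.params.rot_deg == pytest.approx(mis.rot_deg, rel=0.05)
        assert res.params.tilt_x_um_per_mm == pytest.approx(6.0, rel=0.05)
        assert res.params.dz_um == pytest.approx(5.0, rel=0.1)

    def test_trace_is_monotone_non_increasing(self, realistic_base):
        mis = RegistrationParams(flip=True, dx_mm=0.2, rot_deg=-3.0)
        od, osg, _ = make_pair(
            PairSpec(base=realistic_base, misalignment=mis, noise_sd_um=1.0, seed=3)
        )
        res = auto_register(osg, od)
        vals = [t.vbs_um for t in res.trace]
        assert len(vals) >= 2
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_bit_identical_trace_on_rerun(self, realistic_base):
        od, osg, _ = make_pair(
            PairSpec(base=realistic_base,
                     misalignment=RegistrationParams(flip=True, dx_mm=0.25),
                     noise_sd_um=0.5, seed=21)
        )
        r1 = auto_register(osg, od)
        r2 = auto_register(osg, od)
        assert len(r1.trace) == len(r2.trace)
        for a, b in zip(r1.trace, r2.trace):
            assert a.iteration == b.iteration
            assert a.vbs_um == b.vbs_um
            assert a.params == b.params

    def test_left_right_symmetry_noiseless(self, realistic_base):
        mis = RegistrationParams(flip=True, dx_mm=0.2, dy_mm=0.1, rot_deg=2.0)
        od, osg, _ = make_pair(PairSpec(base=realistic_base, misalignment=mis))
        v_lr = auto_register(osg, od).report.vbs_um
        v_rl = auto_register(od, osg).report.vbs_um
        assert abs(v_lr - v_rl) < 0.05

    def test_auto_symmetry_prefers_mirror_on_mirror_pair(self, twin_pair):
        od, osg, _ = twin_pair
        cfg = RegistrationConfig(symmetry="auto")
        res = auto_register(osg, od, config=cfg)
        assert res.params.flip  # tie or win goes to mirror
        assert res.report.vbs_um < 1e-6

    def test_direct_symmetry_on_direct_pair(self, realistic_base):
        # a pair that is a direct (unmirrored) copy: flip=False must win
        od, osg, _ = make_pair(PairSpec(base=realistic_base))
        direct_left = apply_flip(osg)  # undo the anatomy mirror
        cfg = RegistrationConfig(symmetry="auto")
        res = auto_register(direct_left, od, config=cfg)
        assert not res.params.flip
        assert res.report.vbs_um < 1e-6
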