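"""Simulator: conicoid sagitta, pair construction, cohorts, noise model."""

import numpy as np
import pytest

from corneasym.grid import Zone, physical_coords, zone_mask
from corneasym.io import read_manifest
from corneasym.metrics import difference_map
from corneasym.registration import evaluate
from corneasym.synthetic import (
    ConeSpec,
    CorneaDelta,
    CorneaSpec,
    PairSpec,
    conic_sagitta,
    correlated_noise,
    generate_cohort,
    make_cohort,
    make_pair,
    render_surface,
)
from corneasym.transforms import RegistrationParams


class TestRenderSurface:
    def test_reference_sphere_is_zero_elevation(self):
        spec = CorneaSpec(apical_radius_mm=7.8, asphericity_q=0.0)
        g = render_surface(spec)
        assert np.nanmax(np.abs(g.values)) < 1e-9

    def test_conic_sagitta_closed_form(self):
        r, bigr, q = 2.0, 7.8, -0.25
        expected = r**2 / (bigr * (1 + np.sqrt(1 - (1 + q) * r**2 / bigr**2)))
        assert conic_sagitta(np.array(r), bigr, q) == pytest.approx(expected, abs=1e-15)
        # and the rendered elevation equals conic minus reference sphere there
        g = render_surface(CorneaSpec(apical_radius_mm=bigr, asphericity_q=q))
        sphere = r**2 / (bigr * (1 + np.sqrt(1 - r**2 / bigr**2)))
        assert g.values[70, 90] == pytest.approx((expected - sphere) * 1000.0, abs=1e-9)

    def test_cone_adds_amplitude_at_center_exactly(self):
        base = CorneaSpec()
        coned = CorneaSpec(cone=ConeSpec(amplitude_um=20.0, sigma_mm=0.8))
        g0 = render_surface(base)
        g1 = render_surface(coned)
        assert g1.values[70, 70] - g0.values[70, 70] == pytest.approx(20.0)

    def test_circular_footprint(self):
        g = render_surface(CorneaSpec(footprint_diameter_mm=12.0))
        x, y = physical_coords(g)
        assert not g.mask[x**2 + y**2 > 36.0 + 1e-9].any()
        assert g.mask[x**2 + y**2 <= 36.0 - 1e-9].all()
        # ~20k points measured on a 140x140 grid, as on the real device
        assert 10000 < g.mask.sum() < 19600


class TestMakePair:
    def test_perfect_twin_identity_difference(self, realistic_base):
        od, osg, truth = make_pair(PairSpec(base=realistic_base))
        _, rep = evaluate(osg, od, RegistrationParams(flip=True), Zone(4.0))
        assert rep.vbs_um < 1e-9
        assert truth.vbs_4mm_um < 1e-9

    def test_deterministic_from_seed(self, realistic_base):
        spec = PairSpec(base=realistic_base, noise_sd_um=2.0, seed=5)
        a = make_pair(spec)
        b = make_pair(spec)
        assert np.array_equal(a[0].values, b[0].values, equal_nan=True)
        assert np.array_equal(a[1].values, b[1].values, equal_nan=True)

    def test_unilateral_cone_raises_central_vbs_by_bump_mean(self, realistic_base):
        cone = ConeSpec(amplitude_um=25.0, sigma_mm=1.0,
                        center_x_mm=0.8, center_y_mm=-0.8)  # inferotemporal
        od, osg, truth = make_pair(
            PairSpec(base=realistic_base, right_delta=CorneaDelta(cone=cone))
        )
        # oracle: lattice mean of the analytic bump over the 4 mm zone
        x, y = physical_coords(od)
        in4 = zone_mask(od, Zone(4.0))
        bump = 25.0 * np.exp(
            -((x - 0.8) ** 2 + (y + 0.8) ** 2) / (2 * 1.0**2)
        )
        assert truth.vbs_4mm_um == pytest.approx(bump[in4].mean(), rel=1e-9)
        assert truth.vbs_4mm_um > truth.vbs_6mm_um  # cone is central

    def test_ground_truth_params_align_exactly(self, realistic_base):
        mis = RegistrationParams(flip=True, dx_mm=0.33, dy_mm=-0.12,
                                 rot_deg=2.5, dz_um=-4.0,
                                 tilt_x_um_per_mm=3.0, tilt_y_um_per_mm=-5.0)
        od, osg, truth = make_pair(PairSpec(base=realistic_base, misalignment=mis))
        _, rep = evaluate(osg, od, truth.params, Zone(4.0))
        assert rep.vbs_um < 0.05  # bilinear interpolation error only

    @pytest.mark.parametrize("sd", [0.5, 1.0, 2.0, 4.0])
    def test_noise_floor_folded_normal_at_identity(self, realistic_base, sd):
        """Independent per-eye noise -> mean |difference| = 2 sigma / sqrt(pi)."""
        vals = []
        for seed in range(3):
            od, osg, _ = make_pair(
                PairSpec(base=realistic_base, noise_sd_um=sd, seed=40 + seed)
            )
            _, rep = evaluate(osg, od, RegistrationParams(flip=True), Zone(4.0))
            vals.append(rep.vbs_um)
        floor = 2 * sd / np.sqrt(np.pi)
        assert np.mean(vals) == pytest.approx(floor, rel=0.10)

    def test_white_noise_option(self, realistic_base):
        rng = np.random.default_rng(0)
        f = correlated_noise(rng, (200, 200), 2.0, 0.0)
        assert f.std() == pytest.approx(2.0, rel=0.05)


class TestCohort:
    def test_cohort_files_reproducible_bytes(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_cohort(1, 1, d1, scenario="separated", seed=9)
        make_cohort(1, 1, d2, scenario="separated", seed=9)
        for sub in sorted(p.name for p in d1.iterdir()):
            assert (d1 / sub).read_bytes() == (d2 / sub).read_bytes()
        m = read_manifest(d1 / "manifest.csv")
        assert len(m) == 2
        assert {e.label for e in m.entries} == {"normal", "keratoconus"}

    def test_generate_cohort_labels_and_grids(self):
        pairs = generate_cohort(2, 3, "null", seed=1, layers=("anterior",))
        assert [p.label for p in pairs] == ["normal"] * 2 + ["keratoconus"] * 3
        assert len({p.pair_id for p in pairs}) == 5
        od, osg = pairs[0].anterior
        assert od.side == "OD" and osg.side == "OS"
        d = difference_map(osg, od)  # same geometry, subtractable
        assert d.mask.any()
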