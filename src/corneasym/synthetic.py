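"""Synthetic fellow-eye elevation pairs with controlled asymmetry.

Corneal surfaces are modeled as conicoids (apical radius R, asphericity Q)
with optional toric astigmatism and a Gaussian ectatic cone; elevation is
expressed in micrometers relative to a fixed reference sphere of configured
radius, mimicking device elevation maps (raw sagitta would be hundreds of
micrometers and scale-incompatible with clinical VBS values).  The conicoid
sagitta is

    z(r) = r^2 / ( R * (1 + sqrt(1 - (1+Q) r^2 / R^2)) )        [mm]

Fellow eyes are enantiomorphs: the left-eye surface is the mirror (x -> -x)
of the right-eye base surface; interocular biology (radius/asphericity/
astigmatism deltas, a cone in one eye) is injected as per-field perturbations
on the right eye.  Acquisition misalignment (decentration, cyclotorsion,
head tilt) is injected *analytically*: the left-eye grid is the exact
surface evaluated on misaligned coordinates, so the injected
:class:`RegistrationParams` are, by construction, the parameters a perfect
registration should recover.

Measurement noise is zero-mean Gaussian with marginal SD ``noise_sd_um`` and
a short spatial correlation length (default one grid step), reflecting the
smoothing inherent in Scheimpflug surface reconstruction; white noise is
available via ``noise_corr_mm = 0``.  Optional per-eye "irregularity" adds an
independent smooth random surface component (correlation ~1.5 mm) emulating
normal corneal micro-irregularity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ZoneExtentError
from .grid import DEFAULT_N, DEFAULT_SPACING_MM, ElevationGrid, Zone, default_center
from .io import CohortManifest, ManifestEntry, write_elevation_csv, write_manifest
from .transforms import RegistrationParams


@dataclass(frozen=True)
class ConeSpec:
    """Gaussian ectatic bump: elevation += amplitude * exp(-d^2 / (2 sigma^2))."""

    amplitude_um: float
    sigma_mm: float
    center_x_mm: float = 0.0
    center_y_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("cone amplitude must be >= 0")
        if not self.sigma_mm > 0:
            raise ValueError("cone sigma must be > 0")


@dataclass(frozen=True)
class CorneaSpec:
    """One corneal surface: conicoid + toricity + optional cone."""

    apical_radius_mm: float = 7.8  # anterior default; posterior ~6.5
    asphericity_q: float = -0.25
    cyl_um: float = 0.0  # astigmatic elevation amplitude at the footprint edge
    axis_deg: float = 0.0
    cone: Optional[ConeSpec] = None
    footprint_diameter_mm: float = 12.0

    def __post_init__(self) -> None:
        if not self.apical_radius_mm > 0:
            raise ValueError("apical radius must be > 0")
        if not self.footprint_diameter_mm > 0:
            raise ValueError("footprint diameter must be > 0")


@dataclass(frozen=True)
class CorneaDelta:
    """Per-field perturbation of a base spec (applied to the right eye)."""

    d_apical_radius_mm: float = 0.0
    d_asphericity_q: float = 0.0
    d_cyl_um: float = 0.0
    d_axis_deg: float = 0.0
    cone: Optional[ConeSpec] = None  # replaces the base cone if set


def apply_delta(base: CorneaSpec, delta: CorneaDelta) -> CorneaSpec:
    return CorneaSpec(
        apical_radius_mm=base.apical_radius_mm + delta.d_apical_radius_mm,
        asphericity_q=base.asphericity_q + delta.d_asphericity_q,
        cyl_um=base.cyl_um + delta.d_cyl_um,
        axis_deg=base.axis_deg + delta.d_axis_deg,
        cone=delta.cone if delta.cone is not None else base.cone,
        footprint_diameter_mm=base.footprint_diameter_mm,
    )


@dataclass(frozen=True)
class PairSpec:
    """Recipe for one fellow-eye pair.

    ``shared_irregularity_sd_um`` is a smooth random higher-order surface
    component common to both eyes (mirrored into the left eye), emulating the
    well-documented mirror correlation of fellow-eye higher-order shape.  It
    cancels in a perfectly registered difference map but provides the spatial
    landmarks that make decentration/cyclotorsion identifiable — registration
    against a purely quadratic surface is degenerate, because a shifted
    quadratic differs from the original by exactly a plane, which the tilt
    correction absorbs.  ``irregularity_sd_um`` is the per-eye *independent*
    counterpart and contributes residual interocular asymmetry.
    """

    base: CorneaSpec = CorneaSpec()
    right_delta: CorneaDelta = CorneaDelta()
    misalignment: RegistrationParams = RegistrationParams(flip=True)
    noise_sd_um: float = 0.0
    noise_corr_mm: float = 0.1
    shared_irregularity_sd_um: float = 2.5
    shared_irregularity_scale_mm: float = 3.0
    irregularity_sd_um: float = 0.0
    irregularity_corr_mm: float = 1.5
    seed: int = 0


@dataclass
class PairGroundTruth:
    """What the simulator injected, for oracle comparisons."""

    params: RegistrationParams  # the parameters registration should recover
    vbs_4mm_um: float  # noise-free mirror-registered VBS, 4 mm zone
    vbs_6mm_um: float


def conic_sagitta(r_mm: np.ndarray, radius_mm: float, q: float) -> np.ndarray:
    """Closed-form conicoid sagitta (mm); NaN beyond the conic's domain."""
    r2 = np.asarray(r_mm, dtype=float) ** 2
    disc = 1.0 - (1.0 + q) * r2 / radius_mm**2
    with np.errstate(invalid="ignore"):
        return r2 / (radius_mm * (1.0 + np.sqrt(np.where(disc >= 0, disc, np.nan))))


def surface_function(
    spec: CorneaSpec, reference_radius_mm: Optional[float] = None
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Analytic elevation field (micrometers) as a function of (x, y) in mm.

    Elevation = conicoid sagitta - reference-sphere sagitta, plus the toric
    term ``cyl * cos^2(theta - axis) * (r / r_max)^2``, plus the cone bump;
    NaN outside the circular footprint.
    """
    ref_r = spec.apical_radius_mm if reference_radius_mm is None else reference_radius_mm
    r_max = spec.footprint_diameter_mm / 2.0
    axis = np.deg2rad(spec.axis_deg)

    def f(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.sqrt(x**2 + y**2)
        z = (
            conic_sagitta(r, spec.apical_radius_mm, spec.asphericity_q)
            - conic_sagitta(r, ref_r, 0.0)
        ) * 1000.0
        if spec.cyl_um != 0.0:
            theta = np.arctan2(y, x)
            z = z + spec.cyl_um * np.cos(theta - axis) ** 2 * (r / r_max) ** 2
        if spec.cone is not None:
            c = spec.cone
            d2 = (x - c.center_x_mm) ** 2 + (y - c.center_y_mm) ** 2
            z = z + c.amplitude_um * np.exp(-d2 / (2.0 * c.sigma_mm**2))
        return np.where(r <= r_max + 1e-12, z, np.nan)

    return f


def _lattice(n: int, spacing_mm: float) -> Tuple[np.ndarray, np.ndarray]:
    cr, cc = default_center(n)
    idx = np.arange(n, dtype=float)
    return np.meshgrid((idx - cc) * spacing_mm, (idx - cr) * spacing_mm)


def render_surface(
    spec: CorneaSpec,
    n: int = DEFAULT_N,
    spacing_mm: float = DEFAULT_SPACING_MM,
    reference_radius_mm: Optional[float] = None,
    side: str = "OD",
    layer: str = "anterior",
) -> ElevationGrid:
    """Evaluate the surface on the lattice as an :class:`ElevationGrid`."""
    if spec.footprint_diameter_mm > (n - 1) * spacing_mm:
        raise ZoneExtentError(
            f"footprint {spec.footprint_diameter_mm} mm exceeds grid extent "
            f"{(n - 1) * spacing_mm:.1f} mm"
        )
    x, y = _lattice(n, spacing_mm)
    values = surface_function(spec, reference_radius_mm)(x, y)
    return ElevationGrid(
        values=values, spacing_mm=spacing_mm, side=side, layer=layer,
        meta={"synthetic": True},
    )


def random_smooth_field(
    rng: np.random.Generator,
    sd_um: float,
    scale_mm: float,
    n_waves: int = 40,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Analytic zero-mean random field: a sum of cosines with random
    directions, wavelengths near ``scale_mm``, and phases, normalized to the
    requested SD.  Being closed-form, it can be evaluated on warped
    coordinates exactly — which is what lets injected misalignment remain an
    exact ground truth."""
    wavelength = rng.uniform(0.7 * scale_mm, 1.6 * scale_mm, size=n_waves)
    direction = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    amp = rng.standard_normal(n_waves)
    amp = amp * sd_um / np.sqrt(np.sum(amp**2) / 2.0)
    kx = 2.0 * np.pi / wavelength * np.cos(direction)
    ky = 2.0 * np.pi / wavelength * np.sin(direction)

    def f(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        return np.sum(amp * np.cos(kx * x + ky * y + phase), axis=-1)

    return f


def correlated_noise(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    sd_um: float,
    corr_px: float,
) -> np.ndarray:
    """Zero-mean Gaussian field with marginal SD ``sd_um``; ``corr_px > 0``
    low-pass filters white noise to the given correlation length (the
    realization is rescaled to the requested SD)."""
    white = rng.standard_normal(shape)
    if corr_px > 0:
        f = ndimage.gaussian_filter(white, corr_px, mode="reflect")
        f = f / f.std()
    else:
        f = white
    return f * sd_um


def make_pair(
    pair: PairSpec,
    n: int = DEFAULT_N,
    spacing_mm: float = DEFAULT_SPACING_MM,
    reference_radius_mm: Optional[float] = None,
    layer: str = "anterior",
) -> Tuple[ElevationGrid, ElevationGrid, PairGroundTruth]:
    """Render one fellow-eye pair (OD, OS) plus ground truth.

    OD is the base surface with ``right_delta`` applied.  OS is the mirror of
    the base surface, acquired under the injected misalignment: its grid
    holds the exact analytic surface evaluated on misaligned coordinates, so
    registering OS (flip + ``ground_truth.params``) onto OD reproduces the
    base surface exactly up to interpolation error.  Noise and irregularity
    are then added per eye (seeded).
    """
    ref_r = (
        pair.base.apical_radius_mm
        if reference_radius_mm is None
        else reference_radius_mm
    )
    od_spec = apply_delta(pair.base, pair.right_delta)
    s_od_conic = surface_function(od_spec, ref_r)
    s_base_conic = surface_function(pair.base, ref_r)

    ss = np.random.SeedSequence(pair.seed)
    rngs = [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(5)]
    if pair.shared_irregularity_sd_um > 0:
        shared = random_smooth_field(
            rngs[0], pair.shared_irregularity_sd_um, pair.shared_irregularity_scale_mm
        )
        s_od = lambda x, y: s_od_conic(x, y) + shared(x, y)
        s_base = lambda x, y: s_base_conic(x, y) + shared(x, y)
    else:
        s_od, s_base = s_od_conic, s_base_conic

    x, y = _lattice(n, spacing_mm)
    od_vals = s_od(x, y)

    t = pair.misalignment
    th = np.deg2rad(t.rot_deg)
    c, s = np.cos(th), np.sin(th)
    # OS(x, y) = S_base(R_rot(-x, y) + d) - dz - tilt . (R_rot(-x, y) + d)
    px = c * (-x) - s * y + t.dx_mm
    py = s * (-x) + c * y + t.dy_mm
    os_vals = s_base(px, py) - t.dz_um - t.tilt_x_um_per_mm * px - t.tilt_y_um_per_mm * py

    # ground truth: noise-free mirror-registered comparison of the two eyes
    base_vals = s_base(x, y)
    gt_diff = np.abs(od_vals - base_vals)
    gt = {}
    for diam in (4.0, 6.0):
        zone = Zone(diameter_mm=diam)
        r2 = x**2 + y**2
        sel = (r2 <= zone.radius_mm**2 + 1e-12) & np.isfinite(gt_diff)
        gt[diam] = float(np.nanmean(gt_diff[sel])) if sel.any() else float("nan")

    corr_px = pair.noise_corr_mm / spacing_mm
    irr_px = pair.irregularity_corr_mm / spacing_mm
    if pair.noise_sd_um > 0:
        od_vals = od_vals + correlated_noise(rngs[0], od_vals.shape, pair.noise_sd_um, corr_px)
        os_vals = os_vals + correlated_noise(rngs[1], os_vals.shape, pair.noise_sd_um, corr_px)
    if pair.irregularity_sd_um > 0:
        od_vals = od_vals + correlated_noise(
            rngs[2], od_vals.shape, pair.irregularity_sd_um, irr_px
        )
        os_vals = os_vals + correlated_noise(
            rngs[3], os_vals.shape, pair.irregularity_sd_um, irr_px
        )

    od = ElevationGrid(
        values=od_vals, spacing_mm=spacing_mm, side="OD", layer=layer,
        meta={"synthetic": True, "seed": pair.seed},
    )
    osg = ElevationGrid(
        values=os_vals, spacing_mm=spacing_mm, side="OS", layer=layer,
        meta={"synthetic": True, "seed": pair.seed},
    )
    truth = PairGroundTruth(
        params=dataclasses.replace(t, flip=True),
        vbs_4mm_um=gt[4.0],
        vbs_6mm_um=gt[6.0],
    )
    return od, osg, truth


# ---------------------------------------------------------------------------
# cohort scenarios


@dataclass(frozen=True)
class ScenarioConfig:
    """Distributional recipe for a synthetic screening cohort.

    Defaults emulate a clinical screening setting: modest interocular
    differences in curvature/asphericity/astigmatism in everyone, acquisition
    misalignment in everyone, and a decentered Gaussian cone in cases only.
    """

    name: str = "separated"
    anterior_base: CorneaSpec = CorneaSpec(
        apical_radius_mm=7.8, cyl_um=70.0, axis_deg=90.0
    )
    posterior_base: CorneaSpec = CorneaSpec(
        apical_radius_mm=6.5, cyl_um=90.0, axis_deg=90.0
    )
    noise_sd_um: float = 2.5
    noise_corr_mm: float = 0.1
    shared_irregularity_sd_um: float = 2.5
    shared_irregularity_scale_mm: float = 3.0
    irregularity_sd_um: float = 7.0
    posterior_noise_scale: float = 1.5
    posterior_cone_scale: float = 1.3
    # interocular biology (both groups)
    d_radius_sd_mm: float = 0.2
    d_q_sd: float = 0.08
    d_cyl_max_um: float = 12.0
    d_axis_max_deg: float = 30.0
    # acquisition misalignment (both groups)
    shift_max_mm: float = 0.3
    dz_max_um: float = 10.0
    rot_max_deg: float = 3.0
    tilt_max_um_per_mm: float = 5.0
    # case pathology (cone confined to the central ~4 mm)
    cone_amplitude_um: Tuple[float, float] = (40.0, 85.0)
    cone_sigma_mm: Tuple[float, float] = (0.6, 1.2)
    cone_decenter_max_mm: float = 1.5
    cases_have_cone: bool = True


def scenario_config(name: str) -> ScenarioConfig:
    if name == "separated":
        return ScenarioConfig(name="separated")
    if name == "null":
        return ScenarioConfig(name="null", cases_have_cone=False)
    raise ValueError(f"unknown scenario {name!r}; expected 'separated' or 'null'")


@dataclass
class CohortPair:
    pair_id: str
    label: str
    anterior: Tuple[ElevationGrid, ElevationGrid]  # (OD, OS)
    posterior: Tuple[ElevationGrid, ElevationGrid]
    ground_truth: PairGroundTruth  # anterior-layer ground truth


def _draw_pair_specs(
    rng: np.random.Generator, scenario: ScenarioConfig, is_case: bool, seed: int
) -> Tuple[PairSpec, PairSpec]:
    """Draw (anterior, posterior) pair specs sharing biology and head pose."""
    delta_kw = dict(
        d_apical_radius_mm=rng.normal(0.0, scenario.d_radius_sd_mm),
        d_asphericity_q=rng.normal(0.0, scenario.d_q_sd),
        d_cyl_um=rng.uniform(0.0, scenario.d_cyl_max_um),
        d_axis_deg=rng.uniform(-scenario.d_axis_max_deg, scenario.d_axis_max_deg),
    )
    cone = post_cone = None
    if is_case and scenario.cases_have_cone:
        amp = rng.uniform(*scenario.cone_amplitude_um)
        sig = rng.uniform(*scenario.cone_sigma_mm)
        rad = rng.uniform(0.0, scenario.cone_decenter_max_mm)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = rad * np.cos(ang), rad * np.sin(ang)
        cone = ConeSpec(amplitude_um=amp, sigma_mm=sig, center_x_mm=cx, center_y_mm=cy)
        post_cone = ConeSpec(
            amplitude_um=amp * scenario.posterior_cone_scale,
            sigma_mm=sig,
            center_x_mm=cx,
            center_y_mm=cy,
        )
    mis = RegistrationParams(
        flip=True,
        dx_mm=rng.uniform(-scenario.shift_max_mm, scenario.shift_max_mm),
        dy_mm=rng.uniform(-scenario.shift_max_mm, scenario.shift_max_mm),
        dz_um=rng.uniform(-scenario.dz_max_um, scenario.dz_max_um),
        rot_deg=rng.uniform(-scenario.rot_max_deg, scenario.rot_max_deg),
        tilt_x_um_per_mm=rng.uniform(
            -scenario.tilt_max_um_per_mm, scenario.tilt_max_um_per_mm
        ),
        tilt_y_um_per_mm=rng.uniform(
            -scenario.tilt_max_um_per_mm, scenario.tilt_max_um_per_mm
        ),
    )
    common = dict(
        misalignment=mis,
        noise_corr_mm=scenario.noise_corr_mm,
        shared_irregularity_sd_um=scenario.shared_irregularity_sd_um,
        shared_irregularity_scale_mm=scenario.shared_irregularity_scale_mm,
        irregularity_sd_um=scenario.irregularity_sd_um,
    )
    ant = PairSpec(
        base=scenario.anterior_base,
        right_delta=CorneaDelta(cone=cone, **delta_kw),
        noise_sd_um=scenario.noise_sd_um,
        seed=seed,
        **common,
    )
    post = PairSpec(
        base=scenario.posterior_base,
        right_delta=CorneaDelta(cone=post_cone, **delta_kw),
        noise_sd_um=scenario.noise_sd_um * scenario.posterior_noise_scale,
        seed=seed + 1,
        **common,
    )
    return ant, post


def generate_cohort(
    n_normal: int,
    n_case: int,
    scenario: ScenarioConfig | str = "separated",
    seed: int = 0,
    n: int = DEFAULT_N,
    spacing_mm: float = DEFAULT_SPACING_MM,
    layers: Tuple[str, ...] = ("anterior", "posterior"),
) -> List[CohortPair]:
    """Draw a reproducible in-memory cohort of fellow-eye pairs."""
    if isinstance(scenario, str):
        scenario = scenario_config(scenario)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pairs: List[CohortPair] = []
    specs = [("normal", i) for i in range(n_normal)] + [
        ("keratoconus", i) for i in range(n_case)
    ]
    for k, (label, i) in enumerate(specs):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        ant_spec, post_spec = _draw_pair_specs(
            rng, scenario, label == "keratoconus", pair_seed
        )
        ant = (
            make_pair(ant_spec, n=n, spacing_mm=spacing_mm, layer="anterior")
            if "anterior" in layers
            else None
        )
        post = (
            make_pair(post_spec, n=n, spacing_mm=spacing_mm, layer="posterior")
            if "posterior" in layers
            else None
        )
        pairs.append(
            CohortPair(
                pair_id=f"{label[:3]}{i:03d}",
                label=label,
                anterior=ant[:2] if ant else None,
                posterior=post[:2] if post else None,
                ground_truth=ant[2] if ant else (post[2] if post else None),
            )
        )
    return pairs


def make_cohort(
    n_normal: int,
    n_case: int,
    out_dir,
    scenario: ScenarioConfig | str = "separated",
    seed: int = 0,
    n: int = DEFAULT_N,
    spacing_mm: float = DEFAULT_SPACING_MM,
) -> CohortManifest:
    """Generate a cohort and write grids plus a manifest CSV to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = generate_cohort(n_normal, n_case, scenario, seed, n, spacing_mm)
    entries = []
    for p in pairs:
        paths = {}
        for layer, (od, osg) in (("anterior", p.anterior), ("posterior", p.posterior)):
            for side, g in (("od", od), ("os", osg)):
                rel = f"{p.pair_id}_{side}_{layer}.csv"
                write_elevation_csv(g, out_dir / rel)
                paths[f"{side}_{layer}_path"] = rel
        entries.append(ManifestEntry(pair_id=p.pair_id, label=p.label, **paths))
    manifest = CohortManifest(entries=entries, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
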