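"""Rule-based classification of interocular symmetry patterns.

Registered fellow-eye difference maps fall into a small set of canonical
patterns: "flat" (highly symmetric, normal), "tilt" (residual plane —
imaging/visual-axis discrepancy or failed registration), "cone" (central
dome, the keratoconus signature), "4-leaf" (quadrant pattern from
aniso-astigmatism or direct symmetry with astigmatism), or "irregular".

The rule set works on the low-order Zernike spectrum of the *signed*
difference over the analysis zone, coordinates normalized to the zone
radius.  With the orthonormal basis, squared coefficients are energies;
piston carries no shape information and is excluded throughout:

* non-piston RMS below ``flat_threshold_um``            -> flat
* tilt energy (Z1^-1, Z1^1) dominant                    -> tilt
* defocus+spherical (Z2^0, Z4^0) dominant, with a real
  central peak (|reconstruction at the origin| >= RMS)  -> cone
* astigmatism energy (Z2^-2, Z2^2) dominant             -> four_leaf
* no group reaching the dominance fraction              -> irregular
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .errors import CoverageError
from .grid import Zone, physical_coords, zone_lattice_mask
from .metrics import DEFAULT_MIN_COVERAGE, DifferenceMap
from .zernike import MODES, fit_zernike, mode_index, zernike_term

LABELS = ("flat", "tilt", "cone", "four_leaf", "irregular")

_GROUPS = {
    "tilt": ((1, -1), (1, 1)),
    "cone": ((2, 0), (4, 0)),
    "four_leaf": ((2, -2), (2, 2)),
}


@dataclass(frozen=True)
class ClassifierConfig:
    flat_threshold_um: float = 3.0  # non-piston RMS below this is "flat"
    dominance: float = 0.5  # fraction of non-piston energy a group must carry
    min_coverage: float = DEFAULT_MIN_COVERAGE


@dataclass
class PatternLabel:
    label: str
    scores: Dict[str, float]
    features: Dict[str, float]  # Zernike coefficients, micrometers

    def __post_init__(self) -> None:
        assert self.label in LABELS


def classify_pattern(
    diff: DifferenceMap,
    zone: Zone,
    config: ClassifierConfig = ClassifierConfig(),
) -> PatternLabel:
    """Classify the signed difference map over ``zone``."""
    g = diff.as_grid()
    lattice = zone_lattice_mask(g, zone)
    valid = lattice & diff.mask
    n_lattice = int(lattice.sum())
    coverage = valid.sum() / max(n_lattice, 1)
    if n_lattice == 0 or coverage < config.min_coverage:
        raise CoverageError(
            f"pattern classification needs coverage >= {config.min_coverage:.2f}, "
            f"got {coverage:.3f}"
        )

    x, y = physical_coords(g)
    xs = (x[valid] - zone.center_x_mm) / zone.radius_mm
    ys = (y[valid] - zone.center_y_mm) / zone.radius_mm
    rho = np.sqrt(xs**2 + ys**2)
    theta = np.arctan2(ys, xs)
    coeffs, _ = fit_zernike(diff.signed[valid], rho, theta)

    features = {f"Z{n}_{m}": float(c) for (n, m), c in zip(MODES, coeffs)}
    nonpiston = coeffs.copy()
    nonpiston[mode_index(0, 0)] = 0.0
    total_energy = float(np.sum(nonpiston**2))
    rms = float(np.sqrt(total_energy))

    if rms < config.flat_threshold_um:
        return PatternLabel(label="flat", scores={"flat": 1.0}, features=features)

    fractions = {
        name: float(
            sum(coeffs[mode_index(n, m)] ** 2 for n, m in modes) / total_energy
        )
        for name, modes in _GROUPS.items()
    }

    # central non-piston reconstruction; only m = 0 terms are nonzero at rho=0
    zero = np.zeros(1)
    v0 = float(
        sum(
            coeffs[mode_index(n, 0)] * zernike_term(n, 0, zero, zero)[0]
            for n in (2, 4)
        )
    )

    winner = max(fractions, key=lambda k: fractions[k])
    dominant = fractions[winner] >= config.dominance
    if dominant and winner == "cone" and abs(v0) < rms:
        dominant = False  # dome-less radial structure is not a cone pattern

    scores = dict(fractions)
    scores["irregular"] = max(0.0, 1.0 - max(fractions.values()))
    if not dominant:
        scores["irregular"] = max(scores["irregular"], max(fractions.values()) + 1e-9)
        winner = "irregular"
    total = sum(scores.values())
    if total > 0:
        scores = {k: v / total for k, v in scores.items()}
    return PatternLabel(label=winner, scores=scores, features=features)
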