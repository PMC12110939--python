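"""Orthonormal Zernike polynomials on the unit disc, radial order <= 4.

OSA/ANSI double indexing (n, m): m < 0 are sine terms, m > 0 cosine, with the
orthonormal scaling N_n^m = sqrt(2(n+1)/(1+delta_{m0})) so that the mean
square of each basis function over the disc is 1.  With that scaling a
coefficient is the RMS contribution of its term, and sums of squared
coefficients are energies.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

# (n, m) for all terms through radial order 4, OSA ordering
MODES: Tuple[Tuple[int, int], ...] = (
    (0, 0),
    (1, -1),
    (1, 1),
    (2, -2),
    (2, 0),
    (2, 2),
    (3, -3),
    (3, -1),
    (3, 1),
    (3, 3),
    (4, -4),
    (4, -2),
    (4, 0),
    (4, 2),
    (4, 4),
)

_RADIAL = {
    (0, 0): lambda r: np.ones_like(r),
    (1, 1): lambda r: r,
    (2, 0): lambda r: 2 * r**2 - 1,
    (2, 2): lambda r: r**2,
    (3, 1): lambda r: 3 * r**3 - 2 * r,
    (3, 3): lambda r: r**3,
    (4, 0): lambda r: 6 * r**4 - 6 * r**2 + 1,
    (4, 2): lambda r: 4 * r**4 - 3 * r**2,
    (4, 4): lambda r: r**4,
}


def zernike_term(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike Z_n^m evaluated at polar points (rho, theta)."""
    radial = _RADIAL[(n, abs(m))](rho)
    norm = np.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    if m == 0:
        ang = 1.0
    elif m > 0:
        ang = np.cos(m * theta)
    else:
        ang = np.sin(-m * theta)
    return norm * radial * ang


def design_matrix(rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(npoints, 15) matrix of the order-<=4 orthonormal basis."""
    return np.column_stack([zernike_term(n, m, rho, theta) for n, m in MODES])


def fit_zernike(
    values: np.ndarray, rho: np.ndarray, theta: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Least-squares Zernike coefficients (order <= 4) of scattered samples.

    Returns (coefficients in MODES order, RMS of the fit residual).
    """
    a = design_matrix(rho, theta)
    coeffs, *_ = np.linalg.lstsq(a, values, rcond=None)
    resid = values - a @ coeffs
    return coeffs, float(np.sqrt(np.mean(resid**2)))


def mode_index(n: int, m: int) -> int:
    return MODES.index((n, m))
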