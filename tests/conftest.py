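import numpy as np
import pytest

from corneasym.grid import ElevationGrid
from corneasym.metrics import DifferenceMap
from corneasym.synthetic import CorneaSpec


@pytest.fixture(scope="session")
def realistic_base() -> CorneaSpec:
    """A typical normal anterior cornea: prolate conicoid with ~1.3 D of
    with-the-rule astigmatism."""
    return CorneaSpec(apical_radius_mm=7.8, asphericity_q=-0.25,
                      cyl_um=70.0, axis_deg=90.0)


@pytest.fixture
def footprint_grid():
    """Factory: a grid with a circular measured footprint (corners missing),
    optionally with a given elevation field."""

    def _make(values=None, n=140, spacing=0.1, footprint_mm=12.0):
        cr = cc = int(round((n - 1) / 2))
        idx = np.arange(n, dtype=float)
        x, y = np.meshgrid((idx - cc) * spacing, (idx - cr) * spacing)
        vals = np.zeros((n, n)) if values is None else np.asarray(values, float)
        vals = np.where(x**2 + y**2 <= (footprint_mm / 2) ** 2, vals, np.nan)
        return ElevationGrid(values=vals, spacing_mm=spacing)

    return _make


def make_diff(signed: np.ndarray, spacing: float = 0.1) -> DifferenceMap:
    """Wrap a raw signed field as a DifferenceMap (mask = finite)."""
    n = signed.shape[0]
    c = int(round((n - 1) / 2))
    return DifferenceMap(
        signed=signed, mask=np.isfinite(signed), spacing_mm=spacing, center=(c, c)
    )
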