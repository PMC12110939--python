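"""Rendering of signed difference maps.

Diverging palette symmetric about zero with limits at the 99th percentile of
the absolute difference (robust to outliers), zone circles overlaid.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .grid import Zone
from .metrics import DifferenceMap


def render_difference_map(
    diff: DifferenceMap,
    path,
    zones=(Zone(4.0), Zone(6.0)),
    title: str = "Interocular elevation difference",
) -> None:
    signed = diff.signed
    n = signed.shape[0]
    cr, cc = diff.center
    extent = [
        (0 - cc) * diff.spacing_mm,
        (n - 1 - cc) * diff.spacing_mm,
        (0 - cr) * diff.spacing_mm,
        (n - 1 - cr) * diff.spacing_mm,
    ]
    finite = signed[np.isfinite(signed)]
    vmax = float(np.percentile(np.abs(finite), 99)) if finite.size else 1.0
    vmax = max(vmax, 1e-6)

    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    im = ax.imshow(
        signed,
        origin="lower",
        extent=extent,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    for zone in zones:
        circle = plt.Circle(
            (zone.center_x_mm, zone.center_y_mm),
            zone.radius_mm,
            fill=False,
            color="k",
            lw=0.8,
            ls="--",
        )
        ax.add_patch(circle)
        ax.annotate(
            f"{zone.diameter_mm:g} mm",
            (zone.center_x_mm, zone.center_y_mm + zone.radius_mm),
            ha="center",
            va="bottom",
            fontsize=7,
        )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="elevation difference (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
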