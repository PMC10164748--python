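"""Isobologram construction for checkerboard results.

The isobologram plots every tested MOI ratio of a two-species consortium
with the FICI synergy cut-off drawn as a line: on linear axes the locus
FICI == cut is the straight chord from (cut * mMOI_A, 0) to
(0, cut * mMOI_B), so a point lies on or below the chord exactly when its
FICI is at or below the cut-off.  Synergistic MOI ratios are marked in
green.  A log-scale variant is offered for readability of grids spanning
three decades; there the same locus is drawn as a curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # deterministic, head-less rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .checkerboard import CellVerdict, ConsortiumResult, compute_fici

__all__ = ["AxisScale", "IsobologramSpec", "build_isobologram", "render", "points_to_frame"]


class AxisScale(str, Enum):
    LINEAR = "LINEAR"
    LOG = "LOG"


@dataclass
class IsobologramSpec:
    """Plot-ready description of one consortium's isobologram."""

    axis_a_label: str
    axis_b_label: str
    points: list[tuple[float, float, CellVerdict]]
    cutoff_line: tuple[tuple[float, float], tuple[float, float]]
    scale: AxisScale = AxisScale.LINEAR
    fici_cut: float = 0.5
    mmoi_a: float = 1.0
    mmoi_b: float = 1.0


def build_isobologram(
    result: ConsortiumResult, fici_cut: float = 0.5, scale: AxisScale = AxisScale.LINEAR
) -> IsobologramSpec:
    """Points and cut-off line for one evaluated consortium.

    Geometric consistency holds by construction on the linear scale: a point
    (a, b) is on/below the chord iff a/(cut*mMOI_A) + b/(cut*mMOI_B) <= 1
    iff FICI(a, b) <= cut.
    """
    design = result.design
    mmoi_a, mmoi_b = design.mmoi_a.exact_value, design.mmoi_b.exact_value
    points = [
        (c.moi_a.exact_value, c.moi_b.exact_value, c.verdict) for c in result.cells
    ]
    cutoff = ((fici_cut * mmoi_a, 0.0), (0.0, fici_cut * mmoi_b))
    return IsobologramSpec(
        axis_a_label=design.species_a,
        axis_b_label=design.species_b,
        points=points,
        cutoff_line=cutoff,
        scale=scale,
        fici_cut=fici_cut,
        mmoi_a=mmoi_a,
        mmoi_b=mmoi_b,
    )


_VERDICT_STYLE = {
    CellVerdict.SYNERGY: dict(color="#1a9641", marker="o", label="synergistic"),
    CellVerdict.ADDITIVE_OR_NONE: dict(color="#404040", marker="o", label="additive / none"),
    CellVerdict.ANTAGONISM: dict(color="#d7191c", marker="s", label="antagonistic"),
    CellVerdict.NOT_EVALUABLE: dict(color="#bdbdbd", marker="x", label="not evaluable"),
}


def render(spec: IsobologramSpec, path) -> None:
    """Write a deterministic PNG of the isobologram (fixed size and styling;
    identical spec -> byte-identical file)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5), dpi=100)
    for verdict, style in _VERDICT_STYLE.items():
        xs = [p[0] for p in spec.points if p[2] is verdict]
        ys = [p[1] for p in spec.points if p[2] is verdict]
        if xs:
            ax.scatter(xs, ys, s=40, zorder=3, **style)
    (x0, _), (_, y1) = spec.cutoff_line
    if spec.scale is AxisScale.LINEAR:
        ax.plot([x0, 0.0], [0.0, y1], color="#1a9641", lw=1.5, zorder=2,
                label=f"FICI = {spec.fici_cut:g}")
    else:
        # curved image of the same FICI == cut locus on log axes
        t = np.linspace(1e-3, 1.0 - 1e-3, 200)
        ax.plot(t * x0, (1.0 - t) * y1, color="#1a9641", lw=1.5, zorder=2,
                label=f"FICI = {spec.fici_cut:g}")
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel(f"{spec.axis_a_label} MOI")
    ax.set_ylabel(f"{spec.axis_b_label} MOI")
    ax.legend(loc="upper right", fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "lungsynergy"})
    plt.close(fig)


def points_to_frame(spec: IsobologramSpec) -> pd.DataFrame:
    """Companion CSV of plotted coordinates for figure-free environments."""
    rows = [
        {
            "moi_a": repr(a),
            "moi_b": repr(b),
            "fici": f"{compute_fici(a, spec.mmoi_a, b, spec.mmoi_b):.6f}",
            "verdict": verdict.value,
        }
        for a, b, verdict in spec.points
    ]
    return pd.DataFrame(rows, columns=["moi_a", "moi_b", "fici", "verdict"])
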