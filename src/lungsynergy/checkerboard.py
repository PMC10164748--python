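"""Modified checkerboard design and FICI-based synergy classification.

Two anti-inflammatory species are combined on a 4x4 grid of 1:4 serial
dilutions, each ladder anchored at the species' minimal effective MOI for
NF-κB inhibition (mMOI).  For every MOI ratio the fractional inhibitory
concentration index

    FICI = MOI_consortium_A / mMOI_A + MOI_consortium_B / mMOI_B

is computed on exact ladder values.  A cell is synergistic when
FICI <= 0.5 *and* the combination inhibits the stimulated read-out by more
than 50% with BH-adjusted q < 0.05; FICI >= 4 is antagonism; anything else
is additivity / no interaction.  A consortium is synergistic when at least
one of its 16 MOI ratios is.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import (
    AssayKind,
    AssayMeasurement,
    Condition,
    ControlKind,
    MoiLevel,
    Stimulus,
    normalize,
)
from .screening import ConditionSummary, classify_condition
from .stats import attach_qvalues, test_vs_null

__all__ = [
    "CellVerdict",
    "CheckerboardDesign",
    "CheckerboardCell",
    "ConsortiumResult",
    "generate_design",
    "compute_fici",
    "format_fici",
    "classify_cell",
    "max_theoretical_synergy",
    "evaluate_consortium",
    "report_table",
]

logger = logging.getLogger(__name__)

#: absolute tolerance for comparisons of exact-arithmetic FICI values
FICI_TOL = 1e-9


class CellVerdict(str, Enum):
    SYNERGY = "SYNERGY"
    ADDITIVE_OR_NONE = "ADDITIVE_OR_NONE"
    ANTAGONISM = "ANTAGONISM"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class CheckerboardDesign:
    """Full-factorial grid of two dilution ladders (row-major descending)."""

    species_a: str
    species_b: str
    ladder_a: tuple[MoiLevel, ...]
    ladder_b: tuple[MoiLevel, ...]

    @property
    def cells(self) -> list[tuple[MoiLevel, MoiLevel]]:
        return [(a, b) for a in self.ladder_a for b in self.ladder_b]

    @property
    def mmoi_a(self) -> MoiLevel:
        return self.ladder_a[0]

    @property
    def mmoi_b(self) -> MoiLevel:
        return self.ladder_b[0]


@dataclass
class CheckerboardCell:
    """One MOI ratio of the consortium with its FICI and effect evidence."""

    moi_a: MoiLevel
    moi_b: MoiLevel
    mmoi_a: MoiLevel
    mmoi_b: MoiLevel
    fici: float
    verdict: CellVerdict
    summary: ConditionSummary | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def mean_activation(self) -> float | None:
        return self.summary.mean if self.summary is not None else None

    @property
    def q_value(self) -> float | None:
        return self.summary.q_value if self.summary is not None else None


@dataclass
class ConsortiumResult:
    design: CheckerboardDesign
    cells: list[CheckerboardCell]

    @property
    def synergy_cells(self) -> list[CheckerboardCell]:
        return [c for c in self.cells if c.verdict is CellVerdict.SYNERGY]

    @property
    def n_synergistic_cells(self) -> int:
        return len(self.synergy_cells)

    @property
    def synergistic(self) -> bool:
        return self.n_synergistic_cells >= 1

    @property
    def n_theoretical_max(self) -> int:
        return max_theoretical_synergy(self.design)


def generate_design(
    species_a: str,
    mmoi_a: MoiLevel | None,
    species_b: str,
    mmoi_b: MoiLevel | None,
    n_levels: int = 4,
    dilution: float = 4.0,
) -> CheckerboardDesign:
    """Checkerboard grid: each species' ladder starts at its mMOI and
    descends ``n_levels`` steps by 1:``dilution``."""
    for name, mmoi in ((species_a, mmoi_a), (species_b, mmoi_b)):
        if mmoi is None:
            raise ValueError(f"species {name!r} has no mMOI; cannot anchor a checkerboard")
    ladder_a = [MoiLevel(mmoi_a.base, mmoi_a.step + k, dilution) for k in range(n_levels)]
    ladder_b = [MoiLevel(mmoi_b.base, mmoi_b.step + k, dilution) for k in range(n_levels)]
    return CheckerboardDesign(species_a, species_b, tuple(ladder_a), tuple(ladder_b))


def compute_fici(moi_a: float, mmoi_a: float, moi_b: float, mmoi_b: float) -> float:
    """FICI on exact dose values; rounding is display-only (``format_fici``)."""
    moi_a, moi_b = float(moi_a), float(moi_b)
    mmoi_a, mmoi_b = float(mmoi_a), float(mmoi_b)
    if mmoi_a <= 0 or mmoi_b <= 0:
        raise ValueError("single-species mMOI values must be positive")
    if moi_a <= 0 or moi_b <= 0:
        raise ValueError("consortium MOI values must be positive")
    return moi_a / mmoi_a + moi_b / mmoi_b


def format_fici(fici: float) -> str:
    """Two-decimal display form (0.3125 -> '0.31', 0.265625 -> '0.27')."""
    return f"{fici:.2f}"


def classify_cell(
    fici: float,
    summary: ConditionSummary | None,
    fici_synergy: float = 0.5,
    fici_antagonism: float = 4.0,
    threshold_pct: float = 50.0,
    alpha: float = 0.05,
) -> tuple[CellVerdict, list[str]]:
    """Verdict for one MOI ratio.

    FICI <= 0.5 is inclusive (cells printed "0.50" count); the synergy call
    additionally requires > 50% inhibition at q < alpha.  A FICI-passing
    cell whose effect criteria fail is additive, flagged so the failure
    reason (magnitude vs significance) stays auditable.
    """
    flags: list[str] = []
    if summary is None or summary.n < 3:
        return CellVerdict.NOT_EVALUABLE, ["fewer than 3 replicates"]
    if fici >= fici_antagonism - FICI_TOL:
        return CellVerdict.ANTAGONISM, flags
    if fici <= fici_synergy + FICI_TOL:
        if classify_condition(summary, threshold_pct, alpha):
            return CellVerdict.SYNERGY, flags
        flags.append("fici_pass_effect_fail")
        if summary.mean >= threshold_pct:
            flags.append(f"mean {summary.mean:.2f}% not below {threshold_pct:g}%")
        q = summary.q_value
        if q is None or q >= alpha:
            flags.append("not significant")
    return CellVerdict.ADDITIVE_OR_NONE, flags


def max_theoretical_synergy(design: CheckerboardDesign, fici_synergy: float = 0.5) -> int:
    """Number of grid cells whose FICI can be at or below the synergy
    cut-off — a pure function of the dilution fractions.  For the standard
    4x4 1:4 design (fractions 1, 1/4, 1/16, 1/64) this is 9 of 16."""
    count = 0
    for a, b in design.cells:
        fici = compute_fici(a.exact_value, design.mmoi_a.exact_value,
                            b.exact_value, design.mmoi_b.exact_value)
        if fici <= fici_synergy + FICI_TOL:
            count += 1
    return count


def evaluate_consortium(
    design: CheckerboardDesign,
    measurements: Sequence[AssayMeasurement],
    stimulus: Stimulus = Stimulus.LPS,
    fici_synergy: float = 0.5,
    fici_antagonism: float = 4.0,
    threshold_pct: float = 50.0,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> ConsortiumResult:
    """Run the full per-consortium analysis.

    Normalizes the luminescence wells to the plate's stimulus-alone control,
    tests each of the 16 cells against 100%, BH-adjusts over the cells of
    this checkerboard (one family per consortium), and classifies each cell.
    """
    lum = [
        m
        for m in measurements
        if m.condition.assay is AssayKind.NFKB_LUM and m.condition.stimulus is stimulus
    ]
    normalized = normalize(lum, ControlKind.STIMULUS_ALONE)
    groups: dict[tuple[float, float], list[float]] = {}
    for v in normalized:
        c = v.condition
        if c.species_a == design.species_a and c.species_b == design.species_b:
            key = (c.moi_a.exact_value, c.moi_b.exact_value)
            groups.setdefault(key, []).append(v.percent_of_control)

    missing = [
        (a.nominal, b.nominal)
        for a, b in design.cells
        if (a.exact_value, b.exact_value) not in groups
    ]
    if missing:
        raise ValueError(f"checkerboard data missing cells: {missing}")

    summaries: dict[tuple[float, float], ConditionSummary] = {}
    testable = []
    for (a, b) in design.cells:
        key = (a.exact_value, b.exact_value)
        values = np.asarray(groups[key], float)
        if len(values) >= 3:
            condition = Condition(
                design.species_a, a, design.species_b, b, stimulus, AssayKind.NFKB_LUM
            )
            summary = ConditionSummary(
                condition, values, test_vs_null(values, 100.0, alpha_normality)
            )
            summaries[key] = summary
            testable.append(summary)
    attach_qvalues([s.result for s in testable])

    cells = []
    for a, b in design.cells:
        key = (a.exact_value, b.exact_value)
        fici = compute_fici(
            a.exact_value, design.mmoi_a.exact_value, b.exact_value, design.mmoi_b.exact_value
        )
        summary = summaries.get(key)
        verdict, flags = classify_cell(
            fici, summary, fici_synergy, fici_antagonism, threshold_pct, alpha
        )
        if flags:
            logger.info(
                "cell (%s, %s) FICI %s -> %s [%s]",
                a.nominal, b.nominal, format_fici(fici), verdict.value, "; ".join(flags),
            )
        cells.append(CheckerboardCell(a, b, design.mmoi_a, design.mmoi_b, fici, verdict, summary, flags))
    return ConsortiumResult(design, cells)


def report_table(results: Sequence[ConsortiumResult]) -> pd.DataFrame:
    """Summary of synergistic MOI ratios (one row per SYNERGY cell):
    consortium doses, mean activation, printed FICI, and the single-species
    mMOI anchors.  Deterministic ordering."""
    rows = []
    for result in results:
        design = result.design
        for cell in sorted(
            result.synergy_cells,
            key=lambda c: (-c.moi_a.exact_value, -c.moi_b.exact_value),
        ):
            rows.append(
                {
                    "species_a": design.species_a,
                    "species_b": design.species_b,
                    "moi_a": cell.moi_a.nominal,
                    "moi_b": cell.moi_b.nominal,
                    "activation_pct": f"{cell.mean_activation:.2f}",
                    "fici": format_fici(cell.fici),
                    "mmoi_a": design.mmoi_a.nominal,
                    "mmoi_b": design.mmoi_b.nominal,
                }
            )
    columns = [
        "species_a", "species_b", "moi_a", "moi_b",
        "activation_pct", "fici", "mmoi_a", "mmoi_b",
    ]
    return pd.DataFrame(rows, columns=columns)
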