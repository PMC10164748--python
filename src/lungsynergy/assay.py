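"""Domain types and plate-level operations for host–microbe co-culture assays.

The experimental unit is a well of lung epithelial cells exposed to one or
two commensal bacterial species at a given multiplicity of infection (MOI),
with or without a pro-inflammatory stimulus (LPS or H2O2), read out by one
of four assays: NF-κB luciferase luminescence, IL-8 ELISA, intracellular-LDH
viability, or CFU host association.

Doses live on a 1:4 serial-dilution ladder.  :class:`MoiLevel` stores the
exact value ``base * 4**(-step)`` so that dose ratios (and hence FICI values
downstream) are computed without cumulative rounding; a display ``nominal``
reproduces the conventional short form ("3.13", "0.78", "0.2", "0.003").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Stimulus",
    "AssayKind",
    "ControlKind",
    "MoiLevel",
    "Condition",
    "AssayMeasurement",
    "NormalizedValue",
    "moi_to_cfu",
    "build_ladder",
    "normalize",
    "read_measurements_csv",
    "measurements_to_frame",
    "normalized_to_frame",
]


class Stimulus(str, Enum):
    """Pro-inflammatory stimulus applied to the well."""

    LPS = "LPS"
    H2O2 = "H2O2"
    NONE = "NONE"


class AssayKind(str, Enum):
    """Read-out used for the well."""

    NFKB_LUM = "NFKB_LUM"
    IL8_ELISA = "IL8_ELISA"
    LDH_VIABILITY = "LDH_VIABILITY"
    CFU_ASSOC = "CFU_ASSOC"


class ControlKind(str, Enum):
    """Which control condition defines 100% for normalization."""

    STIMULUS_ALONE = "STIMULUS_ALONE"
    UNINFECTED = "UNINFECTED"


def _nominal(value: float) -> str:
    """Short display form of an MOI: two decimals, half away from zero,
    falling back to one significant digit when two decimals would print 0,
    with trailing zeros dropped (0.78125 -> "0.78", 0.1953125 -> "0.2",
    0.0030517578125 -> "0.003")."""
    d = Decimal(repr(value))
    q = d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if q == 0 and d != 0:
        exponent = math.floor(math.log10(abs(value)))
        q = d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_UP)
    text = format(q.normalize(), "f")
    return text


@dataclass(frozen=True)
class MoiLevel:
    """One exact dose on a 1:4 (or other) dilution ladder.

    Parameters
    ----------
    base:
        Ladder anchor (e.g. 50, or a species' minimal effective MOI).
    step:
        Number of 1:`dilution` dilutions applied to the anchor.
    dilution:
        Dilution factor per step; 4 throughout the assay design.
    """

    base: float
    step: int = 0
    dilution: float = 4.0

    def __post_init__(self) -> None:
        if self.base <= 0:
            raise ValueError(f"MOI base must be positive, got {self.base}")
        if self.step < 0 or self.step != int(self.step):
            raise ValueError(f"dilution step must be a non-negative integer, got {self.step}")
        if self.dilution <= 1:
            raise ValueError(f"dilution factor must exceed 1, got {self.dilution}")

    @property
    def exact_value(self) -> float:
        # single power + division: no cumulative per-step error
        return self.base / self.dilution ** self.step

    @property
    def nominal(self) -> str:
        return _nominal(self.exact_value)

    @classmethod
    def from_value(cls, value: float) -> "MoiLevel":
        """Wrap a plain dose (step 0) so CSV round-trips keep exact values."""
        return cls(base=float(value), step=0)

    def diluted(self, extra_steps: int = 1) -> "MoiLevel":
        return MoiLevel(self.base, self.step + extra_steps, self.dilution)

    def __float__(self) -> float:
        return self.exact_value

    # equality/hash on the exact dose: MoiLevel(12.5, 1) is the same level
    # as MoiLevel(3.125, 0)
    def __eq__(self, other: object) -> bool:
        if isinstance(other, MoiLevel):
            return self.exact_value == other.exact_value
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.exact_value)

    def __repr__(self) -> str:
        return f"MoiLevel({self.exact_value!r} [{self.nominal}])"


@dataclass(frozen=True)
class Condition:
    """Full annotation of an experimental arm (species/doses/stimulus/assay)."""

    species_a: str | None = None
    moi_a: MoiLevel | None = None
    species_b: str | None = None
    moi_b: MoiLevel | None = None
    stimulus: Stimulus = Stimulus.NONE
    assay: AssayKind = AssayKind.NFKB_LUM

    def __post_init__(self) -> None:
        if self.species_b is not None and self.species_a is None:
            raise ValueError("species_b present requires species_a present")
        for name, moi in (("a", self.moi_a), ("b", self.moi_b)):
            species = getattr(self, f"species_{name}")
            if (species is None) != (moi is None):
                raise ValueError(
                    f"species_{name} and moi_{name} must be present or absent together"
                )

    @property
    def n_species(self) -> int:
        return (self.species_a is not None) + (self.species_b is not None)

    def describe(self) -> str:
        parts = []
        if self.species_a:
            parts.append(f"{self.species_a}@{self.moi_a.nominal}")
        if self.species_b:
            parts.append(f"{self.species_b}@{self.moi_b.nominal}")
        if not parts:
            parts.append("uninfected")
        return f"{'+'.join(parts)}|{self.stimulus.value}|{self.assay.value}"


@dataclass(frozen=True)
class AssayMeasurement:
    """One well's raw read-out (luminescence, pg/mL, absorbance, or CFU)."""

    condition: Condition
    replicate_id: str
    raw_value: float
    plate_id: str = "P1"

    def __post_init__(self) -> None:
        if self.raw_value < 0:
            raise ValueError(f"raw_value must be non-negative, got {self.raw_value}")


@dataclass(frozen=True)
class NormalizedValue:
    """A well expressed as a percentage of its plate-matched control mean."""

    condition: Condition
    replicate_id: str
    percent_of_control: float
    control_kind: ControlKind
    plate_id: str = "P1"


def moi_to_cfu(moi: float, host_cells: int) -> float:
    """Convert an MOI to the bacterial inoculum (CFU) for a well.

    MOI 50 with 2.5e5 epithelial cells per well means 1.25e7 CFU added.
    """
    if moi < 0:
        raise ValueError(f"MOI must be non-negative, got {moi}")
    if host_cells <= 0:
        raise ValueError(f"host_cells must be positive, got {host_cells}")
    return moi * host_cells


def build_ladder(anchor: float, n_levels: int, dilution: float = 4.0) -> list[MoiLevel]:
    """Serial-dilution ladder of ``n_levels`` doses descending from ``anchor``.

    Values are exact (``anchor / dilution**k``); the nominal renderer
    reproduces the conventional printed grid, e.g. anchored at 50 with 8
    levels: 50, 12.5, 3.13, 0.78, 0.2, 0.05, 0.01, 0.003.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    return [MoiLevel(anchor, step, dilution) for step in range(n_levels)]


def _control_condition(condition: Condition, control_kind: ControlKind) -> Condition:
    if control_kind is ControlKind.STIMULUS_ALONE:
        if condition.stimulus is Stimulus.NONE:
            raise ValueError(
                "STIMULUS_ALONE normalization requires a stimulated condition; "
                f"got {condition.describe()}"
            )
        return Condition(stimulus=condition.stimulus, assay=condition.assay)
    return Condition(stimulus=Stimulus.NONE, assay=condition.assay)


def normalize(
    measurements: Sequence[AssayMeasurement], control_kind: ControlKind
) -> list[NormalizedValue]:
    """Express every well as a percentage of its plate-matched control mean.

    The control is the per-plate mean of the control-condition replicates:
    stimulus-alone wells of the same assay and stimulus for
    ``STIMULUS_ALONE``, untreated uninfected wells of the same assay for
    ``UNINFECTED``.  Control replicates therefore average to exactly 100%
    on each plate.

    Raises
    ------
    ValueError
        If any plate lacks its control condition, or a control mean is zero.
    """
    by_key: dict[tuple[str, Condition], list[float]] = {}
    for m in measurements:
        ctrl = _control_condition(m.condition, control_kind)
        by_key.setdefault((m.plate_id, ctrl), [])
    for m in measurements:
        key = (m.plate_id, m.condition)
        if key in by_key:
            by_key[key].append(m.raw_value)

    control_means: dict[tuple[str, Condition], float] = {}
    for (plate, ctrl), values in by_key.items():
        if not values:
            raise ValueError(
                f"plate {plate!r} has no control wells for condition {ctrl.describe()}"
            )
        mean = sum(values) / len(values)
        if mean == 0:
            raise ValueError(f"control mean is zero on plate {plate!r} ({ctrl.describe()})")
        control_means[(plate, ctrl)] = mean

    out = []
    for m in measurements:
        ctrl = _control_condition(m.condition, control_kind)
        mean = control_means[(m.plate_id, ctrl)]
        out.append(
            NormalizedValue(
                condition=m.condition,
                replicate_id=m.replicate_id,
                percent_of_control=100.0 * m.raw_value / mean,
                control_kind=control_kind,
                plate_id=m.plate_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tidy CSV interface
#
# One row per well: plate_id, replicate_id, species_a, moi_a, species_b,
# moi_b, stimulus, assay, raw_value.  Empty string = absent species/dose.

CSV_COLUMNS = [
    "plate_id",
    "replicate_id",
    "species_a",
    "moi_a",
    "species_b",
    "moi_b",
    "stimulus",
    "assay",
    "raw_value",
]


def _parse_row(row: pd.Series, index: int) -> AssayMeasurement:
    def opt(name: str) -> str | None:
        v = row[name]
        if pd.isna(v) or str(v).strip() == "":
            return None
        return str(v).strip()

    species_a, species_b = opt("species_a"), opt("species_b")
    moi_a_s, moi_b_s = opt("moi_a"), opt("moi_b")
    try:
        condition = Condition(
            species_a=species_a,
            moi_a=MoiLevel.from_value(float(moi_a_s)) if moi_a_s else None,
            species_b=species_b,
            moi_b=MoiLevel.from_value(float(moi_b_s)) if moi_b_s else None,
            stimulus=Stimulus(str(row["stimulus"]).strip()),
            assay=AssayKind(str(row["assay"]).strip()),
        )
        return AssayMeasurement(
            condition=condition,
            replicate_id=str(row["replicate_id"]),
            raw_value=float(row["raw_value"]),
            plate_id=str(row["plate_id"]),
        )
    except (ValueError, KeyError) as exc:
        raise ValueError(f"row {index}: {exc}") from exc


def read_measurements_csv(path) -> list[AssayMeasurement]:
    """Read tidy replicate-level well data; raises with row numbers on bad rows."""
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    if frame.empty:
        raise ValueError("input CSV contains no data rows")
    return [_parse_row(row, i) for i, row in frame.iterrows()]


def _condition_fields(c: Condition) -> dict:
    return {
        "species_a": c.species_a or "",
        "moi_a": repr(c.moi_a.exact_value) if c.moi_a else "",
        "species_b": c.species_b or "",
        "moi_b": repr(c.moi_b.exact_value) if c.moi_b else "",
        "stimulus": c.stimulus.value,
        "assay": c.assay.value,
    }


def measurements_to_frame(measurements: Iterable[AssayMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        row = {"plate_id": m.plate_id, "replicate_id": m.replicate_id}
        row.update(_condition_fields(m.condition))
        row["raw_value"] = repr(m.raw_value)
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def normalized_to_frame(values: Iterable[NormalizedValue]) -> pd.DataFrame:
    rows = []
    for v in values:
        row = {"plate_id": v.plate_id, "replicate_id": v.replicate_id}
        row.update(_condition_fields(v.condition))
        row["percent_of_control"] = f"{v.percent_of_control:.6f}"
        row["control_kind"] = v.control_kind.value
        rows.append(row)
    columns = CSV_COLUMNS[:-1] + ["percent_of_control", "control_kind"]
    return pd.DataFrame(rows, columns=columns)
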