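"""Classification of commensal species from normalized plate read-outs.

Implements the study's decision rules:

* anti-inflammatory — mean NF-κB (or IL-8) read-out below 50% of the
  stimulated control with BH-adjusted q < 0.05;
* cytotoxic — mean viability below 80% of the uninfected control with
  q < 0.05 (both conditions required: a sub-80% mean that is not
  significant is *not* cytotoxic);
* self-activating — the species alone raises the read-out significantly
  above the uninfected control;
* minimal effective MOI (mMOI) — the lowest dose on the 1:4 ladder that is
  anti-inflammatory, requiring every higher tested dose to pass as well
  (an isolated low-dose pass over a failing higher dose is flagged as a
  non-monotone artifact, not an mMOI);
* host-association effect — two-group test of log10(CFU + 1) with vs
  without stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay import (
    AssayKind,
    AssayMeasurement,
    Condition,
    ControlKind,
    MoiLevel,
    Stimulus,
    normalize,
)
from .stats import TestResult, attach_qvalues, test_two_groups, test_vs_null

__all__ = [
    "ConditionSummary",
    "ScreeningVerdict",
    "SpeciesPotency",
    "summarize_by_condition",
    "classify_condition",
    "classify_cytotoxic",
    "classify_self_activation",
    "determine_mmoi",
    "association_effect",
    "screen_panel",
    "ladder_potency",
]

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    """Normalized replicate values for one condition plus its test result."""

    condition: Condition
    values: np.ndarray
    result: TestResult

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def q_value(self) -> float | None:
        return self.result.q_value


@dataclass
class ScreeningVerdict:
    """Per-species outcome of the initial anti-inflammatory/cytotoxicity screen."""

    species: str
    anti_inflammatory_at: set[MoiLevel] = field(default_factory=set)
    cytotoxic_at: set[MoiLevel] = field(default_factory=set)
    self_activating: bool = False

    @property
    def retained(self) -> bool:
        return (
            bool(self.anti_inflammatory_at)
            and not self.cytotoxic_at
            and not self.self_activating
        )

    @property
    def exclusion_reason(self) -> str | None:
        if self.cytotoxic_at:
            return "cytotoxic"
        if self.self_activating:
            return "self-activating"
        if not self.anti_inflammatory_at:
            return "not anti-inflammatory"
        return None


@dataclass
class SpeciesPotency:
    """A species' minimal effective MOI for each read-out, with ladder evidence."""

    species: str
    mmoi_nfkb: MoiLevel | None = None
    mmoi_il8: MoiLevel | None = None
    ladder_evidence: dict[str, list[tuple[MoiLevel, float, float | None, bool]]] = field(
        default_factory=dict
    )
    warnings: list[str] = field(default_factory=list)


def summarize_by_condition(
    normalized, null_value: float = 100.0, alpha_normality: float = 0.05
) -> list[ConditionSummary]:
    """Group normalized values by condition, test each group against the
    control level (100%), and BH-adjust across the family (all conditions
    that share the control in one call)."""
    groups: dict[Condition, list[float]] = {}
    for v in normalized:
        groups.setdefault(v.condition, []).append(v.percent_of_control)
    summaries = []
    for condition, values in groups.items():
        result = test_vs_null(values, null_value, alpha_normality)
        summaries.append(ConditionSummary(condition, np.asarray(values, float), result))
    attach_qvalues([s.result for s in summaries])
    return summaries


def classify_condition(
    summary: ConditionSummary, threshold_pct: float = 50.0, alpha: float = 0.05
) -> bool:
    """Anti-inflammatory call: mean strictly below threshold AND q strictly
    below alpha (boundary values fail)."""
    q = summary.q_value
    return q is not None and summary.mean < threshold_pct and q < alpha


def classify_cytotoxic(
    summary: ConditionSummary, threshold_pct: float = 80.0, alpha: float = 0.05
) -> bool:
    """Cytotoxicity call on %-of-uninfected viability; both the magnitude
    and the significance criterion are required."""
    q = summary.q_value
    return q is not None and summary.mean < threshold_pct and q < alpha


def classify_self_activation(
    commensal_alone: Sequence[float],
    uninfected: Sequence[float],
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> tuple[bool, TestResult]:
    """Does the species alone activate the read-out above the uninfected
    control?  Significant *reductions* are not activation."""
    result = test_two_groups(commensal_alone, uninfected, alpha_normality)
    effective = result.q_value if result.q_value is not None else result.p_value
    activated = effective < alpha and float(np.mean(commensal_alone)) > float(
        np.mean(uninfected)
    )
    return activated, result


def determine_mmoi(
    ladder: Sequence[tuple[MoiLevel, ConditionSummary]],
    threshold_pct: float = 50.0,
    alpha: float = 0.05,
) -> tuple[MoiLevel | None, list[str]]:
    """Minimal effective MOI from a descending dose ladder.

    Returns the lowest dose that passes the anti-inflammatory call *and*
    whose every higher tested dose also passes.  A pass below a failing
    higher dose breaks contiguity: it is reported as a warning and the
    isolated pass does not become the mMOI.
    """
    if not ladder:
        raise ValueError("empty ladder")
    mois = [m.exact_value for m, _ in ladder]
    if any(lo >= hi for hi, lo in zip(mois, mois[1:])):
        raise ValueError("ladder must be sorted descending by MOI")

    passes = [
        classify_condition(summary, threshold_pct, alpha) for _, summary in ladder
    ]
    prefix = 0
    while prefix < len(passes) and passes[prefix]:
        prefix += 1
    warnings = []
    if any(passes[prefix:]):
        stray = [ladder[i][0].nominal for i in range(prefix, len(passes)) if passes[i]]
        warnings.append(
            "non-monotone ladder: dose(s) "
            + ", ".join(stray)
            + " pass below a failing higher dose; not counted as mMOI"
        )
    if prefix == 0:
        return None, warnings
    return ladder[prefix - 1][0], warnings


def association_effect(
    with_stimulus: Sequence[float],
    without_stimulus: Sequence[float],
    alpha_normality: float = 0.05,
) -> TestResult:
    """Two-group test of host-associated CFU counts with vs without the
    pro-inflammatory stimulus, on the log10(CFU + 1) scale."""
    a = np.asarray(with_stimulus, float)
    b = np.asarray(without_stimulus, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("CFU counts must be non-negative")
    return test_two_groups(np.log10(a + 1.0), np.log10(b + 1.0), alpha_normality)


# ---------------------------------------------------------------------------
# panel-level orchestration


def _species_conditions(summaries, assay, stimulus):
    for s in summaries:
        c = s.condition
        if c.assay is assay and c.stimulus is stimulus and c.species_a and not c.species_b:
            yield s


def screen_panel(
    measurements: Sequence[AssayMeasurement],
    stimulus: Stimulus = Stimulus.LPS,
    threshold_activation_pct: float = 50.0,
    threshold_viability_pct: float = 80.0,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> list[ScreeningVerdict]:
    """Full screen: anti-inflammatory calls (NF-κB vs stimulated control),
    cytotoxicity calls (LDH vs uninfected control) and self-activation calls
    (species alone vs uninfected), combined into per-species verdicts."""
    verdicts: dict[str, ScreeningVerdict] = {}

    def verdict(species: str) -> ScreeningVerdict:
        return verdicts.setdefault(species, ScreeningVerdict(species))

    # anti-inflammatory family: stimulated luminescence wells vs stimulus-alone
    lum = [
        m
        for m in measurements
        if m.condition.assay is AssayKind.NFKB_LUM and m.condition.stimulus is stimulus
    ]
    if lum:
        summaries = summarize_by_condition(
            normalize(lum, ControlKind.STIMULUS_ALONE), 100.0, alpha_normality
        )
        for s in _species_conditions(summaries, AssayKind.NFKB_LUM, stimulus):
            if classify_condition(s, threshold_activation_pct, alpha):
                verdict(s.condition.species_a).anti_inflammatory_at.add(s.condition.moi_a)
                logger.info(
                    "%s anti-inflammatory at MOI %s (mean %.1f%%, q=%.3g)",
                    s.condition.species_a, s.condition.moi_a.nominal, s.mean, s.q_value,
                )
            else:
                verdict(s.condition.species_a)

    # cytotoxicity family: viability wells vs uninfected control
    ldh = [m for m in measurements if m.condition.assay is AssayKind.LDH_VIABILITY]
    if ldh:
        summaries = summarize_by_condition(
            normalize(ldh, ControlKind.UNINFECTED), 100.0, alpha_normality
        )
        for s in _species_conditions(summaries, AssayKind.LDH_VIABILITY, Stimulus.NONE):
            if classify_cytotoxic(s, threshold_viability_pct, alpha):
                verdict(s.condition.species_a).cytotoxic_at.add(s.condition.moi_a)
                logger.info(
                    "%s cytotoxic at MOI %s (viability %.1f%%, q=%.3g)",
                    s.condition.species_a, s.condition.moi_a.nominal, s.mean, s.q_value,
                )

    # self-activation: unstimulated species wells vs unstimulated uninfected
    alone = [
        m
        for m in measurements
        if m.condition.assay is AssayKind.NFKB_LUM and m.condition.stimulus is Stimulus.NONE
    ]
    if alone:
        uninfected = [m.raw_value for m in alone if m.condition.species_a is None]
        by_species: dict[str, list[float]] = {}
        for m in alone:
            if m.condition.species_a and not m.condition.species_b:
                by_species.setdefault(m.condition.species_a, []).append(m.raw_value)
        if uninfected:
            for species, values in by_species.items():
                activated, _ = classify_self_activation(
                    values, uninfected, alpha, alpha_normality
                )
                if activated:
                    verdict(species).self_activating = True
                    logger.info("%s activates the NF-κB read-out by itself", species)

    for v in verdicts.values():
        if not v.retained:
            logger.info("%s excluded: %s", v.species, v.exclusion_reason)
    return sorted(verdicts.values(), key=lambda v: v.species)


def ladder_potency(
    species: str,
    measurements: Sequence[AssayMeasurement],
    stimulus: Stimulus = Stimulus.LPS,
    threshold_pct: float = 50.0,
    alpha: float = 0.05,
    alpha_normality: float = 0.05,
) -> SpeciesPotency:
    """Determine mMOI per read-out (NF-κB luminescence, IL-8) from ladder
    experiments for one species.  Each ladder is its own BH family."""
    potency = SpeciesPotency(species)
    for assay, attr in ((AssayKind.NFKB_LUM, "mmoi_nfkb"), (AssayKind.IL8_ELISA, "mmoi_il8")):
        wells = [
            m
            for m in measurements
            if m.condition.assay is assay
            and m.condition.stimulus is stimulus
            and m.condition.species_a in (None, species)
            and m.condition.species_b is None
        ]
        if not any(m.condition.species_a == species for m in wells):
            continue
        summaries = summarize_by_condition(
            normalize(wells, ControlKind.STIMULUS_ALONE), 100.0, alpha_normality
        )
        ladder = sorted(
            (
                (s.condition.moi_a, s)
                for s in summaries
                if s.condition.species_a == species
            ),
            key=lambda pair: -pair[0].exact_value,
        )
        mmoi, warnings = determine_mmoi(ladder, threshold_pct, alpha)
        setattr(potency, attr, mmoi)
        potency.warnings.extend(f"{assay.value}: {w}" for w in warnings)
        potency.ladder_evidence[assay.value] = [
            (moi, s.mean, s.q_value, classify_condition(s, threshold_pct, alpha))
            for moi, s in ladder
        ]
    return potency
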