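"""Synthetic replicate-level assay data with known ground truth.

Each species' effect on a pro-inflammatory read-out is a Hill curve in MOI:

    activation(m) = 100 * (1 - emax * m^h / (m^h + ec50^h))    [% of control]

with separate half-maximal doses for the NF-κB reporter and for IL-8
(IL-8 inhibition typically needs a higher dose).  Cytotoxicity is a second
Hill term on viability; a cytotoxic species also depresses the luminescence
read-out in proportion to viability, reproducing the confound whereby dead
reporter cells mimic anti-inflammatory activity.

Two-species combinations follow Loewe dose-equivalence with an interaction
strength ``alpha``: the combination achieves the activation level A at which
the summed dose fractions equal alpha,

    moi_a / D_a(A) + moi_b / D_b(A) = alpha,

where D_x(A) is the single-species dose producing activation A (inverse
Hill).  alpha = 1 is additivity, alpha < 1 synergy (less total dose needed
for the same effect), alpha > 1 antagonism.  Because FICI is itself a
Loewe-type index, planted alpha and the classifier's target coincide.

Replicate noise is additive Gaussian on the percent scale, truncated at 0,
reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .assay import (
    AssayKind,
    AssayMeasurement,
    Condition,
    MoiLevel,
    Stimulus,
    build_ladder,
)
from .checkerboard import CheckerboardDesign

__all__ = [
    "SpeciesModel",
    "InteractionModel",
    "NoiseModel",
    "single_response",
    "viability_response",
    "dose_for_activation",
    "combo_response",
    "generate_screen",
    "generate_ladder_assay",
    "generate_checkerboard",
    "default_panel",
    "ground_truth_dict",
]

Readout = Literal["nfkb", "il8"]

#: raw-signal anchors per assay (arbitrary instrument units)
BASE_SIGNAL = {
    AssayKind.NFKB_LUM: 2000.0,
    AssayKind.IL8_ELISA: 800.0,
    AssayKind.LDH_VIABILITY: 1.5,
}
#: unstimulated baseline as % of the stimulated control signal
BASELINE_PCT = 5.0


@dataclass(frozen=True)
class SpeciesModel:
    """Ground-truth dose-response parameters for one commensal species."""

    name: str
    ec50_nfkb: float
    ec50_il8: float | None = None  # defaults to 4x the NF-κB dose
    hill: float = 1.5
    emax: float = 1.0
    cytotox_ec50: float = math.inf
    cytotox_hill: float = 2.0
    self_activation: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50_nfkb <= 0 or self.hill <= 0 or self.cytotox_ec50 <= 0:
            raise ValueError("EC50 and Hill parameters must be positive")
        if not 0 < self.emax <= 1:
            raise ValueError("emax must lie in (0, 1]")
        if self.self_activation < 0:
            raise ValueError("self_activation must be >= 0")

    def ec50(self, readout: Readout) -> float:
        if readout == "nfkb":
            return self.ec50_nfkb
        return self.ec50_il8 if self.ec50_il8 is not None else 4.0 * self.ec50_nfkb


@dataclass(frozen=True)
class InteractionModel:
    """Loewe interaction strength: 1 additive, < 1 synergistic, > 1 antagonistic."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise on the percent scale and the replication level."""

    sd_pct: float = 5.0
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be >= 0")
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3 (replication floor of the assay)")


def single_response(model: SpeciesModel, moi: float, readout: Readout = "nfkb") -> float:
    """Noise-free % activation of the read-out at a given MOI (Hill curve)."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    if moi == 0:
        return 100.0
    ec50 = model.ec50(readout)
    frac = moi**model.hill / (moi**model.hill + ec50**model.hill)
    return 100.0 * (1.0 - model.emax * frac)


def viability_response(model: SpeciesModel, moi: float) -> float:
    """Noise-free % viability (of uninfected control) at a given MOI."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    if moi == 0 or math.isinf(model.cytotox_ec50):
        return 100.0
    frac = moi**model.cytotox_hill / (moi**model.cytotox_hill + model.cytotox_ec50**model.cytotox_hill)
    return 100.0 * (1.0 - frac)


def dose_for_activation(model: SpeciesModel, activation_pct: float, readout: Readout = "nfkb") -> float:
    """Inverse Hill: the dose at which the species alone produces the given
    activation level; inf when the level is at/below the species' floor."""
    if not 0 < activation_pct < 100:
        raise ValueError("activation_pct must lie strictly between 0 and 100")
    inhibited = (100.0 - activation_pct) / 100.0
    r = inhibited / model.emax
    if r >= 1.0:
        return math.inf
    return model.ec50(readout) * (r / (1.0 - r)) ** (1.0 / model.hill)


def combo_response(
    a: SpeciesModel,
    b: SpeciesModel,
    moi_a: float,
    moi_b: float,
    interaction: InteractionModel = InteractionModel(),
    readout: Readout = "nfkb",
) -> float:
    """Noise-free % activation of a two-species combination under Loewe
    dose-equivalence with interaction strength alpha.

    Solves moi_a/D_a(A) + moi_b/D_b(A) = alpha for the activation A by
    bracketed root finding (residual < 1e-8).  A single present species
    reduces to its own dose-response curve; the interaction applies only
    when both doses are positive.
    """
    if moi_a < 0 or moi_b < 0:
        raise ValueError("doses must be >= 0")
    if moi_a == 0 and moi_b == 0:
        return 100.0
    if moi_b == 0:
        return single_response(a, moi_a, readout)
    if moi_a == 0:
        return single_response(b, moi_b, readout)

    floor = 100.0 * (1.0 - min(a.emax, b.emax))

    def dose_sum(activation: float) -> float:
        total = 0.0
        for model, moi in ((a, moi_a), (b, moi_b)):
            dose = dose_for_activation(model, activation, readout)
            if math.isfinite(dose):
                total += moi / dose
        return total

    lo = floor + 1e-9 * (100.0 - floor)
    hi = 100.0 - 1e-12 * 100.0
    residual = lambda act: dose_sum(act) - interaction.alpha
    if residual(lo) >= 0:
        # doses exceed what is needed to reach the joint floor
        return floor
    root = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    if abs(residual(root)) > 1e-8:
        raise RuntimeError(
            f"Loewe solve did not converge: residual {residual(root):.3g} at A={root:.6f}"
        )
    return float(root)


# ---------------------------------------------------------------------------
# measurement generation


def _noisy_pct(rng: np.random.Generator, pct: float, noise: NoiseModel) -> float:
    return max(0.0, pct + rng.normal(0.0, noise.sd_pct)) if noise.sd_pct > 0 else max(0.0, pct)


def _emit(
    out: list[AssayMeasurement],
    rng: np.random.Generator,
    condition: Condition,
    true_pct: float,
    noise: NoiseModel,
    plate_id: str,
) -> None:
    base = BASE_SIGNAL[condition.assay]
    for i in range(noise.n_replicates):
        pct = _noisy_pct(rng, true_pct, noise)
        out.append(
            AssayMeasurement(
                condition=condition,
                replicate_id=f"r{i + 1}",
                raw_value=base * pct / 100.0,
                plate_id=plate_id,
            )
        )


def _observed_activation(model: SpeciesModel, moi: float, readout: Readout) -> float:
    """Reporter signal of a live-cell read-out: the Hill response scaled by
    viability (dead reporter cells emit nothing)."""
    return single_response(model, moi, readout) * viability_response(model, moi) / 100.0


def generate_screen(
    panel: Sequence[SpeciesModel],
    mois: Sequence[float] = (50.0, 12.5),
    stimuli: Sequence[Stimulus] = (Stimulus.LPS,),
    noise: NoiseModel = NoiseModel(),
    plate_id: str = "P1",
) -> list[AssayMeasurement]:
    """Replicate-level data for the initial panel screen.

    Emits, per stimulus: the uninfected control, the stimulus-alone control,
    each species x MOI with stimulus (luminescence), each species x MOI
    alone (luminescence, for self-activation), and each species x MOI
    viability plus the uninfected viability control.
    """
    rng = np.random.default_rng(noise.seed)
    out: list[AssayMeasurement] = []
    moi_levels = [MoiLevel.from_value(m) for m in mois]

    for stimulus in stimuli:
        _emit(out, rng, Condition(stimulus=stimulus, assay=AssayKind.NFKB_LUM), 100.0, noise, plate_id)
        for species in panel:
            for moi in moi_levels:
                cond = Condition(species.name, moi, stimulus=stimulus, assay=AssayKind.NFKB_LUM)
                _emit(out, rng, cond, _observed_activation(species, moi.exact_value, "nfkb"), noise, plate_id)

    # unstimulated arms: uninfected baseline and each species alone
    _emit(out, rng, Condition(stimulus=Stimulus.NONE, assay=AssayKind.NFKB_LUM), BASELINE_PCT, noise, plate_id)
    for species in panel:
        for moi in moi_levels:
            cond = Condition(species.name, moi, stimulus=Stimulus.NONE, assay=AssayKind.NFKB_LUM)
            pct = BASELINE_PCT * (1.0 + species.self_activation) * viability_response(
                species, moi.exact_value
            ) / 100.0
            _emit(out, rng, cond, pct, noise, plate_id)

    # viability wells
    _emit(out, rng, Condition(stimulus=Stimulus.NONE, assay=AssayKind.LDH_VIABILITY), 100.0, noise, plate_id)
    for species in panel:
        for moi in moi_levels:
            cond = Condition(species.name, moi, stimulus=Stimulus.NONE, assay=AssayKind.LDH_VIABILITY)
            _emit(out, rng, cond, viability_response(species, moi.exact_value), noise, plate_id)
    return out


def generate_ladder_assay(
    species: SpeciesModel,
    anchor: float = 50.0,
    n_levels: int = 8,
    readout: Readout = "nfkb",
    stimulus: Stimulus = Stimulus.LPS,
    noise: NoiseModel = NoiseModel(),
    plate_id: str = "P1",
) -> list[AssayMeasurement]:
    """Dose-ladder experiment for mMOI determination of one species."""
    assay = AssayKind.NFKB_LUM if readout == "nfkb" else AssayKind.IL8_ELISA
    rng = np.random.default_rng(noise.seed)
    out: list[AssayMeasurement] = []
    _emit(out, rng, Condition(stimulus=stimulus, assay=assay), 100.0, noise, plate_id)
    for moi in build_ladder(anchor, n_levels):
        cond = Condition(species.name, moi, stimulus=stimulus, assay=assay)
        _emit(out, rng, cond, _observed_activation(species, moi.exact_value, readout), noise, plate_id)
    return out


def generate_checkerboard(
    a: SpeciesModel,
    b: SpeciesModel,
    interaction: InteractionModel,
    design: CheckerboardDesign,
    noise: NoiseModel = NoiseModel(),
    stimulus: Stimulus = Stimulus.LPS,
    readout: Readout = "nfkb",
    plate_id: str = "P1",
) -> list[AssayMeasurement]:
    """Replicate-level data for one checkerboard: 16 cells plus the
    stimulus-alone control wells, via the Loewe combination response."""
    assay = AssayKind.NFKB_LUM if readout == "nfkb" else AssayKind.IL8_ELISA
    rng = np.random.default_rng(noise.seed)
    out: list[AssayMeasurement] = []
    _emit(out, rng, Condition(stimulus=stimulus, assay=assay), 100.0, noise, plate_id)
    for moi_a, moi_b in design.cells:
        cond = Condition(a.name, moi_a, b.name, moi_b, stimulus, assay)
        true_pct = combo_response(a, b, moi_a.exact_value, moi_b.exact_value, interaction, readout)
        _emit(out, rng, cond, true_pct, noise, plate_id)
    return out


def default_panel() -> list[SpeciesModel]:
    """15-species synthetic panel mirroring the study's composition: nine
    anti-inflammatory species with minimal effective doses spread across the
    12.5–0.2 ladder, three cytotoxic species (whose luminescence drop is a
    viability artifact), and three inert species."""
    anti = [
        SpeciesModel("Actinomyces naeslundii", ec50_nfkb=10.0, hill=1.8),
        SpeciesModel("Gemella haemolysans", ec50_nfkb=9.0, hill=1.5),
        SpeciesModel("Prevotella nigrescens", ec50_nfkb=0.6, hill=1.6),
        SpeciesModel("Rothia mucilaginosa", ec50_nfkb=0.15, hill=1.6),
        SpeciesModel("Streptococcus sanguinis", ec50_nfkb=2.4, hill=1.7),
        SpeciesModel("Prevotella melaninogenica", ec50_nfkb=11.0, hill=2.0),
        SpeciesModel("Prevotella histicola", ec50_nfkb=8.0, hill=1.5),
        SpeciesModel("Veillonella atypica", ec50_nfkb=6.0, hill=1.4),
        SpeciesModel("Gemella sanguinis", ec50_nfkb=10.5, hill=1.9),
    ]
    cytotoxic = [
        SpeciesModel("Actinomyces oris", ec50_nfkb=8.0, cytotox_ec50=20.0),
        SpeciesModel("Neisseria subflava", ec50_nfkb=6.0, cytotox_ec50=4.0),
        SpeciesModel("Streptococcus salivarius", ec50_nfkb=5.0, cytotox_ec50=3.0),
    ]
    inert = [
        SpeciesModel("Atopobium parvulum", ec50_nfkb=30.0, emax=0.3),
        SpeciesModel("Micrococcus luteus", ec50_nfkb=40.0, emax=0.25),
        SpeciesModel("Prevotella oris", ec50_nfkb=60.0, emax=0.35),
    ]
    return anti + cytotoxic + inert


def ground_truth_dict(
    panel: Sequence[SpeciesModel],
    interaction: InteractionModel | None = None,
    noise: NoiseModel | None = None,
) -> dict:
    """Sidecar record of every planted parameter (JSON-serializable)."""
    payload: dict = {"panel": [asdict(s) for s in panel]}
    for entry in payload["panel"]:
        if math.isinf(entry["cytotox_ec50"]):
            entry["cytotox_ec50"] = None
    if interaction is not None:
        payload["interaction"] = asdict(interaction)
    if noise is not None:
        payload["noise"] = asdict(noise)
    return payload
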