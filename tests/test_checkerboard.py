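"""Checkerboard design, FICI arithmetic, cell classification, and the
end-to-end consortium evaluation on synthetic Loewe ground truth."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungsynergy.checkerboard import (
    CellVerdict,
    classify_cell,
    compute_fici,
    evaluate_consortium,
    format_fici,
    generate_design,
    max_theoretical_synergy,
    report_table,
)
from lungsynergy.assay import MoiLevel, build_ladder
from lungsynergy.synthetic import (
    InteractionModel,
    NoiseModel,
    SpeciesModel,
    generate_checkerboard,
)

from test_screening import summary_with


def design_4x4(mmoi_a=12.5, mmoi_b=3.125):
    return generate_design("A", MoiLevel.from_value(mmoi_a), "B", MoiLevel.from_value(mmoi_b))


class TestComputeFici:
    # the published synergistic MOI ratios: exact ladder values and the
    # two-decimal form they print as
    TABLE2 = [
        (0.78125, 12.5, 0.78125, 3.125, 0.3125, "0.31"),   # consortium 1
        (3.125, 12.5, 0.78125, 3.125, 0.5, "0.50"),
        (0.78125, 3.125, 0.01220703125, 0.1953125, 0.3125, "0.31"),  # consortium 2
        (0.78125, 3.125, 0.048828125, 0.1953125, 0.5, "0.50"),
        (0.78125, 12.5, 0.048828125, 0.1953125, 0.3125, "0.31"),     # consortium 3
        (3.125, 12.5, 0.048828125, 0.1953125, 0.5, "0.50"),
        (3.125, 12.5, 0.1953125, 12.5, 0.265625, "0.27"),            # consortium 5
    ]

    @pytest.mark.parametrize("moi_a, mmoi_a, moi_b, mmoi_b, exact, printed", TABLE2)
    def test_published_fici_values_exact(self, moi_a, mmoi_a, moi_b, mmoi_b, exact, printed):
        fici = compute_fici(moi_a, mmoi_a, moi_b, mmoi_b)
        assert fici == exact
        assert format_fici(fici) == printed

    def test_both_at_mmoi_gives_two(self):
        assert compute_fici(12.5, 12.5, 3.125, 3.125) == 2.0

    def test_quarter_dose_validation_identity(self):
        """Combining both species at mMOI/4 gives FICI exactly 0.5 — the
        arithmetic behind the IL-8 quarter-dose validation scheme."""
        for mmoi_a, mmoi_b in [(50.0, 50.0), (3.125, 0.1953125), (12.5, 3.125)]:
            assert compute_fici(mmoi_a / 4, mmoi_a, mmoi_b / 4, mmoi_b) == 0.5

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_fici(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_fici(0.0, 1.0, 1.0, 1.0)

    @given(
        c=st.floats(0.01, 100, allow_nan=False),
        a=st.floats(0.001, 50),
        b=st.floats(0.001, 50),
        ma=st.floats(0.01, 50),
        mb=st.floats(0.01, 50),
    )
    def test_homogeneous_degree_one(self, c, a, b, ma, mb):
        assert compute_fici(c * a, ma, c * b, mb) == pytest.approx(
            c * compute_fici(a, ma, b, mb), rel=1e-12
        )

    @given(
        a=st.floats(0.001, 50),
        b=st.floats(0.001, 50),
        ma=st.floats(0.01, 50),
        mb=st.floats(0.01, 50),
    )
    def test_symmetric_under_species_swap(self, a, b, ma, mb):
        assert compute_fici(a, ma, b, mb) == pytest.approx(
            compute_fici(b, mb, a, ma), rel=1e-12
        )


class TestGenerateDesign:
    def test_sixteen_cells_with_exact_corner(self):
        design = design_4x4()
        assert len(design.cells) == 16
        smallest = design.cells[-1]
        assert (smallest[0].exact_value, smallest[1].exact_value) == (0.1953125, 0.048828125)

    def test_single_cell_design(self):
        design = generate_design(
            "A", MoiLevel.from_value(1.0), "B", MoiLevel.from_value(1.0), n_levels=1
        )
        assert [(a.exact_value, b.exact_value) for a, b in design.cells] == [(1.0, 1.0)]

    def test_grid_spans_printed_moi_range(self):
        """Anchored at the extreme mMOIs the grid runs nominal 12.5 → 0.003."""
        design = design_4x4(12.5, 0.1953125)
        nominals = {m.nominal for a, b in design.cells for m in (a, b)}
        assert "12.5" in nominals and "0.003" in nominals

    def test_unset_mmoi_names_species(self):
        with pytest.raises(ValueError, match="speciesB"):
            generate_design("speciesA", MoiLevel.from_value(1.0), "speciesB", None)


class TestClassifyCell:
    def test_synergy_at_inclusive_boundary(self):
        """FICI exactly 0.50 with > 50% inhibition is synergistic (the
        published synergy rows include cells printed as 0.50)."""
        verdict, _ = classify_cell(0.5, summary_with(41.08, 0.01))
        assert verdict is CellVerdict.SYNERGY

    def test_fici_pass_effect_fail_is_flagged_additive(self):
        verdict, flags = classify_cell(0.3125, summary_with(55.0, 0.01))
        assert verdict is CellVerdict.ADDITIVE_OR_NONE
        assert "fici_pass_effect_fail" in flags

    def test_significance_failure_reason_logged_distinctly(self):
        verdict, flags = classify_cell(0.3125, summary_with(45.0, 0.50))
        assert verdict is CellVerdict.ADDITIVE_OR_NONE
        assert "fici_pass_effect_fail" in flags and "not significant" in flags

    def test_antagonism_boundary_inclusive(self):
        verdict, _ = classify_cell(4.0, summary_with(90.0, 0.9))
        assert verdict is CellVerdict.ANTAGONISM

    def test_too_few_replicates_not_evaluable(self):
        verdict, _ = classify_cell(0.25, None)
        assert verdict is CellVerdict.NOT_EVALUABLE


class TestMaxTheoreticalSynergy:
    def test_standard_design_nine_of_sixteen(self):
        assert max_theoretical_synergy(design_4x4(), 0.5) == 9

    def test_single_cell_at_mmoi_zero(self):
        design = generate_design(
            "A", MoiLevel.from_value(1.0), "B", MoiLevel.from_value(1.0), n_levels=1
        )
        assert max_theoretical_synergy(design, 0.5) == 0  # FICI = 2

    def test_loose_cutoff_counts_all(self):
        assert max_theoretical_synergy(design_4x4(), 2.0) == 16

    @pytest.mark.parametrize("n_levels", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("cutoff", [0.25, 0.5, 0.75, 1.0, 1.5])
    def test_matches_brute_force_fraction_count(self, n_levels, cutoff):
        """Oracle: enumerate all dilution-fraction pairs 4^-i + 4^-j."""
        design = generate_design(
            "A", MoiLevel.from_value(7.3), "B", MoiLevel.from_value(0.9), n_levels=n_levels
        )
        brute = sum(
            1
            for i, j in itertools.product(range(n_levels), repeat=2)
            if 4.0**-i + 4.0**-j <= cutoff + 1e-9
        )
        assert max_theoretical_synergy(design, cutoff) == brute


def checkerboard_result(alpha, sd=5.0, seed=0, ec50_a=10.0, ec50_b=2.5, hill=1.7):
    """Simulate and evaluate one consortium with ladders anchored at the
    true iso-50% doses (emax = 1, so those equal the EC50s)."""
    a = SpeciesModel("A", ec50_nfkb=ec50_a, hill=hill)
    b = SpeciesModel("B", ec50_nfkb=ec50_b, hill=hill)
    design = generate_design(
        "A", MoiLevel.from_value(ec50_a), "B", MoiLevel.from_value(ec50_b)
    )
    data = generate_checkerboard(
        a, b, InteractionModel(alpha), design, NoiseModel(sd_pct=sd, n_replicates=4, seed=seed)
    )
    return evaluate_consortium(design, data)


class TestEvaluateConsortium:
    def test_flat_100_percent_is_not_synergistic(self):
        result = checkerboard_result(alpha=1.0, sd=0.0, ec50_a=1e6, ec50_b=1e6)
        assert not result.synergistic
        assert result.n_synergistic_cells == 0

    def test_strong_synergy_detected(self):
        result = checkerboard_result(alpha=0.3, sd=5.0, seed=7)
        assert result.synergistic
        # synergy cells must be among the 9 FICI-feasible ones
        assert result.n_synergistic_cells <= result.n_theoretical_max == 9

    def test_loewe_additive_pair_not_synergistic(self):
        """Under additivity the iso-50% boundary sits at FICI = 1, so no
        FICI <= 0.5 cell can reach > 50% inhibition."""
        result = checkerboard_result(alpha=1.0, sd=5.0, seed=7)
        assert not result.synergistic

    def test_missing_cells_are_listed(self):
        a = SpeciesModel("A", ec50_nfkb=10.0)
        b = SpeciesModel("B", ec50_nfkb=2.5)
        design = generate_design("A", MoiLevel.from_value(10.0), "B", MoiLevel.from_value(2.5))
        data = generate_checkerboard(a, b, InteractionModel(1.0), design)
        # drop one cell entirely
        drop = design.cells[5]
        data = [
            m
            for m in data
            if not (
                m.condition.moi_a == drop[0]
                and m.condition.moi_b == drop[1]
                and m.condition.species_a == "A"
            )
        ]
        with pytest.raises(ValueError, match="missing cells"):
            evaluate_consortium(design, data)


class TestReportTable:
    def test_synergy_rows_with_printed_fici(self):
        result = checkerboard_result(alpha=0.3, sd=0.0)
        table = report_table([result])
        assert len(table) == result.n_synergistic_cells > 0
        assert set(table.columns) >= {"moi_a", "moi_b", "activation_pct", "fici"}
        # printed FICI values are two-decimal strings within the synergy range
        assert all(float(f) <= 0.5 for f in table["fici"])

    def test_empty_results_header_only(self):
        table = report_table([])
        assert table.empty and list(table.columns)[:4] == [
            "species_a", "species_b", "moi_a", "moi_b",
        ]
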