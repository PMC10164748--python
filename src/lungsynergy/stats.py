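"""Normality-routed location tests and false-discovery-rate correction.

The assay analysis compares small replicate groups (n >= 3) either against
a fixed null (a normalized read-out against 100% of control) or between two
groups (CFU counts with vs without stimulus).  Each group is first checked
with Shapiro-Wilk; normal-looking data take the parametric test (one-sample
t or Welch two-sample t), otherwise the rank-based analogue (Wilcoxon
signed-rank or Mann-Whitney U).  When several conditions share one control,
Benjamini-Hochberg correction is applied across the family.

Degenerate zero-variance samples (possible with noise-free synthetic data)
are handled by convention: a constant sample equal to the null gives p = 1,
a constant sample different from the null gives p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestName", "TestResult", "test_vs_null", "test_two_groups", "adjust_bh", "attach_qvalues"]


class TestName(str, Enum):
    ONE_SAMPLE_T = "ONE_SAMPLE_T"
    WILCOXON_SIGNED_RANK = "WILCOXON_SIGNED_RANK"
    TWO_SAMPLE_T = "TWO_SAMPLE_T"
    MANN_WHITNEY_U = "MANN_WHITNEY_U"


@dataclass
class TestResult:
    """Outcome of one hypothesis test; ``q_value`` is attached after BH."""

    test_name: TestName
    statistic: float
    p_value: float
    n: tuple[int, ...]
    normality_p: float | None = None
    q_value: float | None = None

    @property
    def significant(self) -> bool:
        """q < 0.05 on the BH-adjusted value (falls back to raw p if unset)."""
        value = self.q_value if self.q_value is not None else self.p_value
        return value < 0.05


def _check_group(values: Sequence[float], label: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"insufficient replicates: {label} needs n >= 3, got n = {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{label} contains non-finite entries")
    return arr


def _shapiro_p(arr: np.ndarray) -> float | None:
    if np.ptp(arr) == 0:
        return None  # undefined for constant data
    return float(sps.shapiro(arr).pvalue)


def test_vs_null(
    values: Sequence[float], null_value: float, alpha_normality: float = 0.05
) -> TestResult:
    """Two-sided test of a replicate group against a fixed null value.

    Shapiro-Wilk routes to a one-sample t-test (normal) or a Wilcoxon
    signed-rank test (non-normal; zero differences dropped, exact null
    distribution for n <= 25 without ties).
    """
    arr = _check_group(values)
    diffs = arr - null_value
    if np.ptp(arr) == 0:
        if diffs[0] == 0:
            return TestResult(TestName.ONE_SAMPLE_T, 0.0, 1.0, (arr.size,))
        sign = math_sign(diffs[0])
        return TestResult(TestName.ONE_SAMPLE_T, sign * np.inf, 0.0, (arr.size,))

    sw_p = _shapiro_p(arr)
    if sw_p is not None and sw_p >= alpha_normality:
        res = sps.ttest_1samp(arr, popmean=null_value)
        return TestResult(
            TestName.ONE_SAMPLE_T, float(res.statistic), float(res.pvalue), (arr.size,), sw_p
        )

    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return TestResult(TestName.WILCOXON_SIGNED_RANK, 0.0, 1.0, (arr.size,), sw_p)
    res = sps.wilcoxon(nonzero, alternative="two-sided", method="auto")
    return TestResult(
        TestName.WILCOXON_SIGNED_RANK, float(res.statistic), float(res.pvalue), (arr.size,), sw_p
    )


def test_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha_normality: float = 0.05,
    method: str = "auto",
) -> TestResult:
    """Two-sided comparison of two independent replicate groups.

    ``method`` is normally ``"auto"`` (Shapiro-Wilk on each group; both
    normal -> Welch t, else Mann-Whitney U with exact small-sample null);
    ``"welch"`` / ``"mannwhitney"`` force a route.
    """
    arr_a = _check_group(a, "group a")
    arr_b = _check_group(b, "group b")

    if np.ptp(arr_a) == 0 and np.ptp(arr_b) == 0:
        if arr_a[0] == arr_b[0]:
            return TestResult(TestName.TWO_SAMPLE_T, 0.0, 1.0, (arr_a.size, arr_b.size))
        sign = math_sign(arr_a[0] - arr_b[0])
        return TestResult(TestName.TWO_SAMPLE_T, sign * np.inf, 0.0, (arr_a.size, arr_b.size))

    if method == "auto":
        p_a, p_b = _shapiro_p(arr_a), _shapiro_p(arr_b)
        normal = (
            p_a is not None
            and p_b is not None
            and p_a >= alpha_normality
            and p_b >= alpha_normality
        )
        candidates = [p for p in (p_a, p_b) if p is not None]
        sw_p = min(candidates) if candidates else None
        method = "welch" if normal else "mannwhitney"
    else:
        sw_p = None

    if method == "welch":
        if np.array_equal(np.sort(arr_a), np.sort(arr_b)):
            return TestResult(TestName.TWO_SAMPLE_T, 0.0, 1.0, (arr_a.size, arr_b.size), sw_p)
        res = sps.ttest_ind(arr_a, arr_b, equal_var=False)
        return TestResult(
            TestName.TWO_SAMPLE_T,
            float(res.statistic),
            float(res.pvalue),
            (arr_a.size, arr_b.size),
            sw_p,
        )
    if method == "mannwhitney":
        res = sps.mannwhitneyu(arr_a, arr_b, alternative="two-sided", method="auto")
        return TestResult(
            TestName.MANN_WHITNEY_U,
            float(res.statistic),
            float(res.pvalue),
            (arr_a.size, arr_b.size),
            sw_p,
        )
    raise ValueError(f"unknown method {method!r}")


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def attach_qvalues(results: Sequence[TestResult]) -> None:
    """BH-adjust one family of test results in place."""
    qs = adjust_bh([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q


def math_sign(x: float) -> float:
    return 1.0 if x > 0 else (-1.0 if x < 0 else 0.0)
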