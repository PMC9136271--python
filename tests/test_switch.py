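"""Switched ON/OFF detection: filter, rank test, state calls, composition."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selenoscope.datamodel import ExpressionMatrix, GroupDesign, ValidationError
from selenoscope.switch import (
    INDETERMINATE,
    OFF,
    ON,
    call_group_state,
    detect_switches,
    quartile_deviation_filter,
    wilcoxon_rank_sum,
)


def rank_sum_oracle(x, y):
    """Independent two-sided permutation p via direct pair counting.

    For every assignment of the pooled values into the two groups, U is
    computed by counting pairs won (ties half) — no ranks involved — and
    extremity is |U − n1·n2/2|.
    """
    pooled = np.concatenate([x, y])
    nx, ny = len(x), len(y)

    def u_of(subset):
        xs = pooled[list(subset)]
        ys = pooled[[i for i in range(nx + ny) if i not in set(subset)]]
        wins = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return wins

    center = nx * ny / 2.0
    dev_obs = abs(u_of(range(nx)) - center)
    hits = sum(
        1
        for subset in combinations(range(nx + ny), nx)
        if abs(u_of(subset) - center) >= dev_obs - 1e-12
    )
    return hits / comb(nx + ny, nx)


class TestQuartileDeviationFilter:
    def _matrix(self, rows):
        return ExpressionMatrix(
            pd.DataFrame(
                np.asarray(rows, dtype=float),
                index=[f"g{i}" for i in range(len(rows))],
                columns=[f"s{j}" for j in range(len(rows[0]))],
            )
        )

    def test_constant_gene_retained(self):
        retained, filtered = quartile_deviation_filter(self._matrix([[5.0] * 5]))
        assert retained == ["g0"] and filtered == []

    def test_zero_heavy_gene_filtered(self):
        # [0,0,0,10]: Q1=0, Q3=2.5, QD=1.25; variance 25 > 1.875
        retained, filtered = quartile_deviation_filter(self._matrix([[0, 0, 0, 10]]))
        assert filtered == ["g0"]

    def test_exact_boundary_retained(self):
        # strict "more than": engineer v == 1.5 × QD exactly.
        # values [0, a, 2a, 3a... symmetric spread: pick values with known v, QD
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        v = vals.var(ddof=1)
        qd = (np.percentile(vals, 75) - np.percentile(vals, 25)) / 2
        factor = v / qd  # with this factor the rule is exactly at equality
        retained, filtered = quartile_deviation_filter(
            self._matrix([vals]), factor=factor
        )
        assert retained == ["g0"]

    def test_too_few_samples_error(self):
        with pytest.raises(ValidationError, match="4 samples"):
            quartile_deviation_filter(self._matrix([[1.0, 2.0, 3.0]]))


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_one(self):
        x = np.array([1.0, 2, 3])
        _, p = wilcoxon_rank_sum(x, x.copy())
        assert p == 1.0

    def test_five_zeros_vs_five_positives(self):
        u, p = wilcoxon_rank_sum(np.zeros(5), np.array([3.0, 7, 11, 12, 20]))
        assert u == 25.0
        assert p == pytest.approx(2 / 252, abs=1e-15)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 7), (7, 7)])
    def test_exact_matches_pair_counting_oracle_with_ties(self, nx, ny, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=nx).astype(float)
            y = rng.integers(0, 4, size=ny).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_in_arguments(self, xs, ys):
        x, y = np.asarray(xs, float), np.asarray(ys, float)
        ux, px = wilcoxon_rank_sum(x, y)
        uy, py = wilcoxon_rank_sum(y, x)
        assert px == pytest.approx(py, abs=1e-12)
        assert ux == pytest.approx(uy, abs=1e-12)

    def test_approx_mode_reasonable_on_large_groups(self, rng):
        x = rng.normal(0, 1, size=30)
        y = rng.normal(2, 1, size=30)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-4


class TestCallGroupState:
    def test_all_zero_is_off(self):
        assert call_group_state(np.zeros(4))[0] == OFF

    def test_interpolated_median_makes_on(self):
        state, median, _ = call_group_state(np.array([0.0, 0, 1, 5]))
        assert median == 0.5 and state == ON

    def test_high_sd_zero_median_is_indeterminate(self):
        state, median, sd = call_group_state(np.array([0.0, 0, 0, 9]))
        assert median == 0.0
        assert sd == pytest.approx(4.5, abs=1e-12)
        assert state == INDETERMINATE

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            call_group_state(np.array([-1.0, 0.0]))


class TestDetectSwitches:
    def _five_v_five(self, baseline_vals, treat_vals):
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        design = GroupDesign(
            {s: ("A" if s.startswith("a") else "B") for s in samples},
            {"A": 0.0, "B": 1.0},
            "A",
        )
        matrix = ExpressionMatrix(
            pd.DataFrame(
                [np.concatenate([baseline_vals, treat_vals])],
                index=["g"],
                columns=samples,
            )
        )
        return matrix, design

    def test_switched_on_composition(self):
        matrix, design = self._five_v_five(np.zeros(5), np.array([8.0, 9, 10, 11, 12]))
        switches, _ = detect_switches(matrix, design)
        assert len(switches) == 1
        row = switches.iloc[0]
        assert row["direction"] == "switched_on"
        assert row["pvalue"] == pytest.approx(2 / 252, abs=1e-15)

    def test_identical_groups_no_record(self):
        vals = np.array([4.0, 5, 6, 7, 8])
        matrix, design = self._five_v_five(vals, vals)
        switches, _ = detect_switches(matrix, design)
        assert len(switches) == 0

    def test_state_constraint_gates_call_on_null_data(self, rng):
        """All groups drawn from one positive-median distribution: no
        group attains median zero, so no switch regardless of p-values."""
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        design = GroupDesign(
            {s: ("A" if s.startswith("a") else "B") for s in samples},
            {"A": 0.0, "B": 1.0},
            "A",
        )
        values = rng.poisson(30, size=(200, 20)).astype(float)
        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(200)], columns=samples)
        )
        switches, states = detect_switches(matrix, design)
        assert (states["median"] > 0).all()
        assert len(switches) == 0

    def test_column_permutation_invariance(self, rng):
        matrix, design = self._five_v_five(np.zeros(5), np.array([8.0, 9, 10, 11, 12]))
        perm = rng.permutation(matrix.sample_ids)
        permuted = ExpressionMatrix(matrix.data[list(perm)])
        s1, _ = detect_switches(matrix, design)
        s2, _ = detect_switches(permuted, design)
        pd.testing.assert_frame_equal(s1, s2)

    def test_factor_argument_applies_variance_filter(self):
        matrix, design = self._five_v_five(np.zeros(5), np.array([8.0, 9, 10, 11, 12]))
        # the zero-heavy switched gene is exactly what the literal rule removes
        switches, _ = detect_switches(matrix, design, factor=1.5)
        assert len(switches) == 0

    def test_small_baseline_errors(self):
        matrix = ExpressionMatrix(
            pd.DataFrame([[0.0, 1, 2]], index=["g"], columns=["a0", "b0", "b1"])
        )
        design = GroupDesign(
            {"a0": "A", "b0": "B", "b1": "B"}, {"A": 0.0, "B": 1.0}, "A"
        )
        with pytest.raises(ValidationError, match="baseline"):
            detect_switches(matrix, design)
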