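"""Model-profile enumeration, selection, series building and assignment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selenoscope.datamodel import ExpressionMatrix, GroupDesign, ValidationError
from selenoscope.profiles import (
    assign_genes,
    build_dose_series,
    generate_candidate_profiles,
    profile_significance,
    select_model_profiles,
)


class TestGenerateCandidateProfiles:
    @pytest.mark.parametrize(
        "d,c,expected",
        [(2, 1, 2), (2, 2, 4), (4, 1, 26), (3, 2, 24), (5, 1, 80), (5, 2, 624)],
    )
    def test_count_matches_closed_form(self, d, c, expected):
        profiles = generate_candidate_profiles(d, c)
        assert len(profiles) == expected == (2 * c + 1) ** (d - 1) - 1

    def test_d2_c1_members(self):
        levels = [p.levels for p in generate_candidate_profiles(2, 1)]
        assert levels == [(0, -1), (0, 1)]

    def test_profiles_start_at_zero_with_bounded_steps(self):
        for p in generate_candidate_profiles(5, 2):
            assert p.levels[0] == 0
            steps = np.diff(p.levels)
            assert np.all(np.abs(steps) <= 2)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            generate_candidate_profiles(1, 1)


class TestSelectModelProfiles:
    def test_budget_above_pool_returns_all(self):
        pool = generate_candidate_profiles(4, 1)
        assert select_model_profiles(pool, m=100) == pool

    def test_m_one_returns_single_seed(self):
        pool = generate_candidate_profiles(4, 1)
        assert len(select_model_profiles(pool, m=1)) == 1

    def test_m_two_attains_max_pairwise_distance(self):
        pool = generate_candidate_profiles(4, 1)
        chosen = select_model_profiles(pool, m=2)

        def dist(a, b):
            return 1 - np.corrcoef(a.levels, b.levels)[0, 1]

        best = max(dist(a, b) for a, b in combinations(pool, 2))
        assert dist(*chosen) == pytest.approx(best, abs=1e-12)

    def test_deterministic(self):
        pool = generate_candidate_profiles(4, 2)
        assert select_model_profiles(pool, m=10) == select_model_profiles(pool, m=10)


def _gradient_design(n_per_group=3):
    groups = {"SD": 0.056, "SY0.15": 0.211, "SY0.30": 0.377, "SY0.45": 0.552}
    samples = {f"{g}_{k}": g for g in groups for k in range(n_per_group)}
    return GroupDesign(samples, groups, "SD")


class TestBuildDoseSeries:
    def _matrix(self, group_means, design):
        rows = {}
        for gene, means in group_means.items():
            vals = []
            for s in design.sample_ids:
                vals.append(means[design.sample_to_group[s]])
            rows[gene] = vals
        return ExpressionMatrix(
            pd.DataFrame.from_dict(rows, orient="index", columns=design.sample_ids)
        )

    def test_constant_gene_all_zero_series(self):
        design = _gradient_design()
        m = self._matrix({"g": dict.fromkeys(design.groups, 7.0)}, design)
        series = build_dose_series(m, design, ["g"], list(design.groups))
        assert np.allclose(series.loc["g"], 0.0)

    def test_doubling_series_closed_form(self):
        design = _gradient_design()
        means = dict(zip(design.groups, [3.0, 7.0, 15.0, 31.0]))
        m = self._matrix({"g": means}, design)
        series = build_dose_series(m, design, ["g"], list(design.groups))
        assert np.allclose(series.loc["g"], [0, 1, 2, 3])

    def test_global_scaling_near_invariance(self):
        """Doubling every group mean leaves the log-ratio series unchanged
        up to the (vanishing at scale) pseudocount perturbation."""
        design = _gradient_design()
        means = dict(zip(design.groups, [300.0, 700.0, 1500.0, 3100.0]))
        doubled = {g: 2 * v for g, v in means.items()}
        s1 = build_dose_series(
            self._matrix({"g": means}, design), design, ["g"], list(design.groups)
        )
        s2 = build_dose_series(
            self._matrix({"g": doubled}, design), design, ["g"], list(design.groups)
        )
        assert np.allclose(s1.loc["g"], s2.loc["g"], atol=5e-3)

    def test_unknown_group_errors(self):
        design = _gradient_design()
        m = self._matrix({"g": dict.fromkeys(design.groups, 1.0)}, design)
        with pytest.raises(ValidationError, match="absent"):
            build_dose_series(m, design, ["g"], ["SD", "nope"])


class TestAssignGenes:
    def setup_method(self):
        self.library = generate_candidate_profiles(4, 1)

    def test_perfect_match_retained_with_r_one(self):
        series = pd.DataFrame([[0.0, 1, 2, 3]], index=["g"])
        target = next(p for p in self.library if p.levels == (0, 1, 2, 3))
        out = assign_genes(series, self.library)
        assert out.loc["g", "profile_index"] == target.index
        assert out.loc["g", "pearson_r"] == pytest.approx(1.0)
        assert bool(out.loc["g", "retained"])

    def test_zero_variance_unassigned(self):
        series = pd.DataFrame([[0.0, 0, 0, 0]], index=["g"])
        out = assign_genes(series, self.library)
        assert out.loc["g", "profile_index"] == -1
        assert not bool(out.loc["g", "retained"])
        assert np.isnan(out.loc["g", "pearson_r"])

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_positive_affine_invariance(self, scale, shift):
        base = pd.DataFrame([[0.0, 1, 0, -1]], index=["g"])
        transformed = base * scale + shift
        a = assign_genes(base, self.library)
        b = assign_genes(transformed, self.library)
        assert a.loc["g", "profile_index"] == b.loc["g", "profile_index"]
        assert a.loc["g", "pearson_r"] == pytest.approx(
            b.loc["g", "pearson_r"], abs=1e-9
        )

    def test_noisy_generators_recovered(self, rng):
        """Genes whose per-sample log2 expression follows a generating
        profile plus N(0, 0.25) noise (10 birds per dose group) land on
        that profile in ≥ 90% of cases after series building."""
        design = _gradient_design(n_per_group=10)
        order = list(design.groups)
        n = 400
        gen = rng.integers(0, len(self.library), size=n)
        cols = design.sample_ids
        values = np.zeros((n, len(cols)))
        for j, s in enumerate(cols):
            gi = order.index(design.sample_to_group[s])
            levels = np.array([self.library[k].levels[gi] for k in gen], float)
            values[:, j] = 100.0 * 2.0 ** (levels + rng.normal(0, 0.25, size=n))
        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(n)], columns=cols)
        )
        series = build_dose_series(matrix, design, list(matrix.gene_ids), order)
        out = assign_genes(series, self.library)
        hit = (out["profile_index"].to_numpy() == [self.library[k].index for k in gen])
        assert hit.mean() >= 0.9

    def test_length_mismatch_errors(self):
        series = pd.DataFrame([[0.0, 1, 2]], index=["g"])
        with pytest.raises(ValidationError, match="length"):
            assign_genes(series, self.library)


class TestProfileSignificance:
    def test_planted_profile_hits_permutation_floor(self, rng):
        library = generate_candidate_profiles(4, 1)
        target = next(p for p in library if p.levels == (0, 1, 2, 3))
        planted = np.tile(np.array([0.0, 1, 2, 3]), (200, 1))
        planted[:, 1:] += rng.normal(0, 0.1, size=(200, 3))
        noise = rng.normal(0, 1, size=(200, 4))
        noise[:, 0] = 0
        series = pd.DataFrame(
            np.vstack([planted, noise]), index=[f"g{i}" for i in range(400)]
        )
        assignments = assign_genes(series, library)
        # n_perm large enough that the permutation floor clears Bonferroni×26
        signif = profile_significance(
            assignments, series, library, n_perm=600, seed=5
        )
        row = signif[signif["profile_index"] == target.index].iloc[0]
        assert row["p_value"] == pytest.approx(1 / 601, abs=1e-12)
        assert bool(row["significant"])

    def test_observed_zero_gives_p_one(self):
        library = generate_candidate_profiles(4, 1)
        series = pd.DataFrame(
            np.zeros((5, 4)), index=[f"g{i}" for i in range(5)]
        )  # all unassigned → observed counts 0 everywhere
        assignments = assign_genes(series, library)
        signif = profile_significance(assignments, series, library, n_perm=100, seed=1)
        assert (signif["p_value"] == 1.0).all()
        assert not signif["significant"].any()

    def test_same_seed_bit_identical(self, rng):
        library = generate_candidate_profiles(4, 1)
        series = pd.DataFrame(
            rng.normal(size=(50, 4)), index=[f"g{i}" for i in range(50)]
        )
        series.iloc[:, 0] = 0.0
        assignments = assign_genes(series, library)
        a = profile_significance(assignments, series, library, n_perm=150, seed=9)
        b = profile_significance(assignments, series, library, n_perm=150, seed=9)
        pd.testing.assert_frame_equal(a, b)
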