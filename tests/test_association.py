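"""Correlation screen and the two correlation-comparison tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memnet.association import (
    correlation_screen,
    fisher_independent_test,
    lateralization_tests,
    pearson_with_p,
    screen_to_frame,
    williams_dependent_test,
)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_pair_toy_matches_hand_computation(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(0.7917946548886297, abs=1e-12)
        assert res.n == 6

    def test_pairwise_complete(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([1.0, 2, np.nan, 4, 5])
        assert pearson_with_p(x, y).n == 3

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match=">= 3"):
            pearson_with_p(np.array([1.0, 2]), np.array([3.0, 4]))


class TestWilliams:
    def test_equal_correlations_give_t_zero(self):
        res = williams_dependent_test(0.4, 0.4, 0.2, 50)
        assert res.t_stat == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,df", [(88, 85), (89, 86), (82, 79)])
    def test_df_is_n_minus_3(self, n, df):
        assert williams_dependent_test(0.3, 0.1, 0.5, n).df == df

    def test_matches_published_formula(self):
        # |R| = 1 - .45^2 - .15^2 - .30^2 + 2(.45)(.15)(.30); rbar = .30
        res = williams_dependent_test(0.45, 0.15, 0.30, 90)
        det = 1 - 0.45**2 - 0.15**2 - 0.30**2 + 2 * 0.45 * 0.15 * 0.30
        expected = (0.45 - 0.15) * np.sqrt(
            (89 * 1.30) / (2 * det * 89 / 87 + 0.30**2 * 0.70**3)
        )
        assert res.t_stat == pytest.approx(expected, rel=1e-12)
        assert res.t_stat == pytest.approx(2.6214958899240015, rel=1e-10)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            williams_dependent_test(0.9, -0.9, 0.9, 30)

    @given(
        st.floats(0.0, 0.6),
        st.floats(0.0, 0.6),
        st.floats(0.0, 0.3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_r_difference(self, r_base, gap, r_kh):
        """|t| grows with the gap between the two dependent correlations."""
        small = williams_dependent_test(r_base, r_base - gap / 2, r_kh, 60)
        large = williams_dependent_test(r_base, r_base - gap, r_kh, 60)
        assert abs(large.t_stat) >= abs(small.t_stat) - 1e-12


class TestFisher:
    def test_equal_correlations_give_z_zero(self):
        assert fisher_independent_test(0.3, 40, 0.3, 60).z_stat == 0.0

    def test_antisymmetric_under_group_swap(self):
        a = fisher_independent_test(0.5, 50, 0.1, 60)
        b = fisher_independent_test(0.1, 60, 0.5, 50)
        assert a.z_stat == pytest.approx(-b.z_stat, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_hand_computed_value(self):
        res = fisher_independent_test(0.5, 50, 0.1, 60)
        assert res.z_stat == pytest.approx(2.278703294905137, rel=1e-10)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            fisher_independent_test(1.0, 50, 0.1, 60)


class TestScreen:
    def test_grid_shape_and_band(self, paper_matrix):
        results = correlation_screen(paper_matrix)
        assert len(results) == 20  # 2 outcomes x 10 MRI variables
        by_key = {(c.var_x, c.var_y): c for c in results}
        for var in ("splenium_fa", "resid_vol_r_hipp", "resid_vol_l_dlpfc"):
            c = by_key[("mem_immediate_z", var)]
            assert 0.1 < c.r < 0.45

    def test_error_isolation_with_constant_column(self, paper_matrix):
        broken = paper_matrix.copy()
        broken["genu_md"] = 1.0
        results = correlation_screen(broken)
        errors = [c for c in results if c.error is not None]
        assert {c.var_y for c in errors} == {"genu_md"}
        assert sum(c.error is None for c in results) == 18

    def test_tsv_roundtrip(self, paper_matrix, tmp_path):
        import pandas as pd

        frame = screen_to_frame(correlation_screen(paper_matrix))
        path = tmp_path / "screen.tsv"
        frame.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t").fillna({"error": ""})
        pd.testing.assert_frame_equal(back, frame)


class TestLateralization:
    def test_df_bookkeeping_follows_block_complete_cases(self, paper_matrix):
        results = {c.label: c for c in lateralization_tests(paper_matrix)}
        frontal = results["mem_immediate_z:dlpfc_l_vs_r"]
        hipp = results["mem_immediate_z:hipp_r_vs_l"]
        assert frontal.n == 88 and frontal.df == 85
        assert hipp.n == 89 and hipp.df == 86
        # tract comparisons use participants with both tracts
        fa = results["mem_immediate_z:fa_splenium_vs_genu"]
        assert fa.n == int(
            (paper_matrix[["mem_immediate_z", "splenium_fa", "genu_fa"]].notna().all(axis=1)).sum()
        )
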