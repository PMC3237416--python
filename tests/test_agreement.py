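"""Agreement battery vs independent oracles and degenerate limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import cohens_kappa
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from adrcat import (
    InsufficientDataError,
    RatingsMatrix,
    agreement_report,
    altman_band,
    exact_agreement_pct,
    extreme_disagreement_pct,
    fleiss_kappa,
    fleiss_kappa_from_counts,
    linear_weighted_kappa,
)
from adrcat.agreement import contingency_table, weighted_kappa_from_table


# -- independent brute-force oracles (plain loops, no shared code) ----------
def bf_weighted_kappa(table):
    k = len(table)
    n = sum(sum(row) for row in table)
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            row_i = sum(table[i]) / n
            col_j = sum(table[r][j] for r in range(k)) / n
            po += w * table[i][j] / n
            pe += w * row_i * col_j
    return (po - pe) / (1.0 - pe)


def bf_fleiss_kappa(counts):
    n_cases = len(counts)
    n = sum(counts[0])
    k = len(counts[0])
    p_j = [sum(row[j] for row in counts) / (n_cases * n) for j in range(k)]
    p_bar = sum(
        (sum(c * c for c in row) - n) / (n * (n - 1)) for row in counts
    ) / n_cases
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1.0 - p_e)


def two_rater(codes_a, codes_b):
    return RatingsMatrix.from_codes(
        np.column_stack([codes_a, codes_b]).astype(float)
    )


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        m = two_rater([1, 2, 3, 4, 2], [1, 2, 3, 4, 2])
        assert linear_weighted_kappa(m).kappa_w == pytest.approx(1.0, abs=1e-15)

    def test_matches_brute_force_on_stated_example(self):
        m = two_rater([1, 2, 3, 4], [1, 2, 4, 3])
        table = contingency_table(*m.pair_codes("rater1", "rater2"))
        assert linear_weighted_kappa(m).kappa_w == pytest.approx(
            bf_weighted_kappa(table.tolist()), abs=1e-12
        )

    def test_matches_statsmodels_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(1, 5, 80)
            y = np.clip(x + rng.integers(-2, 3, 80), 1, 4)
            table = contingency_table(x, y)
            kappa, se, degenerate = weighted_kappa_from_table(table)
            assert not degenerate
            sm = cohens_kappa(table, wt="linear")
            assert kappa == pytest.approx(sm.kappa, abs=1e-12)
            assert se == pytest.approx(np.sqrt(sm.var_kappa), abs=1e-12)

    def test_symmetric_in_rater_order(self):
        a, b = [1, 2, 3, 4, 1, 2], [2, 2, 4, 3, 1, 3]
        fwd = linear_weighted_kappa(two_rater(a, b))
        rev = linear_weighted_kappa(two_rater(b, a))
        assert fwd.kappa_w == pytest.approx(rev.kappa_w, abs=1e-15)
        assert fwd.ci95 == pytest.approx(rev.ci95, abs=1e-15)

    def test_table_equals_case_by_case(self):
        rng = np.random.default_rng(11)
        x = rng.integers(1, 5, 200)
        y = rng.integers(1, 5, 200)
        kappa, _, _ = weighted_kappa_from_table(contingency_table(x, y))
        # case-by-case route: mean per-case weight vs chance expectation
        w = lambda i, j: 1.0 - abs(i - j) / 3.0
        po = np.mean([w(i, j) for i, j in zip(x, y)])
        pe = np.mean([w(i, j) for i in x for j in y])
        assert kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)

    def test_two_category_data_equals_unweighted_cohen(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 3, 100)
        y = np.where(rng.random(100) < 0.7, x, 3 - x)
        table = contingency_table(x, y, k=2)
        kappa, _, _ = weighted_kappa_from_table(table)
        assert kappa == pytest.approx(cohens_kappa(table).kappa, abs=1e-12)

    def test_constant_identical_raters_flagged_degenerate(self):
        result = linear_weighted_kappa(two_rater([2] * 6, [2] * 6))
        assert result.degenerate
        assert np.isnan(result.kappa_w)
        assert result.pct_exact_agreement == 100.0

    def test_insufficient_data_raises(self):
        m = RatingsMatrix.from_codes(
            np.array([[1.0, np.nan], [np.nan, 2.0], [1.0, 1.0]])
        )
        with pytest.raises(InsufficientDataError):
            linear_weighted_kappa(m)

    def test_ci_truncated_to_unit_interval(self):
        result = linear_weighted_kappa(two_rater([1, 2, 3, 4], [1, 2, 3, 4]))
        assert result.ci95[1] <= 1.0


class TestPercentages:
    def test_identical_columns_full_agreement(self):
        m = two_rater([1, 2, 3, 4], [1, 2, 3, 4])
        assert exact_agreement_pct(m) == 100.0
        assert extreme_disagreement_pct(m) == 0.0

    def test_disjoint_columns_zero_agreement(self):
        m = two_rater([1, 1, 1, 1], [2, 3, 2, 4])
        assert exact_agreement_pct(m) == 0.0

    def test_seventeen_of_forty_identical(self):
        a = [1] * 40
        b = [1] * 17 + [2] * 23
        assert exact_agreement_pct(two_rater(a, b)) == pytest.approx(42.5)

    def test_possible_definite_is_extreme_probable_definite_is_not(self):
        base = [3, 3, 3]
        assert extreme_disagreement_pct(two_rater([2, 3, 3], [4, 3, 3])) > 0
        assert extreme_disagreement_pct(two_rater([3, 3, 3], [4, 3, 3])) == 0.0

    def test_single_extreme_pair_in_forty(self):
        a = [3] * 40
        b = [3] * 39 + [1]
        assert extreme_disagreement_pct(two_rater(a, b)) == pytest.approx(2.5)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        codes=st.lists(
            st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=1, max_size=60
        )
    )
    def test_agreement_fractions_partition(self, codes):
        """%EA + %(one step) + %ED = 100 on any two-rater matrix."""
        a, b = zip(*codes)
        m = two_rater(list(a), list(b))
        one_step = 100.0 * np.mean(np.abs(np.array(a) - np.array(b)) == 1)
        total = exact_agreement_pct(m) + one_step + extreme_disagreement_pct(m)
        assert total == pytest.approx(100.0, abs=1e-9)


class TestFleissKappa:
    def test_unanimous_panel_is_one(self):
        codes = np.repeat([[1], [3], [4], [2]], 5, axis=1).astype(float)
        m = RatingsMatrix.from_codes(codes)
        assert fleiss_kappa(m).kappa_fleiss == pytest.approx(1.0, abs=1e-15)

    def test_matches_brute_force_and_statsmodels_on_fixed_counts(self):
        rng = np.random.default_rng(9)
        counts = rng.multinomial(7, [0.1, 0.3, 0.4, 0.2], size=20)
        kappa, se, degenerate = fleiss_kappa_from_counts(counts)
        assert not degenerate
        assert kappa == pytest.approx(bf_fleiss_kappa(counts.tolist()), abs=1e-12)
        assert kappa == pytest.approx(sm_fleiss_kappa(counts), abs=1e-12)
        assert se > 0

    def test_independent_uniform_raters_near_zero(self):
        rng = np.random.default_rng(2000)
        m = RatingsMatrix.from_codes(rng.integers(1, 5, (2000, 7)).astype(float))
        g = fleiss_kappa(m)
        assert abs(g.kappa_fleiss) <= 3 * g.se

    def test_permutation_invariance(self, panel_matrix, rng):
        base = fleiss_kappa(panel_matrix).kappa_fleiss
        codes = panel_matrix.codes.to_numpy()
        shuffled = codes[rng.permutation(codes.shape[0])][:, rng.permutation(codes.shape[1])]
        assert fleiss_kappa(RatingsMatrix.from_codes(shuffled)).kappa_fleiss == (
            pytest.approx(base, abs=1e-12)
        )

    def test_incomplete_cases_excluded_and_counted(self, small_matrix):
        g = fleiss_kappa(small_matrix)
        assert g.n_excluded_cases == 1
        assert g.n_cases == 5

    def test_too_few_cases_raises(self):
        m = RatingsMatrix.from_codes(np.array([[1.0, 2.0]]))
        with pytest.raises(InsufficientDataError):
            fleiss_kappa(m)

    def test_unanimous_single_category_degenerate(self):
        m = RatingsMatrix.from_codes(np.full((6, 4), 3.0))
        g = fleiss_kappa(m)
        assert g.degenerate and np.isnan(g.kappa_fleiss)


class TestAltmanBand:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.3, "poor"),
            (0.13, "poor"),
            (0.20, "poor"),
            (0.27, "fair"),
            (0.45, "moderate"),
            (0.48, "moderate"),
            (0.60, "moderate"),
            (0.605, "good"),
            (0.75, "good"),
            (0.86, "very good"),
            (1.0, "very good"),
        ],
    )
    def test_bands(self, kappa, label):
        assert altman_band(kappa) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            altman_band(1.2)

    def test_nan_undefined(self):
        assert altman_band(float("nan")) == "undefined"


class TestAgreementReport:
    def test_seven_raters_give_21_pairs(self, panel_matrix):
        report = agreement_report(panel_matrix)
        assert len(report.pairwise) == 21
        assert report.global_.band == altman_band(report.global_.kappa_fleiss)

    def test_two_raters_give_one_pair(self):
        m = two_rater([1, 2, 3, 4, 2], [1, 2, 3, 3, 2])
        report = agreement_report(m)
        assert len(report.pairwise) == 1
        assert not np.isnan(report.global_.kappa_fleiss)

    def test_identical_panel_all_perfect(self):
        codes = np.repeat([[1], [2], [3], [4]], 3, axis=1).astype(float)
        report = agreement_report(RatingsMatrix.from_codes(codes))
        for p in report.pairwise:
            assert p.pct_exact_agreement == 100.0
            assert p.pct_extreme_disagreement == 0.0
            assert p.kappa_w == pytest.approx(1.0, abs=1e-15)
        assert report.global_.kappa_fleiss == pytest.approx(1.0, abs=1e-15)

    def test_markdown_layout_has_all_pairs(self, panel_matrix):
        md = agreement_report(panel_matrix).to_markdown()
        assert md.count("%EA/%ED") == 6  # one row block per assessor but the last
        assert "Global kappa" in md

    def test_json_dict_round_trips_counts(self, panel_matrix):
        doc = agreement_report(panel_matrix).to_dict()
        assert len(doc["pairwise"]) == 21
        assert doc["global"]["n_raters"] == 7
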