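"""Rater contingency tests and intensity–amplitude correlation."""

import numpy as np
import pandas as pd
import pytest

from stapetrack import (
    ContingencyTable2x2,
    RaterSummary,
    chi_square_2x2,
    pairwise_rater_tests,
    pearson_correlation,
)
from stapetrack.datasets import load_rater_counts
from stapetrack.stats import (
    DegenerateTableError,
    summaries_from_counts,
    summaries_from_detections,
)


@pytest.fixture(scope="module")
def study_summaries():
    return summaries_from_counts(load_rater_counts())


class TestChiSquare:
    def test_identical_rows_independent(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(30, 70, 30, 70))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_software_vs_surgeon_totals(self):
        """Published overall totals: uncorrected Pearson chi-square gives
        p = 0.0007 to one significant figure."""
        stat, p = chi_square_2x2(ContingencyTable2x2(226, 161, 179, 208))
        assert 0.00065 < p < 0.00075

    @pytest.mark.parametrize(
        "table",
        [ContingencyTable2x2(10, 10, 10, 10), ContingencyTable2x2(15, 5, 5, 15)],
    )
    def test_matches_hand_formula(self, table):
        """Direct evaluation of sum (O - E)^2 / E."""
        O = table.as_array().astype(float)
        E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
        expected = np.sum((O - E) ** 2 / E)
        stat, _ = chi_square_2x2(table)
        assert stat == pytest.approx(expected)

    def test_row_and_column_swap_invariance(self):
        t = ContingencyTable2x2(20, 5, 8, 17)
        s0, p0 = chi_square_2x2(t)
        s1, p1 = chi_square_2x2(ContingencyTable2x2(8, 17, 20, 5))
        s2, p2 = chi_square_2x2(ContingencyTable2x2(5, 20, 17, 8))
        assert s0 == pytest.approx(s1) == pytest.approx(s2)
        assert p0 == pytest.approx(p1) == pytest.approx(p2)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2(ContingencyTable2x2(0, 10, 0, 20))

    def test_yates_reduces_statistic(self):
        t = ContingencyTable2x2(20, 5, 8, 17)
        plain, _ = chi_square_2x2(t, continuity_correction=False)
        yates, _ = chi_square_2x2(t, continuity_correction=True)
        assert yates < plain


class TestPairwiseRaterTests:
    def test_identical_summaries_all_p_one(self):
        s = [RaterSummary(r, 100, 40) for r in "abcd"]
        table = pairwise_rater_tests(s)
        assert len(table) == 6
        assert np.allclose(table["p_raw"], 1.0)
        assert np.allclose(table["p_adjusted"], 1.0)

    def test_published_totals(self, study_summaries):
        table = pairwise_rater_tests(study_summaries)
        get = lambda a, b: table[(table.rater_a == a) & (table.rater_b == b)].iloc[0]
        assert get("software", "intermediate")["p_raw"] < 0.0001
        assert get("software", "unexperienced")["p_raw"] < 0.0001
        assert 0.00065 < get("software", "experienced")["p_raw"] < 0.00075

    def test_bonferroni_cap(self):
        s = [
            RaterSummary("a", 100, 40),
            RaterSummary("b", 100, 45),
            RaterSummary("c", 100, 38),
        ]
        table = pairwise_rater_tests(s)
        # 3 raters -> 3 comparisons; adjustment is 3 * p capped at 1
        assert np.allclose(
            table["p_adjusted"], np.minimum(1.0, 3 * table["p_raw"])
        )
        assert (table["p_adjusted"] <= 1.0).all()

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError, match="applied"):
            pairwise_rater_tests([RaterSummary("a", 100, 40), RaterSummary("b", 99, 40)])


class TestPearsonCorrelation:
    def test_perfect_linear(self):
        levels = np.arange(5, 20, dtype=float)
        r = pearson_correlation(levels, 2 * levels)
        assert r.r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        levels = np.arange(5, 20, dtype=float)
        r = pearson_correlation(levels, -levels + 7)
        assert r.r == pytest.approx(-1.0)

    def test_noisy_fixture_matches_covariance_formula(self):
        rng = np.random.default_rng(12)
        levels = np.arange(15, dtype=float)
        amps = 0.1 * levels + rng.normal(0, 0.2, 15)
        res = pearson_correlation(levels, amps)
        lc = levels - levels.mean()
        ac = amps - amps.mean()
        expected = np.sum(lc * ac) / np.sqrt(np.sum(lc**2) * np.sum(ac**2))
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert abs(res.r - expected) < 0.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = pearson_correlation(x, y).r
        r1 = pearson_correlation(3 * x + 2, 0.5 * y - 4).r
        assert r1 == pytest.approx(r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2, 3], [5, 5, 5])

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])


class TestStudyCounts:
    def test_overall_rates(self, study_summaries):
        rates = {s.rater: 100 * s.rate for s in study_summaries}
        assert rates["software"] == pytest.approx(58.4, abs=0.05)
        assert rates["experienced"] == pytest.approx(46.3, abs=0.05)
        assert rates["intermediate"] == pytest.approx(37.7, abs=0.05)
        assert rates["unexperienced"] == pytest.approx(41.6, abs=0.05)

    def test_totals(self, study_summaries):
        assert all(s.applied == 387 for s in study_summaries)

    def test_summaries_from_detections(self):
        df = pd.DataFrame(
            {
                "rater": ["software"] * 4 + ["experienced"] * 4,
                "detected": [True, True, False, True, False, True, False, False],
            }
        )
        s = summaries_from_detections(df)
        assert {x.rater: x.detected for x in s} == {"software": 3, "experienced": 1}
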