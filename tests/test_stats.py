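"""2x2 diagnostics, ROC, logistic regression and the group tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rspi.model import InputError
from rspi.stats import (
    TwoByTwo,
    chi_square,
    diagnostics,
    logistic_univariate,
    mann_whitney,
    mcnemar_paired,
    roc,
    spearman,
    wilcoxon_paired,
    group_tests,
)


def auc_oracle(scores, labels):
    """All-pairs concordance count: P(responder score > non-responder) + ties/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


class TestDiagnostics:
    def test_reconstructed_cohort_counts(self):
        d = diagnostics(TwoByTwo(tp=18, fp=1, fn=18, tn=12))
        assert d.sensitivity == pytest.approx(0.50)
        assert d.npv == pytest.approx(0.40)
        assert d.specificity == pytest.approx(12 / 13)
        assert d.ppv == pytest.approx(18 / 19)
        assert d.odds_ratio == pytest.approx(12.0)
        lo, hi = d.or_ci
        assert lo < 12.0 < hi

    def test_perfect_separation(self):
        d = diagnostics(TwoByTwo(tp=10, fp=0, fn=0, tn=10))
        assert d.sensitivity == 1.0 and d.specificity == 1.0
        assert math.isinf(d.odds_ratio) and d.or_ci is None

    def test_no_association(self):
        d = diagnostics(TwoByTwo(tp=5, fp=5, fn=5, tn=5))
        assert d.sensitivity == d.specificity == d.ppv == d.npv == 0.5
        assert d.odds_ratio == pytest.approx(1.0)

    def test_zero_margin_marks_only_affected_statistic(self):
        d = diagnostics(TwoByTwo(tp=5, fp=0, fn=5, tn=0))
        assert d.specificity is None and d.odds_ratio is None
        assert d.sensitivity == 0.5 and d.ppv == 1.0 and d.npv == 0.0

    def test_haldane_correction_restores_finite_or(self):
        raw = diagnostics(TwoByTwo(tp=10, fp=0, fn=2, tn=10))
        adj = diagnostics(TwoByTwo(tp=10, fp=0, fn=2, tn=10), haldane=True)
        assert math.isinf(raw.odds_ratio)
        expected = (10.5 * 10.5) / (0.5 * 2.5)
        assert adj.odds_ratio == pytest.approx(expected)
        assert adj.or_ci[0] < adj.odds_ratio < adj.or_ci[1]

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=0)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30))
    def test_wald_ci_brackets_or(self, tp, fp, fn, tn):
        d = diagnostics(TwoByTwo(tp, fp, fn, tn))
        assert d.or_ci[0] <= d.odds_ratio <= d.or_ci[1]


class TestROC:
    def test_uninformative_scores_auc_half(self):
        r = roc([5] * 10, [True] * 5 + [False] * 5)
        assert r.auc == pytest.approx(0.5)

    def test_full_separation(self):
        scores = [10] * 6 + [2] * 6
        labels = [True] * 6 + [False] * 6
        r = roc(scores, labels)
        assert r.auc == pytest.approx(1.0)
        # every cutoff in 3..10 achieves J=1; ties resolve to the largest
        assert r.optimal_cutoff == 10

    def test_auc_equals_concordance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            scores = rng.integers(0, 13, size=n)
            labels = rng.random(n) < 0.6
            if labels.all() or not labels.any():
                continue
            r = roc(scores, labels)
            assert r.auc == pytest.approx(auc_oracle(scores, labels),
                                          abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(InputError):
            roc([1, 2, 3], [True, True, True])

    def test_ordering_invariance(self, rng):
        scores = rng.integers(0, 13, size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        perm = rng.permutation(30)
        r1 = roc(scores, labels)
        r2 = roc(scores[perm], labels[perm])
        assert r1.auc == r2.auc and r1.optimal_cutoff == r2.optimal_cutoff


class TestLogisticUnivariate:
    def test_binary_predictor_or_matches_cross_product(self):
        # reconstructed cohort: 19 high scorers (18 responders), 30 low (18/12)
        x = np.array([1.0] * 19 + [0.0] * 30)
        y = np.array([True] * 18 + [False] * 1 + [True] * 18 + [False] * 12)
        fit = logistic_univariate(x, y)
        assert fit.estimable
        assert fit.odds_ratio == pytest.approx(12.0, rel=1e-6)
        assert fit.or_ci[0] < 12.0 < fit.or_ci[1]

    def test_random_2x2_tables_match_cross_product(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(2, 40, size=4)
            x = np.r_[np.ones(tp + fp), np.zeros(fn + tn)]
            y = np.r_[np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
            fit = logistic_univariate(x, y)
            assert fit.odds_ratio == pytest.approx((tp * tn) / (fp * fn),
                                                   rel=1e-6)

    def test_constant_predictor_flagged(self):
        fit = logistic_univariate([0.0] * 20,
                                  [True] * 10 + [False] * 10)
        assert not fit.estimable and fit.odds_ratio is None

    def test_separated_binary_predictor_flagged(self):
        x = [1.0] * 10 + [0.0] * 10
        y = [True] * 10 + [False] * 10
        assert not logistic_univariate(x, y).estimable

    def test_single_class_outcome_errors(self):
        with pytest.raises(InputError):
            logistic_univariate([0.0, 1.0], [True, True])

    def test_continuous_predictor_recovery(self, rng):
        """At n=500 the MLE of a unit slope lands within 3 SE of truth."""
        n = 500
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
        y = rng.random(n) < p
        fit = logistic_univariate(x, y)
        assert fit.estimable
        assert abs(fit.beta - 1.0) < 3 * fit.se


class TestGroupTests:
    def test_mann_whitney_exact_small_sample(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_wilcoxon_identical_pairs(self):
        _, p = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_mcnemar_no_discordance(self):
        _, p = mcnemar_paired(0, 0)
        assert p == 1.0

    def test_mcnemar_exact_binomial(self):
        # 8 vs 1 discordant pairs: two-sided exact binomial
        _, p = mcnemar_paired(8, 1)
        expected = 2 * sum(math.comb(9, k) for k in (0, 1)) / 2 ** 9
        assert p == pytest.approx(expected)

    def test_spearman_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 25, 80])
        assert rho == pytest.approx(1.0)

    def test_chi_square_runs(self):
        stat, p = chi_square([[20, 10], [5, 15]])
        assert stat > 0 and 0 < p < 1

    def test_group_report_structure(self, rng):
        import pandas as pd
        n = 30
        df = pd.DataFrame({
            "responder": [True] * 18 + [False] * 12,
            "rspi_total": rng.integers(0, 13, size=n),
            "septal_flash": rng.integers(0, 2, size=n),
            "nyha_base": rng.choice([2, 3], size=n),
            "nyha_fu": rng.choice([1, 2], size=n),
            "pattern_base": rng.integers(0, 2, size=n),
            "pattern_fu": rng.integers(0, 2, size=n),
            "delta_lvesv_pct": rng.normal(20, 15, size=n),
        })
        rep = group_tests(df, continuous=["rspi_total"],
                          categorical=["septal_flash"],
                          paired=[("nyha_base", "nyha_fu"),
                                  ("pattern_base", "pattern_fu")])
        assert rep["rspi_total"]["test"] == "mann-whitney"
        assert rep["septal_flash"]["test"] == "chi-square"
        assert rep["nyha_base->nyha_fu"]["test"] == "wilcoxon"
        assert rep["pattern_base->pattern_fu"]["test"] == "mcnemar"
        for key in ("rspi_total", "septal_flash"):
            assert 0 <= rep[key]["p"] <= 1
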