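"""Confusion metrics, odds ratios, ROC/AUC machinery and the pipeline."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from breastdwi import (
    ConfusionMatrix,
    Pathology,
    RocCurve,
    compare_auc_independent,
    compare_auc_paired,
    confusion_metrics,
    empirical_roc,
    engineered_study_cohort,
    evaluate_pipeline,
    hanley_mcneil_se,
    odds_ratio,
    youden_cutoff,
)
from breastdwi.diagnostic_stats import adc_rank_sum, proportions_chi2
from conftest import make_mass


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting Mann-Whitney probability, ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = sum(1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_published_quantitative_counts(self):
        cm = ConfusionMatrix(tp=86, fp=6, fn=26, tn=23)
        assert confusion_metrics(cm) == {
            "sensitivity": 76.79, "specificity": 79.31, "ppv": 93.48,
            "npv": 46.94, "accuracy": 77.30}

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=7, fp=0, fn=0, tn=5)
        assert all(v == 100.0 for v in confusion_metrics(cm).values())

    def test_symmetric_matrix(self):
        cm = ConfusionMatrix(tp=1, fp=1, fn=1, tn=1)
        assert all(v == 50.0 for v in confusion_metrics(cm).values())

    def test_zero_denominator_is_undefined_not_zero(self):
        cm = ConfusionMatrix(tp=0, fp=0, fn=0, tn=10)
        m = confusion_metrics(cm)
        assert m["sensitivity"] is None and m["ppv"] is None
        assert m["specificity"] == 100.0

    def test_exact_rational_identity(self):
        """sens*(tp+fn) + spec*(tn+fp) == accuracy*total, exactly."""
        cm = ConfusionMatrix(tp=86, fp=6, fn=26, tn=23)
        m = confusion_metrics(cm, exact=True)
        lhs = m["sensitivity"] * (cm.tp + cm.fn) + m["specificity"] * (cm.tn + cm.fp)
        assert lhs == m["accuracy"] * cm.total
        assert m["sensitivity"] == Fraction(8600, 112)

    def test_from_calls(self):
        cm = ConfusionMatrix.from_calls([True, True, False, False],
                                        [True, False, True, False])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestOddsRatio:
    @pytest.mark.parametrize("table, or_expected, ci_expected", [
        # reference row first, columns (benign, malignant)
        (((14, 12), (9, 80)), 10.37, (3.69, 29.17)),   # irregular vs oval
        (((19, 4), (6, 58)), 45.92, (11.70, 180.18)),  # heterog. vs homog.
        (((17, 17), (5, 79)), 15.80, (5.12, 48.74)),   # ADC < vs >= cutoff
        (((13, 11), (12, 60)), 5.91, (2.14, 16.29)),   # irregular margin
    ])
    def test_published_univariate_tables(self, table, or_expected, ci_expected):
        res = odds_ratio(table)
        assert round(res.or_value, 2) == or_expected
        assert res.ci_low == pytest.approx(ci_expected[0], abs=0.005)
        assert res.ci_high == pytest.approx(ci_expected[1], abs=0.005)

    def test_woolf_ci_matches_statsmodels(self):
        """Independent cross-check of the log-variance interval against
        statsmodels' Table2x2 (same z -> same bounds)."""
        sm = pytest.importorskip("statsmodels.api")
        # statsmodels convention: rows = exposure (exposed first),
        # columns = (case, non-case)
        res = odds_ratio(((19, 4), (6, 58)))
        t22 = sm.stats.Table2x2([[58, 6], [4, 19]])
        assert res.or_value == pytest.approx(t22.oddsratio)
        lo, hi = t22.oddsratio_confint(0.05)
        # statsmodels uses z = 1.959964; this package fixes z = 1.96
        assert res.ci_low == pytest.approx(lo, rel=2e-3)
        assert res.ci_high == pytest.approx(hi, rel=2e-3)

    def test_symmetric_table_gives_unity(self):
        res = odds_ratio(((5, 5), (5, 5)))
        assert res.or_value == 1.0
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_is_undefined_not_exception(self):
        # spiculated-margin row of the univariate table: no benign lesion
        res = odds_ratio(((13, 11), (0, 25)))
        assert not res.defined
        assert res.or_value is None and res.ci_low is None

    def test_inversion_invariance(self):
        """OR(swap rows and columns) == OR; OR(rows swapped) == 1/OR."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            orig = odds_ratio(((a, b), (c, d))).or_value
            both = odds_ratio(((d, c), (b, a))).or_value
            rows = odds_ratio(((c, d), (a, b))).or_value
            assert both == pytest.approx(orig)
            assert rows * orig == pytest.approx(1.0)


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        roc = empirical_roc([0.1, 0.2, 0.9, 1.0],
                            [False, False, True, True])
        assert roc.auc == 1.0

    def test_auc_equals_brute_force_on_random_instances(self):
        """Tie-aware Mann-Whitney AUC == O(n^2) pair counting, 100 random
        instances including heavy ties."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(4, 120))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = rng.choice([0.2, 0.5, 0.5, 0.9, 1.3], size=n) \
                if rng.random() < 0.5 else rng.normal(size=n)
            roc = empirical_roc(list(scores), list(labels))
            assert roc.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_direction_flip_symmetry(self):
        rng = np.random.default_rng(9)
        scores = rng.permutation(40) / 7.0  # tie-free
        labels = rng.random(40) < 0.6
        hi = empirical_roc(list(scores), list(labels), "higher_is_positive")
        lo = empirical_roc(list(scores), list(labels), "lower_is_positive")
        assert hi.auc + lo.auc == pytest.approx(1.0, abs=1e-12)

    def test_auc_equals_trapezoid_over_points(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=60) + rng.random(60).round(1)  # some ties
        labels = rng.random(60) < 0.5
        roc = empirical_roc(list(scores), list(labels))
        trapezoid = np.trapezoid(roc.points[:, 1], roc.points[:, 2])
        assert roc.auc == pytest.approx(trapezoid, abs=1e-12)

    def test_hanley_mcneil_se_formula(self):
        """SE reproduces the Q1/Q2 closed form by direct re-derivation."""
        a, n1, n2 = 0.78, 20, 25
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        expected = math.sqrt((a * (1 - a) + (n1 - 1) * (q1 - a * a)
                              + (n2 - 1) * (q2 - a * a)) / (n1 * n2))
        assert hanley_mcneil_se(a, n1, n2) == pytest.approx(expected, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1.0, 2.0], [True, True])


class TestYoudenCutoff:
    def test_perfect_separation_two_gaussians(self):
        res = youden_cutoff([0.4, 0.5, 1.4, 1.5],
                            [True, True, False, False],
                            direction="lower_is_positive")
        assert res.j == pytest.approx(1.0)
        assert 0.5 < res.cutoff <= 1.4

    def test_matches_fine_grid_scan(self):
        """argmax over observed values == brute-force scan at 10x grid
        resolution, on random instances."""
        rng = np.random.default_rng(55)
        for _ in range(30):
            n = int(rng.integers(6, 80))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(1.0, 0.3, n), 2)
            res = youden_cutoff(list(scores), list(labels),
                                direction="lower_is_positive")
            pos, neg = scores[labels], scores[~labels]
            grid = np.linspace(scores.min() - 0.1, scores.max() + 0.1,
                               10 * n)
            j_grid = ((pos[:, None] < grid).mean(axis=0)
                      + (neg[:, None] >= grid).mean(axis=0) - 1)
            assert res.j == pytest.approx(j_grid.max(), abs=1e-12)

    def test_synthetic_adc_cohort_recovers_theoretical_cutoff(self):
        """On a two-truncated-Gaussian ADC cohort (study defaults,
        n = 10,000) the empirical maximum-Youden cutoff lands within 0.05
        of the numerically optimized population cutoff."""
        from breastdwi import default_config, generate_cohort, split_visible
        cohort = generate_cohort(default_config(n_lesions=10_000, seed=21))
        visible, _ = split_visible(cohort)
        adc = [r.adc for r in visible]
        labels = [r.pathology is Pathology.MALIGNANT for r in visible]
        res = youden_cutoff(adc, labels, direction="lower_is_positive")

        cfg = default_config()
        def trunc(p):
            a = (p.adc_range[0] - p.adc_mean) / p.adc_sd
            b = (p.adc_range[1] - p.adc_mean) / p.adc_sd
            return sps.truncnorm(a, b, loc=p.adc_mean, scale=p.adc_sd)
        mal, ben = trunc(cfg.malignant), trunc(cfg.benign)
        from scipy.optimize import minimize_scalar
        opt = minimize_scalar(lambda c: -(mal.cdf(c) - ben.cdf(c)),
                              bounds=(0.66, 1.36), method="bounded")
        assert abs(res.cutoff - opt.x) < 0.05

    def test_tie_break_prefers_higher_sensitivity(self):
        # cutoffs 0.9 and 1.5 both reach J = 0.5; 1.5 has sens 1 and wins
        res = youden_cutoff([0.4, 1.2, 0.9, 1.5],
                            [True, True, False, False],
                            direction="lower_is_positive")
        assert res.j == pytest.approx(0.5)
        assert res.sensitivity == 1.0
        assert res.cutoff == pytest.approx(1.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([1.0, 2.0], [False, False])


def _roc_stub(auc, n_pos, n_neg):
    return RocCurve(points=np.empty((0, 3)), auc=auc,
                    se_auc=hanley_mcneil_se(auc, n_pos, n_neg),
                    n_pos=n_pos, n_neg=n_neg)


class TestCompareAucIndependent:
    def test_identical_aucs(self):
        r = _roc_stub(0.8, 30, 30)
        out = compare_auc_independent(r, r)
        assert out["z"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_hand_computation_size_strata(self):
        """z for AUC 0.78 (20 pos / 25 neg) vs 0.84 (91 / 7) re-derived
        from the Q1/Q2 formulas by hand."""
        out = compare_auc_independent(_roc_stub(0.78, 20, 25),
                                      _roc_stub(0.84, 91, 7))

        def var(a, n1, n2):
            q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
            return (a * (1 - a) + (n1 - 1) * (q1 - a * a)
                    + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
        z_hand = (0.78 - 0.84) / math.sqrt(var(0.78, 20, 25) + var(0.84, 91, 7))
        assert out["z"] == pytest.approx(z_hand, abs=1e-12)
        assert out["p"] == pytest.approx(2 * sps.norm.sf(abs(z_hand)), abs=1e-12)

    def test_symmetric_under_swap(self):
        a, b = _roc_stub(0.7, 15, 20), _roc_stub(0.9, 25, 10)
        assert compare_auc_independent(a, b)["p"] == pytest.approx(
            compare_auc_independent(b, a)["p"])
        assert compare_auc_independent(a, b)["z"] == pytest.approx(
            -compare_auc_independent(b, a)["z"])


def delong_brute_force(s1, s2, labels):
    """Independent structural-components computation with explicit loops."""
    pos = [i for i, y in enumerate(labels) if y]
    neg = [i for i, y in enumerate(labels) if not y]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else 0.5 if x == y else 0.0

    stats_out = []
    for s in (s1, s2):
        v10 = [sum(psi(s[i], s[j]) for j in neg) / n for i in pos]
        v01 = [sum(psi(s[i], s[j]) for i in pos) / m for j in neg]
        stats_out.append((np.mean(v10), v10, v01))

    def cov(u, v):
        ubar, vbar = np.mean(u), np.mean(v)
        return sum((a - ubar) * (b - vbar) for a, b in zip(u, v)) / (len(u) - 1)

    (a1, v10_1, v01_1), (a2, v10_2, v01_2) = stats_out
    var = ((cov(v10_1, v10_1) + cov(v10_2, v10_2) - 2 * cov(v10_1, v10_2)) / m
           + (cov(v01_1, v01_1) + cov(v01_2, v01_2) - 2 * cov(v01_1, v01_2)) / n)
    return (a1 - a2) / math.sqrt(var)


class TestCompareAucPaired:
    def test_identical_scores_give_zero(self):
        s = [0.3, 0.5, 0.8, 0.9, 0.2, 0.7]
        y = [False, False, True, True, False, True]
        out = compare_auc_paired(s, s, y)
        assert out["z"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_matches_brute_force_structural_components(self):
        rng = np.random.default_rng(101)
        for _ in range(10):
            n = int(rng.integers(8, 40))
            y = rng.random(n) < 0.5
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            s1 = rng.normal(size=n) + y
            s2 = 0.5 * s1 + rng.normal(size=n)
            out = compare_auc_paired(list(s1), list(s2), list(y))
            assert out["z"] == pytest.approx(
                delong_brute_force(s1, s2, y), abs=1e-10)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(8)
        y = [True] * 10 + [False] * 12
        s1 = list(rng.normal(size=22) + np.array(y))
        s2 = list(rng.normal(size=22))
        assert compare_auc_paired(s1, s2, y)["z"] == pytest.approx(
            -compare_auc_paired(s2, s1, y)["z"], abs=1e-12)

    def test_mixed_directions(self):
        """An ADC-like marker (lower positive) can be compared with an
        ordinal score (higher positive)."""
        y = [True] * 8 + [False] * 8
        adc = [0.7] * 6 + [1.2] * 2 + [1.1] * 6 + [0.8] * 2
        score = [3] * 6 + [1] * 2 + [1] * 6 + [2] * 2
        out = compare_auc_paired(adc, score, y,
                                 direction1="lower_is_positive",
                                 direction2="higher_is_positive")
        assert math.isfinite(out["z"])


@pytest.fixture(scope="module")
def report():
    return evaluate_pipeline(engineered_study_cohort())


class TestEvaluatePipeline:
    def test_reproduces_published_performance_table(self, report):
        """The count-engineered cohort yields the published metric columns
        of all five readings."""
        expected = {
            "dwi_qualitative": dict(sensitivity=94.64, specificity=51.72,
                                    ppv=88.33, npv=71.43),
            "dwi_quantitative": dict(sensitivity=76.79, specificity=79.31,
                                     ppv=93.48, npv=46.94, accuracy=77.30),
            "dwi_combination": dict(sensitivity=92.86, specificity=72.41,
                                    ppv=92.86, npv=72.41, accuracy=88.65),
            "dce_only": dict(sensitivity=99.11, specificity=34.38,
                             ppv=84.09, npv=91.67, accuracy=84.72),
            "dce_plus_adc": dict(sensitivity=97.32, specificity=81.25,
                                 ppv=94.78, npv=89.66, accuracy=93.75),
        }
        for analysis, metrics in expected.items():
            got = report["analyses"][analysis]["metrics"]
            for name, value in metrics.items():
                assert got[name] == pytest.approx(value), (analysis, name)

    def test_visibility_accounting(self, report):
        assert report["n_total"] == 144
        assert report["n_visible"] == 141
        assert report["detection_rate_pct"] == pytest.approx(97.92)

    def test_dwi_analyses_use_visible_lesions_only(self, report):
        cm = report["analyses"]["dwi_quantitative"]["confusion"]
        assert cm.total == 141
        assert report["analyses"]["dce_only"]["confusion"].total == 144

    def test_combination_auc_is_balanced_accuracy(self, report):
        roc = report["analyses"]["dwi_combination"]["roc"]
        m = report["analyses"]["dwi_combination"]["metrics_exact"]
        assert roc.auc == pytest.approx(
            float(m["sensitivity"] + m["specificity"]) / 200, abs=1e-12)
        assert roc.auc == pytest.approx(0.826, abs=0.0005)

    def test_size_strata_partition_visible_lesions(self, report):
        by_size = report["combination_by_size"]
        assert by_size["small"]["n"] + by_size["large"]["n"] == 141
        assert report["combination_size_auc_comparison"] is not None

    def test_all_benign_cohort_has_undefined_sensitivity(self):
        cohort = [make_mass(lesion_id=f"b{k}", adc=1.2) for k in range(6)]
        rep = evaluate_pipeline(cohort)
        m = rep["analyses"]["dwi_quantitative"]["metrics"]
        assert m["sensitivity"] is None
        assert m["specificity"] is not None
        assert rep["analyses"]["dwi_quantitative"]["roc"] is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pipeline([])


class TestDelegatedTests:
    def test_chi2_smoke(self):
        out = proportions_chi2([[25, 20], [7, 91]])
        ref = sps.chi2_contingency(np.array([[25, 20], [7, 91]]))
        assert out["chi2"] == pytest.approx(ref.statistic)
        assert out["p"] == pytest.approx(ref.pvalue)

    def test_rank_sum_smoke(self):
        rng = np.random.default_rng(2)
        b, m = rng.normal(1.14, 0.23, 30), rng.normal(0.88, 0.19, 100)
        out = adc_rank_sum(list(b), list(m))
        ref = sps.mannwhitneyu(b, m, alternative="two-sided")
        assert out["p"] == pytest.approx(ref.pvalue)
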