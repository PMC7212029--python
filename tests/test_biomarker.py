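"""ROC construction, concordance AUC, bootstrap intervals, threshold
selection and classifier application for the low-expression LD rule."""
import numpy as np
import pytest

from conftest import make_norm
from wntstrat import (
    apply_classifier,
    bootstrap_ci,
    roc_curve,
    select_threshold,
)
from wntstrat.biomarker import concordance_auc, trapezoid_auc
from wntstrat.errors import DataError


def _instance(ld, li):
    scores, labels = {}, {}
    for i, v in enumerate(ld):
        scores[f"D{i}"] = float(v)
        labels[f"D{i}"] = "LD"
    for i, v in enumerate(li):
        scores[f"I{i}"] = float(v)
        labels[f"I{i}"] = "LI"
    return scores, labels


def auc_bruteforce(ld, li):
    """Pairwise concordance enumerated pair by pair."""
    total = 0.0
    for a in ld:
        for b in li:
            total += 1.0 if b > a else 0.5 if b == a else 0.0
    return total / (len(ld) * len(li))


class TestRocCurve:
    def test_perfect_separation(self):
        scores, labels = _instance([1, 2], [3, 4])
        curve, auc = roc_curve(scores, labels)
        assert auc == 1.0
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0

    def test_all_ties_is_half(self):
        scores, labels = _instance([5, 5], [5, 5])
        _, auc = roc_curve(scores, labels)
        assert auc == 0.5

    def test_hand_enumerated_pairs(self):
        # pairs (1<3), (1<1.5), (2<3) concordant; (2>1.5) discordant
        scores, labels = _instance([1, 2], [3, 1.5])
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        scores, labels = _instance(rng.normal(4, 1, 20), rng.normal(6, 1, 30))
        curve, _ = roc_curve(scores, labels)
        assert (np.diff(curve.sensitivity) <= 1e-12).all()
        assert (np.diff(curve.specificity) >= -1e-12).all()

    def test_ex_label_is_contract_error(self):
        scores, labels = _instance([1], [2])
        labels["D0"] = "EX"
        with pytest.raises(DataError, match="EX"):
            roc_curve(scores, labels)

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            roc_curve({"A": 1.0}, {"A": "LD"})


class TestAucEquivalences:
    def test_concordance_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n_ld = int(rng.integers(1, 20))
            n_li = int(rng.integers(1, 21))
            # discretised scores force ties
            ld = np.round(rng.normal(4, 1.5, n_ld), 1)
            li = np.round(rng.normal(5, 1.5, n_li), 1)
            assert concordance_auc(ld, li) == pytest.approx(
                auc_bruteforce(ld, li), abs=1e-12
            )

    def test_trapezoid_equals_concordance(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_ld = int(rng.integers(2, 20))
            n_li = int(rng.integers(2, 20))
            ld = np.round(rng.normal(4, 1.5, n_ld), 1)
            li = np.round(rng.normal(5, 1.5, n_li), 1)
            scores, labels = _instance(ld, li)
            curve, auc = roc_curve(scores, labels)
            assert trapezoid_auc(curve) == pytest.approx(auc, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        ld = rng.normal(4, 1, 15)
        li = rng.normal(6, 1, 25)
        base = concordance_auc(ld, li)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert concordance_auc(f(ld), f(li)) == pytest.approx(base, abs=1e-12)


class TestSelectThreshold:
    def test_separable_case_midpoint(self):
        scores, labels = _instance([1, 2], [3, 4])
        curve, _ = roc_curve(scores, labels)
        rule = select_threshold(curve)
        assert rule.threshold == pytest.approx(2.5)
        assert rule.achieved_sensitivity == 1.0
        assert rule.achieved_specificity == 1.0

    def test_matches_exhaustive_cutpoint_search(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            n_ld = int(rng.integers(2, 20))
            n_li = int(rng.integers(2, 21))
            ld = np.round(rng.normal(4, 1.5, n_ld), 1)
            li = np.round(rng.normal(5.5, 1.5, n_li), 1)
            scores, labels = _instance(ld, li)
            curve, _ = roc_curve(scores, labels)
            rule = select_threshold(curve)
            best = max(
                (ld < t).mean() + (li >= t).mean() for t in curve.thresholds
            )
            achieved = (
                rule.achieved_sensitivity + rule.achieved_specificity
            )
            assert achieved == pytest.approx(best, abs=1e-12)

    def test_tie_broken_by_higher_specificity(self):
        # LD=(1,3), LI=(2,4): thresholds 1.5 and 3.5 both reach sens+spec=1.5;
        # 1.5 wins on specificity
        scores, labels = _instance([1, 3], [2, 4])
        curve, _ = roc_curve(scores, labels)
        rule = select_threshold(curve)
        assert rule.threshold == pytest.approx(1.5)
        assert rule.achieved_specificity == 1.0


class TestBootstrapCi:
    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(31)
        scores, labels = _instance(rng.normal(4, 1, 30), rng.normal(6, 1, 40))
        a = bootstrap_ci(scores, labels, n_boot=300, seed=8)
        b = bootstrap_ci(scores, labels, n_boot=300, seed=8)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high

    def test_perfect_separation_keeps_high_lower_bound(self):
        rng = np.random.default_rng(32)
        scores, labels = _instance(rng.normal(0, 1, 50), 10 + rng.normal(0, 1, 50))
        summary = bootstrap_ci(scores, labels, n_boot=500, seed=0)
        assert summary.auc == 1.0 and summary.ci_low >= 0.9

    def test_interval_narrows_with_sample_size(self):
        widths = {}
        for n in (50, 400):
            deltas = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                scores, labels = _instance(
                    rng.normal(4.2, 0.8, n // 10), rng.normal(6.3, 0.8, n)
                )
                s = bootstrap_ci(scores, labels, n_boot=300, seed=seed)
                deltas.append(s.ci_high - s.ci_low)
            widths[n] = np.mean(deltas)
        assert widths[400] < widths[50]


class TestApplyClassifier:
    def _rule(self, threshold, gene="G"):
        from wntstrat.biomarker import ThresholdRule

        return ThresholdRule(
            gene=gene, threshold=threshold,
            achieved_sensitivity=1.0, achieved_specificity=1.0,
        )

    def test_boundary_goes_to_li(self):
        norm = make_norm({"G": [2.0, 3.0]}, ["S1", "S2"])
        predictions, _ = apply_classifier(self._rule(3.0), norm)
        assert predictions == {"S1": "LD", "S2": "LI"}

    def test_no_truth_no_report(self):
        norm = make_norm({"G": [1.0]}, ["S1"])
        predictions, report = apply_classifier(self._rule(2.0), norm)
        assert report is None and predictions["S1"] == "LD"

    def test_ex_samples_reported_not_scored(self):
        norm = make_norm({"G": [1.0, 2.0, 9.0]}, ["S1", "S2", "S3"])
        truth = {"S1": "LD", "S2": "EX", "S3": "LI"}
        _, report = apply_classifier(self._rule(3.0), norm, truth)
        assert report.tp + report.fn + report.tn + report.fp == 2
        assert report.ex_scores == {"S2": 2.0}

    def test_sens_spec_match_gaussian_tail_oracle(self):
        """At a fixed cutpoint on equal-variance Gaussian classes, the
        empirical sensitivity/specificity sit within 0.05 of the analytic
        tail probabilities."""
        from scipy.stats import norm as gauss

        mu_ld, mu_li, sigma, tau = 4.2, 6.3, 0.8, 5.25
        rng = np.random.default_rng(77)
        n = 4000
        samples = [f"S{i}" for i in range(2 * n)]
        values = np.concatenate(
            [rng.normal(mu_ld, sigma, n), rng.normal(mu_li, sigma, n)]
        )
        truth = {
            s: ("LD" if i < n else "LI") for i, s in enumerate(samples)
        }
        norm_m = make_norm({"G": list(values)}, samples)
        _, report = apply_classifier(self._rule(tau), norm_m, truth)
        assert report.sensitivity == pytest.approx(
            gauss.cdf((tau - mu_ld) / sigma), abs=0.05
        )
        assert report.specificity == pytest.approx(
            1 - gauss.cdf((tau - mu_li) / sigma), abs=0.05
        )

    def test_threshold_converges_to_class_midpoint(self):
        """For equal-variance Gaussians the optimal cutpoint approaches
        (mu_ld + mu_li) / 2 at large n."""
        mu_ld, mu_li, sigma = 4.2, 6.3, 0.8
        taus = []
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            scores, labels = _instance(
                rng.normal(mu_ld, sigma, 2000), rng.normal(mu_li, sigma, 2000)
            )
            curve, _ = roc_curve(scores, labels)
            taus.append(select_threshold(curve).threshold)
        assert abs(np.mean(taus) - (mu_ld + mu_li) / 2) < 0.1
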