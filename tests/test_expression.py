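"""Normalisation, outlier z-scores, Welch differential expression and
signature scores, each checked against hand-derived values or textbook
oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from conftest import bh_oracle, make_norm, welch_oracle
from wntstrat import (
    SimulationConfig,
    differential_expression,
    log_cpm,
    signature_score,
    simulate_cohort,
    zscore_outliers,
)
from wntstrat.cohort import ExpressionMatrix
from wntstrat.config import replace_config
from wntstrat.errors import DataError
from wntstrat.expression import benjamini_hochberg, welch_t_matrix


def _counts(values, genes, samples):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples, dtype=np.int64),
        space="counts",
    )


class TestLogCpm:
    def test_zero_count_maps_to_zero(self):
        m = _counts([[0, 10], [1000, 990]], ["A", "B"], ["S1", "S2"])
        norm = log_cpm(m)
        assert norm.values.loc["A", "S1"] == 0.0

    def test_formula_value(self):
        # count 10 in library 1000 -> log2(1 + 10000)
        m = _counts([[10], [990]], ["A", "B"], ["S1"])
        norm = log_cpm(m)
        assert norm.values.loc["A", "S1"] == pytest.approx(
            math.log2(1 + 1e4), abs=1e-12
        )

    def test_scale_invariance(self):
        m1 = _counts([[10, 3], [90, 7]], ["A", "B"], ["S1", "S2"])
        m2 = _counts([[20, 3], [180, 7]], ["A", "B"], ["S1", "S2"])
        pd.testing.assert_series_equal(
            log_cpm(m1).values["S1"], log_cpm(m2).values["S1"]
        )

    def test_zero_library_size_names_sample(self):
        m = _counts([[0, 10]], ["A"], ["S1", "S2"])
        with pytest.raises(DataError, match="S1"):
            log_cpm(m)


class TestZscoreOutliers:
    def test_hand_computed_z(self):
        # values [1,2,3,4,100]: mean 22, sd 43.617..., z(100)=1.788...
        samples = [f"S{i}" for i in range(5)]
        norm = make_norm({"G": [1, 2, 3, 4, 100]}, samples)
        calls = zscore_outliers(norm, ["G"], threshold=2)
        by_sample = {c.sample_id: c for c in calls}
        x = np.array([1, 2, 3, 4, 100.0])
        expected = (100 - x.mean()) / x.std(ddof=1)
        assert by_sample["S4"].z == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.7883, abs=1e-3)
        assert not by_sample["S4"].is_outlier

    def test_threshold_is_inclusive(self):
        samples = [f"S{i}" for i in range(4)]
        values = [0.0, 0.0, 0.0, 1.0]
        x = np.array(values)
        z_top = (1.0 - x.mean()) / x.std(ddof=1)
        norm = make_norm({"G": values}, samples)
        calls = zscore_outliers(norm, ["G"], threshold=z_top)
        assert {c.sample_id: c.is_outlier for c in calls}["S3"] is True

    def test_constant_gene_rejected(self):
        norm = make_norm({"G": [5, 5, 5, 5]}, [f"S{i}" for i in range(4)])
        with pytest.raises(DataError, match="G"):
            zscore_outliers(norm, ["G"])

    def test_planted_rspo_high_recovered(self):
        """The default RSPO shift puts >=90% of planted RSPO-high samples
        above z=2 and <=2% of everything else (20 seeds)."""
        hits = misses = others_flagged = others_total = 0
        for seed in range(20):
            cfg = replace_config(SimulationConfig(), n_samples=300, seed=seed)
            bundle, truth = simulate_cohort(cfg, with_reads=False)
            norm = log_cpm(bundle.expression)
            calls = zscore_outliers(norm, ["RSPO2", "RSPO3"], threshold=2)
            flagged = {c.sample_id for c in calls if c.is_outlier}
            for rec in truth.records:
                if rec.true_subtype == "RSPO_HIGH":
                    hits += rec.sample_id in flagged
                    misses += rec.sample_id not in flagged
                elif rec.true_subtype != "RSPO_FUSION":
                    others_total += 1
                    others_flagged += rec.sample_id in flagged
        assert hits / (hits + misses) >= 0.90
        assert others_flagged / others_total <= 0.02


class TestDifferentialExpression:
    def test_identical_groups_null_identity(self):
        samples = [f"S{i}" for i in range(6)]
        norm = make_norm({"G": [1, 2, 3, 1, 2, 3]}, samples)
        labels = {s: ("LD" if i < 3 else "LI") for i, s in enumerate(samples)}
        (res,) = differential_expression(norm, labels)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_small_group_rejected(self):
        samples = ["S0", "S1", "S2"]
        norm = make_norm({"G": [1, 2, 3]}, samples)
        labels = {"S0": "LD", "S1": "LI", "S2": "LI"}
        with pytest.raises(DataError, match="LD=1"):
            differential_expression(norm, labels)

    def test_degenerate_gene_flagged_not_fatal(self):
        samples = [f"S{i}" for i in range(6)]
        norm = make_norm(
            {"C": [7, 7, 7, 7, 7, 7], "G": [1, 2, 3, 4, 5, 6]}, samples
        )
        labels = {s: ("LD" if i < 3 else "LI") for i, s in enumerate(samples)}
        results = {r.gene: r for r in differential_expression(norm, labels)}
        assert results["C"].degenerate and results["C"].p == 1.0
        assert not results["G"].degenerate

    def test_mean_diff_orientation_is_li_minus_ld(self):
        samples = [f"S{i}" for i in range(6)]
        norm = make_norm({"G": [1.0, 1.0, 1.0, 3.0, 3.0, 3.0]}, samples)
        labels = {s: ("LD" if i < 3 else "LI") for i, s in enumerate(samples)}
        (res,) = differential_expression(norm, labels)
        assert res.mean_diff == pytest.approx(2.0)

    def test_planted_effect_detected(self):
        """mean_diff 2.1, sigma 0.8, n=50/50: AXIN2 passes q<1e-6 in >=95%
        of 20 seeds."""
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"S{i}" for i in range(100)]
            labels = {s: ("LD" if i < 50 else "LI") for i, s in enumerate(samples)}
            data = {"AXIN2": np.concatenate([
                rng.normal(4.2, 0.8, 50), rng.normal(6.3, 0.8, 50)
            ])}
            for g in range(20):
                data[f"BG{g:03d}"] = rng.normal(5, 1, 100)
            norm = make_norm({k: list(v) for k, v in data.items()}, samples)
            results = {r.gene: r for r in differential_expression(norm, labels)}
            detected += results["AXIN2"].q < 1e-6
        assert detected >= 19


class TestBenjaminiHochberg:
    def test_hand_stepped_example(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 then monotone -> all 0.04
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_oracle(p), atol=1e-12
            )


class TestWelch:
    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            na, nb = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            a = rng.normal(rng.normal(), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.normal(), rng.uniform(0.5, 3), nb)
            t, df, p, _ = welch_t_matrix(a[None, :], b[None, :])
            t0, df0, p0 = welch_oracle(a, b)
            assert t[0] == pytest.approx(t0, rel=1e-10)
            assert df[0] == pytest.approx(df0, rel=1e-10)
            assert p[0] == pytest.approx(p0, rel=1e-10)


class TestSignatureScore:
    def test_single_gene_signature_equals_zscore(self):
        samples = [f"S{i}" for i in range(4)]
        norm = make_norm({"G": [1, 2, 3, 4], "H": [4, 3, 2, 1]}, samples)
        scores, dropped = signature_score(norm, ["G"], "sig")
        x = np.array([1, 2, 3, 4.0])
        z = (x - x.mean()) / x.std(ddof=1)
        for s, zi in zip(scores, z):
            assert s.score == pytest.approx(zi, abs=1e-12)
        assert dropped == []

    def test_cohort_mean_is_zero(self):
        samples = [f"S{i}" for i in range(5)]
        norm = make_norm(
            {"G": [1, 5, 2, 4, 3], "H": [2, 2, 9, 1, 3]}, samples
        )
        scores, _ = signature_score(norm, ["G", "H"], "sig")
        assert sum(s.score for s in scores) == pytest.approx(0.0, abs=1e-9)

    def test_absent_genes_dropped_and_reported(self):
        samples = [f"S{i}" for i in range(3)]
        norm = make_norm({"G": [1, 2, 3]}, samples)
        _, dropped = signature_score(norm, ["G", "MISSING"], "sig")
        assert dropped == ["MISSING"]

    def test_all_absent_rejected(self):
        norm = make_norm({"G": [1, 2, 3]}, ["S0", "S1", "S2"])
        with pytest.raises(DataError):
            signature_score(norm, ["X", "Y"], "sig")
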