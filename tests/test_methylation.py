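"""Gene-level beta summaries, differential methylation, CIMP strata and
methylation-expression coupling."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_norm, welch_oracle
from wntstrat import (
    cimp_stratified_comparison,
    dmp_test,
    mean_beta_per_gene,
    meth_expr_correlation,
)
from wntstrat.cohort import MethylationMatrix
from wntstrat.errors import DataError
from wntstrat.methylation import summaries_to_frame


def _meth(beta_rows, probes, samples, genes):
    return MethylationMatrix(
        beta=pd.DataFrame(beta_rows, index=probes, columns=samples, dtype=float),
        probe_map=pd.Series(genes, index=probes),
    )


class TestMeanBeta:
    def test_single_probe_passthrough(self):
        meth = _meth([[0.3, 0.6]], ["p1"], ["S1", "S2"], ["AXIN2"])
        out = mean_beta_per_gene(meth, ["AXIN2"])
        assert {(s.sample_id, s.mean_beta) for s in out} == {("S1", 0.3), ("S2", 0.6)}

    def test_two_probe_mean(self):
        meth = _meth([[0.2], [0.4]], ["p1", "p2"], ["S1"], ["AXIN2", "AXIN2"])
        (s,) = mean_beta_per_gene(meth, ["AXIN2"])
        assert s.mean_beta == pytest.approx(0.3)

    def test_unmapped_gene_rejected(self):
        meth = _meth([[0.2]], ["p1"], ["S1"], ["AXIN2"])
        with pytest.raises(DataError, match="NKD1"):
            mean_beta_per_gene(meth, ["NKD1"])

    def test_output_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        beta = rng.random((6, 10))
        meth = _meth(
            beta, [f"p{i}" for i in range(6)], [f"S{i}" for i in range(10)],
            ["G1"] * 3 + ["G2"] * 3,
        )
        out = mean_beta_per_gene(meth, ["G1", "G2"])
        assert all(0 <= s.mean_beta <= 1 for s in out)


class TestDmpTest:
    def _labels(self, samples, n_ld):
        return {s: ("LD" if i < n_ld else "LI") for i, s in enumerate(samples)}

    def test_welch_against_textbook_oracle(self):
        samples = ["S1", "S2", "S3", "S4"]
        meth = _meth([[0.8, 0.9, 0.1, 0.2]], ["p1"], samples, ["AXIN2"])
        (res,) = dmp_test(meth, self._labels(samples, 2))
        t0, _, p0 = welch_oracle([0.8, 0.9], [0.1, 0.2])
        assert res.t_stat == pytest.approx(t0, rel=1e-10)
        assert res.p == pytest.approx(p0, rel=1e-10)
        assert res.direction == "hyper" and res.mean_diff == pytest.approx(0.7)

    def test_identical_groups_p_one(self):
        samples = ["S1", "S2", "S3", "S4"]
        meth = _meth([[0.5, 0.5, 0.5, 0.5]], ["p1"], samples, ["AXIN2"])
        (res,) = dmp_test(meth, self._labels(samples, 2))
        assert res.p == 1.0 and res.degenerate

    def test_direction_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(12)]
        meth = _meth(
            rng.random((4, 12)), [f"p{i}" for i in range(4)], samples,
            ["G1", "G1", "G2", "G2"],
        )
        labels = self._labels(samples, 6)
        swapped = {s: ("LD" if l == "LI" else "LI") for s, l in labels.items()}
        for a, b in zip(dmp_test(meth, labels), dmp_test(meth, swapped)):
            assert a.mean_diff == pytest.approx(-b.mean_diff, abs=1e-12)
            assert {a.direction, b.direction} == {"hyper", "hypo"} or (
                a.mean_diff == 0
            )

    def test_planted_axin2_hypermethylation_detected(self):
        """With the default coupling, every AXIN2 probe is significantly
        hypermethylated in LD in >=90% of 20 seeds."""
        from wntstrat import SimulationConfig, simulate_cohort
        from wntstrat.config import replace_config

        wins = 0
        for seed in range(20):
            cfg = replace_config(SimulationConfig(), n_samples=250, seed=seed)
            bundle, truth = simulate_cohort(cfg, with_reads=False)
            results = dmp_test(bundle.methylation, truth.classes())
            axin2 = [r for r in results if r.gene == "AXIN2"]
            wins += all(r.q < 0.05 and r.direction == "hyper" for r in axin2)
        assert wins >= 18


class TestCimpComparison:
    def _summaries(self, frame):
        from wntstrat.methylation import GeneMethylationSummary

        return [
            GeneMethylationSummary(g, s, frame.loc[g, s])
            for g in frame.index for s in frame.columns
        ]

    def test_degenerate_stratum_marked_not_testable(self):
        samples = ["S1", "S2", "S3", "S4"]
        frame = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4]], index=["AXIN2"], columns=samples
        )
        labels = {s: "LI" for s in samples}
        cimp = {s: False for s in samples}  # all CIMP-negative
        rows = cimp_stratified_comparison(self._summaries(frame), labels, cimp)
        li_row = next(r for r in rows if r.label == "LI")
        assert not li_row.testable and np.isnan(li_row.p)

    def test_cimp_effect_detected_for_bimodal_gene(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(40)]
        cimp = {s: i < 20 for i, s in enumerate(samples)}
        values = np.where(
            [cimp[s] for s in samples],
            rng.normal(0.7, 0.05, 40),
            rng.normal(0.2, 0.05, 40),
        )
        frame = pd.DataFrame([values], index=["NOTUM"], columns=samples)
        labels = {s: "LI" for s in samples}
        rows = cimp_stratified_comparison(self._summaries(frame), labels, cimp)
        li_row = next(r for r in rows if r.label == "LI")
        assert li_row.testable and li_row.p < 1e-6
        assert li_row.mean_beta_cimp_pos > li_row.mean_beta_cimp_neg


class TestCorrelation:
    def test_affine_decreasing_gives_minus_one(self):
        from wntstrat.methylation import GeneMethylationSummary

        samples = [f"S{i}" for i in range(5)]
        expr = [1.0, 2.0, 3.0, 4.0, 5.0]
        norm = make_norm({"AXIN2": expr}, samples)
        summaries = [
            GeneMethylationSummary("AXIN2", s, 0.9 - 0.1 * x)
            for s, x in zip(samples, expr)
        ]
        (res,) = meth_expr_correlation(summaries, norm)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.n == 5

    def test_constant_beta_undefined(self):
        from wntstrat.methylation import GeneMethylationSummary

        samples = ["S1", "S2", "S3"]
        norm = make_norm({"AXIN2": [1.0, 2.0, 3.0]}, samples)
        summaries = [GeneMethylationSummary("AXIN2", s, 0.5) for s in samples]
        with pytest.raises(DataError, match="AXIN2"):
            meth_expr_correlation(summaries, norm)

    def test_pearson_matches_covariance_oracle(self):
        from wntstrat.methylation import GeneMethylationSummary

        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            samples = [f"S{i}" for i in range(n)]
            x = rng.normal(5, 1.5, n)
            beta = rng.random(n)
            norm = make_norm({"G": list(x)}, samples)
            summaries = [
                GeneMethylationSummary("G", s, b) for s, b in zip(samples, beta)
            ]
            try:
                (res,) = meth_expr_correlation(summaries, norm)
            except DataError:
                continue
            num = ((beta - beta.mean()) * (x - x.mean())).sum()
            den = np.sqrt(
                ((beta - beta.mean()) ** 2).sum() * ((x - x.mean()) ** 2).sum()
            )
            assert res.r == pytest.approx(num / den, abs=1e-12)


def test_summaries_pivot_round_trip():
    from wntstrat.methylation import GeneMethylationSummary

    summaries = [
        GeneMethylationSummary("G1", "S1", 0.1),
        GeneMethylationSummary("G1", "S2", 0.2),
        GeneMethylationSummary("G2", "S1", 0.3),
        GeneMethylationSummary("G2", "S2", 0.4),
    ]
    frame = summaries_to_frame(summaries)
    assert frame.loc["G2", "S1"] == 0.3 and frame.shape == (2, 2)
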