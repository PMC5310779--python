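"""Clade-contrast statistics: paired matrices, ratios, regressions."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import exact_mwu_p
from rge import clade_stats as cs
from rge.tables import ParameterTable


def make_table(values, clade_map, status=None, parameter="distance"):
    return ParameterTable(
        parameter=parameter,
        values=values,
        status=status,
        clade_map=clade_map,
    )


class TestTwoSampleTest:
    def test_identical_groups_welch(self):
        res = cs.two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "welch")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_exact_mwu(self):
        res = cs.two_sample_test([1, 2, 3], [10, 11, 12], "mannwhitney")
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_constant_anova(self):
        res = cs.two_sample_test(None, None, "anova", groups=[[2, 2], [2, 2], [2, 2]])
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_t_flagged(self):
        same = cs.two_sample_test([2, 2, 2], [2, 2, 2], "welch")
        assert same.p == 1.0 and same.flag == "zero-variance"
        shifted = cs.two_sample_test([2, 2, 2], [3, 3, 3], "welch")
        assert shifted.p == 0.0 and shifted.flag == "zero-variance"

    def test_mwu_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(31)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
                x, y = vals[:n1], vals[n1:]
                got = cs.two_sample_test(x, y, "mannwhitney").p
                assert got == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_mwu_with_ties_uses_corrected_normal(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        y = [2.0, 4.0, 4.0, 4.0, 8.0, 9.0, 10.0]
        res = cs.two_sample_test(x, y, "mannwhitney")
        assert 0.0 < res.p <= 1.0


class TestCladeSummary:
    CLADES = {"a1": "I", "a2": "I", "b1": "II", "b2": "II", "out": "outgroup"}

    def test_constant_table(self):
        values = pd.DataFrame(
            5.0, index=["g1", "g2"], columns=["a1", "a2", "b1", "b2", "out"]
        )
        summ = cs.clade_summary(make_table(values, self.CLADES))
        assert (summ["mean"] == 5.0).all()
        assert (summ["sd"] == 0.0).all()

    def test_hand_arithmetic(self):
        values = pd.DataFrame(
            [[1.0, 3.0, 10.0, 20.0, 0.0], [2.0, np.nan, 5.0, 7.0, 0.0]],
            index=["g1", "g2"],
            columns=["a1", "a2", "b1", "b2", "out"],
        )
        summ = cs.clade_summary(make_table(values, self.CLADES)).set_index(
            ["gene", "clade"]
        )
        assert summ.loc[("g1", "I"), "mean"] == pytest.approx(2.0)
        assert summ.loc[("g1", "I"), "sd"] == pytest.approx(np.std([1, 3], ddof=1))
        assert summ.loc[("g2", "I"), "mean"] == pytest.approx(2.0)  # NA-aware
        assert summ.loc[("g2", "I"), "n"] == 1
        assert summ.loc[("g2", "II"), "mean"] == pytest.approx(6.0)


class TestRoundRobinPaired:
    CLADES = {"s1": "I", "s2": "I", "s3": "II"}

    def test_self_pair_flagged(self):
        values = pd.DataFrame(
            np.arange(9.0).reshape(3, 3),
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3"],
        )
        p, avg, flags = cs.round_robin_paired(
            make_table(values, self.CLADES), ["g1", "g2", "g3"]
        )
        assert p.at["s1", "s1"] == 1.0
        assert flags.at["s1", "s1"] == "self-pair"

    def test_constant_shift_degenerate(self):
        values = pd.DataFrame(
            {"s1": [3.0, 5.0, 7.0], "s2": [4.0, 6.0, 8.0], "s3": [1.0, 1.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        p, _, flags = cs.round_robin_paired(
            make_table(values, self.CLADES), ["g1", "g2", "g3"]
        )
        assert p.at["s1", "s2"] == 0.0
        assert flags.at["s1", "s2"] == "degenerate-shift"

    def test_matches_scipy_ttest_rel(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        values = pd.DataFrame(
            rng.standard_normal((8, 3)),
            index=[f"g{i}" for i in range(8)],
            columns=["s1", "s2", "s3"],
        )
        genes = list(values.index)
        p, avg, _ = cs.round_robin_paired(make_table(values, self.CLADES), genes)
        expected = stats.ttest_rel(values["s1"], values["s2"]).pvalue
        assert p.at["s1", "s2"] == pytest.approx(expected, abs=1e-12)
        assert p.at["s2", "s1"] == p.at["s1", "s2"]  # symmetric
        assert avg["s1"] == pytest.approx(values["s1"].mean())

    def test_pairwise_na_dropping(self):
        values = pd.DataFrame(
            {
                "s1": [1.0, 2.0, np.nan, 4.0],
                "s2": [1.5, 2.5, 3.5, np.nan],
                "s3": [0.0, 0.0, 0.0, 0.0],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        p, _, _ = cs.round_robin_paired(
            make_table(values, self.CLADES), ["g1", "g2", "g3", "g4"]
        )
        # shared genes for (s1, s2) are g1, g2 only: constant diff -0.5
        assert p.at["s1", "s2"] == 0.0

    def test_too_few_shared_genes_is_na(self):
        values = pd.DataFrame(
            {"s1": [1.0, np.nan, np.nan], "s2": [np.nan, 2.0, 2.5], "s3": [1.0, 2.0, 3.0]},
            index=["g1", "g2", "g3"],
        )
        p, _, flags = cs.round_robin_paired(
            make_table(values, self.CLADES), ["g1", "g2", "g3"]
        )
        assert np.isnan(p.at["s1", "s2"])
        assert flags.at["s1", "s2"] == "too-few-genes"

    def test_between_clade_pairs_more_significant_on_simulated_data(
        self, default_dataset, default_alignments
    ):
        from rge import evolution_metrics as em

        table = em.distance_table(default_dataset.matrix, default_alignments, "k80")
        pm = cs.pair_matrix(table, list(table.genes), cs.INTACT_SIX)
        clade_map = default_dataset.matrix.clade_map()
        I = [s for s in pm.symbiont_order if clade_map[s] == "I"]
        II = [s for s in pm.symbiont_order if clade_map[s] == "II"]
        between = pm.p_lower.loc[I, II].to_numpy().ravel()
        within = np.concatenate(
            [
                pm.p_lower.loc[I, I].to_numpy()[np.triu_indices(len(I), 1)],
                pm.p_lower.loc[II, II].to_numpy()[np.triu_indices(len(II), 1)],
            ]
        )
        assert between.max() < np.median(within)


class TestRatioAnalysis:
    def test_identical_clades_give_unit_ratios(self):
        clades = {"a1": "I", "a2": "I", "b1": "II", "b2": "II"}
        values = pd.DataFrame(
            [[2.0, 2.0, 2.0, 2.0]] * 6,
            index=[f"g{i}" for i in range(6)],
            columns=list(clades),
        )
        res = cs.ratio_analysis(
            make_table(values, clades), ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        )
        assert res.degraded_mean == pytest.approx(1.0)
        assert res.intact_mean == pytest.approx(1.0)
        assert res.p > cs.ALPHA

    def test_engineered_ratios_exact_p(self):
        clades = {"a1": "I", "b1": "II"}
        deg = {"g0": 1.5, "g1": 1.4, "g2": 1.6}
        intact = {"g3": 1.0, "g4": 1.1, "g5": 0.9}
        values = pd.DataFrame(
            {"a1": {**deg, **intact}, "b1": {g: 1.0 for g in [*deg, *intact]}}
        )
        res = cs.ratio_analysis(
            make_table(values, clades), list(deg), list(intact)
        )
        assert res.degraded_mean == pytest.approx(1.5)
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_overlapping_sets_error(self):
        clades = {"a1": "I", "b1": "II"}
        values = pd.DataFrame({"a1": [1.0], "b1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="overlap"):
            cs.ratio_analysis(make_table(values, clades), ["g"], ["g"])

    def test_zero_clade_two_mean_errors(self):
        clades = {"a1": "I", "b1": "II"}
        values = pd.DataFrame(
            {"a1": [1.0, 1.0], "b1": [0.0, 1.0]}, index=["g0", "g1"]
        )
        with pytest.raises(ValueError, match="zero clade II"):
            cs.ratio_analysis(make_table(values, clades), ["g0"], ["g1"])

    def test_degraded_rate_inflation_recovered(self, default_dataset, default_alignments):
        """Genes released from selection on the clade I stem show higher
        clade I/II distance ratios than genes intact in both clades."""
        from rge import evolution_metrics as em

        table = em.distance_table(default_dataset.matrix, default_alignments, "k80")
        res = cs.ratio_analysis(table)
        assert res.degraded_mean > res.intact_mean


class TestParameterRegression:
    CLADES = {"s1": "I", "s2": "II"}

    def _tables(self, x, y):
        xt = make_table(
            pd.DataFrame(x, index=[f"g{i}" for i in range(len(x))], columns=["s1"]),
            self.CLADES,
            parameter="gc",
        )
        yt = make_table(
            pd.DataFrame(y, index=[f"g{i}" for i in range(len(y))], columns=["s1"]),
            self.CLADES,
            parameter="repeat_density",
        )
        return xt, yt

    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2 * v + 1 for v in x]
        res = cs.parameter_regression(*self._tables(x, y))
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_orthogonal_pattern_zero_r(self):
        res = cs.parameter_regression(
            *self._tables([-1.0, -1.0, 1.0, 1.0], [-1.0, 1.0, -1.0, 1.0])
        )
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(120)
        y = 0.5 * x + rng.standard_normal(120) * 0.3
        res = cs.parameter_regression(*self._tables(list(x), list(y)))
        r_manual = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(r_manual, abs=1e-12)
        slope_manual = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope_manual, abs=1e-12)

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            cs.parameter_regression(*self._tables([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            cs.parameter_regression(*self._tables([1.0, 2.0], [1.0, 2.0]))


class TestHolmAdjust:
    def test_adjusted_never_smaller(self):
        raw = pd.DataFrame(
            [[np.nan, 0.01, 0.04], [0.01, np.nan, 0.20], [0.04, 0.20, np.nan]],
            index=list("abc"),
            columns=list("abc"),
        )
        adj = cs.holm_adjust(raw)
        diffs = (adj - raw).stack()  # stack drops the NaN diagonal
        assert (diffs >= -1e-15).all()
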