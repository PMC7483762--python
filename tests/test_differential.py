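"""Percent-of-control normalization, t-testing, imputation and class summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import null_experiment
from omiconcord import (
    aggregate_class_summary,
    differential_table,
    impute_missing,
    percent_of_control,
    two_tailed_t_test,
)
from omiconcord.matrix import AnalyteMatrix


class TestPercentOfControl:
    def test_identity(self):
        mean, sd = percent_of_control([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(0.0)

    def test_all_zero_treated(self):
        mean, _ = percent_of_control([0.0, 0.0], [10.0, 10.0])
        assert mean == 0.0

    def test_arithmetic_oracle(self):
        # 60/70/80 against a control mean of 100: mean 70, sample SD 10
        mean, sd = percent_of_control([60, 70, 80], [100, 100, 100])
        assert mean == pytest.approx(70.0)
        assert sd == pytest.approx(10.0)

    def test_degenerate_control(self):
        with pytest.raises(ValueError, match="degenerate control"):
            percent_of_control([1.0], [0.0, 0.0])

    def test_empty_group(self):
        with pytest.raises(ValueError):
            percent_of_control([], [1.0])


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert two_tailed_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_pooled_reference_value(self):
        # closed form: t = -3/sqrt(2/3) = -3.6742, df = 4
        assert two_tailed_t_test([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.0213116, abs=2e-6
        )

    def test_symmetry(self):
        x, y = [1.0, 2.5, 3.1], [2.0, 4.0, 4.5, 5.0]
        assert two_tailed_t_test(x, y) == pytest.approx(two_tailed_t_test(y, x))

    def test_zero_variance_equal_means_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert two_tailed_t_test([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            two_tailed_t_test([1.0], [1.0, 2.0])

    def test_welch_differs_under_unequal_variance(self):
        x = [1.0, 1.1, 0.9, 1.05]
        y = [3.0, 8.0, -2.0, 5.0]
        assert two_tailed_t_test(x, y, pooled=True) != pytest.approx(
            two_tailed_t_test(x, y, pooled=False)
        )

    @given(
        st.lists(st.floats(1, 100), min_size=3, max_size=6),
        st.lists(st.floats(1, 100), min_size=3, max_size=6),
        st.floats(0.01, 1000),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, x, y, c):
        if np.std(x) == 0 and np.std(y) == 0:
            return
        p1 = two_tailed_t_test(x, y)
        p2 = two_tailed_t_test([v * c for v in x], [v * c for v in y])
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)


class TestImputation:
    def test_no_missing_returned_unchanged(self, tiny_matrix):
        out = impute_missing(tiny_matrix, seed=1)
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)

    def test_deterministic_given_seed(self, rng):
        matrix = self._matrix_with_missing(rng)
        a = impute_missing(matrix, seed=9)
        b = impute_missing(matrix, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert not a.values.equals(impute_missing(matrix, seed=10).values)

    def test_observed_cells_untouched(self, rng):
        matrix = self._matrix_with_missing(rng)
        out = impute_missing(matrix, seed=2)
        obs = ~matrix.values.isna()
        pd.testing.assert_frame_equal(out.values[obs], matrix.values[obs])
        assert not out.values.isna().any().any()

    def test_downshifted_distribution(self, rng):
        # ~1e4 imputed cells: imputed log2 mean ~= observed mean - 1.8 * SD
        n = 25000
        log2 = rng.normal(20, 1.5, size=(n, 2))
        values = 2.0 ** log2
        miss = rng.random((n, 2)) < 0.2
        values[miss] = np.nan
        samples = pd.DataFrame(
            {
                "cell_line": "L",
                "treatment": ["vehicle", "drug"],
                "timepoint_h": 8,
                "replicate": 1,
            },
            index=["s1", "s2"],
        )
        matrix = AnalyteMatrix(pd.DataFrame(values, columns=["s1", "s2"]), samples)
        out = impute_missing(matrix, shift_sd=1.8, width_sd=0.3, seed=3)
        col = np.log2(out.values["s1"].to_numpy())
        obs = col[~miss[:, 0]]
        imputed = col[miss[:, 0]]
        expected = obs.mean() - 1.8 * obs.std(ddof=1)
        assert imputed.mean() == pytest.approx(expected, rel=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * obs.std(ddof=1), rel=0.1)

    def test_fully_missing_column_rejected(self):
        values = pd.DataFrame({"s1": [np.nan, np.nan], "s2": [1.0, 2.0]})
        samples = pd.DataFrame(
            {
                "cell_line": "L",
                "treatment": ["vehicle", "drug"],
                "timepoint_h": 8,
                "replicate": 1,
            },
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="fewer than 2 observed"):
            impute_missing(AnalyteMatrix(values, samples), seed=0)

    @staticmethod
    def _matrix_with_missing(rng):
        values = 2.0 ** rng.normal(20, 1.5, size=(50, 6))
        values[rng.random((50, 6)) < 0.15] = np.nan
        samples = pd.DataFrame(
            {
                "cell_line": "L",
                "treatment": ["vehicle"] * 3 + ["drug"] * 3,
                "timepoint_h": 8,
                "replicate": [1, 2, 3, 1, 2, 3],
            },
            index=[f"s{i}" for i in range(6)],
        )
        return AnalyteMatrix(pd.DataFrame(values, columns=samples.index), samples)


class TestDifferentialTable:
    def test_planted_effect_called_down(self, tiny_matrix):
        calls = differential_table(tiny_matrix)
        a1 = calls[calls["analyte"] == "a1"].iloc[0]
        assert a1["pct_of_control"] == pytest.approx(50.0)
        assert a1["direction"] == "down"
        a2 = calls[calls["analyte"] == "a2"].iloc[0]
        assert a2["direction"] == "up"

    def test_nonsignificant_pct_stays_unchanged(self):
        # large spread: pct far from 100 but p >> alpha
        values = pd.DataFrame(
            {
                "v1": [10.0], "v2": [200.0], "v3": [50.0],
                "d1": [5.0], "d2": [100.0], "d3": [30.0],
            },
            index=["a"],
        )
        samples = pd.DataFrame(
            {
                "cell_line": "L",
                "treatment": ["vehicle"] * 3 + ["drug"] * 3,
                "timepoint_h": 8,
                "replicate": [1, 2, 3, 1, 2, 3],
            },
            index=values.columns,
        )
        calls = differential_table(AnalyteMatrix(values, samples))
        assert calls.iloc[0]["p_value"] > 0.05
        assert calls.iloc[0]["direction"] == "unchanged"

    def test_direction_partition_and_invariant(self, desk_experiment):
        calls = differential_table(desk_experiment.layers["protein"], alpha=0.05)
        assert set(calls["direction"]) <= {"up", "down", "unchanged"}
        up = calls[calls["direction"] == "up"]
        down = calls[calls["direction"] == "down"]
        assert (up["p_value"] < 0.05).all() and (up["pct_of_control"] > 100).all()
        assert (down["p_value"] < 0.05).all() and (down["pct_of_control"] < 100).all()
        # one call per (analyte, cell line, timepoint)
        assert not calls.duplicated(["analyte", "cell_line", "timepoint_h"]).any()

    def test_null_false_call_count(self):
        res = null_experiment(n_analytes=1000, seed=21)
        calls = differential_table(res.layers["protein"], alpha=0.05)
        for (_, _), grp in calls.groupby(["cell_line", "timepoint_h"]):
            n_false = int((grp["direction"] != "unchanged").sum())
            assert 30 <= n_false <= 70  # ~50 expected at alpha = 0.05

    def test_missing_vehicle_stratum_skipped(self, tiny_matrix):
        drug_only = tiny_matrix.subset(treatment="drug")
        with pytest.warns(UserWarning, match="skipped"):
            calls = differential_table(drug_only)
        assert calls.empty

    def test_technical_replicates_averaged(self, tiny_matrix):
        meta = tiny_matrix.samples.copy()
        meta["tech_replicate"] = 1
        doubled = AnalyteMatrix(tiny_matrix.values, meta)
        pd.testing.assert_frame_equal(
            differential_table(doubled).drop(columns=[]),
            differential_table(tiny_matrix),
        )

    def test_monotone_in_effect_for_fixed_variance(self):
        # same spread, growing shift: p never increases as |pct - 100| grows
        base = np.array([100.0, 110.0, 90.0])
        pvals = []
        for shift in (0.0, 10.0, 20.0, 40.0):
            p = two_tailed_t_test(base + shift, base)
            pvals.append(p)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_bh_flag_reduces_false_calls(self):
        res = null_experiment(n_analytes=500, seed=33)
        raw = differential_table(res.layers["protein"], alpha=0.05)
        adj = differential_table(res.layers["protein"], alpha=0.05, fdr=True)
        n_raw = int((raw["direction"] != "unchanged").sum())
        n_adj = int((adj["direction"] != "unchanged").sum())
        assert n_adj <= n_raw


class TestTypeIError:
    def test_null_significance_rate_matches_alpha(self):
        """Monte-Carlo type-I error across 20 seeded null experiments."""
        rates = []
        for seed in range(20):
            res = null_experiment(n_analytes=250, seed=100 + seed)
            calls = differential_table(res.layers["protein"], alpha=0.05)
            rates.append((calls["direction"] != "unchanged").mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestClassSummary:
    @staticmethod
    def _calls(pcts, analytes=None, cls="GP"):
        analytes = analytes or [f"m{i}" for i in range(len(pcts))]
        return (
            pd.DataFrame(
                {
                    "analyte": analytes,
                    "cell_line": "L",
                    "timepoint_h": 8,
                    "pct_of_control": pcts,
                    "sd_pct": 0.0,
                    "p_value": 0.5,
                    "direction": "unchanged",
                }
            ),
            {a: cls for a in analytes},
        )

    def test_arithmetic(self):
        calls, cmap = self._calls([80.0, 60.0, 70.0])
        summary = aggregate_class_summary(calls, cmap)
        row = summary.iloc[0]
        assert row["mean_pct"] == pytest.approx(70.0)
        assert row["sd_pct"] == pytest.approx(10.0)
        assert row["n"] == 3

    def test_single_member_sd_zero(self):
        calls, cmap = self._calls([88.0])
        assert aggregate_class_summary(calls, cmap).iloc[0]["sd_pct"] == 0.0

    def test_unmapped_analytes_dropped_with_warning(self):
        calls, cmap = self._calls([80.0, 60.0])
        del cmap["m1"]
        with pytest.warns(UserWarning, match="without a class"):
            summary = aggregate_class_summary(calls, cmap)
        assert summary.iloc[0]["n"] == 1

    def test_recovers_planted_class_mean(self, rng):
        # planted true pct 70 with replicate noise: recovered within 1 SE
        n = 400
        pcts = rng.normal(70, 8, size=n)
        calls, cmap = self._calls(list(pcts))
        summary = aggregate_class_summary(calls, cmap)
        se = 8 / np.sqrt(n)
        assert abs(summary.iloc[0]["mean_pct"] - pcts.mean()) < 1e-9
        assert summary.iloc[0]["mean_pct"] == pytest.approx(70, abs=3 * se)


def test_stratum_scale_invariance(tiny_matrix):
    """Multiplying all intensities of a stratum by c leaves pct and p unchanged."""
    scaled = AnalyteMatrix(tiny_matrix.values * 7.3, tiny_matrix.samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = differential_table(tiny_matrix)
        b = differential_table(scaled)
    pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-9)
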