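"""Metabolite group tests, baseline normalization and trend labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietomics import (
    AbundanceMatrix,
    Arm,
    DataError,
    SampleMeta,
    Semantics,
    Timepoint,
    group_ttest,
    normalize_to_baseline,
    paired_baseline_test,
    significant_set,
    trend_classify,
)
from dietomics.datasets import global_metabolites_baseline_week2, reported_pvalues
from dietomics.metabolomics import MetaboliteTestResult


def log2_matrix(rows, samples):
    return AbundanceMatrix(pd.DataFrame(rows, columns=samples), Semantics.LOG2_AREA)


def meta_for(patients, timepoints):
    return [
        SampleMeta(f"{p}_{t.value}", p, t, Arm.SCD)
        for p in patients for t in timepoints
    ]


class TestGroupTtest:
    def test_matches_scipy_pooled_test(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(22, 1, size=(6, 10))
        m = log2_matrix(rows, [f"s{i}" for i in range(10)])
        res = group_ttest(m, [f"s{i}" for i in range(5)],
                          [f"s{i}" for i in range(5, 10)])
        for i, r in enumerate(res):
            t, p = stats.ttest_ind(rows[i, :5], rows[i, 5:], equal_var=True)
            assert r.t_stat == pytest.approx(t, abs=1e-12)
            assert r.p_value == pytest.approx(p, abs=1e-12)
            assert r.df == 8

    def test_identical_groups_null(self):
        vals = [26.0, 27.0, 25.5, 26.5, 26.2]
        m = log2_matrix([vals + vals], [f"s{i}" for i in range(10)])
        (r,) = group_ttest(m, [f"s{i}" for i in range(5)],
                           [f"s{i}" for i in range(5, 10)])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_swapping_groups_negates_t_flips_pattern(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(22, 1, size=(4, 10))
        rows[:, 5:] += 1.0
        m = log2_matrix(rows, [f"s{i}" for i in range(10)])
        g1, g2 = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        for a, b in zip(group_ttest(m, g1, g2), group_ttest(m, g2, g1)):
            assert a.t_stat == pytest.approx(-b.t_stat)
            assert a.p_value == pytest.approx(b.p_value)
            assert {a.pattern, b.pattern} == {"Up", "Down"}

    def test_missing_values_reduce_n(self):
        matrix, meta = global_metabolites_baseline_week2()
        g1 = [m.sample_id for m in meta if m.timepoint is Timepoint.BASELINE]
        g2 = [m.sample_id for m in meta if m.timepoint is Timepoint.WEEK2]
        res = {r.metabolite: r for r in group_ttest(matrix, g1, g2)}
        assert res["stigmasterol"].n2 == 4  # one missing week-2 measurement
        assert res["stigmasterol"].df == 7
        assert res["oleic acid"].n2 == 5

    def test_untestable_flagged_not_dropped(self):
        rows = [[21.0, np.nan, np.nan, np.nan, np.nan, 22.0, 22.5, 23.0, 21.5, 22.2]]
        m = log2_matrix(rows, [f"s{i}" for i in range(10)])
        (r,) = group_ttest(m, [f"s{i}" for i in range(5)],
                           [f"s{i}" for i in range(5, 10)])
        assert not r.testable and np.isnan(r.p_value)

    def test_overlapping_groups_rejected(self):
        m = log2_matrix([[20.0, 21.0]], ["s1", "s2"])
        with pytest.raises(DataError, match="overlap"):
            group_ttest(m, ["s1"], ["s1", "s2"])


class TestSignificantSet:
    def _result(self, name, p):
        return MetaboliteTestResult(name, 5, 5, 20, 21, 1.0, 8, p, "Up")

    def test_inclusive_boundary(self):
        results = [self._result("maltose", 0.0494),
                   self._result("exactly", 0.05),
                   self._result("L-cysteine", 0.0585)]
        assert significant_set(results, 0.05) == ["maltose", "exactly"]

    def test_alpha_one_keeps_all_testable(self):
        results = [self._result("a", 0.99),
                   MetaboliteTestResult("b", 1, 5, 20, 21, float("nan"), 4,
                                        float("nan"), "Up", testable=False)]
        assert significant_set(results, 1.0) == ["a"]


class TestNormalizeToBaseline:
    def _raw(self, per_patient):
        cols, meta = {}, []
        for pid, areas in per_patient.items():
            for t, a in zip(Timepoint, areas):
                cols[f"{pid}_{t.value}"] = [a]
                meta.append(SampleMeta(f"{pid}_{t.value}", pid, t, Arm.WF))
        m = AbundanceMatrix(pd.DataFrame(cols, index=["m1"]), Semantics.RAW_AREA)
        return m, meta

    def test_percent_of_baseline(self):
        m, meta = self._raw({"P001": (200.0, 23.0, 10.0)})
        prof = normalize_to_baseline(m, meta)
        assert prof.loc["m1", ("P001", "week2")] == pytest.approx(11.5)
        assert prof.loc["m1", ("P001", "baseline")] == pytest.approx(100.0)

    def test_unchanged_value_is_100(self):
        m, meta = self._raw({"P001": (37.0, 37.0, 37.0)})
        prof = normalize_to_baseline(m, meta)
        assert prof.loc["m1", ("P001", "week2")] == pytest.approx(100.0)

    def test_zero_later_value_is_zero(self):
        m, meta = self._raw({"P001": (200.0, 0.0, 0.0)})
        prof = normalize_to_baseline(m, meta)
        assert prof.loc["m1", ("P001", "week2")] == 0.0

    def test_zero_baseline_with_signal_goes_missing(self):
        m, meta = self._raw({"P001": (0.0, 50.0, 0.0)})
        prof = normalize_to_baseline(m, meta)
        assert np.isnan(prof.loc["m1", ("P001", "week2")])
        assert prof.loc["m1", ("P001", "week12")] == 0.0  # 0/0

    def test_missing_baseline_sample_is_an_error(self):
        cols = {"P001_week2": [5.0]}
        m = AbundanceMatrix(pd.DataFrame(cols, index=["m1"]), Semantics.RAW_AREA)
        meta = [SampleMeta("P001_week2", "P001", Timepoint.WEEK2, Arm.WF)]
        with pytest.raises(DataError, match="P001"):
            normalize_to_baseline(m, meta)

    def test_idempotent_on_normalized_profile(self):
        m, meta = self._raw({"P001": (200.0, 23.0, 46.0), "P005": (80.0, 120.0, 40.0)})
        prof1 = normalize_to_baseline(m, meta)
        renorm = AbundanceMatrix(
            pd.DataFrame(
                {f"{p}_{t}": prof1[(p, t)].to_numpy()
                 for p, t in prof1.columns},
                index=prof1.index,
            ),
            Semantics.RAW_AREA,
        )
        prof2 = normalize_to_baseline(renorm, meta)
        assert np.allclose(prof1.to_numpy(), prof2.to_numpy())


class TestTrendClassify:
    def _profile(self, w2, w12):
        cols = {}
        for i, (a, b) in enumerate(zip(w2, w12)):
            cols[(f"P{i}", "week2")] = [a]
            cols[(f"P{i}", "week12")] = [b]
        frame = pd.DataFrame(cols, index=["m1"])
        frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                                  names=["patient", "timepoint"])
        return frame

    def test_unanimous_decrease(self):
        # the week-12 percent is below the week-2 percent in all 5 patients
        prof = self._profile([21.6, 109.7, 85.6, 490.7, 231.6],
                             [14.3, 57.4, 14.0, 99.8, 198.3])
        assert trend_classify(prof, Timepoint.WEEK2, Timepoint.WEEK12) == \
            {"m1": "decrease"}

    def test_equal_values_are_none(self):
        prof = self._profile([50.0] * 5, [50.0] * 5)
        assert trend_classify(prof, Timepoint.WEEK2, Timepoint.WEEK12) == \
            {"m1": "none"}

    def test_simple_majority_is_enough(self):
        prof = self._profile([10, 10, 10, 10, 10], [20, 20, 20, 5, 5])
        assert trend_classify(prof, Timepoint.WEEK2, Timepoint.WEEK12) == \
            {"m1": "increase"}


class TestPairedBaselineTest:
    def _matrix(self, base, later):
        cols, meta = {}, []
        for i, (a, b) in enumerate(zip(base, later)):
            cols[f"P{i}_baseline"] = [a]
            cols[f"P{i}_week2"] = [b]
            meta.append(SampleMeta(f"P{i}_baseline", f"P{i}", Timepoint.BASELINE, Arm.WF))
            meta.append(SampleMeta(f"P{i}_week2", f"P{i}", Timepoint.WEEK2, Arm.WF))
        m = AbundanceMatrix(pd.DataFrame(cols, index=["m1"]), Semantics.LOG2_AREA)
        return m, meta

    def test_no_change_gives_p_one(self):
        m, meta = self._matrix([20, 21, 22], [20, 21, 22])
        p, degenerate = paired_baseline_test(m, meta, "m1", Timepoint.WEEK2)
        assert p == 1.0 and not degenerate

    def test_constant_shift_degenerate(self):
        m, meta = self._matrix([20, 21, 22], [21, 22, 23])
        p, degenerate = paired_baseline_test(m, meta, "m1", Timepoint.WEEK2)
        assert p == 0.0 and degenerate

    def test_power_at_two_sd_shift(self):
        """A shift of 2 noise-SDs with n = 5 is detected at alpha = 0.05
        with the power the non-central-t distribution predicts (~0.91),
        within Monte-Carlo error."""
        df, shift_sds = 4, 2.0
        crit = stats.t.ppf(0.975, df)
        ncp = shift_sds * np.sqrt(5)
        expected = 1 - stats.nct.cdf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        assert expected > 0.9

        rng = np.random.default_rng(12345)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            base = rng.normal(22, 0.5, 5)
            later = base + 1.0 + rng.normal(0, 0.5, 5)
            m, meta = self._matrix(base, later)
            p, _ = paired_baseline_test(m, meta, "m1", Timepoint.WEEK2)
            hits += p < 0.05
        mc_sd = np.sqrt(expected * (1 - expected) / n_rep)
        assert abs(hits / n_rep - expected) < 3 * mc_sd
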