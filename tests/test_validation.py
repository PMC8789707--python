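import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fabnorms.cohort import Cohort
from fabnorms.errors import ConfigError, DegenerateDataError
from fabnorms.simulate import default_config, generate_cohort
from fabnorms.validation import (
    correlation_battery,
    min_sample_size,
    regression_power,
    sex_tests,
    subscale_battery,
)


class TestCorrelationBattery:
    def test_default_family_size_and_alpha(self, default_cohort):
        results = correlation_battery(default_cohort)
        assert len(results) == 28
        assert all(r.alpha_adjusted * 28 == 0.05 for r in results)

    def test_monotone_pair_is_one(self, tiny_cohort):
        df = tiny_cohort.df.assign(
            moca_total=pd.array([10, 14, 20, 28], dtype="Int64"),
            age=[80, 70, 50, 30])
        res = correlation_battery(Cohort(df), fab_measures=("age",),
                                  moca_measures=("moca_total",))
        assert res[0].coefficient == pytest.approx(-1.0)

    def test_hand_computed_spearman(self, tiny_cohort):
        # x = 1..6, y = (2,1,4,3,6,5): sum d^2 = 6, rs = 1 - 6*6/(6*35)
        x = pd.Series([1, 2, 3, 4, 5, 6], name="x")
        y = pd.Series([2, 1, 4, 3, 6, 5], name="y")
        from fabnorms.validation import _correlate

        res = _correlate(x, y, "spearman", 0.05)
        assert res.coefficient == pytest.approx(1 - 36 / 210, rel=1e-12)

    def test_zero_variance_flagged_not_crashed(self, tiny_cohort):
        df = tiny_cohort.df.assign(moca_total=pd.array([24] * 4, dtype="Int64"))
        res = correlation_battery(Cohort(df), fab_measures=("FAB",),
                                  moca_measures=("moca_total",))
        assert res[0].undefined and not res[0].significant

    def test_missing_moca_uses_pairwise_complete(self, tiny_cohort):
        df = tiny_cohort.df.copy()
        df.loc[0, "moca_total"] = pd.NA
        res = correlation_battery(Cohort(df), fab_measures=("FAB",),
                                  moca_measures=("moca_total",))
        assert res[0].n == 3

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(list(range(8))))
    def test_spearman_invariant_under_monotone_transform(self, perm):
        from fabnorms.validation import _correlate

        x = pd.Series(np.arange(8.0), name="x")
        y = pd.Series(np.array(perm, dtype=float), name="y")
        a = _correlate(x, y, "spearman", 0.05).coefficient
        b = _correlate(np.exp(x / 3), y ** 3 + 5, "spearman", 0.05).coefficient
        assert a == pytest.approx(b, rel=1e-12)


class TestSubscaleBattery:
    def test_part_whole_positive_and_strongest(self, default_cohort):
        res = {(r.x, r.y): r.coefficient for r in subscale_battery(default_cohort)}
        part_whole = [res[(s, "FAB")] for s in ("FAB1", "FAB2", "FAB3")]
        sub_sub = [res[p] for p in (("FAB1", "FAB2"), ("FAB1", "FAB3"),
                                    ("FAB2", "FAB3"))]
        assert all(c > 0 for c in part_whole + sub_sub)
        assert min(part_whole) > max(sub_sub)


class TestSexTests:
    def _cohort(self, f_vals, m_vals):
        n = len(f_vals) + len(m_vals)
        df = pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": ["F"] * len(f_vals) + ["M"] * len(m_vals),
            "age": 50, "education": 10,
        })
        vals = list(f_vals) + list(m_vals)
        for i in range(1, 7):
            df[f"fab{i}"] = 0
        df["fab1"] = [min(v, 3) for v in vals]
        df["fab2"] = [max(v - 3, 0) for v in vals]
        df["moca_total"] = pd.array([20] * n, dtype="Int64")
        for c in ("moca_ef", "moca_a", "moca_l", "moca_m", "moca_vs", "moca_o"):
            df[c] = pd.array([2] * n, dtype="Int64")
        return Cohort(df)

    def test_identical_groups_t_zero(self):
        res = sex_tests(self._cohort([1, 2, 3], [1, 2, 3]), scales=("FAB",))
        assert res[0].t == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pooled_t(self):
        # F = {1,2,3}, M = {2,4,6}: pooled s^2 = 2.5, t = -2/sqrt(5/3), df = 4
        res = sex_tests(self._cohort([1, 2, 3], [2, 4, 6]), scales=("FAB",))[0]
        assert res.pooled
        assert res.t == pytest.approx(-2 / math.sqrt(5 / 3), rel=1e-12)
        assert res.df == 4

    def test_single_sex_rejected(self):
        c = self._cohort([1, 2, 3], [])
        c.df["sex"] = "F"
        with pytest.raises(DegenerateDataError):
            sex_tests(c, scales=("FAB",))

    def test_unequal_variances_switch_to_welch(self, rng):
        f = rng.normal(3, 0.2, 200).round().clip(0, 6)
        m = rng.normal(3, 2.0, 200).round().clip(0, 6)
        res = sex_tests(self._cohort(f.astype(int), m.astype(int)),
                        scales=("FAB",))[0]
        assert not res.pooled
        assert res.df != int(res.df)  # fractional df

    def test_no_sex_effect_in_default_generator(self):
        clear = 0
        total = 0
        for seed in range(10):
            cohort = generate_cohort(default_config(seed=seed))
            for r in sex_tests(cohort):
                total += 1
                clear += r.p_value > 0.05
        assert clear >= 0.9 * total


class TestPower:
    def test_published_minimum_sample_size(self):
        assert min_sample_size(3, 0.05, 0.05, 0.9) == 287

    def test_strict_integer_search_brackets_target(self):
        n = min_sample_size(3, 0.05, 0.05, 0.9, rounding="ceil")
        assert regression_power(n, 3, 0.05, 0.05) >= 0.9
        assert regression_power(n - 1, 3, 0.05, 0.05) < 0.9

    def test_larger_effect_needs_fewer_subjects(self):
        assert min_sample_size(3, 0.10, 0.05, 0.9) < 287

    def test_conventional_large_effect_oracle(self):
        # independent grid-evaluation oracle froze the continuous solution
        # for (u=3, f2=0.35, alpha=0.05, power=0.8) at n* = 35.31
        assert min_sample_size(3, 0.35, 0.05, 0.8) == 35
        assert min_sample_size(3, 0.35, 0.05, 0.8, rounding="ceil") == 36

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            min_sample_size(3, 0.0, 0.05, 0.9)
        with pytest.raises(ConfigError):
            min_sample_size(3, 0.05, 0.05, 1.2)
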