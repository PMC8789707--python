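import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabnorms.adjustment import (
    AdjustmentEquation,
    TransformSpec,
    adjust_score,
    compare_grid,
    eval_transform,
    fit_adjustment,
    fit_adjustment_arrays,
    generate_grid,
    round_half_up,
    select_transforms_arrays,
)
from fabnorms.errors import ConfigError, SingularFitError, TransformDomainError
from fabnorms.published import load_published
from fabnorms.scales import FAB_TOTAL
from fabnorms.simulate import default_config, draw_demographics


@pytest.fixture(scope="module")
def norms():
    return load_published()


class TestTransforms:
    def test_cubic_age_centering(self):
        spec = TransformSpec("age", "cube", 269630.547368)
        assert eval_transform(spec, 35) == pytest.approx(-226755.547368, abs=1e-6)

    def test_log_education_zero_point(self):
        spec = TransformSpec("education", "log", 2.366383)
        assert eval_transform(spec, np.exp(2.366383)) == pytest.approx(0.0, abs=1e-12)

    def test_reciprocal_education(self):
        spec = TransformSpec("education", "reciprocal", 0.105356)
        assert eval_transform(spec, 5) == pytest.approx(0.094644, abs=1e-9)

    def test_domain_violation_names_transform(self):
        spec = TransformSpec("education", "log", 0.0)
        with pytest.raises(TransformDomainError, match="log"):
            eval_transform(spec, 0)

    def test_log_age_is_rejected(self):
        with pytest.raises(ConfigError):
            TransformSpec("age", "log", 0.0)


class TestAdjustScore:
    def test_published_total_example(self, norms):
        assert round_half_up(adjust_score(12, 35, 5, norms.equations["FAB"])) == 12.28

    def test_centering_identity(self, norms):
        # at the zero points of both transforms the adjustment vanishes
        age0 = 269630.547368 ** (1 / 3)
        edu0 = float(np.exp(2.366383))
        eq = norms.equations["FAB"]
        assert adjust_score(12, age0, edu0, eq) == pytest.approx(12.0, abs=1e-9)

    def test_published_fab1_example(self, norms):
        assert round_half_up(adjust_score(5, 95, 21, norms.equations["FAB1"])) == 5.18

    @settings(derandomize=True, max_examples=30)
    @given(raw=st.integers(0, 17), age=st.integers(21, 96), edu=st.integers(1, 25))
    def test_affine_with_unit_slope(self, norms, raw, age, edu):
        eq = norms.equations["FAB"]
        assert (adjust_score(raw + 1, age, edu, eq)
                - adjust_score(raw, age, edu, eq)) == pytest.approx(1.0, abs=1e-12)


class TestFit:
    def test_noise_free_recovery(self, rng):
        ages = rng.integers(21, 97, 400)
        edus = rng.integers(1, 26, 400)
        y = 16.0 - 4e-6 * (ages ** 3) + 1.5 * np.log(edus)
        eq = fit_adjustment_arrays(ages, edus, y, "cube", "log")
        assert eq.age_coefficient == pytest.approx(4e-6, abs=1e-12)
        assert eq.edu_coefficient == pytest.approx(-1.5, abs=1e-9)

    def test_null_model_has_flat_coefficients(self, rng):
        ages = rng.integers(21, 97, 400)
        edus = rng.integers(1, 26, 400)
        y = rng.normal(12.0, 2.0, 400)  # independent of demographics
        eq = fit_adjustment_arrays(ages, edus, y, "cube", "log")
        assert eq.fit_stats["p_values"]["age"] > 0.05
        assert eq.fit_stats["p_values"]["education"] > 0.05
        assert abs(eq.fit_stats["std_beta"]["age"]) < 0.15

    def test_default_cohort_adjustment_signs(self, default_cohort):
        eq = fit_adjustment(default_cohort, FAB_TOTAL)
        # performance declines with age, rises with education, so the
        # correction adds with age and subtracts with education
        assert eq.age_coefficient > 0
        assert eq.edu_coefficient < 0

    def test_collinear_design_is_singular(self):
        ages = np.full(50, 60)
        edus = np.full(50, 10)
        with pytest.raises(SingularFitError):
            fit_adjustment_arrays(ages, edus, np.arange(50.0), "cube", "log")


class TestSelect:
    def test_single_candidates_returned_unchanged(self, rng):
        ages = rng.integers(21, 97, 100)
        edus = rng.integers(1, 26, 100)
        y = rng.normal(12, 2, 100)
        sel = select_transforms_arrays(ages, edus, y, ["square"], ["reciprocal"])
        assert (sel.age_family, sel.edu_family) == ("square", "reciprocal")
        assert len(sel.table) == 1

    def test_low_noise_generating_pair_selected(self):
        cfg = default_config(n=475)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            ages, edus, _ = draw_demographics(cfg, r)
            y = (17.0 - 4e-6 * (ages.astype(float) ** 3)
                 + 1.565729 * np.log(edus) + r.normal(0, 0.5, ages.size))
            sel = select_transforms_arrays(ages, edus, y)
            hits += (sel.age_family, sel.edu_family) == ("cube", "log")
        assert hits >= 18  # low-noise regime: near-certain identification

    def test_linear_age_effect_education_flat(self, rng):
        ages = rng.integers(21, 97, 475)
        edus = rng.integers(1, 26, 475)
        y = 20.0 - 0.05 * ages + rng.normal(0, 1.0, 475)
        sel = select_transforms_arrays(ages, edus, y)
        assert sel.equation.fit_stats["p_values"]["age"] < 1e-6
        assert sel.equation.fit_stats["p_values"]["education"] > 0.01


class TestGrids:
    def test_zero_coefficient_grid_is_all_zero(self):
        eq = AdjustmentEquation("null", TransformSpec("age", "cube", 0.0), 0.0,
                                TransformSpec("education", "log", 0.0), 0.0)
        grid = generate_grid(eq)
        assert (grid.values.to_numpy() == 0.0).all()

    def test_published_corner_cells(self, norms):
        grid = generate_grid(norms.equations["FAB"])
        assert grid.cell(35, 5) == 0.28
        assert grid.cell(95, 21) == 1.29
        grid3 = generate_grid(norms.equations["FAB3"])
        assert grid3.cell(35, 5) == 0.2

    def test_monotone_in_age_and_education(self, norms):
        for name in ("FAB", "FAB1", "FAB2", "FAB3"):
            grid = generate_grid(norms.equations[name], decimals=6)
            vals = grid.values.to_numpy()
            assert (np.diff(vals, axis=1) > 0).all()   # older -> larger correction
            assert (np.diff(vals, axis=0) < 0).all()   # more educated -> smaller

    def test_compare_grid_reports_mismatches(self, norms):
        grid = generate_grid(norms.equations["FAB"])
        ref = grid.values.copy()
        ref.iloc[0, 0] += 0.5
        mism = compare_grid(grid, ref)
        assert len(mism) == 1
        assert mism.iloc[0]["age"] == 35 and mism.iloc[0]["education"] == 5

    def test_empty_lattice_rejected(self, norms):
        with pytest.raises(ConfigError):
            generate_grid(norms.equations["FAB"], ages=[])


@pytest.mark.parametrize("x, expected", [
    (0.125, 0.13), (-0.125, -0.13), (2.675, 2.68), (1.005, 1.01), (0.2781, 0.28),
])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
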