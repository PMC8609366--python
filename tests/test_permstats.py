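import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofmri_states import (
    ContrastSpec,
    TfceParams,
    group_difference_test,
    mixed_anova_interaction,
    rm_anova_frequency,
    tfce1d,
)
from ofmri_states.permstats import CONTRAST_5HZ, CONTRAST_10HZ, tfce1d_batch
from oracles import tfce_plateau_closed_form


class TestTfce:
    def test_all_zero_curve_maps_to_zero(self):
        np.testing.assert_array_equal(tfce1d(np.zeros(20)), 0.0)

    def test_negative_values_treated_as_zero(self):
        np.testing.assert_array_equal(tfce1d(-np.ones(10)), 0.0)

    @pytest.mark.parametrize("width,height", [(4, 1.0), (9, 2.5), (1, 0.7)])
    def test_plateau_matches_closed_form(self, width, height):
        """An isolated plateau's enhancement converges to w^E h^(H+1)/(H+1)."""
        curve = np.zeros(width + 6)
        curve[3 : 3 + width] = height
        enhanced = tfce1d(curve, TfceParams(n_steps=1000))
        expected = tfce_plateau_closed_form(width, height)
        np.testing.assert_allclose(enhanced[3 : 3 + width], expected, rtol=5e-3)
        np.testing.assert_array_equal(enhanced[:3], 0.0)

    def test_scaling_strictly_increases_enhancement(self):
        rng = np.random.default_rng(0)
        curve = np.abs(rng.standard_normal(30))
        e1 = tfce1d(curve)
        e2 = tfce1d(2.0 * curve)
        nz = e1 > 0
        assert (e2[nz] > e1[nz]).all()

    def test_taller_plateau_dominates_equal_width(self):
        a, b = np.zeros(20), np.zeros(20)
        a[5:10] = 1.0
        b[5:10] = 2.0
        ea, eb = tfce1d(a), tfce1d(b)
        assert (eb[5:10] > ea[5:10]).all()

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(1)
        curves = rng.standard_normal((7, 25))
        batch = tfce1d_batch(curves)
        for i in range(7):
            np.testing.assert_allclose(batch[i], tfce1d(curves[i]), atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_enhancement_nonnegative_and_supported_on_positives(self, seed):
        rng = np.random.default_rng(seed)
        curve = rng.standard_normal(15)
        e = tfce1d(curve)
        assert (e >= 0).all()
        assert (e[curve <= 0] == 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TfceParams(E=-1)
        with pytest.raises(ValueError):
            TfceParams(n_steps=0)


def _curves(rng, n, K=3, W=20, loc=0.0):
    return loc + rng.standard_normal((n, K, W)) * 0.1


class TestGroupDifference:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        g = _curves(rng, 4)
        res = group_difference_test(g, g.copy(), nperm=99, seed=0)
        np.testing.assert_array_equal(res.observed, 0.0)
        np.testing.assert_array_equal(res.p_fwe, 1.0)

    def test_planted_effect_detected_in_on_window(self):
        rng = np.random.default_rng(1)
        g1 = _curves(rng, 8)
        g2 = _curves(rng, 8)
        g1[:, 1, 2:10] += 1.0  # state 1 elevated during ON samples
        res = group_difference_test(g1, g2, nperm=500, seed=0)
        assert res.p_fwe[1, 2:10].min() <= 0.05
        assert res.p_fwe[0].min() > 0.05
        assert res.p_fwe[2].min() > 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        g1, g2 = _curves(rng, 5), _curves(rng, 5)
        r1 = group_difference_test(g1, g2, nperm=200, seed=7)
        r2 = group_difference_test(g1, g2, nperm=200, seed=7)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)

    def test_direction_flips_tail(self):
        rng = np.random.default_rng(3)
        g1, g2 = _curves(rng, 6), _curves(rng, 6)
        g2[:, 0] += 0.5
        res_gt = group_difference_test(g1, g2, direction="greater", nperm=200, seed=0)
        res_lt = group_difference_test(g1, g2, direction="less", nperm=200, seed=0)
        assert res_lt.p_fwe[0].min() < res_gt.p_fwe[0].min()

    def test_across_state_correction_never_smaller_p(self):
        rng = np.random.default_rng(4)
        g1, g2 = _curves(rng, 6), _curves(rng, 6)
        g1[:, 0] += 0.3
        joint = group_difference_test(g1, g2, nperm=300, seed=1)
        single = group_difference_test(g1[:, :1], g2[:, :1], nperm=300, seed=1)
        assert (joint.p_fwe[0] >= single.p_fwe[0] - 1e-12).all()

    def test_small_groups_use_exhaustive_relabelings(self):
        rng = np.random.default_rng(5)
        g1, g2 = _curves(rng, 3), _curves(rng, 3)
        res = group_difference_test(g1, g2, nperm=1000, seed=0)
        assert "exhaustive" in res.scheme
        assert res.nperm == 19  # C(6,3) - 1 non-identity relabelings

    def test_p_floor_matches_formula(self):
        rng = np.random.default_rng(6)
        g1 = _curves(rng, 8) + 5.0
        g2 = _curves(rng, 8)
        res = group_difference_test(g1, g2, nperm=99, seed=0)
        assert res.p_fwe.min() >= 1.0 / (res.nperm + 1) - 1e-12

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="2 subjects"):
            group_difference_test(_curves(rng, 1), _curves(rng, 4))


class TestNullCalibration:
    def test_fwe_rate_within_binomial_band(self):
        """Family-wise rejection rate of the group test under a true null
        stays near the nominal 5% (200 simulated null datasets)."""
        rng = np.random.default_rng(8)
        hits = 0
        n_sets = 200
        for _ in range(n_sets):
            g1 = _curves(rng, 6, K=3, W=20)
            g2 = _curves(rng, 6, K=3, W=20)
            res = group_difference_test(
                g1, g2, nperm=200, seed=int(rng.integers(2**31))
            )
            hits += bool((res.p_fwe <= 0.05).any())
        # 95% binomial band around 0.05 for n=200: [0.02, 0.09] roughly
        assert 0.015 <= hits / n_sets <= 0.095


class TestContrastSpec:
    def test_nonzero_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            ContrastSpec("bad", (1.0, 0.0, 0.0))

    def test_contrast_arithmetic_on_means(self):
        """Weights (+1,-0.5,-0.5) applied to per-subject means (0.6,0.2,0.2)
        give 0.4 for every subject; the one-sample t then saturates at the
        permutation floor."""
        n_sess = 8
        curves = np.zeros((n_sess, 3, 1, 4))
        curves[:, 0] = 0.6
        curves[:, 1] = 0.2
        curves[:, 2] = 0.2
        res = rm_anova_frequency(curves, contrasts=(CONTRAST_5HZ,), nperm=200, seed=0)
        r = res[CONTRAST_5HZ.label]
        # numerator is 0.4 for every session; variance floored
        assert r.observed.min() > 1e4
        np.testing.assert_allclose(r.p_fwe, 1.0 / (200 + 1), atol=1e-12)


class TestRmAnova:
    def test_identical_conditions_give_null(self):
        rng = np.random.default_rng(9)
        base = rng.random((6, 1, 2, 20))
        curves = np.repeat(base, 3, axis=1)
        res = rm_anova_frequency(curves, nperm=99, seed=0)
        np.testing.assert_array_equal(res["F"].observed, 0.0)
        np.testing.assert_array_equal(res["F"].p_fwe, 1.0)
        for spec in (CONTRAST_5HZ, CONTRAST_10HZ):
            np.testing.assert_array_equal(res[spec.label].observed, 0.0)

    def test_planted_5hz_tuning_detected_specifically(self):
        rng = np.random.default_rng(10)
        curves = np.abs(rng.standard_normal((10, 3, 2, 20))) * 0.05
        curves[:, 0, 0, 3:12] += 0.5  # state 0 responds only at 5 Hz
        res = rm_anova_frequency(curves, nperm=500, seed=0)
        assert res[CONTRAST_5HZ.label].p_fwe[0].min() <= 0.05
        assert res[CONTRAST_5HZ.label].p_fwe[1].min() > 0.05
        assert res[CONTRAST_10HZ.label].p_fwe[0].min() > 0.05
        assert res["F"].p_fwe[0].min() <= 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        curves = rng.random((5, 3, 2, 10))
        a = rm_anova_frequency(curves, nperm=100, seed=3)
        b = rm_anova_frequency(curves, nperm=100, seed=3)
        np.testing.assert_array_equal(a["F"].p_fwe, b["F"].p_fwe)

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="frequencies"):
            rm_anova_frequency(np.zeros((5, 2, 2, 10)))


class TestMixedAnova:
    def test_copied_group_gives_zero_interaction(self):
        rng = np.random.default_rng(12)
        A = rng.random((5, 3, 2, 12))
        res = mixed_anova_interaction(A, A.copy(), nperm=99, seed=0)
        np.testing.assert_array_equal(res["F"].observed, 0.0)
        for spec in (CONTRAST_5HZ, CONTRAST_10HZ):
            np.testing.assert_array_equal(res[(spec.label, "A>B")].observed, 0.0)

    def test_tuning_loss_detected(self):
        """Group A has 5 Hz tuning in state 0; group B lost it: the 5 Hz
        contrast x group interaction flags state 0, A>B."""
        rng = np.random.default_rng(13)
        A = np.abs(rng.standard_normal((8, 3, 2, 20))) * 0.05
        B = np.abs(rng.standard_normal((8, 3, 2, 20))) * 0.05
        A[:, 0, 0, 3:12] += 0.5
        res = mixed_anova_interaction(A, B, nperm=500, seed=0)
        assert res[(CONTRAST_5HZ.label, "A>B")].p_fwe[0].min() <= 0.05
        assert res[(CONTRAST_5HZ.label, "B>A")].p_fwe[0].min() > 0.05
        assert res[(CONTRAST_10HZ.label, "A>B")].p_fwe[1].min() > 0.05
        assert res["F"].p_fwe[0].min() <= 0.05

    def test_null_calibration_within_band(self):
        rng = np.random.default_rng(14)
        hits = 0
        n_sets = 120
        for _ in range(n_sets):
            A = rng.standard_normal((6, 3, 2, 12)) * 0.1
            B = rng.standard_normal((6, 3, 2, 12)) * 0.1
            res = mixed_anova_interaction(
                A, B, nperm=150, seed=int(rng.integers(2**31))
            )
            hits += bool((res["F"].p_fwe <= 0.05).any())
        assert hits / n_sets <= 0.12
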