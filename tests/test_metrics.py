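"""Scaling metrics: node t-tests, positional scaling error, parameter tests,
scaling powers, power analysis, diffusion-time arithmetic, verdicts."""

import math

import numpy as np
import pytest

from dvscale.hill import HillParams
from dvscale.metrics import (
    compose_report,
    diffusion_time_ratio,
    metric2_scaling_error,
    metric3_param_tests,
    param_size_correlation,
    power_analysis,
    scaling_power,
)


def fits_from(rows, axis="scaled"):
    return [HillParams(a, b, c, r_squared=0.99, axis=axis, n_points=18)
            for a, b, c in rows]


class TestScalingError:
    def test_identical_fits_zero_error(self):
        f = HillParams(1.0, 0.35, 5.0)
        se = metric2_scaling_error(f, f)
        assert len(se.se_values) > 0
        np.testing.assert_allclose(se.se_values, 0.0, atol=1e-12)

    def test_pure_b_rescaling_closed_form(self):
        """For fits differing only in b, SE(z) = z·|b_B/b_A − 1|."""
        fa = HillParams(1.0, 0.3, 5.0)
        fb = HillParams(1.0, 0.4, 5.0)
        se = metric2_scaling_error(fa, fb)
        np.testing.assert_allclose(
            se.se_values, se.eval_positions / 3.0, atol=1e-8
        )

    def test_flat_flanks_excluded(self):
        fa = HillParams(1.0, 0.35, 5.0)
        se = metric2_scaling_error(fa, fa, flank_lo=0.05, flank_hi=0.95)
        # intensities at kept positions stay inside the flank window
        from dvscale.hill import hill_eval

        m = hill_eval(fa, se.eval_positions)
        assert np.all(m > 0.05) and np.all(m < 0.95)
        assert len(se.eval_positions) < 100

    def test_symmetric_variant_swap_invariant(self):
        fa = HillParams(1.0, 0.3, 5.0)
        fb = HillParams(0.9, 0.45, 4.0)
        ab = metric2_scaling_error(fa, fb, symmetric=True)
        ba = metric2_scaling_error(fb, fa, symmetric=True)
        assert ab.mean_se == pytest.approx(ba.mean_se, rel=0.05)

    def test_mismatched_axes_rejected(self):
        fa = HillParams(1.0, 0.3, 5.0, axis="scaled")
        fb = HillParams(1.0, 0.3, 5.0, axis="relative")
        with pytest.raises(ValueError):
            metric2_scaling_error(fa, fb)


class TestParamTests:
    def test_identical_groups_p_one(self):
        rows = [(1.0, 0.35, 5.0)] * 5
        p = metric3_param_tests(fits_from(rows), fits_from(rows))
        assert p == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_large_shift_detected(self):
        """A 3-pooled-SD shift in b is essentially always significant."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            ba = 0.35 + 0.02 * rng.standard_normal(20)
            bb = 0.35 + 0.06 + 0.02 * rng.standard_normal(20)
            fa = fits_from([(1.0, b, 5.0) for b in ba])
            fb = fits_from([(1.0, b, 5.0) for b in bb])
            hits += metric3_param_tests(fa, fb)["b"] < 0.05
        assert hits >= 49

    def test_too_few_fits_rejected(self):
        rows = [(1.0, 0.35, 5.0)] * 2
        with pytest.raises(ValueError):
            metric3_param_tests(fits_from(rows), fits_from(rows * 3))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        rows_a = [(1 + 0.1 * rng.standard_normal(), 0.35, 5.0) for _ in range(8)]
        rows_b = [(1 + 0.1 * rng.standard_normal(), 0.35, 5.0) for _ in range(8)]
        p1 = metric3_param_tests(fits_from(rows_a), fits_from(rows_b))
        p2 = metric3_param_tests(fits_from(rows_a[::-1]), fits_from(rows_b[::-1]))
        assert p1 == p2


class TestSizeCorrelation:
    def test_inverse_size_dependence_detected(self):
        rng = np.random.default_rng(1)
        Ls = rng.uniform(700, 1300, 20)
        fits = fits_from([(1.0, 0.3 * 1000 / L, 5.0) for L in Ls])
        r, p = param_size_correlation(fits, Ls)["b"]
        assert r < -0.9
        assert p < 1e-4

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            Ls = rng.uniform(700, 1300, 20)
            fits = fits_from(
                [(1.0, 0.35 * math.exp(0.05 * rng.standard_normal()), 5.0)
                 for _ in Ls]
            )
            rejections += param_size_correlation(fits, Ls)["b"][1] < 0.05
        assert 0.01 <= rejections / reps <= 0.12

    def test_constant_L_rejected(self):
        fits = fits_from([(1.0, 0.35, 5.0)] * 5)
        with pytest.raises(ValueError):
            param_size_correlation(fits, np.full(5, 1000.0))


class TestScalingPower:
    def test_planted_exponents_recovered_exactly(self):
        rng = np.random.default_rng(4)
        Ls = rng.uniform(700, 1300, 15)
        for k in (-1.0, 0.0, 1.0):
            fits = fits_from([(1.0, 0.3 * (L / 1000.0) ** k, 5.0) for L in Ls])
            est = scaling_power(fits, Ls)["b"]
            assert est == pytest.approx(k, abs=1e-10)

    def test_non_positive_values_rejected(self):
        fits = fits_from([(1.0, 0.3, 5.0)] * 5)
        with pytest.raises(ValueError):
            scaling_power(fits, np.array([1.0, 2.0, 3.0, -4.0, 5.0]))


class TestPowerAnalysis:
    def test_unit_effect_size_needs_17_per_group(self):
        required, _ = power_analysis(mean_diff=1.0, pooled_sd=1.0, n=20)
        assert required == 17

    def test_zero_effect(self):
        required, achieved = power_analysis(0.0, 1.0, 20)
        assert math.isinf(required)
        assert achieved == pytest.approx(0.05)

    def test_power_monotone_in_n_and_effect(self):
        powers_n = [power_analysis(0.5, 1.0, n)[1] for n in (5, 10, 20, 40)]
        assert all(b > a for a, b in zip(powers_n, powers_n[1:]))
        powers_d = [power_analysis(d, 1.0, 15)[1] for d in (0.2, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(powers_d, powers_d[1:]))


class TestDiffusionTime:
    def test_twenty_percent_larger_is_44_percent_slower(self):
        assert diffusion_time_ratio(1.20, 1.0) == pytest.approx(0.44)

    def test_23_percent_smaller_is_41_percent_faster(self):
        assert diffusion_time_ratio(0.77, 1.0) == pytest.approx(-0.4071)

    def test_equal_sizes_no_change(self):
        assert diffusion_time_ratio(123.0, 123.0) == 0.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            diffusion_time_ratio(-1.0, 1.0)


class TestComposeReport:
    def _metrics(self, p1=0.5, se_scaled=0.01, se_rel=0.1, p3=0.5,
                 achieved=0.9):
        metric1 = {"scaled": [(0.1 * k, p1) for k in range(9)],
                   "relative": [(0.1 * k, 0.01) for k in range(9)]}
        metric2 = {"scaled": {"mean_se": se_scaled, "max_se": 2 * se_scaled},
                   "relative": {"mean_se": se_rel, "max_se": 2 * se_rel}}
        metric3 = {k: {"t_p_value": p3, "pearson_r": 0.1, "pearson_p": 0.5,
                       "scaling_power": 0.0} for k in "abc"}
        power = {"required_n": 9, "achieved_power": achieved}
        return metric1, metric2, metric3, power

    def test_scaling_verdict(self):
        rep = compose_report("A", "B", *self._metrics(), n_per_group=(20, 20))
        assert rep.verdict == "scaling"

    def test_non_scaling_verdict_significant_powered_parameter(self):
        rep = compose_report(
            "A", "B", *self._metrics(p3=0.001, achieved=0.95),
            n_per_group=(20, 20),
        )
        assert rep.verdict == "non_scaling"

    def test_tiny_groups_inconclusive(self):
        rep = compose_report("A", "B", *self._metrics(), n_per_group=(2, 2))
        assert rep.verdict == "inconclusive"

    def test_missing_metric_inconclusive(self):
        m1, m2, m3, power = self._metrics()
        rep = compose_report("A", "B", m1, {}, m3, power, n_per_group=(20, 20))
        assert rep.verdict == "inconclusive"
        assert rep.notes
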