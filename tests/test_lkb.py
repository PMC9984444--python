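import math
from statistics import NormalDist

import numpy as np
import pytest

from conftest import uniform_dose_cohort
from ntcpbench import lkb
from ntcpbench.lkb import (
    DEFAULT_BOUNDS,
    LKBDomainError,
    LKBParameters,
    ParameterBounds,
    cohort_log_loss,
    fit,
    loss_landscape,
    ntcp,
)

PHI = NormalDist().cdf  # independent normal-CDF oracle (stdlib, not scipy)


class TestNtcp:
    @pytest.mark.parametrize("m", [0.1, 0.55, 1.0])
    @pytest.mark.parametrize("d50", [30.0, 47.0, 60.0])
    def test_half_probability_at_d50(self, m, d50):
        assert ntcp(d50, LKBParameters(n=1.0, m=m, d50=d50)) == pytest.approx(0.5, abs=1e-15)

    def test_zero_dose_matches_normal_cdf_oracle(self):
        # t = (0 - D50) / (m * D50) = -1/m = -2 standard deviations
        params = LKBParameters(n=1.0, m=0.5, d50=50.0)
        assert ntcp(0.0, params) == pytest.approx(PHI(-2.0), rel=1e-12)

    def test_approaches_one_at_high_dose(self):
        params = LKBParameters(n=1.0, m=0.3, d50=47.0)
        values = [ntcp(k * 47.0, params) for k in (1.0, 1.5, 2.0, 10.0)]
        assert all(a < b for a, b in zip(values[:-1], values[1:-1]))
        assert values[-2] <= values[-1] > 1 - 1e-12  # saturates at the CDF limit

    def test_strictly_increasing_in_gmd_decreasing_in_d50(self):
        params = LKBParameters(n=1.0, m=0.4, d50=50.0)
        doses = np.linspace(1.0, 100.0, 40)
        probs = ntcp(doses, params)
        assert np.all(np.diff(probs) > 0)
        by_d50 = [ntcp(45.0, LKBParameters(n=1.0, m=0.4, d50=d)) for d in (40.0, 50.0, 60.0)]
        assert by_d50[0] > by_d50[1] > by_d50[2]

    def test_degenerate_slope_rejected(self):
        with pytest.raises(LKBDomainError, match="step-function"):
            ntcp(50.0, LKBParameters(n=1.0, m=1e-9, d50=50.0))


class TestCohortLogLoss:
    def test_constant_half_predictor_gives_log_two(self):
        # every patient at uniform dose exactly D50 -> p = 1/2 regardless of m
        cohort = uniform_dose_cohort([47.0] * 6, [1, 0, 1, 1, 0, 0])
        loss = cohort_log_loss(cohort, LKBParameters(n=1.0, m=0.55, d50=47.0))
        assert loss == pytest.approx(math.log(2), rel=1e-12)

    def test_confident_correct_prediction_near_zero(self):
        cohort = uniform_dose_cohort([470.0], [1])
        loss = cohort_log_loss(cohort, LKBParameters(n=1.0, m=0.1, d50=47.0))
        assert 0 <= loss < 1e-10

    def test_four_patient_hand_computation(self):
        doses = [30.0, 45.0, 50.0, 60.0]
        labels = [1, 0, 1, 0]
        params = LKBParameters(n=1.0, m=0.3, d50=47.0)
        cohort = uniform_dose_cohort(doses, labels)
        expected_terms = []
        for d, y in zip(doses, labels):
            p = PHI((d - 47.0) / (0.3 * 47.0))
            expected_terms.append(-(y * math.log(p) + (1 - y) * math.log(1 - p)))
        expected = sum(expected_terms) / 4
        assert cohort_log_loss(cohort, params) == pytest.approx(expected, rel=1e-10)

    def test_loss_finite_over_whole_fitting_box(self):
        cohort = uniform_dose_cohort([20.0, 80.0], [0, 1])
        for n in (0.01, 4.0):
            for m in (0.0, 1.0):  # m = 0 probes the clipped step-function limit
                for d50 in (0.01, 120.0):
                    loss = cohort_log_loss(cohort, LKBParameters(n=n, m=m, d50=d50))
                    assert np.isfinite(loss) and loss >= 0


class TestFit:
    def test_unknown_method_rejected(self, small_cohorts):
        train, _, _ = small_cohorts
        with pytest.raises(ValueError, match="unknown fit method"):
            fit(train, method="nelder_mead")

    def test_local_method_requires_initial(self, small_cohorts):
        train, _, _ = small_cohorts
        with pytest.raises(ValueError, match="initial"):
            fit(train, method="gradient_descent")

    def test_initial_outside_bounds_rejected(self, small_cohorts):
        train, _, _ = small_cohorts
        with pytest.raises(LKBDomainError, match="outside bounds"):
            fit(
                train,
                method="gradient_descent",
                initial=LKBParameters(n=8.0, m=0.5, d50=47.0),
            )

    def test_unsafe_n_bounds_rejected_without_flag(self, small_cohorts):
        train, _, _ = small_cohorts
        tiny_n = ParameterBounds(n=(0.001, 4.0))
        with pytest.raises(LKBDomainError, match="numerical"):
            fit(train, method="dual_annealing", bounds=tiny_n, seed=0)

    def test_fixed_n_leaves_two_free_parameters(self, small_cohorts):
        train, _, _ = small_cohorts
        result = fit(
            train,
            method="gradient_descent",
            initial=LKBParameters(n=1.0, m=0.5, d50=50.0),
            fix_n=1.0,
        )
        assert result.n_free_parameters == 2
        assert result.params.n == 1.0

    def test_local_fit_from_truth_beats_perturbed_starts(self, small_cohorts):
        train, _, truth = small_cohorts
        start = LKBParameters(n=1.0, m=0.55, d50=47.0)
        at_truth = fit(train, method="gradient_descent", initial=start)
        assert at_truth.converged
        for perturbed in (
            LKBParameters(n=3.5, m=0.9, d50=110.0),
            LKBParameters(n=0.02, m=0.05, d50=5.0),
        ):
            other = fit(train, method="gradient_descent", initial=perturbed)
            assert at_truth.loss <= other.loss + 1e-9

    def test_global_methods_agree_and_are_seed_reproducible(self, small_cohorts):
        train, _, _ = small_cohorts
        da = fit(train, method="dual_annealing", seed=4)
        de = fit(train, method="differential_evolution", seed=4)
        assert da.converged and de.converged
        assert abs(da.loss - de.loss) < 1e-3
        again = fit(train, method="dual_annealing", seed=4)
        assert again.loss == da.loss
        assert again.params == da.params

    def test_result_serializes_to_json(self, small_cohorts, tmp_path):
        train, _, _ = small_cohorts
        result = fit(
            train, method="gradient_descent", initial=LKBParameters(n=1.0, m=0.5, d50=50.0)
        )
        result.to_json(tmp_path / "fit.json")
        assert (tmp_path / "fit.json").stat().st_size > 0


class TestLossLandscape:
    def test_degenerate_grid_equals_log_loss(self, small_cohorts):
        train, _, _ = small_cohorts
        grid = loss_landscape(train, [1.0], [47.0], m_fixed=0.55)
        assert len(grid) == 1
        expected = cohort_log_loss(train, LKBParameters(n=1.0, m=0.55, d50=47.0))
        assert grid["loss"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_gradient_changes_sign_across_optimum(self, small_cohorts):
        train, _, _ = small_cohorts
        best = fit(train, method="dual_annealing", seed=1)
        d50_star = best.params.d50
        grid = loss_landscape(
            train,
            [best.params.n],
            [d50_star - 10.0, d50_star + 10.0],
            m_fixed=best.params.m,
        )
        grads = grid.sort_values("d50")["grad_d50"].to_numpy()
        assert grads[0] < 0 < grads[-1]

    def test_uniform_dvhs_make_loss_flat_in_n(self):
        cohort = uniform_dose_cohort([40.0, 55.0], [0, 1])
        grid = loss_landscape(cohort, [0.05, 0.5, 1.0, 3.0], [47.0], m_fixed=0.5)
        assert np.all(np.abs(grid["grad_n"]) < 1e-8)
        assert grid["loss"].nunique() == 1

    def test_out_of_bounds_node_rejected(self, small_cohorts):
        train, _, _ = small_cohorts
        with pytest.raises(ValueError, match="outside bounds"):
            loss_landscape(train, [1.0, 9.0], [47.0], m_fixed=0.5)
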