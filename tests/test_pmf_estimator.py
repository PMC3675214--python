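import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grooveforge.errors import InputError, TraceFormatError
from grooveforge.pmf_estimator import (
    PullingProtocol,
    PullingTrajectory,
    ThermoParams,
    WorkEnsemble,
    average_force_profile,
    bootstrap_uncertainty,
    compute_work,
    cumulant2_delta_A,
    delta_A_profile,
    estimate_pmf,
    jarzynski_delta_A,
    kj_to_kcal,
    stiff_spring_pmf,
)

work_lists = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=30
)

UNIT_THERMO = ThermoParams(temperature=1.0, kB=1.0)  # beta = 1


def lagged_trajectory(lag, k=5.0, v=1.0, t_end=2.0, n=101, lam0=0.0):
    """Analytic trace with constant spring extension ``lag``."""
    t = np.linspace(0.0, t_end, n)
    protocol = PullingProtocol(k=k, v=v, lambda0=lam0)
    lam = protocol.lambda_at(t)
    return PullingTrajectory(time=t, lam=lam, xi=lam - lag, protocol=protocol)


class TestComputeWork:
    def test_perfect_tracking_gives_zero_work(self):
        work = compute_work(lagged_trajectory(lag=0.0))
        assert np.all(work == 0.0)

    def test_constant_lag_closed_form(self):
        k, v, d = 5.0, 2.0, 0.3
        traj = lagged_trajectory(lag=d, k=k, v=v)
        work = compute_work(traj)
        expected = k * d * v * traj.time
        assert work[0] == 0.0
        scale = np.abs(expected[1:])
        assert np.max(np.abs(work[1:] - expected[1:]) / scale) <= 1e-10

    def test_quadratic_lag_matches_fine_quadrature_oracle(self):
        # xi = lam - c*t^2: integrand k*c*t'^2, W(t) = v*k*c*t^3/3
        k, v, c = 5.0, 1.0, 0.4
        protocol = PullingProtocol(k=k, v=v)

        def trace(n):
            t = np.linspace(0.0, 2.0, n)
            lam = protocol.lambda_at(t)
            return PullingTrajectory(
                time=t, lam=lam, xi=lam - c * t**2, protocol=protocol
            )

        analytic = lambda t: v * k * c * t**3 / 3.0  # noqa: E731
        errors = []
        for n in (11, 21, 41, 81):
            traj = trace(n)
            err = np.max(np.abs(compute_work(traj) - analytic(traj.time)))
            errors.append(err)
        assert all(a > b for a, b in zip(errors, errors[1:]))
        # trapezoid halves the step -> roughly quarters the error
        assert errors[-1] < errors[0] / 10

    def test_non_monotonic_time_rejected(self):
        protocol = PullingProtocol(k=5.0, v=1.0)
        t = np.array([0.0, 0.2, 0.1, 0.3])
        with pytest.raises(TraceFormatError, match="increasing"):
            PullingTrajectory(
                time=t, lam=protocol.lambda_at(t), xi=protocol.lambda_at(t),
                protocol=protocol,
            )

    def test_schedule_violation_rejected(self):
        protocol = PullingProtocol(k=5.0, v=1.0)
        t = np.linspace(0, 1, 11)
        with pytest.raises(TraceFormatError, match="schedule"):
            PullingTrajectory(
                time=t, lam=protocol.lambda_at(t) + 0.5, xi=t, protocol=protocol
            )

    def test_inconsistent_force_column_rejected(self):
        traj = lagged_trajectory(lag=0.1)
        with pytest.raises(TraceFormatError, match="force"):
            PullingTrajectory(
                time=traj.time,
                lam=traj.lam,
                xi=traj.xi,
                protocol=traj.protocol,
                force=np.full_like(traj.time, 99.0),
            )


class TestJarzynskiEstimator:
    def test_single_work_value_is_identity(self):
        assert jarzynski_delta_A([3.0]) == pytest.approx(3.0)

    def test_all_equal_works_return_the_constant(self):
        assert jarzynski_delta_A([2.5] * 10) == pytest.approx(2.5)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InputError):
            jarzynski_delta_A([])

    def test_large_beta_w_is_numerically_stable(self):
        # naive exponentiation would underflow at beta*W ~ 1000
        works = [500.0, 600.0, 700.0]
        beta = ThermoParams().beta
        result = jarzynski_delta_A(works)
        assert np.isfinite(result)
        # dominated by the smallest work: dA = min W + ln(M)/beta
        assert result == pytest.approx(500.0 + np.log(3) / beta, abs=1e-9)
        assert 500.0 <= result <= np.mean(works)

    @given(works=work_lists)
    def test_jensen_bound(self, works):
        assert jarzynski_delta_A(works) <= np.mean(works) + 1e-9

    @given(works=work_lists, shift=st.floats(-20, 20, allow_nan=False))
    def test_constant_shift_moves_estimate_by_the_constant(self, works, shift):
        base = jarzynski_delta_A(works)
        shifted = jarzynski_delta_A([w + shift for w in works])
        assert shifted == pytest.approx(base + shift, abs=1e-8)

    @given(works=work_lists, seed=st.integers(0, 100))
    def test_permutation_invariance(self, works, seed):
        rng = np.random.default_rng(seed)
        permuted = list(rng.permutation(works))
        assert jarzynski_delta_A(permuted) == pytest.approx(
            jarzynski_delta_A(works)
        )


class TestCumulantEstimator:
    def test_zero_variance_returns_mean(self):
        assert cumulant2_delta_A([2.0, 2.0]) == pytest.approx(2.0)

    @pytest.mark.parametrize("x", [1.0, 2.5, -3.0])
    def test_two_point_hand_algebra_at_unit_beta(self, x):
        # mean x/2, unbiased variance x^2/2 -> x/2 - x^2/4
        expected = 0.5 * x - x**2 / 4.0
        assert cumulant2_delta_A([0.0, x], UNIT_THERMO) == pytest.approx(
            expected
        )

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            cumulant2_delta_A([1.0])

    def test_agrees_with_jarzynski_on_gaussian_work(self):
        thermo = ThermoParams()  # 310 K
        rng = np.random.default_rng(42)
        works = rng.normal(5.0, 1.0, size=100_000)
        truth = 5.0 - thermo.beta * 1.0 / 2.0
        assert cumulant2_delta_A(works, thermo) == pytest.approx(
            truth, abs=0.05
        )
        assert jarzynski_delta_A(works, thermo) == pytest.approx(
            truth, abs=0.05
        )


class TestStiffSpringMapping:
    def test_zero_profile_maps_to_zero_pmf(self):
        lam = np.linspace(0, 5, 21)
        protocol = PullingProtocol(k=50.0, v=1.0)
        profile = stiff_spring_pmf(lam, np.zeros_like(lam), protocol)
        assert np.all(profile.phi == 0.0)
        assert np.all(profile.xi == lam)

    def test_profile_is_anchored_at_start(self):
        lam = np.linspace(0, 5, 21)
        protocol = PullingProtocol(k=50.0, v=1.0)
        profile = stiff_spring_pmf(lam, lam**2 + 3.0, protocol)
        assert profile.phi[0] == 0.0
        assert profile.spring_constant == 50.0

    def test_second_order_correction_shifts_xi_against_slope(self):
        lam = np.linspace(0, 5, 201)
        protocol = PullingProtocol(k=50.0, v=1.0)
        delta_A = 0.5 * lam**2
        profile = stiff_spring_pmf(
            lam, delta_A, protocol, second_order=True
        )
        # xi = lam - dA'/k, slope positive -> xi shifted left
        assert np.all(profile.xi[1:] < lam[1:])
        assert np.max(np.abs(profile.xi - lam)) <= np.max(lam) / 50.0 + 1e-9

    def test_non_monotonic_grid_rejected(self):
        protocol = PullingProtocol(k=50.0, v=1.0)
        with pytest.raises(InputError):
            stiff_spring_pmf(
                np.array([0.0, 1.0, 0.5]), np.zeros(3), protocol
            )


class TestWorkEnsembleAndBootstrap:
    def make_ensemble(self, lags, **kwargs):
        trajs = [lagged_trajectory(lag=lag, **kwargs) for lag in lags]
        grid = np.linspace(0.0, 1.5, 16)
        return WorkEnsemble.from_trajectories(trajs, grid)

    def test_work_anchored_at_grid_start(self):
        ensemble = self.make_ensemble([0.1, 0.2, 0.3])
        assert np.all(ensemble.works[:, 0] == 0.0)

    def test_grid_outside_recorded_range_rejected(self):
        trajs = [lagged_trajectory(lag=0.1)]
        with pytest.raises(InputError):
            WorkEnsemble.from_trajectories(trajs, np.linspace(0, 99, 10))

    def test_identical_trajectories_zero_width_interval(self):
        ensemble = self.make_ensemble([0.2, 0.2, 0.2])
        lo, hi = bootstrap_uncertainty(ensemble, replicates=50, seed=1)
        assert np.allclose(hi - lo, 0.0)

    def test_same_seed_same_interval(self):
        ensemble = self.make_ensemble([0.1, 0.2, 0.3, 0.4])
        first = bootstrap_uncertainty(ensemble, replicates=100, seed=9)
        second = bootstrap_uncertainty(ensemble, replicates=100, seed=9)
        assert np.array_equal(first[0], second[0])
        assert np.array_equal(first[1], second[1])

    def test_single_trajectory_bootstrap_rejected(self):
        ensemble = self.make_ensemble([0.1])
        with pytest.raises(InputError):
            bootstrap_uncertainty(ensemble, replicates=10, seed=0)

    def test_interval_width_shrinks_with_ensemble_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for m in (5, 20, 80):
            lags = 0.2 + 0.05 * rng.standard_normal(m)
            ensemble = self.make_ensemble(list(lags))
            lo, hi = bootstrap_uncertainty(ensemble, replicates=200, seed=4)
            widths.append(np.mean(hi - lo))
        assert widths[0] > widths[1] > widths[2]

    def test_delta_a_profile_estimators_agree_on_degenerate_ensemble(self):
        ensemble = self.make_ensemble([0.2, 0.2])
        jar = delta_A_profile(ensemble, estimator="jarzynski")
        cum = delta_A_profile(ensemble, estimator="cumulant2")
        assert np.allclose(jar, cum)

    def test_unknown_estimator_rejected(self):
        ensemble = self.make_ensemble([0.1, 0.2])
        with pytest.raises(InputError):
            delta_A_profile(ensemble, estimator="bogus")


class TestAverageForceProfile:
    def test_single_trajectory_returns_its_own_force(self):
        traj = lagged_trajectory(lag=0.25, k=5.0)
        grid = np.linspace(0, 1.5, 16)
        profile = average_force_profile([traj], grid)
        assert np.allclose(profile, 5.0 * 0.25)

    def test_mirror_lags_cancel(self):
        plus = lagged_trajectory(lag=0.2)
        minus = lagged_trajectory(lag=-0.2)
        grid = np.linspace(0, 1.5, 16)
        assert np.allclose(average_force_profile([plus, minus], grid), 0.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InputError):
            average_force_profile([], np.linspace(0, 1, 5))


def test_kj_to_kcal_conversion_round_trip():
    assert kj_to_kcal([-15.01])[0] == pytest.approx(-3.5875, abs=1e-3)


def test_estimate_pmf_end_to_end_constant_lag():
    """Constant-lag traces: dA is linear, PMF = dA - dA(0) = k*d*(lam-lam0)."""
    k, d = 5.0, 0.2
    trajs = [lagged_trajectory(lag=d, k=k) for _ in range(4)]
    grid = np.linspace(0.0, 1.5, 16)
    profile = estimate_pmf(trajs, grid, bootstrap_replicates=20, seed=0)
    assert np.allclose(profile.phi, k * d * grid, atol=1e-10)
    assert profile.uncertainty is not None
    assert np.all(profile.uncertainty >= 0.0)
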