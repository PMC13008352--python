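import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porocell.estimators import (
    BeadTrace,
    EstimatorError,
    PoreScalingParams,
    PressureStepDataset,
    darcy_fit,
    hyperbolic_lag_fit,
    pore_scaling,
    scaling_estimates,
    tau_p_fit,
    time_lag,
)


class TestTimeLag:
    def test_step_trace_absolute_rule(self):
        t = np.arange(0.0, 3.0, 0.1)
        z = np.where(t < 1.2, 0.0, 0.5)
        assert time_lag(BeadTrace(t, z), rule="absolute") == pytest.approx(1.2, abs=0.1)

    def test_linear_ramp_interpolates_crossing(self):
        """z = 0.05 t crosses the 0.1 um threshold at exactly 2.0 s."""
        t = np.arange(0.0, 5.0, 0.5)
        tr = BeadTrace(t, 0.05 * t)
        assert time_lag(tr, rule="absolute") == pytest.approx(2.0, rel=1e-12)

    def test_fraction_rule_uses_steady_state(self):
        t = np.linspace(0, 20, 401)
        tr = BeadTrace(t, 1.0 - np.exp(-t / 2.0))
        lag = time_lag(tr, rule="fraction", fraction=0.10, steady_value=1.0)
        assert lag == pytest.approx(-2.0 * np.log(0.9), rel=0.01)

    def test_no_crossing_is_distinct_from_zero(self):
        tr = BeadTrace(np.arange(5.0), np.zeros(5))
        assert time_lag(tr, rule="absolute") is None

    def test_noisy_sigmoid_crossing_recovered(self):
        """10% crossing of a noisy sigmoid recovered within 0.05 s (100 seeds)."""
        rng = np.random.default_rng(7)
        t = np.linspace(0, 10, 501)
        z0 = 0.5 / (1.0 + np.exp(-(t - 2.0) / 0.55))
        thr = 0.1 * 0.5
        t_true = float(np.interp(thr, z0, t))
        lags = []
        for _ in range(100):
            z = z0 + rng.normal(0, 0.005, t.shape)
            lag = time_lag(BeadTrace(t, z), rule="fraction", steady_value=0.5)
            lags.append(lag)
        assert np.median(lags) == pytest.approx(t_true, abs=0.05)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fraction_rule_scale_invariant(self, scale):
        t = np.linspace(0, 10, 101)
        z = 0.8 * (1.0 - np.exp(-t / 1.7))
        base = time_lag(BeadTrace(t, z), rule="fraction")
        scaled = time_lag(BeadTrace(t, scale * z), rule="fraction")
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDarcyFit:
    def test_exact_darcy_data_recovered(self):
        """v = 0.125 g data returns k = 0.125 with r^2 = 1."""
        dx = np.array([3.0, 5.0, 8.0, 12.0, 15.0])
        dP = np.array([200.0, 300.0, 400.0, 500.0, 600.0])
        dt = dx**2 / (0.125 * dP)
        fit = darcy_fit(PressureStepDataset(dx, dt, dP))
        assert fit.k == pytest.approx(0.125, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.k_si == pytest.approx(1.25e-13, rel=1e-12)

    def test_bad_lags_rejected_and_counted(self):
        dx = np.array([3.0, 5.0, 8.0, 12.0])
        dP = np.full(4, 100.0)
        dt = np.array([1.0, -1.0, 2.0, 3.0])
        fit = darcy_fit(PressureStepDataset(dx, dt, dP))
        assert fit.n_rejected == 1 and fit.n_used == 3

    def test_too_few_records(self):
        with pytest.raises(EstimatorError):
            darcy_fit(PressureStepDataset([1.0, 2.0], [1.0, 1.0], [10.0, 10.0]))

    @given(c=st.floats(0.5, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pressure_scale_equivariance(self, c):
        """Scaling dP by c (velocities too) leaves recovered k invariant."""
        dx = np.array([3.0, 5.0, 8.0, 12.0, 15.0])
        dP = np.array([200.0, 300.0, 400.0, 500.0, 600.0])
        dt = dx**2 / (0.05 * dP) * np.array([1.1, 0.9, 1.05, 0.95, 1.0])
        k1 = darcy_fit(PressureStepDataset(dx, dt, dP)).k
        k2 = darcy_fit(PressureStepDataset(dx, dt / c, c * dP)).k
        assert k2 == pytest.approx(k1, rel=1e-9)


class TestHyperbolicFit:
    def test_exact_hyperbola(self):
        dP = np.array([50.0, 100.0, 200.0, 400.0])
        fit = hyperbolic_lag_fit(PressureStepDataset(np.full(4, 20.0), 200.0 / dP, dP))
        assert fit.c == pytest.approx(200.0, rel=1e-12)
        assert fit.rms_residual < 1e-12

    def test_constant_lag_reports_misfit(self):
        dP = np.array([50.0, 100.0, 200.0, 400.0])
        fit = hyperbolic_lag_fit(PressureStepDataset(np.full(4, 20.0), np.full(4, 2.0), dP))
        assert fit.relative_residual > 0.2

    def test_requires_three_distinct_pressures(self):
        with pytest.raises(EstimatorError):
            hyperbolic_lag_fit(
                PressureStepDataset([20.0, 20.0, 20.0], [1.0, 1.1, 0.9], [100.0] * 3)
            )

    def test_noisy_recovery_within_15pc(self):
        rng = np.random.default_rng(11)
        dP = np.tile([100.0, 200.0, 400.0], 3)
        cs = []
        for _ in range(50):
            dt = 150.0 / dP * (1.0 + rng.normal(0, 0.10, dP.shape))
            cs.append(hyperbolic_lag_fit(PressureStepDataset(np.full(9, 20.0), dt, dP)).c)
        assert np.median(cs) == pytest.approx(150.0, rel=0.15)


class TestTauPFit:
    def test_pure_exponential_exact(self):
        t = np.linspace(0, 10, 201)
        z = 0.5 - 0.3 * np.exp(-(t - 0.3) / 2.0)
        tr = BeadTrace(t, z - z[0])
        assert tau_p_fit(tr, phase_split_time=0.3) == pytest.approx(2.0, rel=1e-6)

    def test_relaxation_time_ratio_preserved(self):
        """A 3.5-fold tau ratio (the osmotic-shock effect size) is recovered."""
        rng = np.random.default_rng(3)
        t = np.linspace(0, 25, 501)
        taus = []
        for tau in (1.0, 3.5):
            z = 0.4 * (1.0 - np.exp(-t / tau)) + rng.normal(0, 0.005, t.shape)
            taus.append(tau_p_fit(BeadTrace(t, z - z[0]), 0.3))
        assert taus[1] / taus[0] == pytest.approx(3.5, rel=0.10)

    def test_too_short_trace_rejected(self):
        with pytest.raises(EstimatorError):
            tau_p_fit(BeadTrace(np.linspace(0, 0.4, 5), np.zeros(5)), 0.3)


class TestPoreScaling:
    def test_no_volume_change_is_identity(self):
        assert pore_scaling(PoreScalingParams(alpha=1.0, phi=0.5)) == (1.0, 1.0)

    def test_formula_value(self):
        """alpha = 0.6, phi = 0.42: xi/xi0 = 0.432^(1/3) ~ 0.756."""
        xi, tp = pore_scaling(PoreScalingParams(alpha=0.6, phi=0.42))
        assert xi == pytest.approx(0.432 ** (1 / 3), rel=1e-12)
        assert tp == pytest.approx(xi**-2, rel=1e-12)

    def test_direct_pore_size_ratio(self):
        """xi/xi0 = 0.72 doubles the efflux time scale almost twofold."""
        xi, tp = pore_scaling(PoreScalingParams(xi=0.72, xi0=1.0))
        assert tp == pytest.approx(1.929, abs=0.001)

    def test_collapsed_pores_domain_error(self):
        with pytest.raises(ValueError, match="collapsed"):
            pore_scaling(PoreScalingParams(alpha=0.1, phi=2.0))

    @given(
        a1=st.floats(0.45, 0.99),
        da=st.floats(0.005, 0.01),
        phi=st.floats(0.42, 0.6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_volume_ratio(self, a1, da, phi):
        xi1, tp1 = pore_scaling(PoreScalingParams(alpha=a1, phi=phi))
        xi2, tp2 = pore_scaling(PoreScalingParams(alpha=a1 + da, phi=phi))
        assert xi2 > xi1 and tp2 < tp1


class TestScalingEstimates:
    def test_published_scale_estimates(self):
        """t_p = 0.2 s, l = 10 um and tau_z = 0.5 s from the printed inputs."""
        out = scaling_estimates(d=4.0, delta=2.0, D=40.0, gamma=1e-3, E=100.0,
                                delta_z=0.5, k=0.1)
        assert out.L == pytest.approx(np.sqrt(8.0))
        assert out.t_p == pytest.approx(0.2, rel=1e-12)
        assert out.l == pytest.approx(10.0, rel=1e-12)
        assert out.tau_z == pytest.approx(0.5, rel=1e-12)

    def test_missing_required_input_raises(self):
        with pytest.raises(ValueError, match="t_p"):
            scaling_estimates(d=4.0, delta=2.0, require=("t_p",))

    def test_unrequested_outputs_are_none(self):
        out = scaling_estimates(d=4.0, delta=2.0)
        assert out.t_p is None and out.l is None and out.tau_z is None


def test_dataset_validation():
    with pytest.raises(ValueError):
        PressureStepDataset([1.0, -2.0], [1.0, 1.0], [10.0, 10.0])
    with pytest.raises(ValueError):
        PressureStepDataset([1.0], [1.0, 1.0], [10.0, 10.0])
    with pytest.raises(ValueError):
        BeadTrace(np.array([0.0, 1.0, 1.0]), np.zeros(3))
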