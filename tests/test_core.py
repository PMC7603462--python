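"""Unit and property tests of the two-layer strain-driven simulator."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonerheo import (
    IntegrationError,
    MaterialParams,
    ModelVariant,
    ParameterError,
    SignalError,
    StrainSignal,
    integrate_maxwell,
    integrate_prandtl,
    simulate,
    yield_function,
)
from .conftest import make_ramp, random_params, random_piecewise_signal
from .oracles import maxwell_ode, prandtl_explicit, refine_signal  # noqa: F401


class TestYieldFunction:
    @pytest.mark.parametrize(
        "sigma_pr, alpha, expected",
        [
            (0.0, 0.0, -10.0),  # unloaded: f = -sigma_Y
            (10.0, 0.0, 0.0),  # yield onset
            (15.0, 0.01, 15.0 - (10.0 + 10.0 * (1.0 - np.exp(-1.0)))),
        ],
    )
    def test_voce_values(self, sigma_pr, alpha, expected):
        params = MaterialParams(1000.0, 10.0, 20.0, 100.0, 2000.0, 4000.0)
        assert yield_function(sigma_pr, alpha, params) == pytest.approx(expected)

    def test_symmetric_in_compression(self):
        params = MaterialParams(1000.0, 10.0, 20.0, 100.0, 2000.0, 4000.0)
        assert yield_function(-7.0, 0.02, params) == yield_function(7.0, 0.02, params)

    def test_linear_and_perfect_limits(self):
        params = MaterialParams(1000.0, 10.0, 20.0, 100.0, 2000.0, 4000.0)
        lin = ModelVariant(hardening="linear", linear_coeff=500.0)
        assert yield_function(0.0, 0.02, params, lin) == pytest.approx(-20.0)
        perf = ModelVariant(hardening="perfect")
        assert yield_function(0.0, 5.0, params, perf) == pytest.approx(-10.0)

    def test_negative_alpha_rejected(self):
        params = MaterialParams(1000.0, 10.0, 20.0, 100.0, 2000.0, 4000.0)
        with pytest.raises(ParameterError):
            yield_function(0.0, -0.1, params)


class TestPrandtlLayer:
    def test_elastic_ramp(self):
        """Below yield the layer is a plain spring with no plastic strain."""
        params = MaterialParams(1000.0, 50.0, 60.0, 100.0, 0.0, 0.0)
        sig = make_ramp(0.04, 1e-3)  # peak stress 40 < 50
        sigma, eps_p, alpha = integrate_prandtl(sig, params)
        np.testing.assert_allclose(sigma, params.E_pr * sig.eps, rtol=1e-12)
        assert np.all(eps_p == 0.0) and np.all(alpha == 0.0)

    def test_perfect_plasticity_closed_form(self):
        """Elastic-perfectly-plastic ramp: stress caps at sigma_Y, eps_p = eps - sigma_Y/E."""
        params = MaterialParams(1000.0, 10.0, 10.0, 100.0, 0.0, 0.0)
        sig = make_ramp(0.05, 1e-3, n=51)
        sigma, eps_p, alpha = integrate_prandtl(
            sig, params, ModelVariant(hardening="perfect")
        )
        assert sigma[-1] == pytest.approx(10.0, rel=1e-10)
        assert eps_p[-1] == pytest.approx(0.04, rel=1e-10)
        assert alpha[-1] == pytest.approx(0.04, rel=1e-10)

    def test_voce_against_fine_step_explicit_oracle(self):
        """Return mapping on 50 steps matches explicit rate integration at 10^4 finer."""
        params = MaterialParams(1000.0, 10.0, 20.0, 100.0, 0.0, 0.0)
        sig = make_ramp(0.05, 1e-3, n=51)
        sigma, _, alpha = integrate_prandtl(sig, params)
        tf, ef = refine_signal(sig.t, sig.eps, 10_000)
        sigma_ref, alpha_ref = prandtl_explicit(
            tf, ef, params.E_pr, params.sigma_Y, params.sigma_u, params.p
        )
        assert sigma[-1] == pytest.approx(sigma_ref[-1], rel=1e-3)
        assert alpha[-1] == pytest.approx(alpha_ref[-1], rel=1e-3)

    def test_oracle_equivalence_on_random_signals(self):
        """Both stress and alpha agree with the refined explicit oracle on
        random monotone-segment histories."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            params = random_params(rng)
            sig = random_piecewise_signal(rng, n_points=12, eps_scale=0.04)
            sigma, _, alpha = integrate_prandtl(sig, params)
            tf, ef = refine_signal(sig.t, sig.eps, 3000)
            sigma_ref, alpha_ref = prandtl_explicit(
                tf, ef, params.E_pr, params.sigma_Y, params.sigma_u, params.p
            )
            idx = np.searchsorted(tf, sig.t)
            scale = np.max(np.abs(sigma_ref))
            assert np.max(np.abs(sigma - sigma_ref[idx])) <= 1e-3 * scale

    def test_nan_rejected(self):
        with pytest.raises(SignalError):
            StrainSignal(t=[0.0, 1.0, 2.0], eps=[0.0, np.nan, 0.01])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(SignalError):
            StrainSignal(t=[0.0, 2.0, 1.0], eps=[0.0, 0.01, 0.02])
        with pytest.raises(SignalError):
            StrainSignal(t=[0.0, 1.0, 1.0], eps=[0.0, 0.01, 0.02])


class TestMaxwellLayer:
    def test_relaxation_hold(self):
        """Holding strain relaxes stress as sigma0 * exp(-E t / eta)."""
        params = MaterialParams(1000.0, 50.0, 60.0, 100.0, 2000.0, 4000.0)
        tau = params.eta / params.E_mx
        # ramp fast to build stress, then hold
        t = np.concatenate([[0.0, 0.01], 0.01 + np.linspace(0.1, 10.0, 100)])
        eps = np.concatenate([[0.0], np.full(101, 0.001)])
        sigma = integrate_maxwell(StrainSignal(t, eps), params)
        sigma0 = sigma[1]
        expected = sigma0 * np.exp(-(t[2:] - t[1]) / tau)
        np.testing.assert_allclose(sigma[2:], expected, rtol=1e-9)

    def test_steady_state_constant_rate(self):
        """Long-time stress under constant rate approaches eta * rate."""
        params = MaterialParams(1000.0, 50.0, 60.0, 100.0, 2000.0, 4000.0)
        t = np.linspace(0.0, 5000.0, 2000)
        sigma = integrate_maxwell(StrainSignal(t, 1e-3 * t), params)
        assert sigma[-1] == pytest.approx(4.0, rel=1e-6)

    def test_against_generic_ode_oracle(self):
        """Exponential stepping matches an adaptive ODE solve to 1e-6 relative."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            params = random_params(rng)
            sig = random_piecewise_signal(rng, n_points=15, eps_scale=0.03)
            sigma = integrate_maxwell(sig, params)
            ref = maxwell_ode(sig.t, sig.eps, params.E_mx, params.eta)
            scale = max(np.max(np.abs(ref)), 1e-12)
            assert np.max(np.abs(sigma - ref)) <= 1e-6 * scale

    def test_disabled_layer_is_zero(self):
        params = MaterialParams(1000.0, 50.0, 60.0, 100.0, 2000.0, 4000.0)
        sig = make_ramp(0.01, 1e-3)
        sigma = integrate_maxwell(sig, params, ModelVariant(maxwell_enabled=False))
        assert np.all(sigma == 0.0)

    def test_degenerate_tau_raises(self):
        params = MaterialParams(1000.0, 50.0, 60.0, 100.0, 2000.0, 0.0)
        sig = make_ramp(0.01, 1e-3)
        with pytest.raises(ParameterError):
            integrate_maxwell(sig, params)


class TestSimulate:
    def test_stress_superposition_exact(self, avg_params):
        rng = np.random.default_rng(3)
        for _ in range(5):
            sig = random_piecewise_signal(rng)
            traj = simulate(sig, avg_params)
            np.testing.assert_array_equal(
                traj.sigma_mod, traj.sigma_pr + traj.sigma_mx
            )

    def test_instantaneous_step_stiffness(self, avg_params):
        """A near-step strain produces a stress jump of (E_pr + E_mx) * d_eps."""
        d_eps = 1e-6  # below yield
        sig = StrainSignal(t=[0.0, 1e-9], eps=[0.0, d_eps])
        traj = simulate(sig, avg_params)
        expected = (avg_params.E_pr + avg_params.E_mx) * d_eps
        assert traj.sigma_mod[-1] == pytest.approx(expected, rel=1e-6)

    def test_quasi_static_slope_is_long_term_modulus(self, avg_params):
        """A vanishing-rate ramp below yield has slope E_pr within 0.5 %."""
        sig = make_ramp(0.002, 1e-6, n=400)  # peak stress ~7 MPa < sigma_Y
        traj = simulate(sig, avg_params)
        slope = traj.sigma_mod[-1] / sig.eps[-1]
        assert slope == pytest.approx(avg_params.E_pr, rel=5e-3)

    def test_damper_strain_recovery(self, avg_params):
        sig = make_ramp(0.01, 1e-3)
        traj = simulate(sig, avg_params)
        np.testing.assert_allclose(
            traj.eps_v, sig.eps - traj.sigma_mx / avg_params.E_mx, rtol=1e-12
        )

    def test_trajectory_csv_roundtrip(self, avg_params, tmp_path):
        sig = make_ramp(0.01, 1e-3, n=20)
        traj = simulate(sig, avg_params)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == (
            "t_s,eps,sigma_mod_MPa,sigma_pr_MPa,sigma_mx_MPa,eps_p,eps_v,alpha"
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_model_invariants_on_random_histories(seed):
    """Admissibility, monotone hardening, saturation and nonnegative
    dissipation hold along arbitrary loading histories."""
    rng = np.random.default_rng(seed)
    params = random_params(rng)
    sig = random_piecewise_signal(rng, n_points=15, eps_scale=0.05)
    traj = simulate(sig, params)
    f = (
        np.abs(traj.sigma_pr)
        - params.sigma_Y
        - (params.sigma_u - params.sigma_Y) * (1.0 - np.exp(-traj.alpha * params.p))
    )
    assert np.all(f <= 1e-8 * params.sigma_Y)  # Kuhn-Tucker admissibility
    assert np.all(np.diff(traj.alpha) >= 0)  # alpha non-decreasing
    assert np.all(traj.alpha >= np.abs(traj.eps_p) - 1e-15)
    assert np.all(np.abs(traj.sigma_pr) <= params.sigma_u * (1 + 1e-9))
    # plastic dissipation is nonnegative per step
    d_plastic = traj.sigma_pr[1:] * np.diff(traj.eps_p)
    assert np.all(d_plastic >= -1e-12)
    # viscous dissipation: nonnegative on every step where the stress keeps
    # its sign (within a sign-crossing step the endpoint product is not a
    # valid dissipation proxy), and nonnegative in total once the quadrature
    # is converged on a refined grid
    mid = 0.5 * (traj.sigma_mx[1:] + traj.sigma_mx[:-1])
    d_viscous = mid * np.diff(traj.eps_v)
    same_sign = traj.sigma_mx[1:] * traj.sigma_mx[:-1] >= 0
    assert np.all(d_viscous[same_sign] >= -1e-12)
    tf, ef = refine_signal(sig.t, sig.eps, 100)
    fine = simulate(StrainSignal(tf, ef), params)
    mid_f = 0.5 * (fine.sigma_mx[1:] + fine.sigma_mx[:-1])
    assert np.sum(mid_f * np.diff(fine.eps_v)) >= -1e-12


def test_variant_ablation_flags(avg_params):
    """Disabled plasticity locks eps_p; disabled Maxwell kills sigma_mx."""
    sig = make_ramp(0.03, 1e-3)
    no_pl = simulate(sig, avg_params, ModelVariant(plasticity_enabled=False))
    assert np.all(no_pl.eps_p == 0.0)
    np.testing.assert_allclose(no_pl.sigma_pr, avg_params.E_pr * sig.eps)
    no_mx = simulate(sig, avg_params, ModelVariant(maxwell_enabled=False))
    assert np.all(no_mx.sigma_mx == 0.0)
    assert np.all(no_mx.eps_v == 0.0)
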