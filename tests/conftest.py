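import numpy as np
import pytest

from bonerheo import MaterialParams, ModelVariant, StrainSignal


@pytest.fixture(scope="session")
def avg_params():
    """Cohort-average material constants (moduli in MPa)."""
    return MaterialParams(
        E_pr=3640.0, sigma_Y=16.89, sigma_u=63.99, p=172.2, E_mx=1970.0, eta=3710.0
    )


@pytest.fixture(scope="session")
def voce_variant():
    return ModelVariant()


def make_ramp(eps_max, rate, n=200):
    """Constant-rate ramp signal to eps_max at the given strain rate [1/s]."""
    eps = np.linspace(0.0, eps_max, n)
    return StrainSignal(t=eps / rate, eps=eps)


def random_piecewise_signal(rng, n_points=20, t_max=100.0, eps_scale=0.02):
    """Random piecewise-linear strain history (may load, unload, reverse)."""
    t = np.sort(rng.uniform(0.0, t_max, n_points - 1))
    t = np.concatenate([[0.0], t])
    t += np.arange(n_points) * 1e-6  # guard against duplicates
    eps = np.concatenate([[0.0], rng.uniform(-eps_scale, eps_scale, n_points - 1)])
    return StrainSignal(t=t, eps=eps)


def random_params(rng):
    """Random parameter set inside the identification search box."""
    E_pr = rng.uniform(500, 5000)
    sY = rng.uniform(10, 100)
    du = rng.uniform(10, 100)
    p = rng.uniform(10, 1000)
    E_mx = rng.uniform(500, 5000)
    eta = rng.uniform(2000, 20000)
    return MaterialParams(E_pr, sY, sY + du, p, E_mx, eta)
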