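import pytest

from promcycle.model import PromoterCycleModel
from promcycle.simulate import CalibrationModel


@pytest.fixture(scope="session")
def cycle6():
    """Realistic bursty cycle: N=6 equal steps, T=90 min, tau_a=8 min, k_m=5/min."""
    return PromoterCycleModel.equal_steps(
        6, 90.0, off_rate=1 / 8, k_m=5.0, k_p=1.0, gamma_m=1 / 20, gamma_p=1 / 30)


@pytest.fixture(scope="session")
def telegraph():
    """Two-state (N=1) cycle with the same T, tau_a and rates as cycle6."""
    return PromoterCycleModel(
        1, (1 / 90.0,), off_rate=1 / 8, k_m=5.0, k_p=1.0, gamma_m=1 / 20,
        gamma_p=1 / 30)


@pytest.fixture(scope="session")
def small_model():
    """Low-copy-number regime whose (g,m,p) lattice stays a few hundred states."""
    return PromoterCycleModel(
        1, (1 / 45.0,), off_rate=1 / 8, k_m=0.3, k_p=0.2, gamma_m=0.05,
        gamma_p=0.2)


@pytest.fixture(scope="session")
def noisy_calibration():
    return CalibrationModel(gain=1.0, background=0.0, var_floor=0.25, var_slope=0.0)


@pytest.fixture(scope="session")
def noiseless_calibration():
    return CalibrationModel(gain=1.0, background=0.0)


def random_cycle(rng, n_max=6, bursting=False):
    """Random valid promoter cycle for property sweeps."""
    n = int(rng.integers(1, n_max + 1))
    durations = rng.uniform(5.0, 60.0, size=n)
    T = durations.sum()
    tau_a = T * rng.uniform(1e-4, 5e-3) if bursting else rng.uniform(2.0, 30.0)
    return PromoterCycleModel(
        n_inactive=n, step_rates=tuple(1.0 / durations), off_rate=1.0 / tau_a,
        k_m=rng.uniform(0.5, 8.0), k_p=rng.uniform(0.1, 1.0),
        gamma_m=rng.uniform(0.01, 0.1), gamma_p=rng.uniform(0.05, 0.3))
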