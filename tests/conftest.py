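import numpy as np
import pytest

from riboswap import simkit


@pytest.fixture(scope="session")
def kinetics_sim():
    """Default pulse / pulse-chase simulation with planted kinetic groups."""
    cfg = simkit.kinetics_config(seed=7)
    peptides, truth = simkit.simulate_experiment(cfg)
    return cfg, peptides, truth


@pytest.fixture(scope="session")
def lmb_sim():
    """2-day labeling with control and biogenesis-blocked arms."""
    cfg = simkit.lmb_config(seed=11)
    peptides, truth = simkit.simulate_experiment(cfg)
    return cfg, peptides, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free, background-free simulation: measured fractions must equal
    the planted trajectories exactly."""
    base = simkit.kinetics_config(seed=3)
    cfg = simkit.SimConfig(
        proteins=base.proteins, schedules=base.schedules,
        conditions=base.conditions, noise_cv=0.0, background_fraction=0.0,
        n_biological=2, n_technical=1, seed=3)
    peptides, truth = simkit.simulate_experiment(cfg)
    return cfg, peptides, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
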