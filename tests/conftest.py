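import numpy as np
import pytest

from scalerp import design, simulate

PRODUCTION_WINDOWS = [
    design.FixedWindowSpec("cue", -200.0, 800.0),
    design.FixedWindowSpec("response", -800.0, 200.0),
]


@pytest.fixture(scope="session")
def production_windows():
    return list(PRODUCTION_WINDOWS)


@pytest.fixture(scope="session")
def scaled_spec():
    return design.ScaledSpec(330)


@pytest.fixture(scope="session")
def small_noisefree_dataset():
    """10 trials/condition, no noise: fast closed-loop ground truth."""
    cfg = simulate.SimulationConfig(
        trials_per_condition=10, noise_amplitude=0.0, seed=11
    )
    return simulate.simulate_dataset(cfg, n_channels=2)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    cfg = simulate.SimulationConfig(
        trials_per_condition=10, noise_amplitude="signal_rms", seed=12
    )
    return simulate.simulate_dataset(cfg, n_channels=1)


def fit_dataset(dataset, lam=0.0, n_points=330):
    """Build the production-style design for a simulated dataset and solve."""
    from scalerp import solver

    X, Y = design.build_design(
        dataset.recording,
        dataset.events,
        PRODUCTION_WINDOWS,
        design.ScaledSpec(n_points),
    )
    penalty = solver.make_first_derivative_operator(
        X.n_predictors, X.block_boundaries(), lam
    )
    est = solver.solve(X, Y, penalty)
    return X, Y, est
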