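import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conjugate_release import SimConfig, run_ensemble

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def exact_mean_exit_steps(lattice) -> np.ndarray:
    """Expected absorption step count of the 6-neighbour absorbing walk.

    Independent oracle: solves (I - Q) E = 1 for the embedded Markov chain
    of a lone walker on the sphere's sites, where Q[i, j] = 1/6 for every
    in-sphere neighbour j of i and absorption happens on stepping outside.
    With a single particle each Monte Carlo step advances time by exactly
    1 tu, so E is directly comparable with simulated release times.
    """
    ms = lattice.ms
    Q = np.zeros((ms, ms))
    for i in range(ms):
        for j in lattice.neighbors[i]:
            if j >= 0:
                Q[i, j] += 1.0 / 6.0
    return np.linalg.solve(np.eye(ms) - Q, np.ones(ms))


@pytest.fixture(scope="session")
def ensemble_r5():
    """Completed reference ensemble: R=5, C0=0.5, kb=0.1, 30 realizations."""
    return run_ensemble(SimConfig(R=5, C0=0.5, kb=0.1, n_realizations=30, seed=11))


@pytest.fixture(scope="session")
def diffusion_r5():
    """Matched purely diffusional ensemble (all particles free at t=0)."""
    return run_ensemble(
        SimConfig(R=5, C0=0.5, n_realizations=60, seed=11, diffusion_only=True)
    )
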