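import numpy as np
import pytest

import seqpoint as sp


@pytest.fixture(scope="session")
def musec_counts():
    return sp.load_musec_counts()


@pytest.fixture(scope="session")
def musec_info():
    """Sufficient statistics of the bundled trial (full-precision boundary)."""
    return sp.musec_information()


@pytest.fixture(scope="session")
def no_stopping_info(musec_info):
    """Same informations, but an unreachable boundary (no early stopping)."""
    return sp.TrialInformation(
        i1=musec_info.i1,
        i2=musec_info.i2,
        z1=musec_info.z1,
        z2=musec_info.z2,
        theta1=musec_info.theta1,
        theta_obs=musec_info.theta_obs,
        e=40.0,
    )


@pytest.fixture(scope="session")
def sim_results_10k(musec_info):
    """Seeded 10^4-replicate simulations at the three study effects.

    Shared across the simulation and acceptance tests so the expensive
    per-replicate estimator evaluation runs once per effect size.
    """
    out = {}
    for theta, seed in ((0.10, 101), (0.14, 102), (0.18, 103)):
        reps = sp.simulate_replicates(theta, musec_info, 10_000, seed)
        out[theta] = (reps, sp.evaluate_estimators(reps, musec_info))
    return out


def mc_se(sd: float, n: int) -> float:
    """Monte-Carlo standard error of a sample mean."""
    return sd / np.sqrt(n)
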