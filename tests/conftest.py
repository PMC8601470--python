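import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stagematch import CountMatrix, SimConfig, simulate_study

logging.getLogger("stagematch").setLevel(logging.WARNING)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def nb_counts(rng, mu_cpm, phi, libs):
    """Gamma-Poisson draws at CPM-scale means (independent of the package RNG paths)."""
    mu = np.asarray(mu_cpm, dtype=float) / 1e6 * libs[None, :]
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def count_matrix(values, prefix="g", samples=None) -> CountMatrix:
    values = np.asarray(values)
    if samples is None:
        samples = [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(
            values, index=[f"{prefix}{i}" for i in range(values.shape[0])], columns=samples
        )
    )


SMALL_CONFIG = dict(
    n_genes=300,
    n_repeat_loci=80,
    n_drivers=3,
    passengers_per_driver=4,
    n_independent_de_repeats=10,
    n_tss_dmrs=6,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with all planted structures (seed fixed)."""
    return simulate_study(SimConfig(seed=7, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_study():
    """One default-scale study shared by the slower recovery tests."""
    return simulate_study(SimConfig(seed=11))
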