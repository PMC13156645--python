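import dataclasses

import numpy as np
import pytest

from gwnbr.io import SpatialCountDataset
from gwnbr.simulate import CovariateSpec, SyntheticSpec, default_scenario, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 12-unit, 2-covariate dataset for oracle comparisons."""
    rng = np.random.default_rng(42)
    n = 12
    coords = rng.uniform(0, 10, size=(n, 2))
    X = np.column_stack([rng.normal(5, 2, n), rng.uniform(0, 1, n)])
    eta = 0.5 + 0.2 * X[:, 0] + 0.8 * X[:, 1]
    y = rng.poisson(np.exp(eta))
    return SpatialCountDataset(
        unit_labels=tuple(str(i) for i in range(n)),
        response=y,
        covariates=X,
        covariate_names=("x1", "x2"),
        coords=coords,
    )


@pytest.fixture(scope="session")
def default_data():
    """The package's reference synthetic scenario (n=200, theta=0.1)."""
    return generate(default_scenario())


def constant_surface_spec(n=200, theta=0.1, seed=20260419) -> SyntheticSpec:
    """Default scenario with all coefficient drifts removed (global NB truth)."""
    base = default_scenario()
    flat = tuple((a, 0.0, 0.0) for a, _, _ in base.surfaces)
    return dataclasses.replace(base, n=n, theta=theta, seed=seed, surfaces=flat)


@pytest.fixture(scope="session")
def constant_surface_data():
    return generate(constant_surface_spec())


@pytest.fixture(scope="session")
def poisson_spec():
    """Constant surfaces and theta=0: plain Poisson GLM data."""
    return constant_surface_spec(theta=0.0)
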