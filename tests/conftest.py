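"""Shared fixtures: small datasets plus the two expensive recovery traces."""

from __future__ import annotations

import numpy as np
import pytest

from unpbn.gbn import Dataset
from unpbn.sampler import McmcConfig, run_mcmc
from unpbn.simulate import (
    four_component_gbn_spec,
    generate_gbn_mixture,
    two_component_gbn_spec,
)


def set_partitions(items: list):
    """All set partitions of a list (Bell-number many; keep n small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    rng = np.random.default_rng(1)
    return Dataset(rng.normal(0.3, 1.2, size=(6, 2)))


@pytest.fixture(scope="session")
def recovery_mixture2():
    """The two-component study condition: d=3, 200 cells/component,
    v-structure vs chain, |beta| = 1.5, mean separation 4."""
    spec = two_component_gbn_spec(n_cells=200)
    data, truth = generate_gbn_mixture(spec, np.random.default_rng(1))
    return spec, data, truth


@pytest.fixture(scope="session")
def recovery_trace2(recovery_mixture2):
    _, data, _ = recovery_mixture2
    cfg = McmcConfig(n_iterations=2000, burn_in=1000, thinning=5, seed=11)
    return run_mcmc(data, config=cfg)


@pytest.fixture(scope="session")
def recovery_mixture4():
    spec = four_component_gbn_spec(n_cells=150)
    data, truth = generate_gbn_mixture(spec, np.random.default_rng(2))
    return spec, data, truth


@pytest.fixture(scope="session")
def recovery_trace4(recovery_mixture4):
    _, data, _ = recovery_mixture4
    cfg = McmcConfig(n_iterations=3000, burn_in=1500, thinning=5, seed=12)
    return run_mcmc(data, config=cfg)
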