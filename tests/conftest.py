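"""Shared fixtures: small synthetic datasets and a fitted analysis."""

from __future__ import annotations

import numpy as np
import pytest

from cytodisc import DiscordanceModel, InferenceSettings, SimulationConfig
from cytodisc import msa
from cytodisc.simulate import RegionSpec, simulate_bundle


def small_config(seed: int = 7, **kwargs) -> SimulationConfig:
    """A 12-taxon, 1-hybrid benchmark small enough for unit tests."""
    defaults = dict(
        n_taxa=12,
        n_hybrids=1,
        regions=(
            RegionSpec("pl-a", 400, msa.PLASTID, 1.0),
            RegionSpec("pl-b", 400, msa.PLASTID, 1.0),
            RegionSpec("ITS", 500, msa.NUCLEAR, 2.0),
        ),
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_config())


@pytest.fixture(scope="session")
def fitted_small():
    """One full three-phase fit on the small benchmark (shared, ~15 s)."""
    model = DiscordanceModel.from_simulation(
        small_config(),
        settings=InferenceSettings(candidates=("GTR+G",)),
    )
    results = model.fit(seed=3)
    return model, results
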