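"""Shared fixtures: small seeded synthetic studies, reused across modules."""

import numpy as np
import pytest

from svrlsm.synthetic import (default_territory, generate_lesion,
                              generate_parcellation, generate_reference_paths)


@pytest.fixture(scope="session")
def parc20():
    """20^3 grid, 8 connected nodes; enough structure for most unit tests."""
    return generate_parcellation((20, 20, 20), 8, seed=11)


@pytest.fixture(scope="session")
def atlas20(parc20):
    return generate_reference_paths(parc20, n_reference=3, jitter_sd=1.0, seed=12)


@pytest.fixture(scope="session")
def territory20(parc20):
    return default_territory(parc20.grid_shape)


@pytest.fixture(scope="session")
def lesions20(parc20, territory20):
    rng = np.random.default_rng(13)
    vols = rng.integers(40, 700, size=30)
    return [
        generate_lesion(parc20, territory20, int(v), seed=200 + k,
                        subject_id=f"S{k + 1:02d}")
        for k, v in enumerate(vols)
    ]
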