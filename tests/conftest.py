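import numpy as np
import pytest

import alienrich as ar


@pytest.fixture(scope="session")
def small_config():
    return ar.WorldConfig(seed=3)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Fully synthesized 20x20 world shared across read-only tests."""
    return ar.synthesize(small_config)


@pytest.fixture(scope="session")
def grid5():
    return ar.EqualAreaGrid(n_rows=5, n_cols=5)


@pytest.fixture(scope="session")
def weights5(grid5):
    return ar.build_weights(grid5.to_frame(), threshold_km=1.5 * grid5.cell_km)


def make_records(country_ids, years=None, species=None, status=1,
                 provenance="introduction"):
    """Small helper constructing dated introduction records."""
    n = len(country_ids)
    years = years or [1800] * n
    species = species or [f"s{i}" for i in range(n)]
    return [ar.IntroductionRecord(species_id=str(s), family_id="f0",
                                  country_id=str(c), year=y, status=status,
                                  provenance=provenance)
            for s, c, y in zip(species, country_ids, years)]
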