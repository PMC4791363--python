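from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

from streampop import (
    PopulationSpec,
    fragment_and_cover,
    simulate_genome,
)


@pytest.fixture(scope="session")
def two_population_contigs():
    """Two well-separated populations (G+C 0.44 vs 0.29), 50 contigs each."""
    g1 = simulate_genome(PopulationSpec("T1", 0.44, 250_000), seed=101)
    g2 = simulate_genome(PopulationSpec("T2", 0.29, 250_000), seed=102)
    c1 = fragment_and_cover(g1, 50, 3100, 3.0, seed=111)
    c2 = fragment_and_cover(g2, 50, 3100, 2.2, seed=112)
    return c1, c2


@pytest.fixture(scope="session")
def marker_catalogs():
    from streampop import default_catalogs

    return default_catalogs()
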