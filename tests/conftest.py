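"""Shared fixtures: synthetic landscapes and simulated populations.

Simulation fixtures are session-scoped because forward simulation of a RIL
population is the expensive step; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from recmap.hotspots import ChromatinMap
from recmap.simulate import (
    default_marker_grid,
    make_landscape,
    simulate_ril_population,
)

EU = "euchromatic"
HET = "heterochromatic"


@pytest.fixture(scope="session")
def two_hotspot_landscape():
    """20-Mbp chromosome, pericentromeric middle, two planted hotspots."""
    chromatin = {"c1": [(0, 8e6, EU), (8e6, 12e6, HET), (12e6, 20e6, EU)]}
    return make_landscape(
        chrom_spec=[("c1", 20_000_000)],
        chromatin_spec=chromatin,
        hotspot_spec=[
            ("c1", 4_000_000, 200_000, 50.0),
            ("c1", 16_000_000, 200_000, 50.0),
        ],
        background_rates={EU: 5.0, HET: 0.3},
    )


@pytest.fixture(scope="session")
def chromatin_map_c1():
    return ChromatinMap(
        {"c1": [(0, 8_000_000, EU), (8_000_000, 12_000_000, HET),
                (12_000_000, 20_000_000, EU)]}
    )


@pytest.fixture(scope="session")
def sim_population(two_hotspot_landscape):
    """1,000 F5 RILs, markers every 25 kb, fixed seed."""
    markers = default_marker_grid(two_hotspot_landscape, 25_000)
    gm, truth = simulate_ril_population(
        two_hotspot_landscape, markers, n_lines=1000, final_generation=5,
        rng=12345, population_label="popA",
    )
    return gm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
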