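import numpy as np
import pandas as pd
import pytest

from xofit.io_data import (
    BivalentDataset,
    ChromosomeFrame,
    GameteDataset,
    GeneticMap,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """Four markers, three intervals of 0.3 / 0.4 / 0.3 Morgans."""
    return GeneticMap(("m1", "m2", "m3", "m4"), np.array([0.0, 0.3, 0.7, 1.0]))


@pytest.fixture
def tiny_gametes(small_map):
    geno = pd.DataFrame(
        [
            ["A", "A", "B", "B"],
            ["A", "A", "A", "A"],
            ["A", np.nan, "B", "B"],
            ["B", "B", "A", "B"],
        ],
        index=["g1", "g2", "g3", "g4"],
        columns=list(small_map.names),
    )
    return GameteDataset(geno, small_map)


@pytest.fixture
def small_bivalents():
    frame = ChromosomeFrame(1.0, "morgan")
    return BivalentDataset(
        [[0.2, 0.7], [], [0.5], [0.1, 0.4, 0.9]], frame
    )
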