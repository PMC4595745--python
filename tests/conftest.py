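import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sortedseq import CountMatrix, SampleDesign
from sortedseq.simulate import SimParams, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> CountMatrix:
    """6 genes (one spike) x 4 samples, hand-sized."""
    genes = ["g1", "g2", "g3", "g4", "g5", "ERCC-1"]
    counts = pd.DataFrame(
        [
            [30, 25, 40, 35],
            [100, 110, 90, 95],
            [0, 0, 5, 3],
            [500, 480, 510, 505],
            [7, 9, 6, 8],
            [12, 10, 14, 11],
        ],
        index=genes,
        columns=["s1", "s2", "s3", "s4"],
    )
    lengths = pd.Series([1.0, 2.0, 0.5, 1.5, 3.0, 1.0], index=genes)
    is_spike = pd.Series([False] * 5 + [True], index=genes)
    return CountMatrix(counts, lengths, is_spike)


@pytest.fixture
def small_design() -> SampleDesign:
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "cell_type": ["AGRP", "AGRP", "POMC", "POMC"],
                "condition": ["fed", "fed", "fed", "fed"],
                "n_cells": [100, 120, 90, 110],
            }
        )
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One study-shaped simulated dataset shared across tests."""
    return generate_dataset(SimParams(n_genes=2000, seed=11))


@pytest.fixture(scope="session")
def sim_params_small():
    return SimParams(n_genes=500, seed=3)
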