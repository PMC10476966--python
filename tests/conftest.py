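import numpy as np
import pandas as pd
import pytest

from apatwinscan.datamodel import SampleDesign, design_frame
from apatwinscan.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_design():
    return [
        SampleDesign("A1", "A", "b0", 1_000_000),
        SampleDesign("A2", "A", "b1", 1_000_000),
        SampleDesign("A3", "A", "b0", 1_000_000),
        SampleDesign("B1", "B", "b0", 1_000_000),
        SampleDesign("B2", "B", "b1", 1_000_000),
        SampleDesign("B3", "B", "b0", 1_000_000),
    ]


@pytest.fixture(scope="session")
def small_design_df(small_design):
    return design_frame(small_design)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest fixture bundle shared by module tests: 40 genes, 8 shifted
    of which 4 carry planted twin motifs."""
    cfg = SimulationConfig(
        n_genes=40,
        n_shifted=8,
        n_motif_candidates=4,
        delta_log2=3.0,
        mean_gene_count=400.0,
        dispersion=0.05,
        seed=7,
    )
    return simulate_dataset(cfg)
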