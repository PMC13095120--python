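import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import devclock as dc


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete multi-study configuration."""
    return dc.SimulationConfig(
        n_studies=3,
        samples_per_study=5,
        ages=(6.0, 12.0, 18.0, 24.0, 30.0),
        cells_per_sample=80,
        n_genes=300,
        n_positive_genes=30,
        n_negative_genes=30,
        n_modules=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_config):
    return dc.simulate_multistudy(tiny_config)


@pytest.fixture(scope="session")
def tiny_pb(tiny_data):
    dataset, _ = tiny_data
    return dc.pseudobulk(dataset, group_keys="sample_class", normalization="lognorm")


@pytest.fixture(scope="session")
def tiny_clock(tiny_pb):
    return dc.train_clock(tiny_pb, seed=5)


def toy_dataset(counts, ages=None, study="s0", classes=None):
    """Assemble a MultiStudyDataset from a dense genes x cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    ages = ages if ages is not None else [10.0] * n_cells
    classes = classes if classes is not None else ["Neuron"] * n_cells
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "study_id": study,
            "sample_id": [f"{study}_s{i}" for i in range(n_cells)],
            "age_pcw": ages,
            "author_cell_type": classes,
            "broad_class": classes,
            "species": "human",
        }
    )
    return dc.MultiStudyDataset(
        counts=sp.csr_matrix(counts), genes=[f"g{i}" for i in range(n_genes)], cells=cells
    )


def make_pseudobulk(values, ages, studies=None, classes=None, normalization="lognorm", genes=None):
    """Assemble a PseudobulkMatrix directly from a genes x groups array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_groups = values.shape
    studies = studies if studies is not None else ["s0"] * n_groups
    groups = pd.DataFrame(
        {
            "study_id": studies,
            "sample_id": [f"{s}_smp{i}" for i, s in enumerate(studies)],
            "age_pcw": ages,
            "n_cells": 10,
        }
    )
    if classes is not None:
        groups["broad_class"] = classes
    return dc.PseudobulkMatrix(
        values=values,
        genes=list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)],
        groups=groups,
        normalization=normalization,
    )
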