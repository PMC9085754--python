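import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from regaxis import datasets, merge_networks

hyp_settings.register_profile("default", derandomize=True, deadline=None)
hyp_settings.load_profile("default")


@pytest.fixture(scope="session")
def axis_network():
    """Directed regulatory network built from the published worked example."""
    return merge_networks([datasets.regulatory_axis_edges()])


@pytest.fixture(scope="session")
def driver_annot():
    return datasets.driver_transcript_annotation()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def make_expression(
    n_genes=200, n_per_class=10, effect=3.0, noise=0.5, n_de=20, seed=0
):
    """Small planted-DE expression matrix with class labels.

    Returns (matrix, classes, planted) — the first n_de genes are
    shifted up by ``effect`` in resistant samples.
    """
    g = np.random.default_rng(seed)
    samples = [f"R{i}" for i in range(n_per_class)] + [
        f"S{i}" for i in range(n_per_class)
    ]
    classes = {s: ("resistant" if s.startswith("R") else "sensitive") for s in samples}
    values = g.normal(7.0, noise, size=(n_genes, len(samples)))
    values[:n_de, :n_per_class] += effect
    genes = [f"G{i:04d}" for i in range(n_genes)]
    return (
        pd.DataFrame(values, index=genes, columns=samples),
        classes,
        genes[:n_de],
    )


def partition_agreement(membership, truth):
    """Best-matching agreement between a found partition and planted blocks.

    Builds the contingency matrix and solves the assignment problem so
    each found community maps to at most one planted block.
    """
    from scipy.optimize import linear_sum_assignment

    nodes = list(truth)
    comm_ids = sorted({membership[n] for n in nodes})
    block_ids = sorted(set(truth.values()))
    m = np.zeros((len(comm_ids), len(block_ids)))
    for n in nodes:
        m[comm_ids.index(membership[n]), block_ids.index(truth[n])] += 1
    r, c = linear_sum_assignment(-m)
    return m[r, c].sum() / len(nodes)
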