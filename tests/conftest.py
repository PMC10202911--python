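import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from netsig import ExpressionMatrix, GeneGraph


@pytest.fixture
def path_graph():
    """A - B - C."""
    return GeneGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    return GeneGraph.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def star5():
    """Centre 'C0' with 4 leaves."""
    return GeneGraph.from_edges([("C0", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def k4():
    g = nx.complete_graph(4)
    return GeneGraph(nx.relabel_nodes(g, {i: f"N{i}" for i in range(4)}))


def random_gene_graph(n: int, p: float, seed: int) -> GeneGraph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return GeneGraph(nx.relabel_nodes(g, {i: f"G{i:02d}" for i in range(n)}))


def make_matrix(values: np.ndarray, n_control: int, n_case: int,
                genes=None, extra_ann: dict | None = None) -> ExpressionMatrix:
    """Wrap a (genes x samples) array with control columns first."""
    n_genes = values.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols = [f"ctrl{i}" for i in range(n_control)] + [f"case{i}" for i in range(n_case)]
    ann = {"group": ["control"] * n_control + ["case"] * n_case}
    ann.update(extra_ann or {})
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        pd.DataFrame(ann, index=cols),
    )


def shifted_matrix(n_null: int, n_shifted: int, delta: float, n_control: int,
                   n_case: int, seed: int, noise_sd: float = 1.0) -> ExpressionMatrix:
    """Null genes plus genes with a mean shift in cases (no correlation)."""
    rng = np.random.default_rng(seed)
    n_samples = n_control + n_case
    x = rng.normal(8.0, noise_sd, size=(n_null + n_shifted, n_samples))
    x[n_null:, n_control:] += delta
    genes = [f"null{i}" for i in range(n_null)] + [f"hit{i}" for i in range(n_shifted)]
    return make_matrix(x, n_control, n_case, genes=genes)
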