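from __future__ import annotations

import numpy as np
import pytest

from netpharm import load_cki_target_table
from netpharm.network import Network


@pytest.fixture(scope="session")
def target_table():
    """The packaged 48-target topology table."""
    return load_cki_target_table()


@pytest.fixture()
def path_graph() -> Network:
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture()
def star_graph() -> Network:
    return Network.from_edges([("c", f"l{i}") for i in range(5)])


def random_graph(rng: np.random.Generator, n_max: int = 25):
    """A random Erdős–Rényi graph with string node labels."""
    import networkx as nx

    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


def planted_matrix(rng: np.random.Generator, n_per_group: int = 12,
                   n_vars: int = 50, n_planted: int = 5, effect_sd: float = 3.0):
    """Two-class matrix with ``n_planted`` variables shifted by
    ``effect_sd`` standard deviations in the second class."""
    n = 2 * n_per_group
    X = rng.normal(size=(n, n_vars))
    y = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    X[n_per_group:, :n_planted] += effect_sd
    # interleave so venetian-blind CV folds mix both classes
    order = np.argsort(np.tile(np.arange(n_per_group), 2), kind="stable")
    return X[order], y[order]
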