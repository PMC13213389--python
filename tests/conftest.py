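import numpy as np
import pytest
import scipy.sparse as sp

from bodycomp import default_cohort_spec, generate_cohort
from bodycomp.graph import SimilarityGraph


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """One study-sized synthetic cohort (245 male + 270 female), fixed seed."""
    return generate_cohort(default_spec, seed=1)


@pytest.fixture(scope="session")
def make_path_graph():
    """Factory: chain graph v0-v1-...-v(n-1) with given (unit) edge weights."""

    def _make(n, weight=1.0):
        rows, cols, vals = [], [], []
        for i in range(n - 1):
            rows += [i, i + 1]
            cols += [i + 1, i]
            vals += [weight, weight]
        W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return SimilarityGraph(W, k=1, epsilon=1.0)

    return _make


@pytest.fixture(scope="session")
def make_random_instance():
    """Factory: random connected-enough k-NN graph with random labels.

    Returns (graph, labeled indices, label values); retries the point draw
    until every component holds a label so Dirichlet problems are well posed.
    """
    from bodycomp.graph import build_knn_graph, connected_components

    def _make(rng, n=30, dim=3, k=4, n_labels=5):
        for _ in range(50):
            X = rng.standard_normal((n, dim))
            g = build_knn_graph(X, k=k)
            lab = rng.choice(n, size=n_labels, replace=False)
            labeled = set(lab.tolist())
            if all(labeled & set(c.tolist()) for c in connected_components(g)):
                y = rng.standard_normal(n)
                return g, lab, y
        raise RuntimeError("could not draw a labelable instance")

    return _make
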