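import numpy as np
import pytest

from enzloc import ReactionNetwork, ReactionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_net(ids, edges, localized=None):
    """Small directed network straight from an edge list."""
    return ReactionNetwork.from_edges(list(ids), edges, localized)


def make_record(rid, subs, prods, reversible=False, genes=()):
    return ReactionRecord(rid, frozenset(subs), frozenset(prods),
                          reversible, frozenset(genes))


def random_digraph(n, p, rng):
    """Random simple directed adjacency (no self-edges) as int8 matrix."""
    M = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(M, 0)
    return M


def net_from_matrix(M, localized=None):
    ids = [f"N{i}" for i in range(M.shape[0])]
    n = M.shape[0]
    if localized is None:
        localized = np.zeros(n, dtype=bool)
    return ReactionNetwork(ids, M.astype(np.int8), np.asarray(localized, dtype=bool))
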