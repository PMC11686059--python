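"""Comparator global network measures.

Conventions for signed weights (the energy statistic is the only measure
that consumes signs directly): clustering and efficiency use absolute
weights; modularity is optimised on the positive-weight subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .core_energy import ConnectivityMatrix


@dataclass(frozen=True)
class GlobalMeasures:
    gcc: float
    ge: float
    gm: float


def global_clustering(m: ConnectivityMatrix) -> float:
    """Mean weighted clustering coefficient (geometric-mean variant).

    Weights are ``|w|`` rescaled to [0, 1] by the global maximum.  Per
    node, the triangle-intensity coefficient

        C_i = (1 / (k_i (k_i - 1))) * sum_{j,k} (w_ij w_jk w_ik)^(1/3)

    with binary degree ``k_i`` over nonzero edges; nodes with k_i < 2
    contribute 0.  An all-zero matrix yields 0 by convention.
    """
    a = np.abs(m.weights)
    mx = a.max()
    if mx == 0:
        return 0.0
    wc = np.cbrt(a / mx)
    k = (a > 0).sum(axis=1)
    tri = np.diag(wc @ wc @ wc)  # sum over ordered (j, k): counts each pair twice
    denom = k * (k - 1)
    ci = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(ci.mean())


def global_efficiency(m: ConnectivityMatrix) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Edge lengths are ``1 / |w|``; zero-weight edges are absent and
    disconnected pairs contribute 0.
    """
    a = np.abs(m.weights)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    lengths = np.zeros_like(a)
    nz = a > 0
    lengths[nz] = 1.0 / a[nz]
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_modularity(m: ConnectivityMatrix, seed: int = 0) -> float:
    """Newman modularity Q of the best seeded Louvain partition.

    Optimised on the positive-weight subgraph; 0 by convention when no
    positive edges exist.  Deterministic given the seed.
    """
    w = m.weights
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    pos = w[iu, ju] > 0
    g.add_weighted_edges_from(
        zip(iu[pos].tolist(), ju[pos].tolist(), w[iu, ju][pos].tolist())
    )
    if g.number_of_edges() == 0:
        return 0.0
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    return float(nx.community.modularity(g, communities, weight="weight"))


def all_measures(m: ConnectivityMatrix, seed: int = 0) -> GlobalMeasures:
    return GlobalMeasures(
        gcc=global_clustering(m),
        ge=global_efficiency(m),
        gm=global_modularity(m, seed=seed),
    )
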