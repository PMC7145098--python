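"""Homophilous peer network among women.

Women preferentially connect with women of the same race/ethnicity.  The
network is a random graph with approximately Poisson degrees in which each
edge endpoint attaches within the anchor woman's ethnic group with
probability ``homophily`` and across groups otherwise.  By default the
network is inert (the intent model's ``peer_weight`` is 0); peer influence
is an opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PeerNetwork", "build_network", "peer_intent_fraction",
           "peer_intent_fractions"]


@dataclass
class PeerNetwork:
    """An undirected peer network over agent ids."""

    graph: nx.Graph
    mean_degree: float
    homophily: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def same_group_edge_fraction(self, groups: pd.Series) -> float:
        """Realized fraction of edges joining women of the same ethnicity."""
        g = groups.to_dict()
        edges = self.graph.edges()
        if not edges:
            return float("nan")
        same = sum(1 for u, v in edges if g[u] == g[v])
        return same / self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.graph.edges()), columns=["id_a", "id_b"])


def build_network(cohort: pd.DataFrame, mean_degree: float = 8.0,
                  homophily: float = 0.9,
                  seed: int | np.random.SeedSequence = 0) -> PeerNetwork:
    """Build the homophilous peer network.

    ``round(n * mean_degree / 2)`` distinct edges are placed.  For each
    edge one endpoint is drawn uniformly; the second is drawn from the same
    ethnic group with probability ``homophily`` and from the other group
    otherwise.  If the required group is too small to supply a partner the
    draw falls back to cross-group attachment (counted and logged).
    """
    if mean_degree < 0:
        raise ValueError("mean_degree must be nonnegative")
    if not 0.0 <= homophily <= 1.0:
        raise ValueError("homophily must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = cohort["id"].to_numpy()
    groups = cohort["ethnicity"].to_numpy()
    n = len(ids)
    graph = nx.Graph()
    graph.add_nodes_from(ids.tolist())
    target_edges = int(round(n * mean_degree / 2.0))

    by_group = {g: ids[groups == g] for g in np.unique(groups)}
    group_of = dict(zip(ids.tolist(), groups.tolist()))

    edges: set[tuple] = set()
    fallbacks = 0
    max_tries = 50 * max(target_edges, 1)
    tries = 0
    while len(edges) < target_edges and tries < max_tries:
        tries += 1
        u = ids[rng.integers(n)]
        want_same = rng.random() < homophily
        gu = group_of[u]
        if want_same:
            pool = by_group[gu]
            if len(pool) < 2:  # nobody else in the group
                fallbacks += 1
                pool = ids
        else:
            others = [p for g, p in by_group.items() if g != gu]
            pool = np.concatenate(others) if others else ids
            if len(others) == 0:
                fallbacks += 1
        v = pool[rng.integers(len(pool))]
        if u == v:
            continue
        e = (u, v) if u < v else (v, u)
        if e in edges:
            continue
        edges.add(e)
    if fallbacks:
        logger.warning("build_network: %d within-group draws fell back to "
                       "unrestricted attachment", fallbacks)
    if len(edges) < target_edges:
        logger.warning("build_network: placed %d of %d requested edges",
                       len(edges), target_edges)
    graph.add_edges_from(edges)
    return PeerNetwork(graph=graph, mean_degree=mean_degree,
                       homophily=homophily)


def peer_intent_fraction(network: PeerNetwork, woman_id,
                         intents: pd.Series) -> float:
    """Fraction of a woman's network neighbors who intend to breastfeed.

    An isolated woman falls back to the population intent fraction.
    """
    if woman_id not in network.graph:
        raise KeyError(f"unknown agent id {woman_id!r}")
    neighbors = list(network.graph.neighbors(woman_id))
    if not neighbors:
        return float(np.mean(np.asarray(intents, float)))
    vals = intents.loc[neighbors] if isinstance(intents, pd.Series) else \
        np.asarray(intents)[neighbors]
    return float(np.mean(np.asarray(vals, float)))


def peer_intent_fractions(network: PeerNetwork, ids: np.ndarray,
                          intents: np.ndarray) -> np.ndarray:
    """Vectorized :func:`peer_intent_fraction` over a whole cohort.

    ``intents`` is indexed positionally in the order of ``ids``.
    """
    pos = {i: k for k, i in enumerate(ids.tolist())}
    pop_mean = float(np.mean(intents))
    out = np.full(len(ids), pop_mean)
    sums = np.zeros(len(ids))
    degs = np.zeros(len(ids))
    for u, v in network.graph.edges():
        pu, pv = pos[u], pos[v]
        sums[pu] += intents[pv]
        sums[pv] += intents[pu]
        degs[pu] += 1
        degs[pv] += 1
    nz = degs > 0
    out[nz] = sums[nz] / degs[nz]
    return out
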