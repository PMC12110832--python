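"""Personalized PageRank over the co-expression graph, seeded at ICP genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .io_formats import LNCRNA

logger = logging.getLogger(__name__)


@dataclass
class PropagationResult:
    """Influence scores from one propagation run.

    ``scores`` sums to 1 over the graph's nodes and every entry is
    non-negative.
    """

    scores: dict[str, float]
    converged: bool
    iterations: int


def personalized_pagerank(
    graph: nx.Graph,
    seeds: Iterable[str],
    damping: float = 0.85,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PropagationResult:
    """Power iteration with teleportation restricted to the seed nodes.

    Each undirected edge contributes both directions to the row-normalized
    weighted transition matrix.  The personalization vector is uniform over
    the seeds present in the graph and zero elsewhere; dangling nodes teleport
    to it.  Iteration stops when the L1 change drops below ``tol``; if that
    does not happen within ``max_iter`` steps the last iterate is returned
    with ``converged=False``.
    """
    nodes = sorted(graph.nodes)  # deterministic, insertion-order independent
    if not nodes:
        raise ConfigurationError("graph is empty")
    seed_set = set(seeds) & set(nodes)
    if not seed_set:
        raise ConfigurationError("no seed node present in the graph")
    if not 0.0 <= damping < 1.0:
        raise ConfigurationError(f"damping must be in [0, 1), got {damping}")
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}

    weights = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0.0:
            raise ConfigurationError(f"non-positive edge weight on ({a}, {b}): {w}")
        i, j = index[a], index[b]
        weights[i, j] += w
        weights[j, i] += w

    out_strength = weights.sum(axis=1)
    dangling = out_strength == 0.0
    transition = np.zeros_like(weights)
    nz = ~dangling
    transition[nz] = weights[nz] / out_strength[nz, None]

    v = np.zeros(n)
    for s in seed_set:
        v[index[s]] = 1.0 / len(seed_set)

    x = v.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dangling_mass = x[dangling].sum()
        x_new = damping * (x @ transition + dangling_mass * v) + (1.0 - damping) * v
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        logger.warning("propagation did not converge within %d iterations", max_iter)
    x = x / x.sum()  # guard against float drift; mass is conserved analytically
    return PropagationResult(
        scores={node: float(x[index[node]]) for node in nodes},
        converged=converged,
        iterations=iterations,
    )


def top_k_lncrnas(result: PropagationResult, graph: nx.Graph, k: int = 200) -> list[str]:
    """The ``k`` highest-scoring lncRNA nodes, ties broken by id.

    Returns all lncRNAs when fewer than ``k`` exist; an empty list (with a
    warning) when the graph holds no lncRNA nodes.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    lncs = [node for node, data in graph.nodes(data=True) if data.get("cls") == LNCRNA]
    if not lncs:
        logger.warning("graph contains no lncRNA nodes")
        return []
    lncs.sort(key=lambda node: (-result.scores.get(node, 0.0), node))
    return lncs[: min(k, len(lncs))]
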