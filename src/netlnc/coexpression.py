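"""Co-expression network construction anchored on immune-checkpoint genes.

Pearson correlations are computed for candidate pairs drawn from a caller
supplied interaction list, p-values are Benjamini-Hochberg adjusted, and
pairs passing ``p_adj < alpha`` (optionally with an absolute-correlation
floor) become weighted edges.  Edge weights are ``|r|`` so the downstream
propagation operates on non-negative weights; the sign of r is kept as an
edge attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError
from .io_formats import GENE, LNCRNA, EdgeList, ExpressionMatrix

logger = logging.getLogger(__name__)

#: Floor applied to underflowed p-values before any log transform downstream.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class CorrelationRecord:
    feature_a: str
    feature_b: str
    r: float
    p: float
    p_adj: float
    n_obs: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Missing entries are removed pairwise; ``n_obs`` is the number of jointly
    observed pairs.  The p-value comes from
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom and
    is floored at 1e-300.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 complete pairs.
    DegenerateDataError
        Either vector has zero variance over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {n}")
    xv = x[mask]
    yv = y[mask]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("zero variance in one of the vectors")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    p = _pearson_p(r, n)
    return r, p, n


def _pearson_p(r: float, n: int, df_offset: int = 2) -> float:
    """Two-sided p for a (partial) correlation via the t transform."""
    df = n - df_offset
    if abs(r) >= 1.0:
        return P_FLOOR
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(1.0, max(P_FLOOR, p)))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Returns an array in the original input order; empty input yields an
    empty array.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _candidate_pairs(
    expr: ExpressionMatrix, icp_genes: frozenset[str], interactions: EdgeList
) -> list[tuple[str, str]]:
    """Unique testable pairs: lncRNA-gene rows plus gene-gene rows touching an ICP."""
    cls = expr.feature_class
    present = set(expr.feature_ids)
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for a, b in interactions.pairs():
        if a not in present or b not in present:
            continue
        ca, cb = cls[a], cls[b]
        keep = False
        if {ca, cb} == {LNCRNA, GENE}:
            keep = True
        elif ca == GENE and cb == GENE and (a in icp_genes or b in icp_genes):
            keep = True
        if not keep:
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    return pairs


def correlate_pairs(
    expr: ExpressionMatrix, pairs: list[tuple[str, str]]
) -> list[CorrelationRecord]:
    """Pearson + BH over an explicit pair list; degenerate pairs are skipped."""
    raw: list[tuple[str, str, float, float, int]] = []
    for a, b in pairs:
        try:
            r, p, n = pearson_with_p(expr.vector(a), expr.vector(b))
        except (InsufficientDataError, DegenerateDataError) as exc:
            logger.warning("skipping pair (%s, %s): %s", a, b, exc)
            continue
        raw.append((a, b, r, p, n))
    if not raw:
        return []
    p_adj = bh_adjust([row[3] for row in raw])
    return [
        CorrelationRecord(a, b, r, p, float(pa), n)
        for (a, b, r, p, n), pa in zip(raw, p_adj)
    ]


def build_network(
    expr: ExpressionMatrix,
    icp_genes: Iterable[str],
    interactions: EdgeList,
    alpha: float = 0.05,
    min_abs_r: float = 0.0,
) -> nx.Graph:
    """Assemble the weighted lncRNA-gene co-expression graph.

    Candidate pairs come from ``interactions`` restricted to features present
    in ``expr``: lncRNA-gene rows and gene-gene rows involving at least one
    ICP gene.  An edge is kept when its BH-adjusted p-value is below ``alpha``
    and ``|r| >= min_abs_r``; its weight is ``|r|`` and the sign of r is
    stored in the ``sign`` attribute.  Nodes carry ``cls`` (lncRNA/gene) and
    ``is_icp`` attributes; only endpoints of surviving edges appear.
    """
    icp = frozenset(icp_genes)
    present_icp = {g for g in icp if g in set(expr.gene_ids)}
    if not present_icp:
        raise ConfigurationError("no ICP gene present among the expression gene features")
    graph = nx.Graph()
    if len(interactions) == 0:
        logger.warning("interaction list is empty: returning an empty graph")
        return graph
    pairs = _candidate_pairs(expr, icp, interactions)
    records = correlate_pairs(expr, pairs)
    cls = expr.feature_class
    n_edges = 0
    for rec in records:
        if rec.p_adj >= alpha or abs(rec.r) < min_abs_r or rec.r == 0.0:
            continue
        for node in (rec.feature_a, rec.feature_b):
            if node not in graph:
                graph.add_node(node, cls=cls[node], is_icp=node in icp and cls[node] == GENE)
        graph.add_edge(
            rec.feature_a,
            rec.feature_b,
            weight=abs(rec.r),
            sign=1 if rec.r > 0 else -1,
            r=rec.r,
            p=rec.p,
            p_adj=rec.p_adj,
        )
        n_edges += 1
    logger.info("co-expression network: %d nodes, %d edges (tested %d pairs)",
                graph.number_of_nodes(), n_edges, len(records))
    return graph


def write_network(graph: nx.Graph, edges_path, nodes_path) -> None:
    """Serialize a network as the standard edge + node TSV pair."""
    from .io_formats import write_table

    edge_rows = [
        {
            "node_a": min(a, b),
            "node_b": max(a, b),
            "r": data.get("r", float("nan")),
            "p": data.get("p", float("nan")),
            "p_adj": data.get("p_adj", float("nan")),
            "weight": data["weight"],
        }
        for a, b, data in graph.edges(data=True)
    ]
    node_rows = [
        {"id": node, "class": data["cls"], "is_icp": bool(data.get("is_icp", False))}
        for node, data in graph.nodes(data=True)
    ]
    write_table(edge_rows, edges_path,
                columns=["node_a", "node_b", "r", "p", "p_adj", "weight"])
    write_table(node_rows, nodes_path, columns=["id", "class", "is_icp"])


def read_network(edges_path, nodes_path) -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    from .io_formats import read_records

    graph = nx.Graph()
    for row in read_records(nodes_path, {"id": str, "class": str, "is_icp": bool}):
        graph.add_node(row["id"], cls=row["class"], is_icp=row["is_icp"])
    schema = {"node_a": str, "node_b": str, "r": float, "p": float,
              "p_adj": float, "weight": float}
    for row in read_records(edges_path, schema):
        graph.add_edge(row["node_a"], row["node_b"], weight=row["weight"],
                       r=row["r"], p=row["p"], p_adj=row["p_adj"])
    return graph
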