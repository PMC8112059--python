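"""DeltaCon comparison of condition-specific co-accessibility graphs.

Two graphs on a shared node ordering are compared through their node
affinity matrices

    S = (I + eps^2 D - eps A)^(-1),      eps = 1 / (1 + max_i d_ii),

with A the 0/1 adjacency, D the diagonal degree matrix, and eps computed
once from the maximum degree across *both* graphs so the two S matrices
are on the same scale. The distance is the root Euclidean distance

    d = sqrt( sum_ij (sqrt(s1_ij) - sqrt(s2_ij))^2 ),

and the per-node impact of the perturbation is the same distance
restricted to the node's affinity row, for nodes with at least one
altered incident edge; all other nodes score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from arena.starr import bh_adjust


def build_coaccess_graph(
    scored_edges: pd.DataFrame,
    node_table: pd.DataFrame,
    threshold: float = 0.1,
) -> nx.Graph:
    """Threshold a scored pair list (score strictly > threshold) into a graph.

    Nodes come from ``node_table`` (columns ``node_id, node_class``) so
    isolated CREs stay in the graph; an edge naming an unknown node is an
    error.
    """
    g = nx.Graph()
    for rec in node_table.itertuples(index=False):
        g.add_node(rec.node_id, node_class=rec.node_class)
    known = set(node_table["node_id"])
    kept = scored_edges[scored_edges["score"] > threshold]
    for rec in kept.itertuples(index=False):
        for endpoint in (rec.region_a, rec.region_b):
            if endpoint not in known:
                raise ValueError(f"edge references unknown node {endpoint!r}")
        g.add_edge(rec.region_a, rec.region_b)
    return g


@dataclass(frozen=True)
class AffinityMatrix:
    node_order: tuple
    S: np.ndarray
    epsilon: float


def _adjacency(graph: nx.Graph, node_order: list) -> np.ndarray:
    index = {n: i for i, n in enumerate(node_order)}
    a = np.zeros((len(node_order), len(node_order)))
    for u, v in graph.edges():
        i, j = index[u], index[v]
        a[i, j] = 1.0
        a[j, i] = 1.0
    return a


def affinity_matrix(
    graph: nx.Graph,
    node_order: list,
    epsilon: float | None = None,
) -> AffinityMatrix:
    """Fast-belief-propagation affinity matrix of a graph on a node order.

    Nodes in ``node_order`` absent from the graph contribute zero
    rows/columns of A (their affinity row is the identity row). Pass
    ``epsilon`` explicitly to share it across the two graphs of a
    comparison; by default it is 1/(1 + max degree) of this graph.
    """
    missing = set(graph.nodes()) - set(node_order)
    if missing:
        raise ValueError(f"node_order does not cover graph nodes: {sorted(missing)[:3]}")
    a = _adjacency(graph, node_order)
    deg = a.sum(axis=1)
    if epsilon is None:
        epsilon = 1.0 / (1.0 + (deg.max() if len(deg) else 0.0))
    m = np.eye(len(node_order)) + epsilon**2 * np.diag(deg) - epsilon * a
    # m is strictly diagonally dominant for eps < 1/max_deg; fail loudly
    # rather than silently regularising if that ever breaks
    try:
        s = np.linalg.solve(m, np.eye(len(node_order)))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"affinity system singular (epsilon={epsilon})") from err
    return AffinityMatrix(tuple(node_order), s, float(epsilon))


def shared_epsilon(g1: nx.Graph, g2: nx.Graph) -> float:
    """eps = 1/(1 + max degree) over both graphs of a comparison."""
    degs = [d for _, d in g1.degree()] + [d for _, d in g2.degree()]
    return 1.0 / (1.0 + (max(degs) if degs else 0.0))


def _sqrt_clipped(s: np.ndarray) -> np.ndarray:
    if (s < 0).any():
        warnings.warn("negative affinities clipped to 0 before sqrt")
        s = np.clip(s, 0.0, None)
    return np.sqrt(s)


def rooted_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Root Euclidean distance between two affinity matrices (or rows)."""
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    s2 = np.atleast_2d(np.asarray(s2, dtype=float))
    if s1.shape != s2.shape:
        raise ValueError(f"shape mismatch: {s1.shape} vs {s2.shape}")
    diff = _sqrt_clipped(s1) - _sqrt_clipped(s2)
    return float(np.sqrt(np.sum(diff * diff)))


def _altered_nodes(g1: nx.Graph, g2: nx.Graph) -> set:
    """Nodes whose incident edge set differs between the two graphs."""
    e1 = {frozenset((u, v)) for u, v in g1.edges()}
    e2 = {frozenset((u, v)) for u, v in g2.edges()}
    altered = set()
    for edge in e1 ^ e2:
        altered.update(edge)
    return altered


@dataclass(frozen=True)
class DeltaConResult:
    distance: float
    impact: pd.Series
    epsilon: float
    n_nodes: int


def node_impact(
    g1: nx.Graph,
    g2: nx.Graph,
    node_order: list,
    affinities: tuple[AffinityMatrix, AffinityMatrix] | None = None,
) -> pd.Series:
    """Per-node impact w of the perturbation g1 -> g2.

    For a node with at least one incident edge altered between the
    graphs, w is the root Euclidean distance between its affinity rows;
    otherwise w = 0 exactly.
    """
    if affinities is None:
        eps = shared_epsilon(g1, g2)
        affinities = (affinity_matrix(g1, node_order, eps),
                      affinity_matrix(g2, node_order, eps))
    s1, s2 = affinities[0].S, affinities[1].S
    altered = _altered_nodes(g1, g2)
    w = np.zeros(len(node_order))
    for i, node in enumerate(node_order):
        if node in altered:
            w[i] = rooted_distance(s1[i], s2[i])
    return pd.Series(w, index=pd.Index(node_order, name="node_id"), name="impact")


def compare_graphs(g1: nx.Graph, g2: nx.Graph, node_order: list) -> DeltaConResult:
    """Full DeltaCon comparison: shared-epsilon affinities, d, and impacts."""
    eps = shared_epsilon(g1, g2)
    aff1 = affinity_matrix(g1, node_order, eps)
    aff2 = affinity_matrix(g2, node_order, eps)
    d = rooted_distance(aff1.S, aff2.S)
    w = node_impact(g1, g2, node_order, affinities=(aff1, aff2))
    return DeltaConResult(distance=d, impact=w, epsilon=eps,
                          n_nodes=len(node_order))


def class_impact_summary(
    impact: pd.Series,
    calls: pd.Series,
    classes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class impact distributions + pairwise rank-sum tests (BH).

    Classes with < 2 scored nodes are skipped with a warning. Degenerate
    comparisons (all values tied, e.g. every impact 0) report p = 1.
    """
    calls = calls.reindex(impact.index)
    df = pd.DataFrame({"impact": impact, "node_class": calls}).dropna()
    if classes is None:
        classes = sorted(df["node_class"].unique())
    summary = (df.groupby("node_class")["impact"]
               .agg(["count", "median", "mean"]).reindex(classes))
    tests = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            xa = df.loc[df["node_class"] == a, "impact"]
            xb = df.loc[df["node_class"] == b, "impact"]
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"skipping {a} vs {b}: class with < 2 nodes")
                continue
            if xa.nunique() == 1 and xb.nunique() == 1 and xa.iloc[0] == xb.iloc[0]:
                p = 1.0
            else:
                _, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            tests.append({"class_a": a, "class_b": b,
                          "median_a": float(xa.median()),
                          "median_b": float(xb.median()), "p": float(p)})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        tests_df["fdr"] = bh_adjust(tests_df["p"].to_numpy())
    return summary, tests_df
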