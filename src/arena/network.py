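"""Loop-derived cis-regulatory-element (CRE) graphs and interaction statistics.

Nodes are typed CREs — enhancer classes from the STARR-seq calling,
up/down differentially-expressed-gene TSSs, and untested AR binding
sites — and edges are chromatin loops (or thresholded co-accessibility
links). The class-level statistics are

* relative density           D = 2 E_obs / (V (V + 1)),
* expected maximum edges     E_max = V (V + 1) / 2   (same class,
  combinations with repetition so self-loops count),
* expected maximum edges     E_max = V x U           (two classes),
* interaction frequency      IF = E_obs / (D x E_max),

with D always taken from the whole graph. Centrality is computed on the
largest connected component only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from arena.starr import bh_adjust

TSS_WINDOW = 5000
DEG_NODE_CLASS = {"up": "TSS_up", "down": "TSS_down"}


def tss_node_table(tss_table: pd.DataFrame) -> pd.DataFrame:
    """Node ids/classes for DEG TSSs (direction 'none' genes are dropped)."""
    deg = tss_table[tss_table["direction"].isin(DEG_NODE_CLASS)].copy()
    deg["node_id"] = "TSS:" + deg["gene"].astype(str)
    deg["node_class"] = deg["direction"].map(DEG_NODE_CLASS)
    return deg[["node_id", "node_class", "chrom", "tss_pos"]]


def _interval_tree(starts, ends, labels) -> IntervalTree:
    tree = IntervalTree()
    for s, e, lab in zip(starts, ends, labels):
        if e > s:
            tree.addi(int(s), int(e), lab)
    return tree


def anchor_overlap(
    interactions: pd.DataFrame,
    regions: pd.DataFrame,
    tss_table: pd.DataFrame,
    window: int = TSS_WINDOW,
) -> pd.DataFrame:
    """Map loop anchors to region / DEG-TSS node labels and emit edges.

    Each anchor is labelled with every region interval it intersects and
    every DEG TSS whose +/- ``window`` interval it intersects (0-based
    half-open arithmetic). One edge is emitted per labelled pair per
    loop; loops with an unlabelled end emit nothing. Output columns:
    ``node_a, node_b, pair_id``.
    """
    required = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]
    bad = interactions.index[interactions[required].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed BEDPE row at line {bad[0] + 1}")

    tree = _interval_tree(regions["start"], regions["end"], regions["region_id"])
    deg = tss_node_table(tss_table)
    for _, row in deg.iterrows():
        lo = max(0, int(row["tss_pos"]) - window)
        hi = int(row["tss_pos"]) + window
        tree.addi(lo, hi, row["node_id"])

    def labels(start: int, end: int) -> list[str]:
        return sorted(iv.data for iv in tree.overlap(int(start), int(end)))

    rows = []
    for rec in interactions.itertuples(index=False):
        la = labels(rec.start_a, rec.end_a)
        lb = labels(rec.start_b, rec.end_b)
        pid = getattr(rec, "pair_id", None)
        for a in la:
            for b in lb:
                u, v = sorted((a, b))
                rows.append((u, v, pid))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "pair_id"])


def build_graph(edges: pd.DataFrame, node_table: pd.DataFrame) -> nx.Graph:
    """Deduplicated undirected graph with ``node_class`` attributes.

    ``node_table`` needs columns ``node_id`` and ``node_class``; every
    edge endpoint must appear there. Self-edges are retained.
    """
    g = nx.Graph()
    for rec in node_table.itertuples(index=False):
        g.add_node(rec.node_id, node_class=rec.node_class)
    known = set(node_table["node_id"])
    for rec in edges.itertuples(index=False):
        for endpoint in (rec.node_a, rec.node_b):
            if endpoint not in known:
                raise ValueError(f"edge references unknown node {endpoint!r}")
        g.add_edge(rec.node_a, rec.node_b)
    return g


def graph_density(e_obs: int, v: int) -> float:
    """Relative density D = 2 E_obs / (V (V + 1)); self-pairs allowed."""
    if v < 1:
        raise ValueError("V must be >= 1")
    return 2.0 * e_obs / (v * (v + 1))


def expected_max_edges(v: int, u: int | None = None, same_class: bool = False) -> int:
    """Maximum possible edges: V(V+1)/2 within a class, V x U across two."""
    if same_class:
        return v * (v + 1) // 2
    if u is None:
        raise ValueError("cross-class E_max needs both class sizes")
    return v * u


@dataclass(frozen=True)
class NetworkClassStats:
    class_u: str
    class_v: str
    n_u: int
    n_v: int
    e_obs: int
    density_whole: float
    e_max: int
    interaction_frequency: float


def _class_nodes(g: nx.Graph, cls: str) -> set:
    return {n for n, d in g.nodes(data=True) if d.get("node_class") == cls}


def count_class_edges(g: nx.Graph, class_u: str, class_v: str) -> int:
    """Edges with one endpoint in each class (self-edges count once)."""
    nu = _class_nodes(g, class_u)
    nv = _class_nodes(g, class_v)
    count = 0
    for a, b in g.edges():
        if (a in nu and b in nv) or (a in nv and b in nu):
            count += 1
    return count


def interaction_frequency(g: nx.Graph, class_u: str, class_v: str) -> NetworkClassStats:
    """Observed-over-expected edge frequency between two node classes.

    IF = E_obs / (D x E_max) with D the whole-graph relative density and
    E_max the same-class or cross-class maximum. A graph with D = 0
    yields IF = NaN (flagged, not an error).
    """
    nu = _class_nodes(g, class_u)
    nv = _class_nodes(g, class_v)
    if not nu or not nv:
        raise ValueError(f"class {class_u if not nu else class_v!r} absent from graph")
    d_whole = graph_density(g.number_of_edges(), g.number_of_nodes())
    same = class_u == class_v
    e_max = expected_max_edges(len(nu), len(nv), same_class=same)
    e_obs = count_class_edges(g, class_u, class_v)
    if d_whole == 0:
        if_score = float("nan")
    else:
        if_score = e_obs / (d_whole * e_max)
    return NetworkClassStats(class_u, class_v, len(nu), len(nv), e_obs,
                             d_whole, e_max, if_score)


@dataclass(frozen=True)
class CentralityReport:
    degree: dict
    betweenness: dict
    component_nodes: frozenset


def centrality(g: nx.Graph) -> CentralityReport:
    """Degree and betweenness centrality on the largest connected component.

    Component size ties break on the smallest lexicographic node id.
    Betweenness uses the standard 2/((n-1)(n-2)) normalisation.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = sorted(nx.connected_components(g),
                        key=lambda c: (-len(c), min(str(n) for n in c)))
    comp = components[0]
    sub = g.subgraph(comp)
    return CentralityReport(
        degree=dict(nx.degree_centrality(sub)),
        betweenness=dict(nx.betweenness_centrality(sub, normalized=True)),
        component_nodes=frozenset(comp),
    )


def loop_count_by_class(g: nx.Graph, classes: list[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node loop counts grouped by class + pairwise rank-sum tests.

    Returns ``(degrees, tests)``. Degrees use graph degree, which counts
    a self-loop twice (handshake convention). Class pairs where either
    side has < 2 nodes are skipped with a warning.
    """
    rows = [(n, d.get("node_class"), g.degree(n)) for n, d in g.nodes(data=True)]
    degrees = pd.DataFrame(rows, columns=["node_id", "node_class", "degree"])
    if classes is None:
        classes = sorted(degrees["node_class"].dropna().unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to compare loop counts")
    tests = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            xa = degrees.loc[degrees["node_class"] == a, "degree"]
            xb = degrees.loc[degrees["node_class"] == b, "degree"]
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"skipping {a} vs {b}: class with < 2 nodes")
                continue
            _, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            tests.append({"class_a": a, "class_b": b,
                          "mean_degree_a": float(xa.mean()),
                          "mean_degree_b": float(xb.mean()), "p": float(p)})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        tests_df["fdr"] = bh_adjust(tests_df["p"].to_numpy())
    return degrees, tests_df


def distance_ecdf(
    regions: pd.DataFrame,
    promoters: pd.DataFrame,
    bin_size: int = 100,
    class_col: str = "enhancer_class",
) -> dict[str, pd.DataFrame]:
    """Binned ECDF of region-to-nearest-promoter distance per class.

    Distance is 0 for a promoter position inside the half-open region
    interval, otherwise the absolute gap; distances are floored to
    ``bin_size`` bins. Returns, per class, a table of ``bin`` and
    nondecreasing ``ecdf`` reaching 1. Empty classes are skipped.
    """
    if len(promoters) == 0:
        raise ValueError("no promoters supplied")
    pos = np.sort(promoters["tss_pos"].to_numpy())
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    idx = np.searchsorted(pos, (starts + ends) // 2)
    dist = np.full(len(regions), np.inf)
    for shift in (-1, 0, 1):
        j = np.clip(idx + shift, 0, len(pos) - 1)
        t = pos[j]
        d = np.where((t >= starts) & (t < ends), 0,
                     np.where(t < starts, starts - t, t - (ends - 1)))
        dist = np.minimum(dist, d)
    bins = (dist // bin_size).astype(int) * bin_size

    out: dict[str, pd.DataFrame] = {}
    for cls, grp in pd.Series(bins, index=regions.index).groupby(
            regions[class_col]):
        if len(grp) == 0:
            continue
        vals = np.sort(grp.to_numpy())
        uniq, counts = np.unique(vals, return_counts=True)
        out[cls] = pd.DataFrame({"bin": uniq,
                                 "ecdf": np.cumsum(counts) / len(vals)})
    return out
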