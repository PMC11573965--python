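"""Sample-similarity graph: Spearman correlation between feature-table rows.

Each feature-table row (one tumor mesh, ten feature values) becomes a node;
an undirected weighted edge links two nodes whenever the Spearman rank
correlation across their ten feature values is at or above a threshold
(default 0.7). The ranks are taken across the ten heterogeneous features
within each row, so the correlation measures whether two meshes order their
features the same way — a profile similarity, invariant to per-row monotone
rescaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)


@dataclass
class SampleGraph:
    """Undirected weighted graph over feature-table rows.

    ``node_ids`` are the unique_id values (order defines node index);
    ``edges`` is (E, 2) int with node *indices* (src < dst in unique_id
    lexicographic order); ``weights`` the Spearman correlations.
    """

    node_ids: np.ndarray
    labels: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> pd.DataFrame:
        """Edge table with 1-based edge numbers and source/target unique_ids."""
        return pd.DataFrame({
            "edge_number": np.arange(1, self.n_edges + 1),
            "source_node": self.node_ids[self.edges[:, 0]],
            "target_node": self.node_ids[self.edges[:, 1]],
            "correlation": self.weights,
        })

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for nid, lab in zip(self.node_ids, self.labels):
            g.add_node(int(nid), label=str(lab))
        for (i, j), w in zip(self.edges, self.weights):
            g.add_edge(int(self.node_ids[i]), int(self.node_ids[j]), weight=float(w))
        return g


@dataclass
class GraphStats:
    n_nodes: int
    n_edges: int
    intra_benign: int
    intra_malignant: int
    inter_class: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "intra_benign": self.intra_benign,
            "intra_malignant": self.intra_malignant,
            "inter_class": self.inter_class,
        }


def spearman(x, y) -> float:
    """Spearman rank correlation of two equal-length value vectors.

    Pearson correlation of average-tie ranks; NaN if either vector is
    constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _row_spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations between the rows of X (n, p)."""
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def build_graph(
    table: pd.DataFrame,
    threshold: float = 0.7,
    features: list[str] | None = None,
    standardize: bool = False,
) -> SampleGraph:
    """Threshold the row-wise Spearman matrix into an undirected graph.

    An edge joins rows i < j (by unique_id) when their correlation is at or
    above ``threshold`` (inclusive); ``threshold = -1`` connects every pair
    with a defined correlation. Rows whose feature vector is constant have
    undefined correlations and contribute no edges. ``standardize`` optionally
    z-scores feature columns first (rank patterns then compare deviations).
    """
    features = features or FEATURE_NAMES
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    ids = table["unique_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("unique_id values must be distinct")
    order = np.argsort(ids, kind="stable")
    table = table.iloc[order]
    ids = ids[order]
    labels = table["target"].to_numpy()
    X = table[features].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    corr = _row_spearman_matrix(X)
    iu, ju = np.triu_indices(len(ids), k=1)
    w = corr[iu, ju]
    keep = ~np.isnan(w) & (w >= threshold)
    n_undef = int(np.isnan(w).sum())
    if n_undef:
        log.warning("%d row pairs with undefined correlation got no edge", n_undef)
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return SampleGraph(
        node_ids=ids, labels=labels, edges=edges,
        weights=w[keep].astype(float), threshold=threshold,
    )


def graph_stats(graph: SampleGraph) -> GraphStats:
    """Partition the edge count into intra-benign / intra-malignant / inter-class."""
    a = graph.labels[graph.edges[:, 0]] if graph.n_edges else np.array([])
    b = graph.labels[graph.edges[:, 1]] if graph.n_edges else np.array([])
    intra_b = int(np.sum((a == "benign") & (b == "benign")))
    intra_m = int(np.sum((a == "malignant") & (b == "malignant")))
    return GraphStats(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        intra_benign=intra_b,
        intra_malignant=intra_m,
        inter_class=graph.n_edges - intra_b - intra_m,
    )


def write_edge_list(graph: SampleGraph, path) -> None:
    """Edge-list CSV (edge_number, source_node, target_node, correlation).

    Correlations are rounded to 2 decimals on export; full precision stays in
    the in-memory graph.
    """
    df = graph.edge_list()
    df["correlation"] = df["correlation"].round(2)
    df.to_csv(path, index=False)


def write_graph_stats(stats: GraphStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.as_dict(), fh, indent=2)


def threshold_sweep(
    table: pd.DataFrame,
    thresholds=(-1, 0.5, 0.6, 0.7, 0.8, 0.9),
    gat_config=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Edge count (and optional classifier test accuracy) per threshold.

    ``-1`` encodes "no threshold" (all defined-correlation pairs connected).
    Edge counts are non-increasing in the threshold. When ``gat_config`` is
    given, a GAT is trained per threshold with a fixed seed and split.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for th in thresholds:
        g = build_graph(table, threshold=th)
        row = {"threshold": th, "n_edges": g.n_edges}
        if gat_config is not None:
            from .gat import train_gat

            _, report = train_gat(table, g, gat_config, seed=seed)
            row["test_accuracy"] = report.test_accuracy
        rows.append(row)
    return pd.DataFrame(rows)
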