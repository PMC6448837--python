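"""Binary single-layer and multilayer networks from MIC matrices.

An intra-layer edge joins two features of the same layer whose MIC
strictly exceeds the threshold tau; a cross-layer edge joins a miRNA and
a protein by the same rule. Isolated nodes are retained in the network
objects (they remain scoring entities), while scan tables report "active"
nodes (degree >= 1), whose count falls as tau rises.

The threshold scan supports the two selection principles used to pick a
working tau: (1) raising tau must not lose too many active nodes (default
cap 5% relative to the most permissive tau scanned), and (2) among the
remaining thresholds, the normal-vs-cancer edge-count difference (curve
Y1) should be as large as possible; curve Y2 tracks the smaller of the
two conditions' active-node counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mic import MICMatrix

__all__ = [
    "LayerNetwork",
    "MultilayerNetwork",
    "ThresholdScan",
    "threshold_graph",
    "build_multilayer",
    "threshold_scan",
    "recommend_threshold",
    "write_graphml",
    "edge_list",
]


@dataclass
class LayerNetwork:
    """One layer's node set and binary adjacency at a fixed MIC threshold."""

    layer: str
    condition: str
    nodes: list[str]
    adjacency: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    @property
    def n_active_nodes(self) -> int:
        return int((self.degrees() > 0).sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        idx = np.argwhere(np.triu(self.adjacency, 1))
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in idx)
        return g


@dataclass
class MultilayerNetwork:
    """Two intra-layer networks plus binary miRNA x protein cross adjacency."""

    mirna_layer: LayerNetwork
    protein_layer: LayerNetwork
    cross_adjacency: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cross_adjacency)
        expect = (len(self.mirna_layer.nodes), len(self.protein_layer.nodes))
        if c.shape != expect:
            raise ValueError(f"cross adjacency shape {c.shape}, expected {expect}")
        if self.mirna_layer.condition != self.protein_layer.condition:
            raise ValueError("both layers must describe the same condition")
        self.cross_adjacency = c.astype(np.int8)

    @property
    def condition(self) -> str:
        return self.mirna_layer.condition

    @property
    def n_cross_edges(self) -> int:
        return int(self.cross_adjacency.sum())


def threshold_graph(
    micm: MICMatrix, tau: float, layer: str = "", condition: str = ""
) -> LayerNetwork:
    """Binarize a square MIC matrix: edge iff MIC > tau (strict), i != j."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    if not micm.symmetric:
        raise ValueError("threshold_graph needs a square symmetric MIC matrix")
    adj = (micm.values > tau).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # guard against asymmetric float storage
    return LayerNetwork(layer, condition, list(micm.row_features), adj, tau)


def build_multilayer(
    mirna_net: LayerNetwork,
    protein_net: LayerNetwork,
    cross_mic: MICMatrix,
    tau: float | None = None,
) -> MultilayerNetwork:
    """Join two same-condition layers by thresholding their cross-layer MIC."""
    if tau is None:
        tau = mirna_net.threshold
    if cross_mic.row_features != mirna_net.nodes or cross_mic.col_features != protein_net.nodes:
        raise ValueError("cross-layer MIC matrix does not match the two node sets")
    cross = (cross_mic.values > tau).astype(np.int8)
    return MultilayerNetwork(mirna_net, protein_net, cross)


# ---------------------------------------------------------------------------
# threshold scan and selection principles
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Node/edge counts per (threshold, layer, condition), with Y1/Y2 curves.

    ``table`` has columns threshold, layer, condition, n_active_nodes,
    n_edges. ``curves`` has, per threshold and layer, Y1 = (normal edges -
    cancer edges) and Y2 = min(normal active nodes, cancer active nodes).
    """

    table: pd.DataFrame
    curves: pd.DataFrame

    @property
    def thresholds(self) -> list[float]:
        return sorted(self.table["threshold"].unique())


def threshold_scan(mics: dict, taus: list[float]) -> ThresholdScan:
    """Count active nodes and edges for every threshold.

    ``mics`` maps ``(layer, condition)`` to a square :class:`MICMatrix`,
    with condition one of "normal"/"tumor".
    """
    if not taus:
        raise ValueError("taus must not be empty")
    if any(t < 0 or t > 1 for t in taus):
        raise ValueError("every threshold must lie in [0, 1]")
    rows = []
    for tau in sorted(taus):
        for (layer, condition), micm in mics.items():
            net = threshold_graph(micm, tau, layer, condition)
            rows.append(
                {
                    "threshold": tau,
                    "layer": layer,
                    "condition": condition,
                    "n_active_nodes": net.n_active_nodes,
                    "n_edges": net.n_edges,
                }
            )
    table = pd.DataFrame(rows)
    curve_rows = []
    for tau in sorted(taus):
        sub = table[table["threshold"] == tau]
        for layer in sorted({l for l, _ in mics}):
            normal = sub[(sub["layer"] == layer) & (sub["condition"] == "normal")]
            cancer = sub[(sub["layer"] == layer) & (sub["condition"] == "tumor")]
            if normal.empty or cancer.empty:
                continue
            curve_rows.append(
                {
                    "threshold": tau,
                    "layer": layer,
                    "y1": int(normal["n_edges"].iloc[0] - cancer["n_edges"].iloc[0]),
                    "y2": int(min(normal["n_active_nodes"].iloc[0], cancer["n_active_nodes"].iloc[0])),
                }
            )
    return ThresholdScan(table, pd.DataFrame(curve_rows))


def recommend_threshold(scan: ThresholdScan, node_loss_cap: float = 0.05) -> float:
    """Pick the working threshold by the two selection principles.

    Feasible thresholds lose at most ``node_loss_cap`` of each network's
    active nodes relative to the smallest threshold scanned; among those,
    the threshold maximizing the total |Y1| (summed over layers) wins,
    with ties going to the smaller threshold. If no threshold satisfies
    the cap, the overall |Y1| argmax is returned with a warning.
    """
    taus = scan.thresholds
    if len(taus) < 3:
        raise ValueError("threshold scan must cover at least 3 thresholds")
    base = scan.table[scan.table["threshold"] == taus[0]]
    base_nodes = {
        (r["layer"], r["condition"]): r["n_active_nodes"] for _, r in base.iterrows()
    }
    scores = (
        scan.curves.assign(absy1=lambda d: d["y1"].abs())
        .groupby("threshold")["absy1"]
        .sum()
    )

    def feasible(tau: float) -> bool:
        sub = scan.table[scan.table["threshold"] == tau]
        for _, r in sub.iterrows():
            b = base_nodes[(r["layer"], r["condition"])]
            if b > 0 and (b - r["n_active_nodes"]) / b > node_loss_cap:
                return False
        return True

    candidates = [t for t in taus if feasible(t)]
    if not candidates:
        warnings.warn(
            f"no scanned threshold keeps active-node loss within {node_loss_cap:.0%}; "
            "returning the |Y1| argmax regardless",
            stacklevel=2,
        )
        candidates = taus
    best = max(candidates, key=lambda t: (scores.get(t, 0), -t))
    return float(best)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _multilayer_graph(mln: MultilayerNetwork) -> nx.Graph:
    g = nx.Graph()
    for net in (mln.mirna_layer, mln.protein_layer):
        for node in net.nodes:
            g.add_node(node, layer=net.layer)
        for i, j in np.argwhere(np.triu(net.adjacency, 1)):
            g.add_edge(net.nodes[i], net.nodes[j], interlayer=False)
    for i, j in np.argwhere(mln.cross_adjacency):
        g.add_edge(mln.mirna_layer.nodes[i], mln.protein_layer.nodes[j], interlayer=True)
    return g


def write_graphml(mln: MultilayerNetwork, path) -> None:
    """Export a multilayer network as GraphML with layer/interlayer attributes."""
    nx.write_graphml(_multilayer_graph(mln), path)


def edge_list(mln: MultilayerNetwork) -> pd.DataFrame:
    """All edges as (source, target, layer_pair) rows."""
    rows = []
    for net in (mln.mirna_layer, mln.protein_layer):
        pair = f"{net.layer}-{net.layer}"
        for i, j in np.argwhere(np.triu(net.adjacency, 1)):
            rows.append({"source": net.nodes[i], "target": net.nodes[j], "layer_pair": pair})
    for i, j in np.argwhere(mln.cross_adjacency):
        rows.append(
            {
                "source": mln.mirna_layer.nodes[i],
                "target": mln.protein_layer.nodes[j],
                "layer_pair": f"{mln.mirna_layer.layer}-{mln.protein_layer.layer}",
            }
        )
    return pd.DataFrame(rows, columns=["source", "target", "layer_pair"])
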