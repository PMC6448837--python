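"""Node importance from condition differences in centrality and degree.

For each molecular layer, every node k receives

    S_k = |B*_k| + |D*_k|

where B*_k standardizes (over the layer's nodes) the absolute
normal-vs-cancer difference in shortest-path betweenness centrality
computed within that layer, and D*_k standardizes the absolute
difference in cross-layer degree (interlayer edges only). Large S marks
molecules whose network role changes most between normal and cancer
tissue. Standardization uses the population (divide-by-n) standard
deviation, so small hand-worked examples are exact.

Betweenness is the standard pair-normalized estimator with fractional
counting over multiple shortest paths; an unnormalized raw-count variant
is available via ``normalized=False``. Isolated nodes score zero in both
measures for the condition where they are isolated, keeping every
candidate comparable across conditions.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .network import LayerNetwork, MultilayerNetwork

__all__ = [
    "betweenness",
    "cross_layer_degree",
    "standardize_diff",
    "importance_scores",
    "jarque_bera",
    "rank_nodes",
]


def betweenness(net: LayerNetwork, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness of every node in a single layer.

    With ``normalized=True`` each value is the fraction of ordered-distinct
    pairs (i, j), i != j != k, whose shortest paths pass through k,
    counting multiple shortest paths fractionally. Isolated nodes get 0.
    """
    g = net.to_networkx()
    return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=normalized).items()}


def cross_layer_degree(mln: MultilayerNetwork) -> dict[str, int]:
    """Number of interlayer edges incident to each node (both layers)."""
    out: dict[str, int] = {}
    mirna_deg = mln.cross_adjacency.sum(axis=1)
    prot_deg = mln.cross_adjacency.sum(axis=0)
    for node, d in zip(mln.mirna_layer.nodes, mirna_deg):
        out[node] = int(d)
    for node, d in zip(mln.protein_layer.nodes, prot_deg):
        out[node] = int(d)
    return out


def standardize_diff(values: dict[str, float]) -> dict[str, float]:
    """Center and scale a node->value map by its population mean and SD.

    A zero-spread input returns all zeros with a warning (no node stands
    out), never a division error.
    """
    if not values:
        raise ValueError("cannot standardize an empty value map")
    keys = list(values)
    v = np.array([values[k] for k in keys], dtype=float)
    sd = float(v.std())  # population convention
    if sd == 0:
        warnings.warn("zero variance across nodes; standardized values set to 0", stacklevel=2)
        return {k: 0.0 for k in keys}
    mean = float(v.mean())
    return {k: (float(x) - mean) / sd for k, x in zip(keys, v)}


def jarque_bera(values) -> tuple[float, float]:
    """Jarque-Bera normality check: JB = n/6 (skew^2 + (kurt-3)^2 / 4).

    Returns (statistic, p-value) with p from a chi-squared(2) reference.
    Used diagnostically on the signed betweenness differences before
    treating their standardization as comparable across nodes.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("Jarque-Bera needs at least 8 observations")
    if np.ptp(v) == 0:
        raise ValueError("Jarque-Bera is undefined for zero-variance input")
    res = scipy.stats.jarque_bera(v)
    return float(res.statistic), float(res.pvalue)


def _layer_universe(a: LayerNetwork, b: LayerNetwork) -> list[str]:
    seen = dict.fromkeys(a.nodes)
    seen.update(dict.fromkeys(b.nodes))
    return list(seen)


def importance_scores(
    normal: MultilayerNetwork,
    cancer: MultilayerNetwork,
    normalized: bool = True,
) -> pd.DataFrame:
    """Score every node of both layers from a normal/cancer network pair.

    Returns one row per node with all intermediate quantities:
    betweenness per condition, cross-layer degree per condition, absolute
    differences, their standardized versions, and the final score
    ``score = |b_star| + |d_star|``. The two layers are standardized and
    scored independently. Swapping the two inputs leaves the scores
    unchanged (only absolute differences enter).
    """
    if normal.condition == cancer.condition:
        raise ValueError("inputs must describe two different conditions")
    d_normal = cross_layer_degree(normal)
    d_cancer = cross_layer_degree(cancer)
    frames = []
    for net_n, net_c in (
        (normal.mirna_layer, cancer.mirna_layer),
        (normal.protein_layer, cancer.protein_layer),
    ):
        if net_n.layer != net_c.layer:
            raise ValueError("layer tags disagree between conditions")
        nodes = _layer_universe(net_n, net_c)
        if not (set(net_n.nodes) & set(net_c.nodes)):
            raise ValueError(
                f"{net_n.layer} layer: no shared nodes between conditions; "
                "score both conditions over the same candidate set"
            )
        b_n = betweenness(net_n, normalized)
        b_c = betweenness(net_c, normalized)
        rows = pd.DataFrame(
            {
                "node": nodes,
                "layer": net_n.layer,
                "b_normal": [b_n.get(k, 0.0) for k in nodes],
                "b_cancer": [b_c.get(k, 0.0) for k in nodes],
                "d_normal": [d_normal.get(k, 0) for k in nodes],
                "d_cancer": [d_cancer.get(k, 0) for k in nodes],
            }
        )
        rows["b_diff"] = (rows["b_normal"] - rows["b_cancer"]).abs()
        rows["d_diff"] = (rows["d_normal"] - rows["d_cancer"]).abs()
        rows["b_signed_diff"] = rows["b_normal"] - rows["b_cancer"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b_star = standardize_diff(dict(zip(rows["node"], rows["b_diff"])))
            d_star = standardize_diff(dict(zip(rows["node"], rows["d_diff"])))
        rows["b_star"] = [b_star[k] for k in nodes]
        rows["d_star"] = [d_star[k] for k in nodes]
        rows["score"] = rows["b_star"].abs() + rows["d_star"].abs()
        frames.append(rows)
    table = pd.concat(frames, ignore_index=True)
    table["betweenness_part"] = table["b_star"].abs()
    table["degree_part"] = table["d_star"].abs()
    table = table.sort_values(["layer", "score", "node"], ascending=[True, False, True], kind="mergesort")
    table["rank"] = table.groupby("layer")["score"].rank(method="first", ascending=False).astype(int)
    return table.reset_index(drop=True)


def rank_nodes(table: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Order a score table by descending score (ties by node id ascending).

    The returned table keeps the betweenness part |b_star| and the degree
    part |d_star| as explicit columns so each bar of a score ranking can
    be decomposed; they sum to ``score`` exactly.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    out = table.copy()
    out["betweenness_part"] = out["b_star"].abs()
    out["degree_part"] = out["d_star"].abs()
    out = out.sort_values(["score", "node"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.head(top_n).reset_index(drop=True)
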