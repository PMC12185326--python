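"""Optional visualisation helpers (never on the analysis path).

Network graphs use a seeded Fruchterman-Reingold layout; edge display
thresholds are purely cosmetic and default to showing everything.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_network", "plot_cooccurrence"]


def plot_network(
    net,
    which: str = "temporal",
    threshold: float = 0.0,
    top_edges: int | None = None,
    seed: int = 0,
    ax=None,
):
    """Draw one network with node placement by Fruchterman-Reingold.

    `top_edges` keeps only the strongest edges by |weight| (ties all kept);
    positive edges are drawn in blue, negative in red.
    """
    import matplotlib.pyplot as plt
    import networkx as nx

    M = getattr(net, which)
    directed = which == "temporal"
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(net.node_labels)
    p = len(net.node_labels)
    weights = []
    for i in range(p):
        js = range(p) if directed else range(i)
        for j in js:
            if i == j:
                continue
            w = M[i, j]
            if abs(w) > threshold:
                weights.append((abs(w), net.node_labels[j], net.node_labels[i], w))
    weights.sort(reverse=True)
    if top_edges is not None and len(weights) > top_edges:
        cut = weights[top_edges - 1][0]
        weights = [e for e in weights if e[0] >= cut]   # non-superiority: keep ties
    for _, s, t, w in weights:
        G.add_edge(s, t, weight=w)

    pos = nx.spring_layout(G, seed=seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx_nodes(G, pos, ax=ax, node_color="#dddddd", node_size=600)
    nx.draw_networkx_labels(G, pos, ax=ax, font_size=7)
    edges = list(G.edges(data=True))
    colors = ["tab:blue" if d["weight"] > 0 else "tab:red" for *_, d in edges]
    widths = [40 * abs(d["weight"]) for *_, d in edges]
    nx.draw_networkx_edges(G, pos, ax=ax, edge_color=colors, width=widths,
                           arrows=directed)
    ax.set_axis_off()
    return ax


def plot_cooccurrence(result, ax=None):
    """Heatmap of community co-occurrence, hierarchically ordered."""
    import matplotlib.pyplot as plt

    order = np.asarray(result.heatmap_order)
    M = result.cooccurrence[np.ix_(order, order)]
    labels = [result.node_labels[i] for i in order]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(M, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="co-occurrence probability")
    return ax
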