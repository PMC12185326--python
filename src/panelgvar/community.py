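"""Spinglass community structure and co-occurrence over repeated runs.

The Potts-model simulated-annealing optimiser (igraph's spinglass
implementation, with the negative-weight extension when repulsive edges
are present) is stochastic, so community structure is summarised over many
runs: the co-occurrence matrix holds the fraction of runs in which two
nodes share a community, and communities are ranked by how often their
exact node set appears.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

__all__ = [
    "CommunityResult",
    "symmetrize",
    "spinglass_partition",
    "community_cooccurrence",
]


def symmetrize(weights: np.ndarray, rule: str = "average") -> np.ndarray:
    """Undirect a temporal edge matrix before Potts optimisation.

    "average" uses (w_ij + w_ji) / 2; "max" keeps the entry of larger
    magnitude.  Symmetric input passes through unchanged.
    """
    W = np.asarray(weights, dtype=float)
    if rule == "average":
        return 0.5 * (W + W.T)
    if rule == "max":
        flip = np.abs(W.T) > np.abs(W)
        return np.where(flip, W.T, W)
    raise ValueError("rule must be 'average' or 'max'")


def _graph_from_weights(W: np.ndarray, threshold: float = 0.0):
    p = W.shape[0]
    edges, weights = [], []
    for i in range(p):
        for j in range(i):
            if abs(W[i, j]) > threshold:
                edges.append((j, i))
                weights.append(float(W[i, j]))
    g = ig.Graph(n=p, edges=edges)
    g.es["weight"] = weights
    return g


def spinglass_partition(
    weights: np.ndarray,
    spins: int = 8,
    gamma: float = 1.0,
    seed: int = 0,
    threshold: float = 0.0,
    symmetrize_rule: str = "average",
) -> np.ndarray:
    """One simulated-annealing Potts partition of the weighted network.

    Negative edges penalise co-assignment (igraph's "neg" implementation).
    Components are optimised separately (the annealer requires a connected
    graph); isolated nodes become singleton communities, with a warning if
    the whole graph has no edges.  Deterministic for a fixed seed.
    """
    W = symmetrize(np.asarray(weights, dtype=float), symmetrize_rule)
    np.fill_diagonal(W, 0.0)
    if spins < 2:
        raise ValueError("spins must be >= 2")
    p = W.shape[0]
    g = _graph_from_weights(W, threshold)
    if g.ecount() == 0:
        warnings.warn(
            "network has no edges after thresholding; every node is its "
            "own community", stacklevel=2,
        )
        return np.arange(p)
    rng = random.Random(seed)
    membership = np.full(p, -1, dtype=int)
    next_label = 0
    has_negative = any(w < 0 for w in g.es["weight"])
    impl = "negative" if has_negative else "original"
    for comp in g.connected_components():
        if len(comp) == 1:
            membership[comp[0]] = next_label
            next_label += 1
            continue
        sub = g.induced_subgraph(comp)
        random.seed(rng.randrange(2**31 - 1))  # igraph draws from random
        cl = sub.community_spinglass(
            weights="weight",
            spins=min(spins, len(comp)),
            gamma=gamma,
            implementation=impl,
            start_temp=1.0,
            stop_temp=0.01,
            cool_fact=0.99,
        )
        for local, node in enumerate(comp):
            membership[node] = cl.membership[local] + next_label
        next_label += max(cl.membership) + 1
    return membership


@dataclass
class CommunityResult:
    """Aggregate of repeated stochastic partitions."""

    cooccurrence: np.ndarray            # fraction of runs sharing a community
    run_partitions: list
    top_communities: list               # [(node-label tuple, percent of runs)]
    heatmap_order: np.ndarray           # hierarchical-clustering leaf order
    node_labels: list[str]
    n_runs: int
    n_failed: int = 0
    log: list = field(default_factory=list)


def community_cooccurrence(
    weights: np.ndarray,
    runs: int = 1000,
    spins: int = 8,
    gamma: float = 1.0,
    seed: int = 0,
    threshold: float = 0.0,
    node_labels: list[str] | None = None,
    top_k: int = 3,
    symmetrize_rule: str = "average",
) -> CommunityResult:
    """Co-occurrence probabilities and ranked communities over many runs.

    Per-run seeds derive from the master seed; failed runs are excluded
    from every denominator and logged.  Heatmap row order comes from
    average-linkage hierarchical clustering of 1 - cooccurrence.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    p = np.asarray(weights).shape[0]
    if node_labels is None:
        node_labels = [f"f_{k + 1:02d}" for k in range(p)]
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(runs) % (2**31 - 1)
    co = np.zeros((p, p))
    partitions = []
    counts: dict = {}
    log = []
    n_failed = 0
    for r in range(runs):
        try:
            memb = spinglass_partition(
                weights, spins=spins, gamma=gamma, seed=int(run_seeds[r]),
                threshold=threshold, symmetrize_rule=symmetrize_rule,
            )
        except Exception as exc:  # noqa: BLE001 - run-scoped failure
            n_failed += 1
            log.append({"run": r, "status": "error", "detail": str(exc)})
            continue
        partitions.append(memb)
        co += (memb[:, None] == memb[None, :]).astype(float)
        for lab in np.unique(memb):
            nodes = tuple(sorted(np.flatnonzero(memb == lab)))
            counts[nodes] = counts.get(nodes, 0) + 1
    completed = runs - n_failed
    if completed == 0:
        raise RuntimeError("every community-detection run failed")
    co /= completed
    np.fill_diagonal(co, 1.0)

    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [
        (tuple(node_labels[i] for i in nodes), 100.0 * c / completed)
        for nodes, c in ranked
        if len(nodes) > 1
    ][:top_k]

    if p > 2:
        dist = ssd.squareform(np.clip(1.0 - co, 0.0, None), checks=False)
        order = sch.leaves_list(sch.linkage(dist, method="average"))
    else:
        order = np.arange(p)
    return CommunityResult(
        cooccurrence=co,
        run_partitions=partitions,
        top_communities=top,
        heatmap_order=np.asarray(order),
        node_labels=list(node_labels),
        n_runs=completed,
        n_failed=n_failed,
        log=log,
    )
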