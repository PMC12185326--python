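"""From fitted model parameters to the three reported networks.

Temporal edges are partial directed correlations (PDC): the correlation
between node j at wave t-1 and node i at wave t conditioning on all other
nodes at t-1, evaluated on the model-implied lag-augmented within-person
covariance.  Contemporaneous and between-person edges are the usual
partial correlations read off the standardized precision matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine

__all__ = [
    "NetworkEstimate",
    "CentralityTable",
    "partial_corr_from_precision",
    "temporal_pdc",
    "to_networks",
    "classify_edges",
    "centrality",
]


def partial_corr_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations -K_ij / sqrt(K_ii K_jj), unit diagonal."""
    d = np.sqrt(np.diag(K))
    R = -K / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def temporal_pdc(B: np.ndarray, sigma_zeta: np.ndarray) -> np.ndarray:
    """Partial directed correlations of a stationary lag-1 process.

    Entry [i, j] is the partial correlation of node j at t-1 with node i at
    t, conditioning on the remaining p-1 nodes at t-1 (the diagonal holds
    the autocorrelation partials).  Computed from the joint covariance of
    (y_{t-1}, y_t):

        V = [[S0, S0 B'], [B S0, S0]],   S0 = B S0 B' + Sigma_zeta,

    by inverting, per target node i, the covariance of the p lagged nodes
    together with node i at t.  Structural zeros of B map to zeros exactly.
    """
    p = B.shape[0]
    S0 = engine.stationary_within_cov(B, sigma_zeta)
    cross = S0 @ B.T          # Cov(y_{t-1}, y_t)
    pdc = np.zeros((p, p))
    for i in range(p):
        # covariance of (y_{t-1,1..p}, y_{t,i})
        V = np.empty((p + 1, p + 1))
        V[:p, :p] = S0
        V[:p, p] = cross[:, i]
        V[p, :p] = cross[:, i]
        V[p, p] = S0[i, i]
        K = np.linalg.inv(V)
        denom = np.sqrt(np.diag(K)[:p] * K[p, p])
        pdc[i, :] = -K[:p, p] / denom
    # the partial correlation vanishes exactly where the regression
    # coefficient does, so structural zeros survive standardization
    pdc[B == 0.0] = 0.0
    return pdc


@dataclass
class NetworkEstimate:
    """The three standardized networks of one fitted panel GVAR."""

    temporal: np.ndarray          # [i, j] = PDC of edge j -> i
    contemporaneous: np.ndarray   # partial correlations, symmetric
    between: np.ndarray           # partial correlations, symmetric
    node_labels: list[str]
    cluster_labels: list[str] | None = None

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_list(self, which: str = "temporal", threshold: float = 0.0):
        """(source, target, weight, class) rows; threshold is applied to
        |weight| for display purposes only."""
        M = getattr(self, which)
        labels = self.node_labels
        rows = []
        if which == "temporal":
            classes = classify_edges(self, threshold=threshold)
            cls_map = {}
            for j, i in classes["unidirectional"]:
                cls_map[(j, i)] = "unidirectional"
            for j, i in classes["bidirectional"]:
                cls_map[(j, i)] = "bidirectional"
            for i in classes["autocorrelative"]:
                cls_map[(i, i)] = "autocorrelative"
            for i in range(self.p):
                for j in range(self.p):
                    w = M[i, j]
                    if abs(w) > threshold:
                        rows.append(
                            (labels[j], labels[i], float(w),
                             cls_map.get((j, i), "none"))
                        )
        else:
            for i in range(self.p):
                for j in range(i):
                    w = M[i, j]
                    if abs(w) > threshold:
                        rows.append((labels[j], labels[i], float(w), "undirected"))
        return rows


def to_networks(
    B: np.ndarray,
    omega_zeta: np.ndarray,
    omega_between: np.ndarray,
    node_labels: list[str] | None = None,
    cluster_labels: list[str] | None = None,
) -> NetworkEstimate:
    """Standardize fitted parameters into the three reported networks."""
    p = B.shape[0]
    if node_labels is None:
        node_labels = [f"f_{k + 1:02d}" for k in range(p)]
    sigma_zeta = np.linalg.inv(omega_zeta)
    return NetworkEstimate(
        temporal=temporal_pdc(B, sigma_zeta),
        contemporaneous=partial_corr_from_precision(omega_zeta),
        between=partial_corr_from_precision(omega_between),
        node_labels=list(node_labels),
        cluster_labels=cluster_labels,
    )


def classify_edges(
    net: NetworkEstimate | np.ndarray, threshold: float = 0.0
) -> dict:
    """Split temporal edges into autocorrelative / unidirectional /
    bidirectional after thresholding |z|.

    Returns `autocorrelative` as node indices with nonzero diagonal,
    `unidirectional` as (source, target) pairs and `bidirectional` as
    (source, target) pairs listed in both directions.
    """
    M = net.temporal if isinstance(net, NetworkEstimate) else np.asarray(net)
    p = M.shape[0]
    nz = np.abs(M) > threshold
    auto = [i for i in range(p) if nz[i, i]]
    uni, bi = [], []
    for i in range(p):
        for j in range(p):
            if i == j or not nz[i, j]:
                continue
            if nz[j, i]:
                bi.append((j, i))       # edge j -> i, reciprocated
            else:
                uni.append((j, i))
    return {"autocorrelative": auto, "unidirectional": uni, "bidirectional": bi}


@dataclass
class CentralityTable:
    """Per-node strength centralities; autoregressive edges excluded."""

    node_labels: list[str]
    c_in: np.ndarray
    c_out: np.ndarray
    strength_contemporaneous: np.ndarray
    strength_between: np.ndarray

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.node_labels,
                "c_in": self.c_in,
                "c_out": self.c_out,
                "strength_contemporaneous": self.strength_contemporaneous,
                "strength_between": self.strength_between,
            }
        )


def centrality(net: NetworkEstimate) -> CentralityTable:
    """Absolute-weight strength centralities.

    c_out(j) sums |z| over edges leaving node j, c_in(i) over edges entering
    node i; the diagonal (autoregressive) entries are excluded.  The
    undirected networks contribute a single strength per node.
    """
    M = np.abs(net.temporal.copy())
    np.fill_diagonal(M, 0.0)
    c_in = M.sum(axis=1)
    c_out = M.sum(axis=0)
    C = np.abs(net.contemporaneous.copy())
    np.fill_diagonal(C, 0.0)
    Bm = np.abs(net.between.copy())
    np.fill_diagonal(Bm, 0.0)
    return CentralityTable(
        node_labels=list(net.node_labels),
        c_in=c_in,
        c_out=c_out,
        strength_contemporaneous=C.sum(axis=1),
        strength_between=Bm.sum(axis=1),
    )
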