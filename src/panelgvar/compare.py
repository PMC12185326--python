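"""Permutation comparison of diagnosis-specific sub-networks.

Groups are first restricted to their common retained features and refitted.
Under the permutation null, each node's individual-level trajectory (its
length-T occurrence vector) is independently re-assigned across individuals
within each group: marginal and autocorrelative structure is preserved
while cross-node coupling — and hence any genuine edge difference — is
destroyed.  Each permuted dataset is re-preprocessed and refitted, observed
edge-weight differences are referenced to the permuted differences by the
counting rule p = #(|permuted diff| >= |observed diff|) / iterations, and
Benjamini-Hochberg FDR control is applied per group pair and matrix type.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import engine, networks
from .preprocess import (
    DEFAULT_COVARIATES,
    PanelMoments,
    _design_matrix,
    filter_eligibility,
    preprocess_panel,
)
from .simulate import PanelData

__all__ = [
    "EdgeComparison",
    "ComparisonResult",
    "align_common_nodes",
    "permute_and_compare",
    "fdr_adjust",
    "permutation_pvalues",
]

MATRIX_KEYS = ("temporal", "contemporaneous", "between")


@dataclass
class EdgeComparison:
    """Edge-wise comparison of one matrix type for one ordered group pair."""

    pair: tuple[str, str]
    matrix: str
    observed_diff: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    permuted_diffs: np.ndarray | None = None

    @property
    def fraction_significant(self) -> float:
        mask = _tested_mask(self.matrix, self.observed_diff.shape[0])
        return float(self.significant[mask].mean())


@dataclass
class ComparisonResult:
    """All pairwise comparisons plus bookkeeping."""

    comparisons: dict
    node_labels: list[str]
    n_iterations: int
    n_dropped: int
    iteration_log: list = field(default_factory=list)

    def summary_fractions(self) -> dict:
        return {
            (pair, matrix): cmp_.fraction_significant
            for (pair, matrix), cmp_ in self.comparisons.items()
        }


def _tested_mask(matrix: str, p: int) -> np.ndarray:
    """Cells that constitute distinct edge comparisons."""
    if matrix == "temporal":
        return np.ones((p, p), dtype=bool)
    return np.tril(np.ones((p, p), dtype=bool), k=-1)


def align_common_nodes(panels: dict, **preprocess_kwargs) -> dict:
    """Restrict each group's panel to the intersection of retained features.

    Retained features are determined per group by the eligibility and
    near-zero-variance screens; the intersection is ordered by the first
    group's feature order so all groups share one topology.
    """
    if len(panels) < 2:
        raise ValueError("need at least two groups to compare")
    retained = {}
    for name, panel in panels.items():
        _, resid, _ = preprocess_panel(panel, **preprocess_kwargs)
        retained[name] = list(resid.retained_features)
    common = set.intersection(*(set(v) for v in retained.values()))
    if not common:
        raise ValueError("groups share no retained features")
    first = next(iter(panels))
    order = [f for f in retained[first] if f in common]
    out = {}
    for name, panel in panels.items():
        drop = [f for f in panel.features if f not in common]
        out[name] = PanelData(
            panel.df.drop(columns=drop),
            [f for f in panel.features if f in common],
            panel.n_waves,
        )
        out[name].features = order  # shared ordering
    return out


def _permute_node_trajectories(
    panel: PanelData, rng: np.random.Generator
) -> PanelData:
    """Shuffle, per feature, which individual carries each trajectory."""
    df = panel.df.sort_values(["id", "wave"]).reset_index(drop=True)
    n = df["id"].nunique()
    T = panel.n_waves
    out = df.copy()
    for feat in panel.features:
        block = df[feat].to_numpy().reshape(n, T)
        out[feat] = block[rng.permutation(n)].reshape(-1)
    return PanelData(out, list(panel.features), T)


class _PreparedGroup:
    """One group's data staged for many permuted refits.

    Eligibility is applied once and the per-wave covariate designs (which
    the permutation never moves) are pre-factorised, so each iteration only
    permutes trajectories, residualizes by cached projections, stacks
    moments and refits.  The operations are the ones the one-shot
    pre-processing chain performs, restated on arrays.
    """

    def __init__(self, panel: PanelData, covariate_names, min_waves,
                 missing_policy):
        eligible, _ = filter_eligibility(panel, min_waves=min_waves)
        df = eligible.df.sort_values(["id", "wave"]).reset_index(drop=True)
        self.features = list(panel.features)
        self.p = len(self.features)
        self.T = panel.n_waves
        self.n = df["id"].nunique()
        self.Y = df[self.features].to_numpy(dtype=float).reshape(
            self.n, self.T, self.p
        )
        self.missing_policy = missing_policy
        self.designs = []
        for t in range(self.T):
            sub = df[df["wave"] == t + 1]
            X, _ = _design_matrix(sub, covariate_names or DEFAULT_COVARIATES)
            self.designs.append((X, np.linalg.pinv(X)))
        self.columns = [
            f"w{t}_{f}" for t in range(1, self.T + 1) for f in self.features
        ]

    def permuted(self, rng: np.random.Generator,
                 unit: str = "trajectory") -> np.ndarray:
        """Per-node permutation: "trajectory" re-assigns whole length-T
        vectors across individuals (preserves autocorrelation, breaks
        cross-node coupling); "cell" shuffles every feature-wave column
        independently (fully i.i.d. null)."""
        Yp = np.empty_like(self.Y)
        if unit == "trajectory":
            for k in range(self.p):
                Yp[:, :, k] = self.Y[rng.permutation(self.n), :, k]
        elif unit == "cell":
            for k in range(self.p):
                for t in range(self.T):
                    Yp[:, t, k] = self.Y[rng.permutation(self.n), t, k]
        else:
            raise ValueError("unit must be 'trajectory' or 'cell'")
        return Yp

    def moments(self, Y: np.ndarray) -> PanelMoments:
        R = np.empty_like(Y)
        for t in range(self.T):
            X, pinv = self.designs[t]
            yt = Y[:, t, :]
            nan_mask = np.isnan(yt)
            if not nan_mask.any():
                R[:, t, :] = yt - X @ (pinv @ yt)
            else:
                for k in range(self.p):
                    obs = ~nan_mask[:, k]
                    Xo = X[obs]
                    beta, *_ = np.linalg.lstsq(Xo, yt[obs, k], rcond=None)
                    col = np.full(self.n, np.nan)
                    col[obs] = yt[obs, k] - Xo @ beta
                    R[:, t, k] = col
        stacked = R.reshape(self.n, self.T * self.p)
        if np.isnan(stacked).any():
            wide = pd.DataFrame(stacked, columns=self.columns)
            mean = wide.mean(skipna=True).to_numpy()
            cov = wide.cov(min_periods=2).to_numpy()
        else:
            mean = stacked.mean(axis=0)
            cov = np.cov(stacked, rowvar=False)
        return PanelMoments(
            mean=mean, cov=0.5 * (cov + cov.T), n=self.n,
            feature_order=list(self.features), n_waves=self.T,
        )

    def fit(self, Y: np.ndarray, start=None, gtol=1e-8):
        m = self.moments(Y)
        raw = engine.fit_ml(m.cov, m.mean, self.p, self.T, start=start,
                            gtol=gtol)
        net = networks.to_networks(
            raw.B, raw.omega_zeta, raw.omega_between,
            node_labels=self.features,
        )
        return raw, {
            "temporal": net.temporal,
            "contemporaneous": net.contemporaneous,
            "between": net.between,
        }


def permutation_pvalues(
    observed: np.ndarray, permuted: np.ndarray
) -> np.ndarray:
    """Counting rule: fraction of permuted |diff| >= observed |diff|."""
    return (np.abs(permuted) >= np.abs(observed)[None]).mean(axis=0)


def fdr_adjust(p_matrix: np.ndarray, mask: np.ndarray, level: float = 0.05):
    """Benjamini-Hochberg step-up over the masked cells.

    Returns (q_matrix, significance flags); untested cells get q = 1.
    """
    q = np.ones_like(p_matrix, dtype=float)
    sig = np.zeros_like(p_matrix, dtype=bool)
    pv = p_matrix[mask]
    if pv.size:
        rej, qv, _, _ = multipletests(pv, alpha=level, method="fdr_bh")
        q[mask] = qv
        sig[mask] = qv < level
    return q, sig


def permute_and_compare(
    panels: dict,
    iterations: int = 250,
    seed: int = 0,
    level: float = 0.05,
    add_one: bool = False,
    keep_null: bool = False,
    permutation_unit: str = "trajectory",
    covariate_names: list[str] | None = None,
    min_waves: int | None = None,
    missing_policy: str = "pairwise",
) -> ComparisonResult:
    """Permutation test of edge differences across aligned group panels.

    `panels` maps group name -> PanelData already restricted to common
    features (see :func:`align_common_nodes`).  `add_one` switches the
    p-value to the conservative (k+1)/(m+1) variant.  Deterministic for a
    fixed seed.
    """
    names = list(panels)
    feats = [tuple(p.features) for p in panels.values()]
    if len(set(feats)) != 1:
        raise ValueError("groups must share an identical ordered feature set")
    features = list(feats[0])
    p = len(features)

    prepared = {
        name: _PreparedGroup(panel, covariate_names, min_waves, missing_policy)
        for name, panel in panels.items()
    }
    observed_fits = {}
    observed_mats = {}
    for name in names:
        raw, mats = prepared[name].fit(prepared[name].Y)
        observed_fits[name] = raw
        observed_mats[name] = mats

    pairs = list(itertools.combinations(names, 2))
    observed_diff = {
        (a, b): {k: observed_mats[a][k] - observed_mats[b][k] for k in MATRIX_KEYS}
        for a, b in pairs
    }

    rng = np.random.default_rng(seed)
    null: dict = {
        (pair, k): [] for pair in pairs for k in MATRIX_KEYS
    }
    log: list = []
    n_dropped = 0
    for it in range(iterations):
        perm_mats = {}
        ok = True
        for name in names:
            grp = prepared[name]
            Yp = grp.permuted(rng, unit=permutation_unit)
            try:
                _, mats = grp.fit(Yp, start=observed_fits[name], gtol=1e-7)
            except Exception as exc:  # noqa: BLE001
                log.append({"iteration": it, "group": name, "status": "error",
                            "detail": str(exc)})
                ok = False
                break
            perm_mats[name] = mats
        if not ok:
            n_dropped += 1
            continue
        for a, b in pairs:
            for k in MATRIX_KEYS:
                null[((a, b), k)].append(perm_mats[a][k] - perm_mats[b][k])
        log.append({"iteration": it, "status": "ok"})

    completed = iterations - n_dropped
    if completed < 1:
        raise RuntimeError("every permutation iteration failed")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} permutation iterations dropped; p-value "
            f"denominators use {completed} completed iterations",
            stacklevel=2,
        )

    comparisons = {}
    for pair in pairs:
        for k in MATRIX_KEYS:
            perm = np.stack(null[(pair, k)])
            obs = observed_diff[pair][k]
            pv = permutation_pvalues(obs, perm)
            if add_one:
                pv = (pv * completed + 1.0) / (completed + 1.0)
            mask = _tested_mask(k, p)
            qv, sig = fdr_adjust(pv, mask, level=level)
            comparisons[(pair, k)] = EdgeComparison(
                pair=pair,
                matrix=k,
                observed_diff=obs,
                p_values=pv,
                q_values=qv,
                significant=sig,
                permuted_diffs=perm if keep_null else None,
            )
    return ComparisonResult(
        comparisons=comparisons,
        node_labels=features,
        n_iterations=completed,
        n_dropped=n_dropped,
        iteration_log=log,
    )
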