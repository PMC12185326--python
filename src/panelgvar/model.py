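"""Model/Results interface for the fixed-effects lag-1 panel graphical VAR.

`PanelGVAR` is constructed from stacked moments (or straight from a panel
via `from_panel`, which runs the pre-processing chain); `fit()` returns a
`PanelGVARResults` carrying the estimates, fit indices and diagnostics,
with pruning, recoverability simulation and network derivation hanging off
the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from . import engine, networks
from .preprocess import PanelMoments, preprocess_panel

__all__ = ["PanelGVAR", "PanelGVARResults", "PruneComparison", "RecoveryResult"]


class PanelGVAR:
    """Fixed-effects lag-1 panel graphical VAR on stacked moments.

    Parameters
    ----------
    moments : PanelMoments
        Wave-major stacked mean vector, covariance matrix and sample size.
    """

    def __init__(self, moments: PanelMoments):
        moments.validate()
        self.moments = moments
        self.p = moments.p
        self.n_waves = moments.n_waves
        self.node_labels = list(moments.feature_order)

    @classmethod
    def from_panel(cls, panel, **preprocess_kwargs) -> "PanelGVAR":
        """Build the model from a long-format panel.

        Runs eligibility filtering, the near-zero-variance screen,
        covariate residualization and moment stacking; keyword arguments
        are forwarded to :func:`panelgvar.preprocess.preprocess_panel`.
        """
        moments, resid, log = preprocess_panel(panel, **preprocess_kwargs)
        model = cls(moments)
        model._preprocess_log = log
        model._residual_panel = resid
        return model

    def fit(
        self,
        start=None,
        gtol: float = 1e-8,
        maxiter: int = 5000,
        warn_small_n: bool = True,
    ) -> "PanelGVARResults":
        """Quasi-Newton maximum-likelihood fit from a deterministic start."""
        k = engine.count_free_parameters(self.p)
        if warn_small_n and self.moments.n <= k:
            warnings.warn(
                f"sample size n={self.moments.n} does not exceed the "
                f"{k} free parameters; estimates may be unstable",
                stacklevel=2,
            )
        raw = engine.fit_ml(
            self.moments.cov,
            self.moments.mean,
            self.p,
            self.n_waves,
            start=start,
            gtol=gtol,
            maxiter=maxiter,
        )
        return PanelGVARResults(self, raw)


class PanelGVARResults:
    """Estimates, uncertainties and diagnostics of a fitted panel GVAR."""

    def __init__(self, model: PanelGVAR, raw: engine.MLFit, df: int | None = None):
        self.model = model
        self._raw = raw
        self.B = raw.B
        self.omega_zeta = raw.omega_zeta
        self.omega_between = raw.omega_between
        self.mu = raw.mu
        self.converged = raw.converged
        self.grad_norm = raw.grad_norm
        self.n = model.moments.n
        self.discrepancy = raw.discrepancy
        self.df = engine.saturated_df(model.p, model.n_waves) if df is None else df
        self.chi2 = max((self.n - 1) * raw.discrepancy, 0.0)
        base_chi2, base_df = engine.baseline_chi2(model.moments.cov, self.n)
        self.fit_indices = engine.fit_indices(
            self.chi2, self.df, self.n, base_chi2, base_df
        )

    # -- derived quantities -------------------------------------------------

    @property
    def sigma_zeta(self) -> np.ndarray:
        return np.linalg.inv(self.omega_zeta)

    @property
    def sigma_between(self) -> np.ndarray:
        return np.linalg.inv(self.omega_between)

    def implied_covariance(self) -> tuple[np.ndarray, np.ndarray]:
        """Model-implied stacked mean and covariance."""
        return engine.implied_moments(
            self.B, self.sigma_zeta, self.sigma_between, self.mu,
            self.model.n_waves,
        )

    def to_networks(self, cluster_labels=None) -> networks.NetworkEstimate:
        """Temporal PDC, contemporaneous and between partial correlations."""
        return networks.to_networks(
            self.B, self.omega_zeta, self.omega_between,
            node_labels=self.model.node_labels,
            cluster_labels=cluster_labels,
        )

    def centrality(self) -> networks.CentralityTable:
        return networks.centrality(self.to_networks())

    # -- pruning ------------------------------------------------------------

    def prune(self, alpha: float = 0.01) -> "PruneComparison":
        """Wald-prune non-significant edges and refit the sparse model.

        Edge parameters (temporal coefficients and the off-diagonal
        precision entries) whose Wald p-value exceeds `alpha` are fixed to
        zero; the likelihood-ratio chi-square difference between the
        saturated and sparse fits is returned.
        """
        p = self.model.p
        layout, cov = engine.observed_information(
            self.model.moments.cov, self.model.moments.mean, self._raw,
            self.n, self.model.n_waves,
        )
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        mask_B = np.ones((p, p), dtype=bool)
        mask_Kz = np.ones((p, p), dtype=bool)
        mask_Kb = np.ones((p, p), dtype=bool)
        n_pruned = 0
        for k, (kind, i, j) in enumerate(layout):
            if kind == "mu" or (kind in ("Kz", "Kb") and i == j):
                continue
            if kind == "B":
                est = self._raw.B[i, j]
            elif kind == "Kz":
                est = self._raw.omega_zeta[i, j]
            else:
                est = self._raw.omega_between[i, j]
            z = est / se[k] if se[k] > 0 else np.inf
            pval = 2.0 * scipy.stats.norm.sf(abs(z))
            if pval > alpha:
                n_pruned += 1
                if kind == "B":
                    mask_B[i, j] = False
                elif kind == "Kz":
                    mask_Kz[i, j] = mask_Kz[j, i] = False
                else:
                    mask_Kb[i, j] = mask_Kb[j, i] = False
        if n_pruned == 0:
            return PruneComparison(
                sparse=self, delta_chi2=0.0, delta_df=0, p_value=1.0,
                n_pruned=0,
            )
        sparse_raw = engine.fit_ml_masked(
            self.model.moments.cov, self.model.moments.mean, p,
            self.model.n_waves, start=self._raw,
            mask_B=mask_B, mask_Kz=mask_Kz, mask_Kb=mask_Kb,
        )
        sparse = PanelGVARResults(self.model, sparse_raw, df=self.df + n_pruned)
        delta_chi2 = max(sparse.chi2 - self.chi2, 0.0)
        p_value = float(scipy.stats.chi2.sf(delta_chi2, n_pruned))
        return PruneComparison(
            sparse=sparse, delta_chi2=delta_chi2, delta_df=n_pruned,
            p_value=p_value, n_pruned=n_pruned,
        )

    # -- recoverability -----------------------------------------------------

    def simulate_recovery(self, n: int | None = None, seed: int = 0) -> "RecoveryResult":
        """Draw a cohort from the fitted structure and refit.

        Stacked vectors are sampled through the Cholesky factor of the
        implied covariance; the refitted model's fit indices and the
        Pearson correlation between generating and recovered off-diagonal
        temporal PDCs quantify recoverability.
        """
        if n is None:
            n = self.n
        mean, Sigma = self.implied_covariance()
        L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(Sigma.shape[0]))
        rng = np.random.default_rng(seed)
        X = mean + rng.standard_normal((n, Sigma.shape[0])) @ L.T
        sim_moments = PanelMoments(
            mean=X.mean(axis=0),
            cov=np.cov(X, rowvar=False),
            n=n,
            feature_order=list(self.model.node_labels),
            n_waves=self.model.n_waves,
        )
        refit = PanelGVAR(sim_moments).fit(start=self._raw)
        gen_pdc = self.to_networks().temporal
        rec_pdc = refit.to_networks().temporal
        off = ~np.eye(self.model.p, dtype=bool)
        if np.std(gen_pdc[off]) > 0 and np.std(rec_pdc[off]) > 0:
            r = float(np.corrcoef(gen_pdc[off], rec_pdc[off])[0, 1])
        else:
            r = np.nan
        return RecoveryResult(
            results=refit, fit_indices=refit.fit_indices, edge_correlation=r,
            cholesky_factor=L,
        )

    # -- presentation -------------------------------------------------------

    def summary(self, top_edges: int = 10) -> str:
        fi = self.fit_indices
        net = self.to_networks()
        lines = [
            "Fixed-effects lag-1 panel graphical VAR",
            "=" * 55,
            f"features (p):        {self.model.p}",
            f"waves (T):           {self.model.n_waves}",
            f"individuals (n):     {self.n}",
            f"converged:           {self.converged} "
            f"(max|grad| = {self.grad_norm:.2e})",
            f"chi2({fi.df}) = {fi.chi2:.1f}, p = {fi.p_value:.4g}",
            f"RMSEA = {fi.rmsea:.4f} "
            f"[95% CI {fi.rmsea_ci[0]:.4f}, {fi.rmsea_ci[1]:.4f}]",
            f"CFI = {fi.cfi:.3f}, TLI = {fi.tli:.3f}",
            "-" * 55,
            f"strongest temporal edges (PDC, top {top_edges}):",
        ]
        M = net.temporal
        order = np.argsort(-np.abs(M), axis=None)[:top_edges]
        for flat in order:
            i, j = np.unravel_index(flat, M.shape)
            kind = "auto" if i == j else "cross"
            lines.append(
                f"  {net.node_labels[j]:>10s} -> {net.node_labels[i]:<10s} "
                f"z = {M[i, j]:+.4f}  ({kind})"
            )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "B": self.B.tolist(),
            "omega_zeta": self.omega_zeta.tolist(),
            "omega_between": self.omega_between.tolist(),
            "mu": self.mu.tolist(),
            "node_labels": list(self.model.node_labels),
            "n": self.n,
            "n_waves": self.model.n_waves,
            "converged": self.converged,
            "fit_indices": self.fit_indices.as_dict(),
        }


@dataclass
class PruneComparison:
    """Saturated-versus-sparse likelihood-ratio comparison."""

    sparse: PanelGVARResults
    delta_chi2: float
    delta_df: int
    p_value: float
    n_pruned: int


@dataclass
class RecoveryResult:
    """Refit of data simulated from the fitted structure."""

    results: PanelGVARResults
    fit_indices: engine.FitIndices
    edge_correlation: float
    cholesky_factor: np.ndarray
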