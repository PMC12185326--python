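"""Synthetic wave-structured symptom panels with a known generative GVAR.

Emulates an EHR-derived cohort: individuals observed at T fixed three-month
waves, p binary (or continuous latent) symptom-occurrence features, baseline
covariates (age, gender, ethnicity, four medication flags) and per-wave
documentation-volume covariates (entry and word counts).  The latent process
is exactly the fixed-effects lag-1 GVAR the estimator assumes, so parameter
recovery is well defined; a binarisation mode thresholds each latent feature
at a configured quantile to produce occurrence indicators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine

__all__ = [
    "SimConfig",
    "PanelData",
    "generate_population",
    "plant_group_difference",
    "apply_missingness",
    "smd_like_config",
    "sparse_stationary_temporal",
]

GENDER_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("white", "black", "asian", "mixed", "other")
MED_COLUMNS = (
    "med_antidepressant",
    "med_moodstab",
    "med_anxiolytic",
    "med_antipsychotic",
)
BASE_COVARIATES = ("age", "gender", "ethnicity") + MED_COLUMNS
WAVE_COVARIATES = ("ehr_entries", "ehr_words")


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration for one synthetic cohort.

    `temporal_matrix[i, j]` is the lag-1 effect of feature j on feature i;
    its spectral radius must be below 1.  `contemporaneous_pcor` is the
    within-wave partial-correlation structure of the innovations (unit
    diagonal); `between_cov` the covariance of the person-specific random
    intercepts.  `covariate_effects` maps a covariate name to a length-p
    vector of additive effects per standard deviation of that covariate on
    the latent scale.  `binarize_quantiles`, when set, thresholds feature k
    at its q_k empirical quantile (prevalence 1 - q_k).
    """

    n_individuals: int
    temporal_matrix: np.ndarray
    contemporaneous_pcor: np.ndarray
    between_cov: np.ndarray
    n_waves: int = 6
    innovation_scales: np.ndarray | None = None
    covariate_effects: dict = field(default_factory=dict)
    binarize_quantiles: np.ndarray | None = None
    missing_wave_rate: float = 0.0
    mean_ehr_entries: float = 8.0
    mean_words_per_entry: float = 120.0
    seed: int = 0

    @property
    def p(self) -> int:
        return int(np.asarray(self.temporal_matrix).shape[0])

    def innovation_cov(self) -> np.ndarray:
        """Innovation covariance implied by the partial correlations.

        Off-diagonal partial correlations w_ij translate into a precision
        K_ij = -w_ij sqrt(K_ii K_jj); diagonal precisions are set so the
        innovation standard deviations equal `innovation_scales` (default 1)
        up to the correlation structure.
        """
        W = np.asarray(self.contemporaneous_pcor, dtype=float)
        p = W.shape[0]
        K = -W.copy()
        np.fill_diagonal(K, 1.0)
        scales = (
            np.ones(p)
            if self.innovation_scales is None
            else np.asarray(self.innovation_scales, dtype=float)
        )
        w = np.linalg.eigvalsh(K)
        if w.min() <= 1e-10:
            raise ValueError(
                "contemporaneous partial correlations do not define an "
                "invertible precision matrix"
            )
        cov = np.linalg.inv(K)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d) * np.outer(scales, scales)
        return 0.5 * (cov + cov.T)

    def validate(self) -> None:
        B = np.asarray(self.temporal_matrix, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("temporal_matrix must be square")
        rho = engine.spectral_radius(B)
        if rho >= 1.0:
            raise ValueError(
                f"temporal_matrix is non-stationary: spectral radius "
                f"{rho:.4f} >= 1"
            )
        W = np.asarray(self.contemporaneous_pcor, dtype=float)
        if not np.allclose(np.diag(W), 1.0):
            raise ValueError("contemporaneous_pcor must have unit diagonal")
        self.innovation_cov()  # raises if not invertible
        Sb = np.asarray(self.between_cov, dtype=float)
        if np.linalg.eigvalsh(0.5 * (Sb + Sb.T)).min() < -1e-10:
            raise ValueError("between_cov must be positive semi-definite")
        if not 0.0 <= self.missing_wave_rate < 1.0:
            raise ValueError("missing_wave_rate must be in [0, 1)")
        if self.binarize_quantiles is not None:
            q = np.asarray(self.binarize_quantiles, dtype=float)
            if q.shape != (self.p,) or np.any(q <= 0) or np.any(q >= 1):
                raise ValueError(
                    "binarize_quantiles must be p values strictly in (0, 1)"
                )


@dataclass
class PanelData:
    """Long-format panel: one row per individual-wave.

    `df` columns: id, wave (1..T), the feature columns, baseline covariates,
    per-wave EHR volume and the `observed` flag.  Unobserved waves keep their
    row (features missing, EHR counts zero) so every individual contributes
    exactly T rows.
    """

    df: pd.DataFrame
    features: list[str]
    n_waves: int

    @property
    def individuals(self) -> np.ndarray:
        return self.df["id"].unique()

    @property
    def n_individuals(self) -> int:
        return int(self.df["id"].nunique())

    def feature_array(self) -> np.ndarray:
        """(n, T, p) array of feature values, NaN where unobserved."""
        d = self.df.sort_values(["id", "wave"])
        n = d["id"].nunique()
        return d[self.features].to_numpy(dtype=float).reshape(
            n, self.n_waves, len(self.features)
        )

    def observed_matrix(self) -> np.ndarray:
        d = self.df.sort_values(["id", "wave"])
        n = d["id"].nunique()
        return d["observed"].to_numpy(dtype=bool).reshape(n, self.n_waves)

    def subset(self, ids) -> "PanelData":
        mask = self.df["id"].isin(np.asarray(ids))
        return PanelData(
            self.df.loc[mask].reset_index(drop=True), list(self.features),
            self.n_waves,
        )

    def copy(self) -> "PanelData":
        return PanelData(self.df.copy(), list(self.features), self.n_waves)


def _feature_names(p: int) -> list[str]:
    return [f"f_{k + 1:02d}" for k in range(p)]


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline covariates on the cohort's demographic scale."""
    age = np.clip(rng.normal(43.5, 16.1, n), 16.0, 95.0)
    gender = rng.choice(GENDER_LEVELS, size=n, p=[0.51, 0.49])
    ethnicity = rng.choice(
        ETHNICITY_LEVELS, size=n, p=[0.565, 0.295, 0.071, 0.032, 0.037]
    )
    meds = {
        "med_antidepressant": rng.binomial(1, 0.39, n),
        "med_moodstab": rng.binomial(1, 0.17, n),
        "med_anxiolytic": rng.binomial(1, 0.24, n),
        "med_antipsychotic": rng.binomial(1, 0.53, n),
    }
    return pd.DataFrame({"age": age, "gender": gender, "ethnicity": ethnicity, **meds})


def _covariate_numeric(base: pd.DataFrame, name: str) -> np.ndarray:
    """Standardised numeric representation used for latent effects."""
    if name == "age":
        x = base["age"].to_numpy(dtype=float)
    elif name == "gender":
        x = (base["gender"] == "male").to_numpy(dtype=float)
    elif name == "ethnicity":
        x = (base["ethnicity"] != "white").to_numpy(dtype=float)
    elif name in MED_COLUMNS:
        x = base[name].to_numpy(dtype=float)
    else:
        raise KeyError(f"unknown baseline covariate {name!r}")
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_population(config: SimConfig) -> PanelData:
    """Simulate a cohort from the configured generative GVAR.

    Wave 1 latents are drawn from the stationary within-person distribution,
    later waves follow y_t = a_i + B (y_{t-1} - a_i) + eps_t.  Covariate
    effects are added linearly on the latent scale (constant over waves for
    baseline covariates, wave-specific for EHR volume).  Deterministic for a
    fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, T = config.n_individuals, config.p, config.n_waves
    B = np.asarray(config.temporal_matrix, dtype=float)
    sigma_zeta = config.innovation_cov()
    sigma_between = np.asarray(config.between_cov, dtype=float)

    S0 = engine.stationary_within_cov(B, sigma_zeta)
    L0 = np.linalg.cholesky(S0 + 1e-12 * np.eye(p))
    # random intercepts (PSD, possibly singular -> eigen factor)
    w, V = np.linalg.eigh(0.5 * (sigma_between + sigma_between.T))
    Lb = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Lz = np.linalg.cholesky(sigma_zeta)

    a = rng.standard_normal((n, p)) @ Lb.T
    y = np.empty((n, T, p))
    y[:, 0, :] = a + rng.standard_normal((n, p)) @ L0.T
    for t in range(1, T):
        eps = rng.standard_normal((n, p)) @ Lz.T
        y[:, t, :] = a + (y[:, t - 1, :] - a) @ B.T + eps

    base = _draw_covariates(rng, n)
    ehr_entries = rng.negative_binomial(
        5, 5.0 / (5.0 + config.mean_ehr_entries), size=(n, T)
    ) + 1
    words_per_entry = np.exp(
        rng.normal(np.log(config.mean_words_per_entry), 0.5, size=(n, T))
    )
    ehr_words = np.rint(ehr_entries * words_per_entry).astype(int)

    for name, effect in config.covariate_effects.items():
        eff = np.asarray(effect, dtype=float)
        if eff.shape != (p,):
            raise ValueError(f"effect for {name!r} must have length p={p}")
        if name in WAVE_COVARIATES:
            raw = ehr_entries if name == "ehr_entries" else ehr_words
            x = (raw - raw.mean()) / raw.std()
            y += x[:, :, None] * eff[None, None, :]
        else:
            x = _covariate_numeric(base, name)
            y += x[:, None, None] * eff[None, None, :]

    if config.binarize_quantiles is not None:
        q = np.asarray(config.binarize_quantiles, dtype=float)
        flat = y.reshape(n * T, p)
        thresholds = np.array([np.quantile(flat[:, k], q[k]) for k in range(p)])
        y = (y > thresholds[None, None, :]).astype(float)

    features = _feature_names(p)
    rows = {
        "id": np.repeat(np.arange(n), T),
        "wave": np.tile(np.arange(1, T + 1), n),
    }
    df = pd.DataFrame(rows)
    feat_flat = y.reshape(n * T, p)
    for k, name in enumerate(features):
        df[name] = feat_flat[:, k]
    for col in base.columns:
        df[col] = np.repeat(base[col].to_numpy(), T)
    df["ehr_entries"] = ehr_entries.reshape(-1)
    df["ehr_words"] = ehr_words.reshape(-1)
    df["observed"] = 1

    panel = PanelData(df, features, T)
    if config.missing_wave_rate > 0:
        panel = apply_missingness(
            panel, config.missing_wave_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return panel


def apply_missingness(panel: PanelData, rate: float, seed: int) -> PanelData:
    """Mark individual-waves unobserved completely at random.

    Feature values become missing and per-wave EHR counts zero for the
    dropped waves; rows are kept so the panel stays rectangular.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    df = panel.df.sort_values(["id", "wave"]).reset_index(drop=True)
    drop = rng.random(len(df)) < rate
    df.loc[drop, panel.features] = np.nan
    df.loc[drop, ["ehr_entries", "ehr_words"]] = 0
    df.loc[drop, "observed"] = 0
    return PanelData(df, list(panel.features), panel.n_waves)


def plant_group_difference(
    config: SimConfig, edge: tuple[int, int], delta: float
) -> SimConfig:
    """Return a config whose temporal matrix differs by `delta` on one edge.

    `edge = (j, i)` names the lag-1 effect of feature j on feature i, i.e.
    entry [i, j] of the temporal matrix.
    """
    j, i = edge
    B = np.array(config.temporal_matrix, dtype=float, copy=True)
    B[i, j] += delta
    rho = engine.spectral_radius(B)
    if rho >= 1.0:
        raise ValueError(
            f"planted difference makes the temporal matrix non-stationary "
            f"(spectral radius {rho:.4f})"
        )
    return dataclasses.replace(config, temporal_matrix=B)


def sparse_stationary_temporal(
    p: int,
    autocorr: tuple[float, float] = (0.04, 0.12),
    cross_edges: int | None = None,
    cross_scale: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """A sparse stationary temporal matrix with modest autocorrelations and a
    few weak cross-lagged effects, on the scale seen in symptom panels."""
    rng = np.random.default_rng(seed)
    B = np.diag(rng.uniform(*autocorr, size=p))
    if cross_edges is None:
        cross_edges = 2 * p
    off = [(i, j) for i in range(p) for j in range(p) if i != j]
    chosen = rng.choice(len(off), size=min(cross_edges, len(off)), replace=False)
    for k in chosen:
        i, j = off[k]
        B[i, j] = rng.normal(0.0, cross_scale)
    if engine.spectral_radius(B) >= 0.95:
        B *= 0.9 / engine.spectral_radius(B)
    return B


def smd_like_config(
    n_individuals: int = 6462,
    p: int = 23,
    n_waves: int = 6,
    binarize: bool = True,
    missing_wave_rate: float = 0.055,
    seed: int = 0,
) -> SimConfig:
    """Default cohort-scale configuration.

    Matches the emulated study population: 6462 individuals, 23 retained
    occurrence features, six three-month waves, MCAR wave missingness chosen
    so the mean number of observed waves is about 5.67 of 6, binary features
    with prevalences between roughly 5% and 35%, and weak documentation-
    volume confounding through the per-wave EHR entry count.
    """
    rng = np.random.default_rng(seed)
    B = sparse_stationary_temporal(p, seed=seed)
    W = np.eye(p)
    # a handful of contemporaneous partial correlations of modest size
    off = [(i, j) for i in range(p) for j in range(i)]
    chosen = rng.choice(len(off), size=min(3 * p, len(off)), replace=False)
    for k in chosen:
        i, j = off[k]
        W[i, j] = W[j, i] = rng.uniform(-0.12, 0.2)
    between = 0.25 * np.eye(p) + 0.05
    quantiles = rng.uniform(0.65, 0.95, size=p) if binarize else None
    effects = {
        "ehr_entries": rng.uniform(0.05, 0.15, size=p),
        "age": rng.normal(0.0, 0.05, size=p),
        "med_antipsychotic": rng.normal(0.0, 0.08, size=p),
    }
    return SimConfig(
        n_individuals=n_individuals,
        temporal_matrix=B,
        contemporaneous_pcor=W,
        between_cov=between,
        n_waves=n_waves,
        covariate_effects=effects,
        binarize_quantiles=quantiles,
        missing_wave_rate=missing_wave_rate,
        seed=seed,
    )
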