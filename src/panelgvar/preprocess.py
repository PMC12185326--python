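"""Panel pre-processing: eligibility, variance screening, residualization,
and the stacked sufficient statistics the estimator consumes.

The pipeline mirrors standard practice for wave-structured occurrence
panels: individuals with too few observed waves are dropped, features whose
occurrence is (nearly) constant are excluded, the remaining features are
regressed on covariates wave by wave and replaced by their residuals, and
the residual panel is stacked wave-major into a p*T vector per individual
whose mean and covariance feed the maximum-likelihood fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import (
    BASE_COVARIATES,
    MED_COLUMNS,
    WAVE_COVARIATES,
    PanelData,
)

__all__ = [
    "PanelMoments",
    "ResidualPanel",
    "filter_eligibility",
    "filter_near_zero_variance",
    "residualize",
    "compute_moments",
    "preprocess_panel",
]

DEFAULT_COVARIATES = list(BASE_COVARIATES) + list(WAVE_COVARIATES)


@dataclass
class PanelMoments:
    """Stacked sample moments: mean (length p*T), covariance (p*T x p*T), n.

    Stacking is wave-major: entries [t*p:(t+1)*p] are the features of wave
    t+1 in `feature_order`.
    """

    mean: np.ndarray
    cov: np.ndarray
    n: int
    feature_order: list[str]
    n_waves: int

    @property
    def p(self) -> int:
        return len(self.feature_order)

    def validate(self) -> None:
        pt = self.p * self.n_waves
        if self.mean.shape != (pt,) or self.cov.shape != (pt, pt):
            raise ValueError("moment dimensions inconsistent with p and T")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class ResidualPanel:
    """Panel whose feature values are covariate-adjusted residuals."""

    panel: PanelData
    retained_features: list[str]
    exclusion_log: dict = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)


def _observed_wave_counts(panel: PanelData) -> pd.Series:
    return panel.df.groupby("id")["observed"].sum()


def filter_eligibility(
    panel: PanelData, min_waves: int | None = None
) -> tuple[PanelData, int]:
    """Keep individuals observed in enough waves.

    Default threshold: more than ceil(2T/3) observed waves, which for the
    canonical six-wave design retains individuals with >= 5 observed waves
    and drops those with four or fewer.
    """
    T = panel.n_waves
    if min_waves is None:
        min_waves = math.ceil(2 * T / 3) + 1
    counts = _observed_wave_counts(panel)
    keep = counts.index[counts >= min_waves]
    n_excluded = int(panel.n_individuals - len(keep))
    if len(keep) == 0:
        raise ValueError(
            f"eligibility filter (>= {min_waves} of {T} observed waves) "
            f"removed every individual"
        )
    return panel.subset(keep), n_excluded


def filter_near_zero_variance(
    panel: PanelData,
    freq_ratio_cut: float = 19.0,
    prevalence_floor: float | None = None,
) -> tuple[PanelData, dict]:
    """Exclude features whose pooled distribution is nearly constant.

    A feature is dropped when the ratio of its most to second-most frequent
    value over observed individual-waves exceeds `freq_ratio_cut` (default
    19, the 95/5 rule), or when its minority prevalence falls below
    `prevalence_floor` (optional).  Returns the reduced panel and a log of
    feature -> (reason, statistic).
    """
    obs = panel.df[panel.df["observed"] == 1]
    log: dict = {}
    keep: list[str] = []
    for feat in panel.features:
        vals = obs[feat].dropna()
        counts = vals.value_counts()
        if len(counts) <= 1:
            log[feat] = ("zero variance", float("inf"))
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        minority = 1.0 - counts.iloc[0] / counts.sum()
        if ratio > freq_ratio_cut:
            log[feat] = ("near-zero variance (frequency ratio)", float(ratio))
        elif prevalence_floor is not None and minority < prevalence_floor:
            log[feat] = ("prevalence below floor", float(minority))
        else:
            keep.append(feat)
    if not keep:
        raise ValueError("near-zero-variance filter excluded every feature")
    reduced = PanelData(
        panel.df.drop(columns=[f for f in panel.features if f not in keep]),
        keep,
        panel.n_waves,
    )
    return reduced, log


def _design_matrix(
    df: pd.DataFrame, covariate_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded covariate design for one wave's rows."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for name in covariate_names:
        if name in ("gender", "ethnicity"):
            dummies = pd.get_dummies(df[name], prefix=name, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(df[name].to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def residualize(
    panel: PanelData,
    covariate_names: list[str] | None = None,
) -> ResidualPanel:
    """Replace each feature at each wave by its OLS residual on covariates.

    The design holds an intercept, the baseline covariates, and — when
    requested — that wave's EHR entry and word counts.  Regressions are fit
    per feature-wave on observed rows only; unobserved waves stay missing.
    Collinear design columns are handled by a minimum-norm least-squares
    solve, with a warning naming the deficient wave.
    """
    if covariate_names is None:
        covariate_names = DEFAULT_COVARIATES
    df = panel.df.sort_values(["id", "wave"]).reset_index(drop=True)
    out = df.copy()
    dropped: list[str] = []
    for wave in range(1, panel.n_waves + 1):
        rows = df.index[(df["wave"] == wave) & (df["observed"] == 1)]
        if len(rows) == 0:
            continue
        sub = df.loc[rows]
        X, names = _design_matrix(sub, covariate_names)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"rank-deficient covariate design at wave {wave} "
                f"(rank {rank} < {X.shape[1]}); minimum-norm solution used",
                stacklevel=2,
            )
            dropped.append(f"wave_{wave}")
        Y = sub[panel.features].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out.loc[rows, panel.features] = Y - X @ beta
    return ResidualPanel(
        panel=PanelData(out, list(panel.features), panel.n_waves),
        retained_features=list(panel.features),
        dropped_columns=dropped,
    )


def _stacked_frame(panel: PanelData) -> pd.DataFrame:
    """One row per individual, columns wave-major: w{t}_{feature}."""
    d = panel.df.sort_values(["id", "wave"])
    n = d["id"].nunique()
    T, p = panel.n_waves, len(panel.features)
    arr = d[panel.features].to_numpy(dtype=float).reshape(n, T * p)
    cols = [f"w{t}_{f}" for t in range(1, T + 1) for f in panel.features]
    return pd.DataFrame(arr, columns=cols, index=d["id"].unique())


def _nearest_psd(S: np.ndarray) -> tuple[np.ndarray, float]:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    clipped = np.clip(w, 0.0, None)
    repaired = V @ np.diag(clipped) @ V.T
    return 0.5 * (repaired + repaired.T), float(np.abs(w - clipped).max())


def compute_moments(
    residual_panel: ResidualPanel | PanelData,
    missing_policy: str = "pairwise",
) -> PanelMoments:
    """Stacked mean and covariance of the (residualised) panel.

    `missing_policy`: "pairwise" uses pairwise-complete observations;
    "impute" first fills missing cells with the person mean of that
    feature-wave column's feature, then the grand column mean.  If pairwise
    deletion leaves the covariance indefinite it is repaired by eigenvalue
    clipping, with the adjustment magnitude reported in a warning.
    """
    panel = residual_panel.panel if isinstance(residual_panel, ResidualPanel) else residual_panel
    wide = _stacked_frame(panel)
    p, T = len(panel.features), panel.n_waves
    if wide.shape[0] < 3:
        raise ValueError("moment computation needs at least 3 individuals")
    if missing_policy == "impute":
        arr = panel.feature_array()  # (n, T, p)
        person_mean = np.nanmean(arr, axis=1, keepdims=True)
        arr = np.where(np.isnan(arr), np.broadcast_to(person_mean, arr.shape), arr)
        col_mean = np.nanmean(arr, axis=0, keepdims=True)
        arr = np.where(np.isnan(arr), np.broadcast_to(col_mean, arr.shape), arr)
        wide = pd.DataFrame(
            arr.reshape(arr.shape[0], T * p), columns=wide.columns, index=wide.index
        )
    elif missing_policy != "pairwise":
        raise ValueError("missing_policy must be 'pairwise' or 'impute'")
    mean = wide.mean(skipna=True).to_numpy()
    cov = wide.cov(min_periods=2).to_numpy()
    if np.isnan(cov).any() or np.isnan(mean).any():
        raise ValueError(
            "moments contain missing cells; too few complete pairs"
        )
    wmin = np.linalg.eigvalsh(0.5 * (cov + cov.T)).min()
    if wmin < -1e-10:
        cov, adj = _nearest_psd(cov)
        warnings.warn(
            f"pairwise-complete covariance was indefinite; nearest-PSD "
            f"repair applied (max eigenvalue adjustment {adj:.3e})",
            stacklevel=2,
        )
    cov = 0.5 * (cov + cov.T)
    return PanelMoments(
        mean=mean,
        cov=cov,
        n=int(wide.shape[0]),
        feature_order=list(panel.features),
        n_waves=T,
    )


def preprocess_panel(
    panel: PanelData,
    covariate_names: list[str] | None = None,
    min_waves: int | None = None,
    freq_ratio_cut: float = 19.0,
    prevalence_floor: float | None = None,
    missing_policy: str = "pairwise",
    skip_variance_filter: bool = False,
    feature_subset: list[str] | None = None,
) -> tuple[PanelMoments, ResidualPanel, dict]:
    """Full pre-processing chain: eligibility -> variance screen ->
    residualization -> stacked moments.

    `feature_subset` freezes the retained features (used by the bootstrap
    and permutation stages, which must keep the full-model dimensionality);
    when given, the variance screen is skipped.
    """
    eligible, n_excluded = filter_eligibility(panel, min_waves=min_waves)
    log: dict = {"n_excluded_individuals": n_excluded}
    if feature_subset is not None:
        keep = [f for f in eligible.features if f in set(feature_subset)]
        eligible = PanelData(
            eligible.df.drop(columns=[f for f in eligible.features if f not in keep]),
            keep,
            eligible.n_waves,
        )
    elif not skip_variance_filter:
        eligible, nzv_log = filter_near_zero_variance(
            eligible, freq_ratio_cut=freq_ratio_cut,
            prevalence_floor=prevalence_floor,
        )
        log["excluded_features"] = nzv_log
    resid = residualize(eligible, covariate_names=covariate_names)
    moments = compute_moments(resid, missing_policy=missing_policy)
    return moments, resid, log
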