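"""Maximum-likelihood machinery for the fixed-effects lag-1 panel graphical VAR.

The model for individual i observed at waves t = 1..T is

    y_it = mu + a_i + eta_it,
    eta_it = B eta_{i,t-1} + zeta_it,          zeta_it ~ N(0, Sigma_zeta),
    a_i ~ N(0, Sigma_B),

with the within-person process started from its stationary distribution
(S0 solving the discrete Lyapunov equation S0 = B S0 B' + Sigma_zeta).
Stacking the T waves gives a pT-dimensional Gaussian whose covariance has
within-person blocks B^{t-s} S0 (t >= s) plus Sigma_B in every cell block,
and mean mu replicated across waves.

Estimation minimises the Gaussian ML discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - pT
               + (m - mean(theta))' Sigma^-1 (m - mean(theta))

over theta = (B, Omega_zeta, Omega_B, mu), where S and m are the sample
stacked covariance and mean.  The two precision matrices (Omega = Sigma^-1)
are parameterised by Cholesky factors with log-diagonals so every iterate is
positive definite.  Gradients are analytic: the Lyapunov sensitivity is
handled by an adjoint Lyapunov solve, so one gradient costs a handful of
p x p solves plus one pT x pT factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize
import scipy.stats

__all__ = [
    "FitIndices",
    "stationary_within_cov",
    "implied_moments",
    "saturated_df",
    "count_free_parameters",
    "count_moments",
    "fit_ml",
    "fit_ml_masked",
    "discrepancy",
    "fit_indices",
    "baseline_chi2",
    "observed_information",
]

# spectral-radius guard: the optimiser is pushed back smoothly once
# rho(B) exceeds this, keeping every accepted iterate stationary
_RHO_MAX = 0.995
_PENALTY = 1.0e6


# ---------------------------------------------------------------------------
# model-implied moments
# ---------------------------------------------------------------------------

def _dlyap(B: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve S = B S B' + Q.  Small systems go through the dense Kronecker
    solve (faster below ~12 nodes); larger ones use the bilinear transform."""
    p = B.shape[0]
    if p <= 12:
        S = np.linalg.solve(
            np.eye(p * p) - np.kron(B, B), Q.reshape(-1)
        ).reshape(p, p)
        return S
    return sla.solve_discrete_lyapunov(B, Q, method="bilinear")


def stationary_within_cov(B: np.ndarray, sigma_zeta: np.ndarray) -> np.ndarray:
    """Stationary within-person covariance S0 = B S0 B' + Sigma_zeta."""
    rho = spectral_radius(B)
    if rho >= 1.0:
        raise ValueError(
            f"temporal matrix is non-stationary (spectral radius {rho:.4f} >= 1)"
        )
    S0 = _dlyap(B, sigma_zeta)
    return 0.5 * (S0 + S0.T)


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(B))))


def implied_moments(
    B: np.ndarray,
    sigma_zeta: np.ndarray,
    sigma_between: np.ndarray,
    mu: np.ndarray,
    n_waves: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied stacked mean (length pT) and covariance (pT x pT).

    Wave-major stacking: entries [t*p:(t+1)*p] belong to wave t.  The block
    at waves (t, s) with t >= s is B^(t-s) S0 + Sigma_B; blocks below the
    diagonal are the transposes.
    """
    p = B.shape[0]
    T = int(n_waves)
    S0 = stationary_within_cov(B, sigma_zeta)
    powers = [np.eye(p)]
    for _ in range(1, T):
        powers.append(B @ powers[-1])
    lagged = [powers[h] @ S0 for h in range(T)]
    Sigma = np.empty((p * T, p * T))
    for t in range(T):
        for s in range(T):
            blk = lagged[t - s] if t >= s else lagged[s - t].T
            Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk + sigma_between
    mean = np.tile(np.asarray(mu, dtype=float), T)
    return mean, 0.5 * (Sigma + Sigma.T)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def count_free_parameters(p: int) -> int:
    """Free parameters of the saturated model: B (p^2), two symmetric
    precisions (p(p+1)/2 each) and the stationary means (p)."""
    return p * p + 2 * (p * (p + 1) // 2) + p


def count_moments(p: int, n_waves: int) -> int:
    pt = p * n_waves
    return pt + pt * (pt + 1) // 2


def saturated_df(p: int, n_waves: int) -> int:
    """Degrees of freedom of the saturated panel-GVAR covariance structure."""
    return count_moments(p, n_waves) - count_free_parameters(p)


# ---------------------------------------------------------------------------
# discrepancy + analytic gradient in "structural" coordinates
# ---------------------------------------------------------------------------

def _penalised(B: np.ndarray):
    """Smooth push-back when a line-search iterate leaves the stationary
    region.  Returns (F, dF/dB) for the penalty, or None when rho < RHO_MAX."""
    vals, vecs = np.linalg.eig(B)
    k = int(np.argmax(np.abs(vals)))
    rho = float(np.abs(vals[k]))
    if rho < _RHO_MAX:
        return None
    lam = vals[k]
    v = vecs[:, k]
    lvals, lvecs = np.linalg.eig(B.T)
    kl = int(np.argmin(np.abs(lvals - lam)))
    u = lvecs[:, kl]
    denom = u @ v
    if np.abs(denom) < 1e-12:
        grad_lam = np.zeros_like(B, dtype=complex)
    else:
        grad_lam = np.outer(u, v) / denom          # d lambda / dB
    grad_rho = np.real(np.conj(lam) * grad_lam) / max(rho, 1e-12)
    excess = rho - _RHO_MAX
    F = _PENALTY * (1.0 + excess) ** 2
    gB = _PENALTY * 2.0 * (1.0 + excess) * grad_rho
    return F, gB


def discrepancy(
    S: np.ndarray,
    mbar: np.ndarray,
    B: np.ndarray,
    sigma_zeta: np.ndarray,
    sigma_between: np.ndarray,
    mu: np.ndarray,
    n_waves: int,
    logdet_S: float,
    with_grad: bool = True,
):
    """ML discrepancy F and (optionally) its gradient.

    The gradient is returned with respect to the *structural* matrices
    (B, Sigma_zeta, Sigma_B, mu); callers chain it into whatever
    parameterisation they optimise over.
    """
    p = B.shape[0]
    T = int(n_waves)
    pT = p * T

    pen = _penalised(B)
    if pen is not None:
        F, gB = pen
        if not with_grad:
            return F
        return F, (gB, np.zeros((p, p)), np.zeros((p, p)), np.zeros(p))

    S0 = _dlyap(B, sigma_zeta)
    S0 = 0.5 * (S0 + S0.T)
    powers = [np.eye(p)]
    for _ in range(1, T):
        powers.append(B @ powers[-1])
    lagged = [powers[h] @ S0 for h in range(T)]
    Sigma = np.empty((pT, pT))
    for t in range(T):
        for s in range(T):
            blk = lagged[t - s] if t >= s else lagged[s - t].T
            Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk + sigma_between

    try:
        cf = sla.cho_factor(Sigma, lower=True)
    except sla.LinAlgError:
        big = 1e12
        if not with_grad:
            return big
        return big, (np.zeros((p, p)), np.zeros((p, p)), np.zeros((p, p)), np.zeros(p))

    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Sigma_inv = sla.cho_solve(cf, np.eye(pT))
    d = mbar - np.tile(mu, T)
    sid = Sigma_inv @ d
    F = (
        logdet
        + float(np.sum(Sigma_inv * S))
        - logdet_S
        - pT
        + float(d @ sid)
    )
    if not with_grad:
        return F

    # G_ij = dF / dSigma_ij treating all entries as free
    G = Sigma_inv - Sigma_inv @ S @ Sigma_inv - np.outer(sid, sid)
    G = 0.5 * (G + G.T)
    Gb = G.reshape(T, p, T, p)

    # lag-aggregated blocks: dF_within = sum_h tr(A_h' d(B^h S0))
    A = [Gb[np.arange(T), :, np.arange(T), :].sum(axis=0)]
    for h in range(1, T):
        idx = np.arange(h, T)
        A.append(2.0 * Gb[idx, :, idx - h, :].sum(axis=0))

    grad_B = np.zeros((p, p))
    for h in range(1, T):
        for k in range(h):
            grad_B += powers[k].T @ A[h] @ S0 @ powers[h - 1 - k].T

    P = np.zeros((p, p))
    for h in range(T):
        P += powers[h].T @ A[h]
    Ps = 0.5 * (P + P.T)
    Q = _dlyap(B.T, Ps)
    Q = 0.5 * (Q + Q.T)
    grad_B += 2.0 * Q @ B @ S0

    grad_sigma_zeta = Q
    grad_sigma_between = Gb.sum(axis=(0, 2))
    grad_sigma_between = 0.5 * (grad_sigma_between + grad_sigma_between.T)
    grad_mu = -2.0 * sid.reshape(T, p).sum(axis=0)
    return F, (grad_B, grad_sigma_zeta, grad_sigma_between, grad_mu)


# ---------------------------------------------------------------------------
# Cholesky-of-precision parameterisation (saturated fits)
# ---------------------------------------------------------------------------

def _tril_indices(p):
    return np.tril_indices(p)


def _chol_pack(L: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor -> free vector (log on the diagonal)."""
    p = L.shape[0]
    out = L[np.tril_indices(p)].copy()
    diag_pos = np.cumsum(np.arange(1, p + 1)) - 1
    out[diag_pos] = np.log(L[np.diag_indices(p)])
    return out


def _chol_unpack(v: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = v
    diag_pos = np.cumsum(np.arange(1, p + 1)) - 1
    L[np.diag_indices(p)] = np.exp(v[diag_pos])
    return L


def _chol_chain(M_K: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Chain dF/dK (K = L L', M_K symmetric) into the packed factor vector."""
    p = L.shape[0]
    GL = 2.0 * M_K @ L
    GL = np.tril(GL)
    GL[np.diag_indices(p)] *= L[np.diag_indices(p)]
    return GL[np.tril_indices(p)]


def _precision_grad(M_sigma: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """dF/dSigma -> dF/dK for K = Sigma^-1."""
    return -sigma @ M_sigma @ sigma


@dataclass
class MLFit:
    """Raw optimiser output in structural coordinates."""

    B: np.ndarray
    omega_zeta: np.ndarray
    omega_between: np.ndarray
    mu: np.ndarray
    discrepancy: float
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""

    @property
    def sigma_zeta(self) -> np.ndarray:
        return np.linalg.inv(self.omega_zeta)

    @property
    def sigma_between(self) -> np.ndarray:
        return np.linalg.inv(self.omega_between)


def _default_start(S: np.ndarray, mbar: np.ndarray, p: int, T: int):
    """Deterministic start: B = 0.1 I, the average within-wave variance split
    evenly between the within- and between-person components, means from the
    wave-averaged sample means."""
    Sbar = np.zeros((p, p))
    for t in range(T):
        Sbar += S[t * p:(t + 1) * p, t * p:(t + 1) * p]
    Sbar /= T
    v = np.clip(np.diag(Sbar), 1e-6, None)
    B0 = 0.1 * np.eye(p)
    Kz0 = np.diag(2.0 / v)
    Kb0 = np.diag(2.0 / v)
    mu0 = mbar.reshape(T, p).mean(axis=0)
    return B0, Kz0, Kb0, mu0


def _safe_logdet(S: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(ld):
        warnings.warn(
            "sample covariance is not positive definite; discrepancy offset "
            "uses a ridge-stabilised log-determinant",
            stacklevel=3,
        )
        w = np.linalg.eigvalsh(S)
        w = np.clip(w, 1e-10 * max(w.max(), 1.0), None)
        ld = float(np.sum(np.log(w)))
    return float(ld)


def fit_ml(
    S: np.ndarray,
    mbar: np.ndarray,
    p: int,
    n_waves: int,
    start: MLFit | tuple | None = None,
    gtol: float = 1e-8,
    maxiter: int = 5000,
) -> MLFit:
    """Fit the saturated panel GVAR by quasi-Newton ML.

    Parameters are (B, chol(Omega_zeta), chol(Omega_B), mu); the start is
    deterministic unless an explicit warm start is given.
    """
    T = int(n_waves)
    S = np.asarray(S, dtype=float)
    mbar = np.asarray(mbar, dtype=float)
    logdet_S = _safe_logdet(S)

    if start is None:
        B0, Kz0, Kb0, mu0 = _default_start(S, mbar, p, T)
    elif isinstance(start, MLFit):
        B0, Kz0, Kb0, mu0 = start.B, start.omega_zeta, start.omega_between, start.mu
    else:
        B0, Kz0, Kb0, mu0 = start

    Lz0 = np.linalg.cholesky(Kz0)
    Lb0 = np.linalg.cholesky(Kb0)
    nb = p * p
    nc = p * (p + 1) // 2
    x0 = np.concatenate([
        np.asarray(B0, dtype=float).ravel(),
        _chol_pack(Lz0),
        _chol_pack(Lb0),
        np.asarray(mu0, dtype=float),
    ])

    def split(x):
        B = x[:nb].reshape(p, p)
        Lz = _chol_unpack(x[nb:nb + nc], p)
        Lb = _chol_unpack(x[nb + nc:nb + 2 * nc], p)
        mu = x[nb + 2 * nc:]
        return B, Lz, Lb, mu

    def fun(x):
        B, Lz, Lb, mu = split(x)
        Kz = Lz @ Lz.T
        Kb = Lb @ Lb.T
        sigma_z = sla.cho_solve((Lz, True), np.eye(p))
        sigma_b = sla.cho_solve((Lb, True), np.eye(p))
        F, (gB, gSz, gSb, gmu) = discrepancy(
            S, mbar, B, sigma_z, sigma_b, mu, T, logdet_S
        )
        gKz = _precision_grad(gSz, sigma_z)
        gKb = _precision_grad(gSb, sigma_b)
        g = np.concatenate([
            gB.ravel(),
            _chol_chain(gKz, Lz),
            _chol_chain(gKb, Lb),
            gmu,
        ])
        return F, g

    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol, "maxcor": 30},
    )
    B, Lz, Lb, mu = split(res.x)
    Kz = Lz @ Lz.T
    Kb = Lb @ Lb.T
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-4)
    fit = MLFit(
        B=B,
        omega_zeta=0.5 * (Kz + Kz.T),
        omega_between=0.5 * (Kb + Kb.T),
        mu=mu,
        discrepancy=max(float(res.fun), 0.0),
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        message=str(res.message),
    )
    if not converged:
        warnings.warn(
            f"panel GVAR fit did not meet the gradient tolerance "
            f"(max|grad| = {grad_norm:.2e}); best-so-far parameters returned",
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# direct symmetric parameterisation with zero masks (pruned refits, Wald SEs)
# ---------------------------------------------------------------------------

def _sym_pack_indices(p):
    rows, cols = np.tril_indices(p)
    return rows, cols


def _build_masked_layout(p, mask_B, mask_Kz, mask_Kb):
    """Index layout of the free parameters in the direct parameterisation.

    mask_* entries are True where the parameter is FREE.  Diagonals of the
    precisions are always free; the masks of symmetric matrices are read on
    the lower triangle.
    """
    layout = []
    for i in range(p):
        for j in range(p):
            if mask_B[i, j]:
                layout.append(("B", i, j))
    for i in range(p):
        for j in range(i + 1):
            if i == j or mask_Kz[i, j]:
                layout.append(("Kz", i, j))
    for i in range(p):
        for j in range(i + 1):
            if i == j or mask_Kb[i, j]:
                layout.append(("Kb", i, j))
    for i in range(p):
        layout.append(("mu", i, 0))
    return layout


def _masked_fun_factory(S, mbar, p, T, layout, logdet_S):
    def unpack(x):
        B = np.zeros((p, p))
        Kz = np.zeros((p, p))
        Kb = np.zeros((p, p))
        mu = np.zeros(p)
        for val, (kind, i, j) in zip(x, layout):
            if kind == "B":
                B[i, j] = val
            elif kind == "Kz":
                Kz[i, j] = val
                Kz[j, i] = val
            elif kind == "Kb":
                Kb[i, j] = val
                Kb[j, i] = val
            else:
                mu[i] = val
        return B, Kz, Kb, mu

    def fun(x):
        B, Kz, Kb, mu = unpack(x)
        g_big = 1e12
        try:
            Lz = np.linalg.cholesky(Kz)
            Lb = np.linalg.cholesky(Kb)
        except np.linalg.LinAlgError:
            return g_big, np.zeros(len(x))
        sigma_z = sla.cho_solve((Lz, True), np.eye(p))
        sigma_b = sla.cho_solve((Lb, True), np.eye(p))
        F, (gB, gSz, gSb, gmu) = discrepancy(
            S, mbar, B, sigma_z, sigma_b, mu, T, logdet_S
        )
        gKz = _precision_grad(gSz, sigma_z)
        gKb = _precision_grad(gSb, sigma_b)
        g = np.empty(len(x))
        for k, (kind, i, j) in enumerate(layout):
            if kind == "B":
                g[k] = gB[i, j]
            elif kind == "Kz":
                g[k] = gKz[i, j] if i == j else gKz[i, j] + gKz[j, i]
            elif kind == "Kb":
                g[k] = gKb[i, j] if i == j else gKb[i, j] + gKb[j, i]
            else:
                g[k] = gmu[i]
        return F, g

    return fun, unpack


def fit_ml_masked(
    S: np.ndarray,
    mbar: np.ndarray,
    p: int,
    n_waves: int,
    start: MLFit,
    mask_B: np.ndarray | None = None,
    mask_Kz: np.ndarray | None = None,
    mask_Kb: np.ndarray | None = None,
    gtol: float = 1e-8,
    maxiter: int = 5000,
) -> MLFit:
    """Refit with selected parameters fixed to zero (sparse / pruned model).

    Parameterises B and the two precisions directly by their free entries,
    starting from `start` (typically the saturated optimum, so iterates stay
    inside the positive-definite region).
    """
    T = int(n_waves)
    S = np.asarray(S, dtype=float)
    logdet_S = _safe_logdet(S)
    if mask_B is None:
        mask_B = np.ones((p, p), dtype=bool)
    if mask_Kz is None:
        mask_Kz = np.ones((p, p), dtype=bool)
    if mask_Kb is None:
        mask_Kb = np.ones((p, p), dtype=bool)
    layout = _build_masked_layout(p, mask_B, mask_Kz, mask_Kb)
    fun, unpack = _masked_fun_factory(S, mbar, p, T, layout, logdet_S)

    x0 = []
    for kind, i, j in layout:
        if kind == "B":
            x0.append(start.B[i, j])
        elif kind == "Kz":
            x0.append(start.omega_zeta[i, j])
        elif kind == "Kb":
            x0.append(start.omega_between[i, j])
        else:
            x0.append(start.mu[i])
    x0 = np.asarray(x0)

    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol, "maxcor": 30},
    )
    B, Kz, Kb, mu = unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac)))
    return MLFit(
        B=B,
        omega_zeta=Kz,
        omega_between=Kb,
        mu=mu,
        discrepancy=max(float(res.fun), 0.0),
        converged=bool(res.success or grad_norm < 1e-4),
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def observed_information(
    S: np.ndarray,
    mbar: np.ndarray,
    fit: MLFit,
    n: int,
    n_waves: int,
    step: float = 1e-5,
):
    """Observed information in the direct parameterisation at `fit`.

    -2 log L ~ (n-1) F, so the information is 0.5 (n-1) H with H the Hessian
    of F, obtained by central differences of the analytic gradient.  Returns
    (layout, covariance of the free parameters); a ridge is added (with a
    warning) if the information is numerically singular.
    """
    p = fit.B.shape[0]
    T = int(n_waves)
    logdet_S = _safe_logdet(np.asarray(S, dtype=float))
    mask = np.ones((p, p), dtype=bool)
    layout = _build_masked_layout(p, mask, mask, mask)
    fun, _ = _masked_fun_factory(np.asarray(S, float), np.asarray(mbar, float),
                                 p, T, layout, logdet_S)
    x0 = []
    for kind, i, j in layout:
        if kind == "B":
            x0.append(fit.B[i, j])
        elif kind == "Kz":
            x0.append(fit.omega_zeta[i, j])
        elif kind == "Kb":
            x0.append(fit.omega_between[i, j])
        else:
            x0.append(fit.mu[i])
    x0 = np.asarray(x0)
    m = len(x0)
    H = np.empty((m, m))
    for k in range(m):
        h = step * max(1.0, abs(x0[k]))
        xp = x0.copy()
        xp[k] += h
        xm = x0.copy()
        xm[k] -= h
        _, gp = fun(xp)
        _, gm = fun(xm)
        H[:, k] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    info = 0.5 * (n - 1) * H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = None
    if cov is None or not np.all(np.isfinite(cov)):
        warnings.warn(
            "observed information numerically singular; ridge-stabilised "
            "inverse used for standard errors",
            stacklevel=2,
        )
        w = np.linalg.eigvalsh(info)
        ridge = max(1e-8, 1e-8 - w.min())
        cov = np.linalg.inv(info + ridge * np.eye(m))
    return layout, cov


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    """Covariance-structure fit statistics for one fitted model."""

    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    n: int
    baseline_chi2: float = field(default=np.nan)
    baseline_df: int = field(default=0)

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci_lower": self.rmsea_ci[0],
            "rmsea_ci_upper": self.rmsea_ci[1],
            "cfi": self.cfi,
            "tli": self.tli,
            "n": self.n,
            "baseline_chi2": self.baseline_chi2,
            "baseline_df": self.baseline_df,
        }


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.95):
    """Noncentrality-inversion RMSEA confidence interval (bisection to 1e-6)."""
    if df <= 0 or n <= 1:
        return (0.0, 0.0)
    alpha = 1.0 - level

    def cdf(nc):
        if nc <= 0:
            return scipy.stats.chi2.cdf(chi2, df)
        return scipy.stats.ncx2.cdf(chi2, df, nc)

    def invert(target):
        # find nc with P(X <= chi2 | df, nc) = target; cdf decreasing in nc
        if cdf(0.0) < target:
            return 0.0
        lo, hi = 0.0, max(chi2, 1.0)
        while cdf(hi) > target:
            hi *= 2.0
            if hi > 1e10:
                break
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if cdf(mid) > target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6:
                break
        return 0.5 * (lo + hi)

    nc_lo = invert(1.0 - alpha / 2.0)
    nc_hi = invert(alpha / 2.0)
    denom = df * (n - 1)
    return (float(np.sqrt(nc_lo / denom)), float(np.sqrt(nc_hi / denom)))


def fit_indices(
    chi2: float,
    df: int,
    n: int,
    baseline_chi2_value: float,
    baseline_df_value: int,
) -> FitIndices:
    """RMSEA (with 95% CI), CFI and TLI from chi-square statistics.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    CFI = 1 - max(chi2-df, 0) / max(baseline_chi2 - baseline_df, chi2-df, 0);
    TLI = [(chi2_b/df_b) - (chi2/df)] / [(chi2_b/df_b) - 1].
    """
    if df <= 0 or baseline_df_value <= 0:
        raise ValueError("df and baseline df must be positive")
    excess = max(chi2 - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1)))) if n > 1 else 0.0
    base_excess = max(baseline_chi2_value - baseline_df_value, 0.0)
    denom = max(base_excess, excess)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    base_ratio = baseline_chi2_value / baseline_df_value
    ratio = chi2 / df
    if base_ratio <= 1.0:
        if base_ratio < ratio:
            warnings.warn(
                "baseline model fits no worse than the target model; "
                "TLI clamped", stacklevel=2,
            )
        tli = 1.0 if ratio <= base_ratio else 0.0
    else:
        tli = (base_ratio - ratio) / (base_ratio - 1.0)
    p_value = float(scipy.stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        rmsea=rmsea,
        rmsea_ci=_rmsea_ci(chi2, df, n),
        cfi=float(cfi),
        tli=float(tli),
        n=int(n),
        baseline_chi2=float(baseline_chi2_value),
        baseline_df=int(baseline_df_value),
    )


def baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence baseline: diagonal covariance, free means.

    F_base = -log|R| with R the sample correlation matrix, so
    chi2 = -(n-1) log|R|; df = pT(pT+1)/2 - pT.
    """
    pT = S.shape[0]
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(d, d)
    sign, ld = np.linalg.slogdet(R)
    if sign <= 0:
        w = np.clip(np.linalg.eigvalsh(R), 1e-10, None)
        ld = float(np.sum(np.log(w)))
    chi2 = max(-(n - 1) * float(ld), 0.0)
    df = pT * (pT + 1) // 2 - pT
    return chi2, df
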