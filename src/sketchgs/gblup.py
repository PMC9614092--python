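"""Reaction-norm G-BLUP: kernels, REML variance components, BLUP prediction.

Three nested models for a multi-environment trial, indexed by the random
effects they carry beyond the intercept and i.i.d. residual:

    EL    y = mu + E_i + L_j + eps          (no markers)
    GE    y = mu + E_i + g_j + eps
    GExE  y = mu + E_i + g_j + gE_ij + eps

with Cov(y) = sum_r sigma2_r K_r + sigma2_eps I, where the kernels are
the observation-level environment incidence product, line incidence
product, genomic relationship G = XX'/d mapped to observations, and the
Schur (element-wise) product of the genomic and environment kernels for
the genotype-by-environment deviation.

Variance components are estimated by REML, profiled over the residual
variance and maximized over log variance ratios with Nelder-Mead (no
gradients, nonnegativity by construction); prediction of held-out cells
is the conditional mean of the fitted joint Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .qc import MarkerMatrix
from .reduce import ReducedMarkers

__all__ = [
    "KernelSet",
    "FittedGSModel",
    "ConvergenceError",
    "build_kernels",
    "fit_mixed_model",
    "predict_blup",
    "MODEL_COMPONENTS",
]

MODEL_COMPONENTS = {
    "EL": ("var_E", "var_L"),
    "GE": ("var_E", "var_g"),
    "GExE": ("var_E", "var_g", "var_gE"),
}

_KERNEL_OF = {"var_E": "K_E", "var_L": "K_L", "var_g": "K_g", "var_gE": "K_gE"}


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate's estimates."""

    def __init__(self, message: str, last_estimates: dict):
        super().__init__(message)
        self.last_estimates = last_estimates


@dataclass
class KernelSet:
    """Observation-level covariance kernels for one phenotype table."""

    G: np.ndarray                   # n_lines x n_lines genomic relationship
    line_ids: list
    obs: pd.DataFrame               # columns line, env, rep (one row per obs)
    K_E: np.ndarray
    K_L: np.ndarray
    K_g: np.ndarray
    K_gE: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    def kernel(self, component: str) -> np.ndarray:
        return getattr(self, _KERNEL_OF[component])


@dataclass
class FittedGSModel:
    """REML estimates plus everything needed to predict held-out cells."""

    model: str
    mu_hat: float
    var_hat: dict
    kernels: KernelSet
    training_index: np.ndarray
    y: np.ndarray                   # full observation vector, kernel order
    reml_loglik: float
    converged: bool = True
    n_evals: int = 0


def _marker_values(X) -> tuple[np.ndarray, list]:
    if isinstance(X, ReducedMarkers):
        V = X.values
        if X.mode == "projected":
            # re-standardize projected features so trace(G) = n holds for
            # every reduction method and kernels stay on a common scale
            sd = V.std(axis=0)
            if (sd == 0).any():
                keep = sd > 0
                V = V[:, keep]
                sd = sd[keep]
            V = (V - V.mean(axis=0)) / sd
        return V, list(X.line_ids)
    if isinstance(X, MarkerMatrix):
        if not X.standardized:
            raise ValueError("marker matrix must be standardized before kernels")
        return X.values, list(X.line_ids)
    raise TypeError(f"cannot build kernels from {type(X).__name__}")


def build_kernels(X, pheno: pd.DataFrame) -> KernelSet:
    """Genomic relationship and observation-level kernels.

    ``G = XX'/d`` with ``d`` the current column count; the environment,
    line, genomic and interaction kernels are expanded to observation
    rows through the incidence maps, with the interaction kernel the
    Schur product of the genomic and environment kernels (zero whenever
    two observations sit in different environments).
    """
    V, line_ids = _marker_values(X)
    d = V.shape[1]
    G = V @ V.T / d

    pos = {l: i for i, l in enumerate(line_ids)}
    missing = sorted(set(pheno["line"]) - set(pos))
    if missing:
        raise ValueError(f"phenotyped line(s) missing from markers: {missing[:5]}")
    obs = pheno[[c for c in ("line", "env", "rep") if c in pheno.columns]].reset_index(
        drop=True
    )
    li = obs["line"].map(pos).to_numpy()
    env_codes = pd.Categorical(obs["env"]).codes

    K_E = (env_codes[:, None] == env_codes[None, :]).astype(float)
    K_L = (li[:, None] == li[None, :]).astype(float)
    K_g = G[np.ix_(li, li)]
    return KernelSet(G=G, line_ids=line_ids, obs=obs, K_E=K_E, K_L=K_L, K_g=K_g,
                     K_gE=K_g * K_E)


def _profiled_neg_reml(z, y, kernels_tr, n, p=1):
    """-2x profiled REML criterion at log variance ratios ``z``."""
    W = np.eye(n)
    for g, K in zip(np.exp(z), kernels_tr):
        W += g * K
    try:
        c, low = linalg.cho_factor(W, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdetW = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    Wi_y = linalg.cho_solve((c, low), y, check_finite=False)
    Wi_1 = linalg.cho_solve((c, low), ones, check_finite=False)
    xtwx = float(ones @ Wi_1)
    mu = float(ones @ Wi_y) / xtwx
    ypy = float(y @ Wi_y) - xtwx * mu ** 2
    if ypy <= 0:
        return np.inf, None
    crit = logdetW + np.log(xtwx) + (n - p) * np.log(ypy)
    return crit, (mu, ypy, logdetW, xtwx)


def fit_mixed_model(
    pheno: pd.DataFrame,
    kernels: KernelSet,
    model: str,
    training_index: np.ndarray | None = None,
    max_evals: int = 500,
    tol: float = 1e-6,
) -> FittedGSModel:
    """REML fit of one model on the training observations.

    Maximizes the restricted likelihood over log variance ratios
    ``sigma2_r / sigma2_eps`` (Nelder-Mead, residual variance profiled
    out), then recovers the component estimates and the GLS intercept.
    Components driven to the boundary are reported as exactly 0.
    """
    if model not in MODEL_COMPONENTS:
        raise ValueError(f"model must be one of {sorted(MODEL_COMPONENTS)}")
    y_full = pheno["value"].to_numpy(dtype=float)
    if len(y_full) != kernels.n_obs:
        raise ValueError("phenotype table does not match kernel set")
    if training_index is None:
        training_index = np.arange(kernels.n_obs)
    training_index = np.asarray(training_index, dtype=int)
    if training_index.size == 0:
        raise ValueError("training_index is empty")

    comps = MODEL_COMPONENTS[model]
    tr = training_index
    ktr = [kernels.kernel(c)[np.ix_(tr, tr)] for c in comps]
    y = y_full[tr]
    n, p = y.size, 1

    def objective(z):
        return _profiled_neg_reml(np.clip(z, -30.0, 30.0), y, ktr, n)[0]

    # Nelder-Mead with restarts inside one evaluation budget: a restart
    # rebuilds the simplex around the current best point, which resolves
    # the slow creep along boundary plateaus (components pinned near 0)
    x = np.zeros(len(comps))
    used = 0
    res = None
    for _attempt in range(3):
        res = optimize.minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={
                "maxfev": max_evals,
                "fatol": tol,
                "xatol": 1e-4,
                "adaptive": len(comps) > 2,
            },
        )
        used += res.nfev
        x = res.x
        if res.success:
            break
    res.x = np.clip(x, -30.0, 30.0)
    crit, aux = _profiled_neg_reml(res.x, y, ktr, n)
    if aux is None or not np.isfinite(crit):
        raise ConvergenceError("REML objective not finite at optimum", {})
    mu, ypy, logdetW, xtwx = aux
    s2e = ypy / (n - p)
    gammas = np.exp(res.x)
    var_hat = {"var_eps": float(s2e)}
    for name, g in zip(comps, gammas):
        v = float(g * s2e)
        var_hat[name] = 0.0 if g < 1e-8 else v
    if not res.success:
        raise ConvergenceError(
            f"REML did not converge within {max_evals} evaluations",
            {"mu_hat": mu, **var_hat},
        )
    loglik = -0.5 * (
        (n - p) * np.log(s2e)
        + logdetW
        + np.log(xtwx)
        + (n - p)
        + (n - p) * np.log(2 * np.pi)
    )
    return FittedGSModel(
        model=model,
        mu_hat=float(mu),
        var_hat=var_hat,
        kernels=kernels,
        training_index=tr,
        y=y_full,
        reml_loglik=float(loglik),
        converged=bool(res.success),
        n_evals=used,
    )


def _conditional_mean(fit: FittedGSModel, train: np.ndarray, test: np.ndarray):
    """mu + C[test, train] V[train]^-1 (y_train - mu) from fitted components."""
    comps = MODEL_COMPONENTS[fit.model]
    K = fit.kernels
    C_tt = np.zeros((test.size, train.size))
    V_tr = np.zeros((train.size, train.size))
    for c in comps:
        full = K.kernel(c)
        s2 = fit.var_hat.get(c, 0.0)
        if s2 > 0:
            C_tt += s2 * full[np.ix_(test, train)]
            V_tr += s2 * full[np.ix_(train, train)]
    V_tr[np.diag_indices_from(V_tr)] += fit.var_hat["var_eps"]
    resid = fit.y[train] - fit.mu_hat
    try:
        sol = linalg.cho_solve(linalg.cho_factor(V_tr, check_finite=False), resid)
    except linalg.LinAlgError:
        V_tr[np.diag_indices_from(V_tr)] += 1e-8 * np.trace(V_tr) / train.size
        sol = linalg.cho_solve(linalg.cho_factor(V_tr, check_finite=False), resid)
    return fit.mu_hat + C_tt @ sol


def predict_blup(fit: FittedGSModel, test_index: np.ndarray) -> np.ndarray:
    """BLUP predictions for held-out observations.

    The conditional mean of the joint Gaussian implied by the fitted
    components: observations in an environment absent from training get
    zero environment and interaction cross-covariance, so their
    prediction reduces to the intercept plus the genomic (or line) term.
    """
    test = np.asarray(test_index, dtype=int)
    if np.intersect1d(test, fit.training_index).size:
        raise ValueError("test_index overlaps the training observations")
    return _conditional_mean(fit, fit.training_index, test)
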