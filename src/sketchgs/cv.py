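"""Cross-validation schemes, within-environment accuracy, trend summary.

Three schemes mirror the questions a breeder asks of a multi-environment
trial: CV0 predicts all lines in an entirely new environment
(leave-one-environment-out, deterministic), CV1 predicts entirely new
lines (5 folds over lines, repeated), and CV2 predicts line-environment
cells left out completely at random (5 folds over observations,
repeated).  Accuracy is the Pearson correlation between observed values
and predictions computed separately within each environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import FittedGSModel, KernelSet, _conditional_mean, fit_mixed_model

__all__ = [
    "CVResult",
    "TrendSummary",
    "within_env_correlation",
    "run_cv",
    "summarize_trend",
]

SCHEMES = ("CV0", "CV1", "CV2")


@dataclass
class CVResult:
    """Per-environment correlations collected over folds and replicates."""

    scheme: str
    model: str
    per_env_corr: dict                     # env -> list of defined correlations
    n_reps: int
    fold_assignments: list = field(default_factory=list)
    n_undefined: int = 0

    def env_means(self) -> dict:
        return {e: float(np.mean(v)) for e, v in self.per_env_corr.items() if v}

    @property
    def mean_correlation(self) -> float:
        """Headline accuracy: average the per-environment means."""
        means = self.env_means()
        if not means:
            return float("nan")
        return float(np.mean(list(means.values())))

    def pooled_correlation_values(self) -> list:
        return [c for v in self.per_env_corr.values() for c in v]


def within_env_correlation(observed, predicted, env_labels, min_pairs: int = 3) -> dict:
    """Pearson correlation of observed vs predicted within each environment.

    Environments with fewer than ``min_pairs`` pairs or zero variance in
    either vector are flagged undefined (NaN), never coerced to a number.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    envs = np.asarray(env_labels)
    if not (obs.size == pred.size == envs.size):
        raise ValueError("observed, predicted and env_labels must align")
    out = {}
    for e in pd.unique(envs):
        m = envs == e
        o, p = obs[m], pred[m]
        # relative floor so numerically-constant predictions flag undefined
        o_const = o.std() <= 1e-10 * max(1.0, np.abs(o).max())
        p_const = p.std() <= 1e-10 * max(1.0, np.abs(p).max())
        if o.size < min_pairs or o_const or p_const:
            out[e] = float("nan")
        else:
            out[e] = float(np.corrcoef(o, p)[0, 1])
    return out


def _folds_for_scheme(scheme, obs, rng, n_folds=5):
    """List of test-index arrays for one replicate of a scheme."""
    if scheme == "CV0":
        envs = pd.unique(obs["env"])
        return [np.nonzero((obs["env"] == e).to_numpy())[0] for e in envs]
    if scheme == "CV1":
        lines = pd.unique(obs["line"])
        perm = rng.permutation(len(lines))
        groups = np.array_split(np.asarray(lines)[perm], n_folds)
        return [
            np.nonzero(obs["line"].isin(g).to_numpy())[0] for g in groups if g.size
        ]
    if scheme == "CV2":
        idx = rng.permutation(len(obs))
        return [np.sort(f) for f in np.array_split(idx, n_folds)]
    raise ValueError(f"unknown scheme {scheme!r}")


def run_cv(
    pheno: pd.DataFrame,
    kernels: KernelSet,
    model: str,
    scheme: str,
    n_reps: int = 20,
    seed: int = 0,
    refit_per_fold: bool = True,
    base_fit: FittedGSModel | None = None,
    n_folds: int = 5,
    min_test: int = 3,
) -> CVResult:
    """Run one cross-validation scheme for one model.

    CV0 is deterministic with exactly one fold (and one correlation) per
    environment; CV1/CV2 draw ``n_reps`` independent 5-fold partitions
    reproducible from ``(seed, replicate index)``.  With
    ``refit_per_fold=False`` the variance components of ``base_fit`` (or
    a single full-data REML fit) are reused and only the BLUP system is
    re-solved per fold — the standard shortcut for large grids.
    Undefined per-environment correlations are excluded and counted.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    obs = kernels.obs
    if scheme == "CV0":
        if obs["env"].nunique() < 2:
            raise ValueError("CV0 requires at least two environments")
        n_reps = 1

    if not refit_per_fold and base_fit is None:
        base_fit = fit_mixed_model(pheno, kernels, model)

    y = pheno["value"].to_numpy(dtype=float)
    env = obs["env"].to_numpy()
    all_idx = np.arange(len(obs))
    per_env: dict = {e: [] for e in pd.unique(env)}
    assignments, n_undef = [], 0

    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        folds = _folds_for_scheme(scheme, obs, rng)
        assignments.append(folds)
        for test in folds:
            train = np.setdiff1d(all_idx, test)
            if refit_per_fold:
                fit = fit_mixed_model(pheno, kernels, model, training_index=train)
                pred = _conditional_mean(fit, train, test)
            else:
                pred = _conditional_mean(base_fit, train, test)
            corr = within_env_correlation(y[test], pred, env[test], min_pairs=min_test)
            for e, c in corr.items():
                if np.isnan(c):
                    n_undef += 1
                else:
                    per_env[e].append(c)
    return CVResult(
        scheme=scheme,
        model=model,
        per_env_corr=per_env,
        n_reps=n_reps,
        fold_assignments=assignments,
        n_undefined=n_undef,
    )


@dataclass
class TrendSummary:
    """Accuracy-versus-size curve and its 95%-of-max operating point."""

    size_grid: list
    mean_corr: list
    se_corr: list
    size_95: int
    corr_at_95: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.size_grid, "mean_corr": self.mean_corr, "se_corr": self.se_corr}
        )


def summarize_trend(results: dict) -> TrendSummary:
    """Size -> accuracy curve with the smallest size at 95% of the max.

    ``results`` maps marker-count sizes to either a CVResult, a float
    mean correlation, or a sequence of correlations.  ``size_95`` is the
    smallest evaluated size whose mean correlation reaches 95% of the
    maximum mean correlation over the grid.
    """
    if len(results) < 2:
        raise ValueError("need at least two evaluated sizes")
    sizes = sorted(results)
    means, ses = [], []
    for k in sizes:
        v = results[k]
        if isinstance(v, CVResult):
            vals = v.pooled_correlation_values()
            means.append(v.mean_correlation)
            ses.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0)
        elif np.isscalar(v):
            means.append(float(v))
            ses.append(0.0)
        else:
            vals = np.asarray(v, dtype=float)
            means.append(float(vals.mean()))
            ses.append(float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0)
    arr = np.asarray(means)
    if np.isnan(arr).all():
        raise ValueError("all correlations undefined")
    best = np.nanmax(arr)
    ok = np.nonzero(arr >= 0.95 * best)[0]
    i95 = int(ok[0])
    return TrendSummary(
        size_grid=sizes,
        mean_corr=means,
        se_corr=ses,
        size_95=sizes[i95],
        corr_at_95=means[i95],
    )
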