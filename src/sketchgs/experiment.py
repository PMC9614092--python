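"""Full experiment grid: methods x sizes x models x CV schemes x replicates.

Orchestrates the pipeline end to end on a standardized marker matrix and
phenotype table: reduced marker sets are generated per (method, size,
replicate) with seeds fanned out deterministically from one master seed,
each reduced set is pushed through kernel construction, model fitting
and the requested cross-validation schemes, replicate results are
averaged reduction-replicate-first, and accuracy-versus-size trends are
summarized per (method, model, scheme).  The environment+line baseline
is evaluated once — marker reduction cannot affect it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cv import CVResult, run_cv, summarize_trend
from .gblup import build_kernels, fit_mixed_model
from .qc import MarkerMatrix
from .rnla import approx_leverage, exact_leverage, importance_distribution
from .reduce import (
    METHODS,
    marker_tree,
    reduce_cluster,
    reduce_deterministic,
    reduce_random_projection,
    reduce_random_sampling,
    reduce_ridge,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "default_size_grid"]

RANDOMIZED = {"ran_proj", "ran_sample", "cluster"}


def default_size_grid(d: int, n_sizes: int = 26, start: int = 200) -> list:
    """A grid of ``n_sizes`` marker counts from ``start`` to ``d``.

    Log-spaced between the endpoints (duplicates collapsed toward
    neighbouring values), always ending at the full size ``d``.
    """
    if d <= start:
        return sorted({max(1, d // 2), d})
    raw = np.unique(
        np.round(np.geomspace(start, d, n_sizes)).astype(int)
    )
    raw[-1] = d
    return sorted(np.unique(raw).tolist())


@dataclass
class ExperimentConfig:
    """Grid definition and replicate counts for one experiment run."""

    size_grid: list = field(default_factory=list)   # default built from d
    methods: tuple = METHODS
    models: tuple = ("GE", "GExE")
    schemes: tuple = ("CV0", "CV1", "CV2")
    n_dr_reps: int = 100
    n_cv_reps: int = 20
    master_seed: int = 0
    leverage: str = "approx"                        # "approx" | "exact" (sampling probs)
    det_rank: int | None = None                     # SVD rank for deterministic ranking
                                                    # (None: components above average
                                                    # variance, a Kaiser-style rule)
    refit_per_fold: bool = False
    include_baseline: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.size_grid and sorted(self.size_grid) != list(self.size_grid):
            raise ValueError("size_grid must be sorted ascending")
        if self.n_dr_reps < 1 or self.n_cv_reps < 1:
            raise ValueError("replicate counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("methods", "models", "schemes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExperimentResult:
    """Long-format correlations, per-cell aggregates, trends, provenance."""

    long: pd.DataFrame        # method, model, scheme, size, dr_rep, environment, correlation
    cells: pd.DataFrame       # method, model, scheme, size -> mean corr over DR reps
    trends: pd.DataFrame      # method, model, scheme -> size_95, corr_at_95
    provenance: list
    failures: list

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(out / "results_long.tsv", sep="\t", index=False)
        self.cells.to_csv(out / "results_cells.tsv", sep="\t", index=False)
        self.trends.to_csv(out / "trend_summary.tsv", sep="\t", index=False)
        with open(out / "provenance.jsonl", "w") as fh:
            for rec in self.provenance:
                fh.write(json.dumps(rec, default=str) + "\n")


def cell_seed(master_seed: int, method: str, size: int, rep: int) -> int:
    """Deterministic per-cell seed: a pure function of its coordinates."""
    mi = METHODS.index(method)
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(mi, size, rep))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _reduced_for(method, X, k, seed, det_scores, probs, ranking_cache, pheno):
    if method == "ran_proj":
        return reduce_random_projection(X, k, seed)
    if method == "ran_sample":
        return reduce_random_sampling(X, k, probs, seed)
    if method == "det_sample":
        return reduce_deterministic(X, k, det_scores)
    if method == "cluster":
        return reduce_cluster(X, k, seed)
    if method == "ridge":
        if "ranking" not in ranking_cache:
            y_line = pheno.groupby("line")["value"].mean()
            y = y_line.reindex(X.line_ids).to_numpy()
            _, ranking = reduce_ridge(X, y, k=X.n_markers, seed=seed)
            ranking_cache["ranking"] = ranking
        order = ranking_cache["ranking"].order
        from .reduce import _select

        return _select(X, order[:k], "ridge", seed)
    raise ValueError(method)


def run_experiment(
    config: ExperimentConfig, genotypes: MarkerMatrix, phenotypes: pd.DataFrame
) -> ExperimentResult:
    """Execute the full grid and aggregate accuracies.

    ``genotypes`` must already be cleaned and standardized.  Stage
    failures are recorded per cell and the run continues.
    """
    X = genotypes
    if not X.standardized:
        raise ValueError("genotypes must be standardized (see sketchgs.qc)")
    d = X.n_markers
    sizes = list(config.size_grid) or default_size_grid(d)
    if sizes[-1] > d:
        raise ValueError(f"size_grid max {sizes[-1]} exceeds marker count {d}")

    t0 = time.time()
    if config.leverage == "exact":
        scores = exact_leverage(X)
    else:
        scores = approx_leverage(X, seed=cell_seed(config.master_seed, "ran_sample", 0, 0))
    probs = importance_distribution(scores)
    det_scores = None
    if "det_sample" in config.methods:
        det_rank = config.det_rank
        if det_rank is None:
            # components with above-average variance span the structure the
            # deterministic ranking should target
            sv = np.linalg.svd(X.values, compute_uv=False)
            det_rank = max(1, int((sv**2 > (sv**2).mean()).sum()))
        det_scores = exact_leverage(X, k=det_rank)
    if "cluster" in config.methods:
        marker_tree(X)  # warm the cache once
    provenance = [
        {
            "stage": "setup",
            "leverage": config.leverage,
            "n_lines": X.n_lines,
            "n_markers": d,
            "sizes": sizes,
            "master_seed": config.master_seed,
            "elapsed_s": round(time.time() - t0, 3),
        }
    ]

    rows, cell_rows, failures = [], [], []
    ranking_cache: dict = {}

    for method in config.methods:
        n_reps = config.n_dr_reps if method in RANDOMIZED else 1
        for size in sizes:
            t_cell = time.time()
            # per-(method, size, model, scheme): collect per-rep headline means
            agg: dict = {(m, s): [] for m in config.models for s in config.schemes}
            for rep in range(n_reps):
                seed = cell_seed(config.master_seed, method, size, rep)
                try:
                    red = _reduced_for(
                        method, X, size, seed, det_scores, probs, ranking_cache, phenotypes
                    )
                    kern = build_kernels(red, phenotypes)
                    for model in config.models:
                        base = (
                            None
                            if config.refit_per_fold
                            else fit_mixed_model(phenotypes, kern, model)
                        )
                        for scheme in config.schemes:
                            res = run_cv(
                                phenotypes,
                                kern,
                                model,
                                scheme,
                                n_reps=config.n_cv_reps,
                                seed=seed,
                                refit_per_fold=config.refit_per_fold,
                                base_fit=base,
                            )
                            agg[(model, scheme)].append(res.mean_correlation)
                            for e, vals in res.per_env_corr.items():
                                if vals:
                                    rows.append(
                                        (method, model, scheme, size, rep, e,
                                         float(np.mean(vals)))
                                    )
                except Exception as exc:  # keep the grid running
                    failures.append(
                        {"method": method, "size": size, "rep": rep, "error": repr(exc)}
                    )
                    logger.warning("cell failed: %s size=%d rep=%d: %r", method, size, rep, exc)
            for (model, scheme), vals in agg.items():
                ok = [v for v in vals if np.isfinite(v)]
                cell_rows.append(
                    (method, model, scheme, size,
                     float(np.mean(ok)) if ok else float("nan"), len(ok))
                )
            provenance.append(
                {
                    "stage": "cell",
                    "method": method,
                    "size": size,
                    "n_dr_reps": n_reps,
                    "elapsed_s": round(time.time() - t_cell, 3),
                }
            )

    long = pd.DataFrame(
        rows,
        columns=["method", "model", "scheme", "size", "dr_rep", "environment", "correlation"],
    )
    cells = pd.DataFrame(
        cell_rows, columns=["method", "model", "scheme", "size", "mean_corr", "n_reps_ok"]
    )

    if config.include_baseline:
        kern_full = build_kernels(X, phenotypes)
        for scheme in config.schemes:
            try:
                res = run_cv(
                    phenotypes,
                    kern_full,
                    "EL",
                    scheme,
                    n_reps=config.n_cv_reps,
                    seed=cell_seed(config.master_seed, METHODS[0], d, 10_000),
                    refit_per_fold=config.refit_per_fold,
                )
                cells.loc[len(cells)] = ["baseline", "EL", scheme, d,
                                         res.mean_correlation, 1]
            except Exception as exc:
                failures.append({"method": "baseline", "scheme": scheme, "error": repr(exc)})

    trend_rows = []
    for (method, model, scheme), grp in cells[cells["method"] != "baseline"].groupby(
        ["method", "model", "scheme"]
    ):
        curve = dict(zip(grp["size"], grp["mean_corr"]))
        if len(curve) >= 2:
            ts = summarize_trend(curve)
            trend_rows.append(
                (method, model, scheme, ts.size_95, ts.corr_at_95, max(ts.mean_corr))
            )
    trends = pd.DataFrame(
        trend_rows,
        columns=["method", "model", "scheme", "size_95", "corr_at_95", "max_corr"],
    )
    provenance.append({"stage": "done", "config": asdict(config),
                       "n_failures": len(failures),
                       "elapsed_s": round(time.time() - t0, 3)})
    return ExperimentResult(
        long=long, cells=cells, trends=trends, provenance=provenance, failures=failures
    )
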