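"""Synthetic multi-environment genomic-prediction data with known truth.

Generates (i) an allele-dosage matrix with LD-block correlation via a
latent-Gaussian haplotype model and (ii) long-format phenotypes from the
reaction-norm variance-component model

    y_ijk = mu + E_i + g_j + gE_ij + eps_ijk,

with E_i ~ N(0, var_E), genomic values g built from a random causal
subset of standardized markers and rescaled so their realized population
variance equals var_g exactly, the genotype-by-environment deviation gE
drawn from the Schur-product covariance var_gE * [Z_g G Z_g'] o [Z_e Z_e'],
and i.i.d. residuals.  An optional non-genomic line effect L_j ~
N(0, var_L) supports the environment+line baseline model.

The generator emulates the shape of a multi-environment screening-nursery trial
(hundreds of lines, ~10 environments, tens of thousands of SNPs); it is
the test bed for the dimensionality-reduction pipeline, not a model of
any particular species' LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qc import MarkerMatrix, standardize

__all__ = [
    "TrueVariances",
    "SimConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotypes",
    "write_phenotypes",
    "read_phenotypes",
]


@dataclass(frozen=True)
class TrueVariances:
    """True variance components of the generating model (trait units^2)."""

    mu: float = 0.0
    var_E: float = 1.0
    var_L: float = 0.0
    var_g: float = 1.0
    var_gE: float = 0.0
    var_eps: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_E", "var_L", "var_g", "var_gE", "var_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Shape and parameters of one simulated multi-environment trial."""

    n_lines: int = 315
    n_markers: int = 26_817
    n_envs: int = 9
    reps_per_cell: int = 1
    block_size: int = 50
    within_block_rho: float = 0.5
    # optional LD heterogeneity: per-block correlation drawn uniformly from
    # this range (overrides within_block_rho when set); heterogeneous LD
    # gives markers a decaying leverage profile, as seen in real SNP panels
    rho_range: tuple[float, float] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 500
    var_components: TrueVariances = field(default_factory=TrueVariances)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie inside (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        if self.rho_range is not None:
            rlo, rhi = self.rho_range
            if not 0.0 <= rlo <= rhi < 1.0:
                raise ValueError("rho_range must lie inside [0, 1)")
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        for name in ("n_lines", "n_markers", "n_envs", "reps_per_cell", "block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Drawn effects and realized variances retained for oracle checks."""

    mu: float
    env_effects: np.ndarray          # length I
    line_effects: np.ndarray         # length J (non-genomic, 0 if var_L = 0)
    genetic_values: np.ndarray       # length J, realized pop. variance = var_g
    ge_effects: np.ndarray           # one per (env, line) cell
    causal_indices: np.ndarray
    causal_betas: np.ndarray
    realized_var_g: float
    realized_var_eps: float


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent RNG substreams fanned out from one integer seed."""
    root = np.random.SeedSequence(seed)
    keys = ("genotypes", "effects", "noise")
    return {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}


def simulate_genotypes(config: SimConfig) -> MarkerMatrix:
    """Draw an ``n_lines x n_markers`` dosage matrix with LD blocks.

    Two latent Gaussian "haplotype" draws per line share an equicorrelated
    factor within each block of ``block_size`` consecutive markers
    (correlation ``within_block_rho``; blocks independent); each latent
    value is thresholded at the quantile of that marker's allele
    frequency, drawn uniformly from ``maf_range``, and the two resulting
    alleles are summed to a 0/1/2 dosage.
    """
    rng = _substreams(config.seed)["genotypes"]
    n, d = config.n_lines, config.n_markers
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=d)
    thresh = stats.norm.ppf(maf)

    n_blocks = -(-d // config.block_size)
    if config.rho_range is not None:
        rhos = rng.uniform(config.rho_range[0], config.rho_range[1], size=n_blocks)
    else:
        rhos = np.full(n_blocks, config.within_block_rho)

    dosage = np.zeros((n, d), dtype=float)
    for b, start in enumerate(range(0, d, config.block_size)):
        width = min(config.block_size, d - start)
        sq, sr = np.sqrt(rhos[b]), np.sqrt(1.0 - rhos[b])
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            z = sq * shared + sr * rng.standard_normal((n, width))
            dosage[:, start : start + width] += z < thresh[start : start + width]
    return MarkerMatrix(dosage)


def simulate_phenotypes(
    markers: MarkerMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the phenotype table for every (env, line, replicate) cell.

    Returns a long-format frame with columns ``line``, ``env``, ``rep``,
    ``value`` and the :class:`TruthRecord` of drawn effects.  Causal
    markers are chosen uniformly among polymorphic markers; monomorphic
    markers are never causal (the generator resamples the causal set from
    the polymorphic pool and errors only if the pool is too small).
    """
    if markers.n_lines != config.n_lines:
        raise ValueError("marker matrix does not match config.n_lines")
    vc = config.var_components
    streams = _substreams(config.seed)
    rng_eff, rng_noise = streams["effects"], streams["noise"]

    n, I, r = config.n_lines, config.n_envs, config.reps_per_cell
    poly = np.nonzero(markers.values.std(axis=0) > 0)[0]
    if poly.size < config.n_causal:
        raise ValueError(
            f"only {poly.size} polymorphic markers available for "
            f"{config.n_causal} causal effects"
        )

    # genomic values from standardized causal markers, rescaled so the
    # realized population variance across lines is exactly var_g
    g = np.zeros(n)
    causal = np.sort(rng_eff.choice(poly, size=config.n_causal, replace=False))
    beta = rng_eff.standard_normal(config.n_causal)
    if vc.var_g > 0:
        Zc = standardize(markers.subset_markers(causal)).values
        raw = Zc @ beta
        sd = raw.std()
        if sd == 0:
            raise ValueError("degenerate genomic values (all causal effects cancel)")
        beta = beta * np.sqrt(vc.var_g) / sd
        g = raw * np.sqrt(vc.var_g) / sd
    else:
        beta = np.zeros(config.n_causal)

    E = rng_eff.normal(0.0, np.sqrt(vc.var_E), size=I) if vc.var_E > 0 else np.zeros(I)
    L = rng_eff.normal(0.0, np.sqrt(vc.var_L), size=n) if vc.var_L > 0 else np.zeros(n)

    # one cell per (env, line); gE from the Schur-product covariance
    env_idx = np.repeat(np.arange(I), n)
    line_idx = np.tile(np.arange(n), I)
    if vc.var_gE > 0:
        Xs = standardize(markers.subset_markers(poly)).values
        G = Xs @ Xs.T / Xs.shape[1]
        env_match = (env_idx[:, None] == env_idx[None, :]).astype(float)
        cov = vc.var_gE * G[np.ix_(line_idx, line_idx)] * env_match
        cov[np.diag_indices_from(cov)] += 1e-8
        chol = np.linalg.cholesky(cov)
        gE = chol @ rng_eff.standard_normal(cov.shape[0])
    else:
        gE = np.zeros(I * n)

    cell_mean = vc.mu + E[env_idx] + L[line_idx] + g[line_idx] + gE
    eps = (
        rng_noise.normal(0.0, np.sqrt(vc.var_eps), size=(I * n, r))
        if vc.var_eps > 0
        else np.zeros((I * n, r))
    )
    y = cell_mean[:, None] + eps

    pheno = pd.DataFrame(
        {
            "line": np.repeat([markers.line_ids[j] for j in line_idx], r),
            "env": np.repeat([f"E{i:02d}" for i in env_idx], r),
            "rep": np.tile(np.arange(1, r + 1), I * n),
            "value": y.ravel(),
        }
    )
    truth = TruthRecord(
        mu=vc.mu,
        env_effects=E,
        line_effects=L,
        genetic_values=g,
        ge_effects=gE,
        causal_indices=causal,
        causal_betas=beta,
        realized_var_g=float(g.var()),
        realized_var_eps=float(eps.var()) if eps.size > 1 else 0.0,
    )
    return pheno, truth


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    """Write the long-format phenotype table as TSV."""
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a TSV phenotype table (columns line, env, rep, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "env": str})
    missing = {"line", "env", "rep", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df
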