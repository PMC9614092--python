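"""Marker-matrix container, quality control, and standardization.

Genotypes are held as an ``n_lines x n_markers`` allele-dosage matrix
(0/1/2 with NaN for missing).  All downstream kernels are built from the
centered-and-scaled version of this matrix, standardized with the
*population* (divisor ``n``) variance so that ``trace(XX'/d) = n`` holds
exactly — the identity the genomic relationship matrix is tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "clean_markers",
    "standardize",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
]


@dataclass
class MarkerMatrix:
    """Lines x markers dosage or standardized matrix with row/column IDs.

    Parameters
    ----------
    values
        ``(n_lines, n_markers)`` float array.  Dosages in {0, 1, 2} with
        NaN for missing, or centered/scaled values if ``standardized``.
    line_ids, marker_ids
        Unique labels for rows and columns.
    standardized
        True once every column has mean 0 and population variance 1.
    """

    values: np.ndarray
    line_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D lines x markers matrix")
        n, d = self.values.shape
        if not self.line_ids:
            self.line_ids = [f"L{i:04d}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"M{j:05d}" for j in range(d)]
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        if len(self.line_ids) != n:
            raise ValueError("line_ids length does not match row count")
        if len(self.marker_ids) != d:
            raise ValueError("marker_ids length does not match column count")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line IDs")
        if len(set(self.marker_ids)) != d:
            raise ValueError("duplicate marker IDs")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, columns: np.ndarray) -> "MarkerMatrix":
        """New matrix keeping ``columns`` (integer indices) in order."""
        cols = np.asarray(columns, dtype=int)
        return MarkerMatrix(
            self.values[:, cols],
            line_ids=self.line_ids,
            marker_ids=[self.marker_ids[j] for j in cols],
            standardized=self.standardized,
        )


@dataclass
class QCReport:
    """Counts of markers/lines removed by each cleaning filter."""

    n_markers_in: int = 0
    n_lines_in: int = 0
    removed_missing: int = 0
    removed_maf: int = 0
    removed_monomorphic: int = 0
    lines_removed: int = 0
    n_imputed: int = 0
    n_markers_out: int = 0
    n_lines_out: int = 0


def clean_markers(
    raw: MarkerMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    impute: str = "mean",
    line_max_missing: float = 0.10,
) -> tuple[MarkerMatrix, QCReport]:
    """Filter markers on missingness and minor-allele frequency.

    Markers with a missing fraction above ``max_missing`` or a MAF below
    ``maf_min`` are removed, as are monomorphic markers; lines whose
    missing fraction across the retained markers exceeds
    ``line_max_missing`` are dropped; remaining gaps are imputed with the
    per-marker mean dosage (the only ``impute`` rule implemented).  The
    operation is idempotent at fixed thresholds.
    """
    if impute != "mean":
        raise ValueError(f"unknown imputation rule: {impute!r}")
    V = raw.values.copy()
    n, d = V.shape
    rep = QCReport(n_markers_in=d, n_lines_in=n)

    miss = np.isnan(V)
    keep_missing = miss.mean(axis=0) <= max_missing
    rep.removed_missing = int((~keep_missing).sum())

    V = V[:, keep_missing]
    marker_ids = [m for m, k in zip(raw.marker_ids, keep_missing) if k]

    line_keep = np.isnan(V).mean(axis=1) <= line_max_missing if V.size else np.ones(n, bool)
    rep.lines_removed = int((~line_keep).sum())
    V = V[line_keep]
    line_ids = [l for l, k in zip(raw.line_ids, line_keep) if k]

    with np.errstate(invalid="ignore"):
        p = np.nanmean(V, axis=0) / 2.0  # allele frequency of the counted allele
    maf = np.minimum(p, 1.0 - p)
    poly = np.nanvar(V, axis=0) > 0
    keep_maf = maf >= maf_min
    rep.removed_monomorphic = int((~poly & keep_maf).sum())
    rep.removed_maf = int((~keep_maf).sum())
    keep = keep_maf & poly
    V = V[:, keep]
    marker_ids = [m for m, k in zip(marker_ids, keep) if k]

    if V.shape[1] == 0:
        raise ValueError("all markers removed by QC filters")

    miss = np.isnan(V)
    rep.n_imputed = int(miss.sum())
    if rep.n_imputed:
        col_mean = np.nanmean(V, axis=0)
        V[miss] = np.take(col_mean, np.nonzero(miss)[1])

    rep.n_lines_out, rep.n_markers_out = V.shape
    return MarkerMatrix(V, line_ids=line_ids, marker_ids=marker_ids), rep


def standardize(markers: MarkerMatrix) -> MarkerMatrix:
    """Center each marker and scale to unit population variance.

    Uses the divisor-``n`` variance so that ``trace(XX'/d) = n`` exactly.
    Raises if any marker has zero variance (run :func:`clean_markers`
    first).
    """
    V = markers.values
    if np.isnan(V).any():
        raise ValueError("missing values present; clean/impute before standardizing")
    mu = V.mean(axis=0)
    sd = V.std(axis=0)  # ddof=0
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance marker(s): {[markers.marker_ids[j] for j in zero[:5]]}"
        )
    X = (V - mu) / sd
    return replace(markers, values=X, standardized=True)


# -- delimited text I/O ------------------------------------------------------

def write_genotypes(markers: MarkerMatrix, path) -> None:
    """Write lines x markers dosages as TSV (first column = line ID)."""
    df = pd.DataFrame(markers.values, index=markers.line_ids, columns=markers.marker_ids)
    df.to_csv(path, sep="\t", index_label="line")


def read_genotypes(path, missing: tuple = ("", "NA", "nan")) -> MarkerMatrix:
    """Read the TSV genotype format written by :func:`write_genotypes`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(missing))
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
    )


def read_vcf(path) -> MarkerMatrix:
    """Import a VCF as an allele-dosage matrix (ALT-allele counts).

    Diploid GT fields are converted to dosages; phased and unphased calls
    are treated alike, missing calls become NaN, and multi-allelic sites
    are dropped with a logged count.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        rows.append(dose)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_multi:
        logger.info("dropped %d multi-allelic site(s)", n_multi)
    if not rows:
        raise ValueError("no biallelic sites found in VCF")
    return MarkerMatrix(np.vstack(rows).T, line_ids=samples, marker_ids=ids)
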