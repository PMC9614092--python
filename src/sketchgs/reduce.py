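"""Five dimensionality-reduction front-ends for marker matrices.

Each maps a standardized ``n x d`` marker matrix to a requested size
``k``: random projection (FJLT / subsampled randomized Hadamard
transform, feature extraction), leverage-score importance sampling,
deterministic top-leverage selection, Ward hierarchical-clustering
representatives, and ridge-coefficient ranking (all feature selection).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import KFold

from .qc import MarkerMatrix
from .rnla import ImportanceDistribution, LeverageScores, SketchSpec, make_sketch

__all__ = [
    "ReducedMarkers",
    "RidgeRanking",
    "ClusterTree",
    "reduce_random_projection",
    "reduce_random_sampling",
    "reduce_deterministic",
    "threshold_count",
    "marker_tree",
    "reduce_cluster",
    "reduce_ridge",
]

METHODS = ("ran_proj", "ran_sample", "det_sample", "cluster", "ridge")


@dataclass
class ReducedMarkers:
    """An ``n x k`` reduced marker set with method/size/seed provenance.

    ``projected`` mode holds linear combinations of markers (no marker
    IDs); ``selected`` mode holds an exact column submatrix of the parent
    with the chosen marker IDs recorded.
    """

    values: np.ndarray
    mode: str                       # "projected" | "selected"
    method: str
    size: int
    replicate_seed: int
    line_ids: list = field(default_factory=list)
    selected_marker_ids: list = field(default_factory=list)
    selected_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.size:
            raise ValueError("size does not match number of columns")
        if self.mode == "projected" and self.selected_marker_ids:
            raise ValueError("projected mode carries no marker IDs")
        if self.mode == "selected":
            if len(self.selected_marker_ids) != self.size:
                raise ValueError("selected mode requires one ID per column")
            if len(set(self.selected_marker_ids)) != self.size:
                raise ValueError("selected marker IDs must be unique")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class RidgeRanking:
    """Full ridge coefficient vector and the cross-validated penalty."""

    coefficients: np.ndarray
    lambda_chosen: float
    lambda_grid: np.ndarray
    cv_folds: int
    order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class ClusterTree:
    """Ward merge history over marker columns, built once per matrix."""

    linkage: np.ndarray             # (d-1) x 4 scipy linkage matrix
    n_markers: int
    metric: str = "euclidean"
    criterion: str = "ward"

    def cut(self, k: int) -> np.ndarray:
        """Labels (1..k) assigning each marker to one of ``k`` clusters."""
        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            raise ValueError(f"could not form exactly {k} non-empty clusters")
        return labels


def _check_selection_size(k: int, d: int) -> None:
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")


def _select(X: MarkerMatrix, idx: np.ndarray, method: str, seed: int) -> ReducedMarkers:
    idx = np.asarray(idx, dtype=int)
    return ReducedMarkers(
        values=X.values[:, idx],
        mode="selected",
        method=method,
        size=idx.size,
        replicate_seed=seed,
        line_ids=list(X.line_ids),
        selected_marker_ids=[X.marker_ids[j] for j in idx],
        selected_indices=idx,
    )


def reduce_random_projection(
    X: MarkerMatrix, k: int, seed: int, identity: bool = False
) -> ReducedMarkers:
    """Project markers to ``k`` linear combinations with an FJLT sketch.

    ``identity=True`` with ``k = d`` bypasses the sketch entirely and
    returns the input columns unchanged (a degenerate passthrough useful
    for testing the downstream pipeline).
    """
    d = X.n_markers
    _check_selection_size(k, d)
    if identity:
        if k != d:
            raise ValueError("identity passthrough requires k = d")
        values = X.values.copy()
    else:
        op = make_sketch(SketchSpec("fjlt", input_dim=d, sketch_dim=k, seed=seed))
        values = op(X.values)
    return ReducedMarkers(
        values=values,
        mode="projected",
        method="ran_proj",
        size=k,
        replicate_seed=seed,
        line_ids=list(X.line_ids),
    )


def reduce_random_sampling(
    X: MarkerMatrix, k: int, probs: ImportanceDistribution, seed: int
) -> ReducedMarkers:
    """Sample ``k`` distinct markers without replacement by importance.

    Successive draws follow the leverage-based importance distribution
    renormalized over the markers not yet chosen.
    """
    d = X.n_markers
    p = np.asarray(probs.probs, dtype=float)
    if p.size != d:
        raise ValueError("importance distribution does not match marker count")
    support = int((p > 0).sum())
    if k > support:
        raise ValueError(
            f"k={k} exceeds the {support} markers with positive probability"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(d, size=k, replace=False, p=p)
    return _select(X, idx, "ran_sample", seed)


def reduce_deterministic(
    X: MarkerMatrix, k: int, scores: LeverageScores
) -> ReducedMarkers:
    """Keep the ``k`` markers with the largest leverage scores.

    Ties broken toward the lower column index; IDs recorded in
    descending-score order, so the top-``k`` sets are nested in ``k``.
    """
    d = X.n_markers
    _check_selection_size(k, d)
    s = np.asarray(scores.scores, dtype=float)
    if s.size != d:
        raise ValueError("scores do not match marker count")
    order = np.lexsort((np.arange(d), -s))
    return _select(X, order[:k], "det_sample", seed=0)


def threshold_count(scores: LeverageScores, theta: float) -> int:
    """Smallest ``c`` whose top-``c`` leverage-score sum exceeds ``theta``."""
    s = np.sort(np.asarray(scores.scores, dtype=float))[::-1]
    csum = np.cumsum(s)
    hit = np.nonzero(csum > theta)[0]
    if hit.size == 0:
        raise ValueError(f"total score {csum[-1]:.6g} never exceeds theta={theta}")
    return int(hit[0]) + 1


# Ward trees are expensive; cache per matrix content so that multiple cut
# sizes on the same matrix reuse one linkage computation.
_TREE_CACHE: dict[str, ClusterTree] = {}
_TREE_CACHE_MAX = 4


def marker_tree(X: MarkerMatrix) -> ClusterTree:
    """Ward linkage over marker columns (Euclidean), cached by content."""
    key = hashlib.sha1(X.values.tobytes()).hexdigest()
    tree = _TREE_CACHE.get(key)
    if tree is None:
        Z = linkage(X.values.T, method="ward", metric="euclidean")
        tree = ClusterTree(linkage=Z, n_markers=X.n_markers)
        if len(_TREE_CACHE) >= _TREE_CACHE_MAX:
            _TREE_CACHE.pop(next(iter(_TREE_CACHE)))
        _TREE_CACHE[key] = tree
    return tree


def reduce_cluster(
    X: MarkerMatrix, k: int, seed: int, tree: ClusterTree | None = None
) -> ReducedMarkers:
    """One representative marker per Ward cluster, ``k`` clusters.

    The dendrogram is built once per matrix (cached; pass ``tree`` to
    reuse an explicit one) and cut into exactly ``k`` clusters; one
    member is drawn uniformly from each cluster with ``seed``.
    """
    d = X.n_markers
    _check_selection_size(k, d)
    if tree is None:
        tree = marker_tree(X)
    labels = tree.cut(k)
    rng = np.random.default_rng(seed)
    reps = [
        int(rng.choice(np.nonzero(labels == lab)[0]))
        for lab in range(1, k + 1)
    ]
    return _select(X, np.sort(reps), "cluster", seed)


def _ridge_path(A: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
    """Ridge coefficients (with intercept) for every penalty at once.

    One thin SVD of the centered design gives the whole path:
    beta(lam) = V diag(s / (s^2 + lam)) U' y_c.
    """
    x_mean = A.mean(axis=0)
    y_mean = y.mean()
    U, s, Vt = np.linalg.svd(A - x_mean, full_matrices=False)
    uty = U.T @ (y - y_mean)
    shrink = s[:, None] / (s[:, None] ** 2 + lambdas[None, :])
    betas = Vt.T @ (shrink * uty[:, None])  # d x n_lambda
    intercepts = y_mean - x_mean @ betas
    return betas, intercepts


def reduce_ridge(
    X: MarkerMatrix,
    y: np.ndarray,
    k: int,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[ReducedMarkers, RidgeRanking]:
    """Rank markers by |ridge coefficient| and keep the top ``k``.

    The penalty is chosen from ``lambda_grid`` by ``cv_folds``-fold
    cross-validated mean squared error on the line-level response ``y``
    (one value per line, e.g. the per-line mean phenotype across
    environments).  Ties in |coefficient| break toward the lower column
    index.
    """
    d = X.n_markers
    _check_selection_size(k, d)
    y = np.asarray(y, dtype=float)
    if y.size != X.n_lines:
        raise ValueError("y must have one value per line")
    if X.n_lines < cv_folds:
        raise ValueError(f"need at least {cv_folds} lines for {cv_folds}-fold CV")
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 6, 17)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_err = np.zeros(lambda_grid.size)
    for tr, te in kf.split(X.values):
        betas, intercepts = _ridge_path(X.values[tr], y[tr], lambda_grid)
        pred = X.values[te] @ betas + intercepts  # n_te x n_lambda
        cv_err += ((y[te, None] - pred) ** 2).sum(axis=0)
    lam_i = int(np.argmin(cv_err))
    lam = float(lambda_grid[lam_i])

    betas, _ = _ridge_path(X.values, y, lambda_grid[lam_i : lam_i + 1])
    coef = betas[:, 0]
    order = np.lexsort((np.arange(d), -np.abs(coef)))
    ranking = RidgeRanking(
        coefficients=coef,
        lambda_chosen=lam,
        lambda_grid=lambda_grid,
        cv_folds=cv_folds,
        order=order,
    )
    return _select(X, order[:k], "ridge", seed), ranking
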