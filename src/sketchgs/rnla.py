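"""Randomized linear-algebra primitives.

Four Johnson–Lindenstrauss sketching constructions (Gaussian, sparse
Rademacher, subsampled randomized Hadamard / FJLT, and the Clarkson–
Woodruff count sketch), the fast Walsh–Hadamard transform they rely on,
and exact / two-stage approximate statistical leverage scores for the
columns of a marker matrix.

Orientation: markers sit in the columns of the ``n x d`` matrix with
``d >> n``; leverage is computed for columns (equivalently rows of the
transpose), and sketch operators map length-``d`` vectors to
length-``k`` vectors along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

from .qc import MarkerMatrix

__all__ = [
    "SketchSpec",
    "SketchOperator",
    "make_sketch",
    "fwht",
    "LeverageScores",
    "ImportanceDistribution",
    "exact_leverage",
    "approx_leverage",
    "importance_distribution",
]

SketchKind = Literal["gaussian", "rademacher", "sparse_rademacher", "fjlt", "cw"]


@dataclass(frozen=True)
class SketchSpec:
    """Specification of a random sketch: kind, dimensions and seed."""

    kind: SketchKind
    input_dim: int
    sketch_dim: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.sketch_dim <= self.input_dim:
            raise ValueError(
                f"sketch_dim must be in [1, input_dim]; got {self.sketch_dim} > {self.input_dim}"
            )
        if self.kind not in ("gaussian", "rademacher", "sparse_rademacher", "fjlt", "cw"):
            raise ValueError(f"unknown sketch kind: {self.kind!r}")


def fwht(v: np.ndarray) -> np.ndarray:
    """Fast Walsh–Hadamard transform along the last axis.

    Multiplies by the *unnormalized* Sylvester-ordered Hadamard matrix in
    ``m * 2^m`` operations; the input length must be a power of two.
    ``fwht(fwht(v)) / 2^m == v``.
    """
    a = np.array(v, dtype=float)
    n = a.shape[-1]
    if n < 1 or n & (n - 1):
        raise ValueError(f"length must be a power of two, got {n}")
    lead = a.shape[:-1]
    h = 1
    while h < n:
        a = a.reshape(*lead, n // (2 * h), 2, h)
        top = a[..., 0, :] + a[..., 1, :]
        bot = a[..., 0, :] - a[..., 1, :]
        a = np.stack((top, bot), axis=-2)
        h *= 2
    return a.reshape(*lead, n)


class SketchOperator:
    """A linear map from length-``d`` to length-``k`` vectors.

    Scaled so that ``E ||S v||^2 = ||v||^2`` for any fixed ``v``.  Apply
    with ``op(M)``; the map acts on the last axis, so an ``n x d`` matrix
    becomes ``n x k``.
    """

    def __init__(self, spec: SketchSpec):
        self.spec = spec
        self.input_dim = spec.input_dim
        self.output_dim = spec.sketch_dim
        self.seed = spec.seed
        d, k = spec.input_dim, spec.sketch_dim
        rng = np.random.default_rng(spec.seed)
        self._S = None  # dense/sparse k x d factor when materialized
        if spec.kind == "gaussian":
            self._S = rng.normal(0.0, np.sqrt(1.0 / k), size=(k, d))
        elif spec.kind == "rademacher":
            self._S = rng.choice([-1.0, 1.0], size=(k, d)) / np.sqrt(k)
        elif spec.kind == "sparse_rademacher":
            # 2/3 zeros, +-1 with probability 1/6 each, rescaled to unit
            # expected column norm
            vals = rng.choice([0.0, 0.0, 0.0, 0.0, -1.0, 1.0], size=(k, d))
            self._S = vals * np.sqrt(3.0 / k)
        elif spec.kind == "cw":
            # count sketch: exactly one +-1 per input coordinate (column)
            rows = rng.integers(0, k, size=d)
            signs = rng.choice([-1.0, 1.0], size=d)
            self._S = sparse.csr_matrix(
                (signs, (rows, np.arange(d))), shape=(k, d)
            )
        elif spec.kind == "fjlt":
            # subsampled randomized Hadamard transform: P H D with zero
            # padding of d to the next power of two
            self._d_pad = 1 << (d - 1).bit_length()
            self._signs = rng.choice([-1.0, 1.0], size=d)
            self._coords = rng.choice(self._d_pad, size=k, replace=False)
            self._scale = np.sqrt(self._d_pad / k) / np.sqrt(self._d_pad)

    @property
    def hadamard_dim(self) -> int:
        """Padded (power-of-two) dimension used by the FJLT, if any."""
        if self.spec.kind != "fjlt":
            raise AttributeError("only FJLT sketches use a Hadamard dimension")
        return self._d_pad

    def dense(self) -> np.ndarray:
        """The sketch as a dense ``k x d`` matrix (tests and small inputs)."""
        if self._S is not None:
            return self._S.toarray() if sparse.issparse(self._S) else np.asarray(self._S)
        return self(np.eye(self.input_dim)).T

    def __call__(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        if M.shape[-1] != self.input_dim:
            raise ValueError(
                f"last axis has length {M.shape[-1]}, expected {self.input_dim}"
            )
        if self.spec.kind == "fjlt":
            pad = np.zeros(M.shape[:-1] + (self._d_pad,))
            pad[..., : self.input_dim] = M * self._signs
            rot = fwht(pad)  # unnormalized; normalization folded into _scale
            return rot[..., self._coords] * self._scale
        if sparse.issparse(self._S):
            out = self._S @ M.reshape(-1, self.input_dim).T
            return np.asarray(out).T.reshape(M.shape[:-1] + (self.output_dim,))
        return M @ self._S.T


def make_sketch(spec: SketchSpec) -> SketchOperator:
    """Build the sketch operator described by ``spec``."""
    return SketchOperator(spec)


# -- leverage scores ---------------------------------------------------------

@dataclass
class LeverageScores:
    """Per-marker leverage scores over the columns of the marker matrix."""

    scores: np.ndarray
    rank_used: int
    kind: Literal["exact", "approximate"]
    r1: int | None = None
    r2: int | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < -1e-12).any():
            raise ValueError("leverage scores must be nonnegative")
        self.scores = np.clip(self.scores, 0.0, None)


@dataclass
class ImportanceDistribution:
    """A proper probability distribution over marker columns."""

    probs: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, MarkerMatrix) else np.asarray(X, dtype=float)


def exact_leverage(X, k: int | None = None) -> LeverageScores:
    """Exact leverage scores of the marker columns from the top-``k`` SVD.

    The score of column ``i`` is the squared Euclidean norm of the ``i``-th
    column of the top-``k`` right-singular-vector matrix; the scores sum
    to ``k``.  Defaults to the full numerical rank.
    """
    V = _values(X)
    s_tol = 1e-10
    _, s, Vt = np.linalg.svd(V, full_matrices=False)
    rank = int((s > s_tol * s[0]).sum()) if s.size else 0
    if k is None:
        k = rank
    if not 1 <= k <= rank:
        raise ValueError(f"k must be in [1, rank={rank}], got {k}")
    scores = (Vt[:k] ** 2).sum(axis=0)
    return LeverageScores(scores=scores, rank_used=k, kind="exact")


def approx_leverage(
    X,
    r1: int | None = None,
    r2: int | None = None,
    seed: int = 0,
    max_retries: int = 3,
    required_rank: int | None = None,
) -> LeverageScores:
    """Two-stage sketched approximation of the column leverage scores.

    Working with the transposed matrix ``A`` (markers as rows, ``d x n``
    tall), a first-stage FJLT with ``r1`` rows compresses the long axis so
    that the pseudo-inverse is computed on an ``r1 x n`` matrix, and a
    second-stage Gaussian sketch with ``r2`` columns compresses the row-norm
    computation of ``A (Pi1 A)^+``.  Cheap relative to the exact SVD and,
    at generous ``(r1, r2)``, within a factor ``1 +- eps`` of the exact
    scores with high probability.

    Two variance reductions with unchanged expectation are applied: the
    Gaussian second-stage columns are orthonormalized (an orthogonal
    random projection scaled to preserve squared norms), and the returned
    scores are rescaled to sum to the sketch rank — the invariant exact
    scores satisfy by construction.

    Defaults: ``r1 = 2 min(n, d)`` (small first stage), ``r2 = ceil(8 ln d)``
    (large second stage relative to its cost, which is negligible).
    """
    A = _values(X).T  # d x n, markers as rows
    d, n = A.shape
    small = min(n, d)
    if r1 is None:
        r1 = 2 * small
    if r2 is None:
        r2 = int(np.ceil(8 * np.log(max(d, 2))))
    if r1 < small:
        raise ValueError(f"r1 must be >= min(n, d) = {small}, got {r1}")
    if r2 < 1:
        raise ValueError("r2 must be >= 1")
    r1 = min(r1, d)

    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng_seed = seed + attempt
        pi1 = make_sketch(SketchSpec("fjlt", input_dim=d, sketch_dim=r1, seed=rng_seed))
        # Pi1 A: sketch the long (marker) axis of A, i.e. the columns of A'
        SA = pi1(A.T).T  # r1 x n
        s = np.linalg.svd(SA, compute_uv=False)
        rank_sa = int((s > 1e-10 * s[0]).sum()) if s.size and s[0] > 0 else 0
        # a sketch with r1 >= min(n, d) preserves rank(A) almost surely;
        # retry (fresh seed) on the measure-zero failures, or when the
        # caller states the rank the sketch must retain
        floor = required_rank if required_rank is not None else 1
        if rank_sa < floor:
            last_err = np.linalg.LinAlgError(
                f"sketched matrix rank {rank_sa} below required {floor}"
            )
            continue
        B = np.linalg.pinv(SA, rcond=1e-10)  # n x r1
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 2)))
        if r2 < r1:
            # orthonormal columns scaled so E ||v' Pi2||^2 = ||v||^2
            Q, _ = np.linalg.qr(rng.standard_normal((r1, r2)))
            pi2 = Q * np.sqrt(r1 / r2)
        else:
            # r2 >= r1: a scaled orthogonal map preserves norms exactly
            Q, _ = np.linalg.qr(rng.standard_normal((r2, r2)))
            pi2 = Q[:r1, :]
        T = A @ (B @ pi2)  # d x r2
        scores = (T ** 2).sum(axis=1)
        total = scores.sum()
        if total > 0:
            scores *= rank_sa / total
        return LeverageScores(
            scores=scores, rank_used=rank_sa, kind="approximate", r1=r1, r2=r2
        )
    raise np.linalg.LinAlgError(
        f"sketched matrix rank-deficient after {max_retries} attempts"
    ) from last_err


def importance_distribution(scores: LeverageScores) -> ImportanceDistribution:
    """Normalize leverage scores into an importance sampling distribution.

    Normalizes by the score total, which equals the SVD rank ``k`` for
    exact scores, so in the full-rank square-basis case this coincides
    with dividing by the column count.
    """
    s = np.asarray(scores.scores, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("all leverage scores are zero")
    return ImportanceDistribution(probs=s / total)
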