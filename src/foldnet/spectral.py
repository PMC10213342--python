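"""Uncentered Gram-matrix spectral coordination of a small gene panel.

For a panel submatrix X (s genes x n samples, log10 scale) the statistic of
interest is the eigen-spectrum of the *uncentered* inner-product (Gram)
matrix R = X Xᵀ, with R[i, j] the plain dot product of gene rows i and j.
No mean-centering or scaling is applied — this is what distinguishes the
statistic from covariance PCA: the mean expression level is part of the
signal.  Eigenvalues are reported as fractions of their sum ("percentage
transformed"), so the leading fraction λ₁/Σλ measures how concentrated the
panel's joint variation is on a single direction — the coordination of the
network.  In the study system this fraction rises from ≈0.56 in controls to
≈0.79 in severe dementia, and the orientation of the leading eigenvector
flips between those groups.

Eigenvector signs are not identifiable from R alone (R is invariant under
X -> -X), so two conventions are kept side by side:

* ``vectors_raw`` — orientation anchored to the data: each eigenvector is
  flipped so its dot product with the group's mean expression profile is
  positive.  Cross-group alignments and reversal flags are computed on these.
* ``vectors`` — the reporting convention: each vector flipped so its
  largest-magnitude component is positive (tables are comparable only up to
  a global sign per column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GramMatrix",
    "SpectralResult",
    "CoordinationComparison",
    "gram_matrix",
    "eigendecompose",
    "leading_fraction",
    "leading_vector_alignment",
    "compare_leading_vectors",
    "coordination_trajectory",
    "bootstrap_leading_fraction",
]

_SYM_RTOL = 1e-10
_PSD_TOL = 1e-9


@dataclass
class GramMatrix:
    """Uncentered inner-product matrix of panel gene rows for one group."""

    group: str
    matrix: np.ndarray  # s x s symmetric PSD
    n: int  # number of samples the dot products ran over
    mean_profile: np.ndarray | None = None  # column-mean of X; anchors eigenvector orientation

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        s = self.matrix.shape[0]
        if self.matrix.shape != (s, s):
            raise ValueError("Gram matrix must be square")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > _SYM_RTOL * scale:
            raise ValueError("Gram matrix is not symmetric")
        if np.any(np.diag(self.matrix) < 0):
            raise ValueError("Gram matrix has a negative diagonal entry")
        tr = float(np.trace(self.matrix))
        if tr > 0 and np.linalg.eigvalsh((self.matrix + self.matrix.T) / 2).min() < -_PSD_TOL * tr:
            raise ValueError("Gram matrix is not positive semi-definite")

    @property
    def s(self) -> int:
        return self.matrix.shape[0]


def gram_matrix(X: np.ndarray, group: str = "") -> GramMatrix:
    """R[i, j] = dot(gene row i, gene row j), uncentered and unscaled."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("panel matrix must be s x n with s >= 2 and n >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("panel matrix contains non-finite entries")
    R = X @ X.T
    R = (R + R.T) / 2.0
    return GramMatrix(group=str(group), matrix=R, n=X.shape[1], mean_profile=X.mean(axis=1))


def _orient(vec: np.ndarray, anchor: np.ndarray | None) -> np.ndarray:
    """Flip sign so the vector points along the anchor (fallback: largest
    component positive)."""
    if anchor is not None:
        d = float(vec @ anchor)
        if abs(d) > 1e-12 * (np.linalg.norm(anchor) + 1.0):
            return vec if d > 0 else -vec
    k = int(np.argmax(np.abs(vec)))
    return vec if vec[k] >= 0 else -vec


def _report_sign(vec: np.ndarray) -> np.ndarray:
    k = int(np.argmax(np.abs(vec)))
    return vec if vec[k] >= 0 else -vec


@dataclass
class SpectralResult:
    """Fraction-normalized eigen-spectrum of a panel Gram matrix."""

    group: str
    fractions: np.ndarray  # descending, sums to 1
    raw_eigenvalues: np.ndarray
    vectors: np.ndarray  # s x s, column k for fractions[k]; reporting sign
    vectors_raw: np.ndarray  # data-anchored orientation; used for alignments
    sign_convention: str = "mean-profile anchored"

    @property
    def s(self) -> int:
        return len(self.fractions)

    @classmethod
    def from_table(
        cls, vectors: np.ndarray, fractions: Sequence[float] | None = None, group: str = ""
    ) -> "SpectralResult":
        """Wrap an externally reported eigenvector table (columns = vectors,
        first column = leading).  The printed orientation is kept as-is."""
        V = np.asarray(vectors, dtype=float)
        s = V.shape[1]
        fr = np.asarray(fractions, dtype=float) if fractions is not None else np.full(s, np.nan)
        return cls(
            group=str(group),
            fractions=fr,
            raw_eigenvalues=np.full(s, np.nan),
            vectors=np.column_stack([_report_sign(V[:, k]) for k in range(s)]),
            vectors_raw=V.copy(),
            sign_convention="as reported",
        )


def eigendecompose(R: GramMatrix) -> SpectralResult:
    """Eigendecompose R; fractions are eigenvalues over their sum, descending.

    Ties (degenerate eigenvalues) are ordered by descending first-component
    magnitude of their eigenvectors; vectors within a tied block are not
    unique and only the spanned subspace is meaningful.
    """
    S = (R.matrix + R.matrix.T) / 2.0
    tr = float(np.trace(S))
    if tr <= 0:
        raise ValueError("degenerate panel: Gram matrix has zero trace")
    w, V = np.linalg.eigh(S)
    order = np.argsort(-w, kind="stable")
    w, V = w[order], V[:, order]
    # reorder within numerically tied blocks
    tol = 1e-12 * max(tr, 1.0)
    i = 0
    while i < len(w):
        j = i
        while j + 1 < len(w) and abs(w[j + 1] - w[i]) <= tol:
            j += 1
        if j > i:
            sub = np.argsort(-np.abs(V[0, i : j + 1]), kind="stable")
            V[:, i : j + 1] = V[:, i : j + 1][:, sub]
        i = j + 1
    w = np.clip(w, 0.0, None)
    fractions = w / w.sum()
    raw = np.column_stack([_orient(V[:, k], R.mean_profile) for k in range(len(w))])
    rep = np.column_stack([_report_sign(raw[:, k]) for k in range(len(w))])
    return SpectralResult(
        group=R.group,
        fractions=fractions,
        raw_eigenvalues=w,
        vectors=rep,
        vectors_raw=raw,
    )


def leading_fraction(sr: SpectralResult) -> float:
    """λ₁ / Σλ, the coordination statistic; in [1/s, 1] for a Gram spectrum."""
    return float(sr.fractions[0])


def leading_vector_alignment(u: np.ndarray, v: np.ndarray) -> float:
    """Dot product of two leading eigenvectors (unit vectors -> in [-1, 1])."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("leading vectors have mismatched panel sizes")
    return float(u @ v)


def compare_leading_vectors(a: SpectralResult, b: SpectralResult) -> tuple[float, bool]:
    """Alignment of the two groups' leading eigenvectors and a reversal flag.

    Uses the orientation-anchored vectors; ``reversed`` is True when the
    alignment is negative (the leading direction flipped between groups).
    """
    if a.s != b.s:
        raise ValueError(f"panel sizes differ: {a.s} vs {b.s}")
    alignment = leading_vector_alignment(a.vectors_raw[:, 0], b.vectors_raw[:, 0])
    return alignment, alignment < 0


@dataclass
class CoordinationComparison:
    """Cross-group summary of leading fractions and eigenvector alignments."""

    groups: list[str]
    leading_fractions: np.ndarray
    deltas: np.ndarray  # consecutive-stage differences of the leading fraction
    alignment: np.ndarray  # pairwise dot products of anchored leading vectors
    reversed_vs_first: np.ndarray  # bool, alignment with the first group < 0


def coordination_trajectory(results: Sequence[SpectralResult]) -> CoordinationComparison:
    """Leading-fraction trajectory and full alignment matrix over >= 2 groups."""
    if len(results) < 2:
        raise ValueError("need at least two groups")
    s = results[0].s
    if any(r.s != s for r in results):
        raise ValueError("inconsistent panel sizes across groups")
    lead = np.array([leading_fraction(r) for r in results])
    U = np.column_stack([r.vectors_raw[:, 0] for r in results])
    A = U.T @ U
    return CoordinationComparison(
        groups=[r.group for r in results],
        leading_fractions=lead,
        deltas=np.diff(lead),
        alignment=A,
        reversed_vs_first=A[0] < 0,
    )


def bootstrap_leading_fraction(
    X: np.ndarray, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, float, float]:
    """Column-resampling bootstrap CI for the leading fraction (diagnostic
    extension for the very small per-group n of this design; not part of the
    core statistic)."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    est = leading_fraction(eigendecompose(gram_matrix(X)))
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = leading_fraction(eigendecompose(gram_matrix(X[:, idx])))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return est, float(lo), float(hi)
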