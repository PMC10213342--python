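"""Simplified weighted co-expression module detection and module-trait
correlation.

The stage follows the soft-thresholding recipe: gene-gene Spearman
correlations are raised (in absolute value) to a soft power beta (default 8)
to form a weighted adjacency in [0, 1]; genes are clustered by
average-linkage hierarchical clustering on 1 - adjacency; clusters below the
minimum size (default 30) fall into an "unassigned" sink (the grey module);
and modules whose eigengenes correlate above 1 - merge_cut (default
merge_cut 0.25) are merged until stable.

This is a deliberately simplified variant of the WGCNA workflow: the
topological-overlap transform is an optional extra (off by default — the
default distance is 1 - adjacency) and the dynamic tree cut is replaced by a
static cut at a configurable height plus the size filter and eigengene
merging.  It is not a bit-for-bit WGCNA port.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyMatrix",
    "ModuleAssignment",
    "ModuleTraitMatrix",
    "UNASSIGNED",
    "spearman_matrix",
    "soft_adjacency",
    "topological_overlap",
    "pick_soft_power",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
]

UNASSIGNED = "unassigned"


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded co-expression adjacency: a_ij = |corr_ij|^beta."""

    gene_ids: list[str]
    matrix: np.ndarray
    beta: int

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("adjacency shape does not match gene_ids")
        if np.abs(a - a.T).max() > 1e-10 or a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency must be symmetric with entries in [0, 1]")
        self.matrix = np.clip(a, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    """Gene -> module labels; non-sink modules satisfy the minimum size."""

    gene_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValueError("gene_ids and labels length mismatch")

    @property
    def assignments(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.labels))

    @property
    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def genes_in(self, label: str) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})


@dataclass
class ModuleTraitMatrix:
    """Pearson correlations (and p-values) between module eigengenes and
    numerically coded clinical traits."""

    correlations: pd.DataFrame  # modules x traits
    p_values: pd.DataFrame


def spearman_matrix(m: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Spearman correlation (average ranks for ties).

    Constant genes (zero rank variance) get correlation 0 with a warning.
    """
    X = np.asarray(m.values, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s); correlations set to 0")
    safe = ranks.copy()
    safe[const] = np.arange(X.shape[1])  # placeholder to avoid 0/0; zeroed below
    C = np.corrcoef(safe)
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def soft_adjacency(corr: np.ndarray, beta: int = 8, gene_ids: list[str] | None = None) -> AdjacencyMatrix:
    """a_ij = |corr_ij|^beta with diagonal forced to 1 (unsigned network;
    identical to the signed power for even beta)."""
    if int(beta) != beta or beta < 1:
        raise ValueError("beta must be a positive integer")
    corr = np.asarray(corr, dtype=float)
    a = np.abs(corr) ** int(beta)
    np.fill_diagonal(a, 1.0)
    ids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(a.shape[0])]
    return AdjacencyMatrix(gene_ids=list(ids), matrix=a, beta=int(beta))


def topological_overlap(adj: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency (optional
    transform; the default pipeline clusters on the adjacency itself)."""
    a = adj.matrix.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.nan_to_num(tom, nan=0.0)


def pick_soft_power(
    corr: np.ndarray,
    candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    rsq_threshold: float = 0.8,
    n_bins: int = 10,
) -> tuple[int | None, pd.DataFrame]:
    """Scale-free topology fit per candidate soft power.

    For each beta, the connectivity k_i = sum_j a_ij (j != i) is binned and
    log10(frequency) is regressed on log10(mean k); the fit index is R² with
    a negative slope required (a scale-free degree distribution decays).
    Returns the smallest candidate with fit >= ``rsq_threshold`` (None with a
    warning if no candidate qualifies) plus the full fit table.
    """
    rows = []
    chosen: int | None = None
    for beta in candidates:
        a = soft_adjacency(corr, beta=beta).matrix.copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        mean_k = float(k.mean())
        rsq, slope = 0.0, np.nan
        pos = k[k > 0]
        if len(pos) >= 4 and pos.max() > pos.min():
            edges = np.linspace(pos.min(), pos.max() + 1e-12, n_bins + 1)
            which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
            xs, ys = [], []
            for b in range(n_bins):
                sel = which == b
                if sel.sum() > 0:
                    xs.append(pos[sel].mean())
                    ys.append(sel.sum() / len(pos))
            if len(xs) >= 3:
                res = stats.linregress(np.log10(xs), np.log10(ys))
                slope = float(res.slope)
                rsq = float(res.rvalue**2) if res.slope < 0 else 0.0
        rows.append({"beta": beta, "fit_rsq": rsq, "slope": slope, "mean_connectivity": mean_k})
        if chosen is None and rsq >= rsq_threshold:
            chosen = beta
    table = pd.DataFrame(rows)
    if chosen is None:
        warnings.warn("no candidate soft power reaches the scale-free fit threshold")
    return chosen, table


def module_eigengene(Xm: np.ndarray) -> np.ndarray:
    """First right singular vector of the gene-standardized module submatrix.

    One value per sample (unit norm); the sign is fixed so the eigengene
    correlates positively with the module's mean standardized profile.
    """
    Xm = np.asarray(Xm, dtype=float)
    if Xm.ndim != 2 or Xm.shape[0] < 2:
        raise ValueError("module needs at least 2 genes")
    sd = Xm.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant module submatrix")
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant gene(s) dropped from eigengene")
    Z = (Xm[keep] - Xm[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    ref = Z.mean(axis=0)
    d = float(e @ ref)
    if d < 0 or (d == 0 and e.sum() < 0):
        e = -e
    return e


def _relabel_by_size(gene_ids: list[str], raw: np.ndarray) -> list[str]:
    """Deterministic labels: module_1 is the largest (ties: earliest gene)."""
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(raw):
        if r != 0:
            groups.setdefault(int(r), []).append(i)
    order = sorted(groups, key=lambda r: (-len(groups[r]), min(groups[r])))
    name = {r: f"module_{k + 1}" for k, r in enumerate(order)}
    return [name[int(r)] if r != 0 else UNASSIGNED for r in raw]


def detect_modules(
    adj: AdjacencyMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    cut_height: float | None = None,
    expression: ExpressionMatrix | None = None,
    use_tom: bool = False,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - adjacency with a static cut.

    Clusters smaller than ``min_size`` go to the sink; when ``expression`` is
    given, modules whose eigengenes correlate above 1 - ``merge_cut`` are
    merged iteratively until stable.  ``cut_height`` defaults to the midpoint
    of the largest gap between consecutive sorted merge heights (searched in
    the upper half of the dendrogram), a static stand-in for an adaptive
    tree cut: well-separated module structure opens a wide gap between
    within-module and between-module merges, while structureless data yield
    no meaningful gap and fall through to the size filter.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not (0.0 < merge_cut < 1.0):
        raise ValueError("merge_cut must be in (0, 1)")
    n = len(adj.gene_ids)
    if n < min_size:
        warnings.warn("fewer genes than min_size; everything unassigned")
        return ModuleAssignment(list(adj.gene_ids), [UNASSIGNED] * n)
    sim = topological_overlap(adj) if use_tom else adj.matrix
    d = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = np.sort(Z[:, 2])
    if cut_height is None:
        upper = heights[len(heights) // 2 :]
        gaps = np.diff(upper)
        k = int(np.argmax(gaps)) if len(gaps) else 0
        h = float((upper[k] + upper[min(k + 1, len(upper) - 1)]) / 2.0)
    else:
        h = float(cut_height)
    raw = fcluster(Z, t=h, criterion="distance")
    # size filter
    sizes = pd.Series(raw).value_counts()
    small = set(sizes[sizes < min_size].index)
    raw = np.array([0 if r in small else r for r in raw])
    if expression is not None and raw.any():
        expr = expression.subset_genes(adj.gene_ids)
        for _ in range(100):
            labs = sorted({int(r) for r in raw if r != 0})
            if len(labs) < 2:
                break
            eigs = {
                l: module_eigengene(expr.values[raw == l]) for l in labs
            }
            E = np.column_stack([eigs[l] for l in labs])
            C = np.corrcoef(E.T)
            np.fill_diagonal(C, -np.inf)
            i, j = np.unravel_index(int(np.argmax(C)), C.shape)
            if C[i, j] <= 1.0 - merge_cut:
                break
            keep, absorb = sorted((labs[i], labs[j]))
            raw[raw == absorb] = keep
        else:  # pragma: no cover - safety bound
            warnings.warn("module merging did not stabilize in 100 rounds")
    labels = _relabel_by_size(list(adj.gene_ids), raw)
    logger.info("modules: %s", ModuleAssignment(list(adj.gene_ids), labels).module_sizes)
    return ModuleAssignment(list(adj.gene_ids), labels)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> ModuleTraitMatrix:
    """Pearson correlation and two-sided p per (module eigengene, trait).

    Both frames are samples x columns and are aligned on their shared index;
    traits must be numerically coded (group 1-4, sex 0/1, Braak ordinal).
    Constant traits get correlation 0 with a warning.
    """
    shared = eigengenes.index.intersection(traits.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between eigengenes and traits")
    E = eigengenes.loc[shared]
    T = traits.loc[shared]
    corr = pd.DataFrame(index=E.columns, columns=T.columns, dtype=float)
    pval = pd.DataFrame(index=E.columns, columns=T.columns, dtype=float)
    for tr in T.columns:
        tvals = pd.to_numeric(T[tr], errors="coerce")
        ok = tvals.notna()
        if tvals[ok].nunique() <= 1:
            warnings.warn(f"constant trait {tr!r}; correlations set to 0")
            corr[tr], pval[tr] = 0.0, 1.0
            continue
        for mod in E.columns:
            r, p = stats.pearsonr(E.loc[ok, mod], tvals[ok])
            corr.loc[mod, tr] = float(r)
            pval.loc[mod, tr] = float(p)
    return ModuleTraitMatrix(correlations=corr, p_values=pval)
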