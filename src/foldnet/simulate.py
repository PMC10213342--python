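"""Synthetic-data generators planting every structure the pipeline assumes.

Four generators, all pure functions of their seed:

* :func:`simulate_panel` — four panel genes over severity groups of sizes
  9/7/8/7 with a group-specific planted uncentered Gram spectrum (leading
  fraction drifting ≈0.56 -> ≈0.79 across stages) and configurable planted
  leading directions (including sign flips).  Spectra are planted in the
  uncentered sense: the planted directions include the mean component.
* :func:`simulate_mmse` — MMSE in [0, 30] as a linear function of the four
  log-expression values plus Gaussian noise, rounded and clipped.
* :func:`simulate_classification_cohort` — a two-class cohort whose
  (sum, SD) features are bivariate normal, the class means separated by a
  Mahalanobis distance delta; panel values are back-constructed to match
  the features exactly.
* :func:`simulate_background_modules` — background genes organized into
  correlated modules (one latent factor per module) plus independent noise
  genes, with the ground-truth assignment returned.

Raw-scale output uses g = 10^x - 1 so the pipeline's log step is exercised
end to end; a planted global sign flip cannot be represented as nonnegative
raw intensities, so flipped configurations are used with the log-scale
matrices directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GROUP_CODES, GROUP_NAMES, Scale, DEFAULT_PANEL

__all__ = [
    "PanelSimConfig",
    "CohortSimConfig",
    "PanelSim",
    "ClassificationSim",
    "ModuleSim",
    "simulate_panel",
    "simulate_mmse",
    "simulate_classification_cohort",
    "simulate_background_modules",
]

#: Default planted eigenvalue fractions per group: leading fraction drifts
#: slowly over the first three stages and jumps in the severe stage.
DEFAULT_SPECTRA: dict[str, tuple[float, ...]] = {
    "control": (0.56, 0.20, 0.14, 0.10),
    "incipient": (0.58, 0.19, 0.13, 0.10),
    "moderate": (0.60, 0.19, 0.12, 0.09),
    "severe": (0.79, 0.11, 0.06, 0.04),
}

DEFAULT_GROUP_SIZES: dict[str, int] = {"control": 9, "incipient": 7, "moderate": 8, "severe": 7}


@dataclass
class PanelSimConfig:
    """Planted per-group Gram spectra and leading directions.

    ``directions`` maps group -> unit 4-vector for the leading gene-space
    direction; None means the default positive direction (consistent with
    nonnegative intensities) for every group.  ``noise_scale`` is additive
    Gaussian noise on the log scale.  ``trace`` sets the overall energy so
    log values land in a realistic microarray range (~2.5).
    """

    spectra: Mapping[str, Sequence[float]] = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    directions: Mapping[str, np.ndarray] | None = None
    noise_scale: float = 0.02
    trace: float = 400.0
    seed: int = 0
    gene_ids: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        for g, fr in self.spectra.items():
            fr = np.asarray(fr, dtype=float)
            if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0) or np.any(np.diff(fr) > 1e-12):
                raise ValueError(f"spectrum for {g!r} must be nonincreasing, >= 0, summing to 1")
            if self.group_sizes[g] < len(fr):
                raise ValueError(f"group {g!r} smaller than panel size; exact spectrum impossible")


def _orthonormal_with_first(first: np.ndarray, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis whose first column is ``first`` (unit-normalized)."""
    q1 = np.asarray(first, dtype=float)
    q1 = q1 / np.linalg.norm(q1)
    M = rng.standard_normal((dim, dim))
    M[:, 0] = q1
    Q, _ = np.linalg.qr(M)
    # QR may flip the first column; re-anchor it
    if Q[:, 0] @ q1 < 0:
        Q[:, 0] *= -1
    # re-orthogonalize the rest against the exact q1
    Q[:, 0] = q1
    for j in range(1, dim):
        v = Q[:, j]
        for i in range(j):
            v = v - (v @ Q[:, i]) * Q[:, i]
        Q[:, j] = v / np.linalg.norm(v)
    return Q


@dataclass
class PanelSim:
    """Output of :func:`simulate_panel`."""

    expression: ExpressionMatrix  # raw scale (g = 10^max(x,0) - 1)
    metadata: pd.DataFrame
    log_matrices: dict[str, np.ndarray]  # exact planted log-scale matrices per group
    config: PanelSimConfig


def simulate_panel(config: PanelSimConfig | None = None) -> PanelSim:
    """Plant per-group spectra: X = sum_k sqrt(lambda_k) q_k w_kᵀ + noise.

    q_k are orthonormal gene-space directions (q_1 the planted leading
    direction), w_k orthonormal sample-space vectors with w_1 the positive
    constant vector (so the leading direction carries the mean component,
    matching the uncentered statistic).  At ``noise_scale = 0`` the Gram
    fractions of ``log_matrices`` equal the targets exactly.
    """
    config = config or PanelSimConfig()
    rng = np.random.default_rng(config.seed)
    s = len(config.gene_ids)
    default_dir = np.ones(s) / np.sqrt(s)
    log_mats: dict[str, np.ndarray] = {}
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    rows_meta = []
    for group in config.spectra:
        n = int(config.group_sizes[group])
        fracs = np.asarray(config.spectra[group], dtype=float)
        lam = fracs * config.trace
        direction = (
            np.asarray(config.directions[group], dtype=float)
            if config.directions is not None and group in config.directions
            else default_dir
        )
        # redraw the random completions a few times if raw nonnegativity fails
        X = None
        for _ in range(20):
            Q = _orthonormal_with_first(direction, s, rng)
            W = _orthonormal_with_first(np.ones(n) / np.sqrt(n), n, rng)[:, :s]
            cand = (Q * np.sqrt(lam)) @ W.T
            cand = cand + config.noise_scale * rng.standard_normal((s, n))
            if X is None:
                X = cand
            if cand.min() >= 0:
                X = cand
                break
        log_mats[group] = X
        for j in range(n):
            sid = f"{group}_{j + 1}"
            sample_ids.append(sid)
            rows_meta.append({"sample_id": sid, "group": GROUP_CODES[group.lower()]})
        cols.append(X)
    Xall = np.hstack(cols)
    raw = np.power(10.0, np.clip(Xall, 0.0, None)) - 1.0
    expr = ExpressionMatrix(list(config.gene_ids), sample_ids, raw, Scale.RAW)
    return PanelSim(
        expression=expr,
        metadata=pd.DataFrame(rows_meta),
        log_matrices=log_mats,
        config=config,
    )


@dataclass
class CohortSimConfig:
    """Cohort-level generator settings (MMSE regression, classification,
    background modules)."""

    # MMSE = clip(round(intercept + coeffs . x + N(0, noise_sd)), 0, 30)
    mmse_coeffs: tuple[float, ...] = (8.0, 6.0, -5.0, -6.0)
    mmse_intercept: float = 10.0
    mmse_noise_sd: float = 1.0
    # classification: class means separated by delta in Mahalanobis distance
    delta: float = 1.5
    n_control: int = 180
    n_patient: int = 181
    feature_mean: tuple[float, float] = (10.0, 0.4)  # (sum, SD) of control class
    feature_sd: tuple[float, float] = (0.8, 0.1)
    # background modules
    n_modules: int = 3
    genes_per_module: int = 40
    within_corr: float = 0.8
    n_noise_genes: int = 30
    n_samples: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not (0.0 < self.within_corr < 1.0):
            raise ValueError("within_corr must be in (0, 1)")


def simulate_mmse(
    panel: ExpressionMatrix | np.ndarray,
    config: CohortSimConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Integer MMSE per sample: linear in the four log-expression values plus
    Gaussian noise, rounded and clipped to [0, 30]."""
    config = config or CohortSimConfig()
    X = panel.values if isinstance(panel, ExpressionMatrix) else np.asarray(panel, dtype=float)
    if X.shape[0] != len(config.mmse_coeffs):
        raise ValueError("panel must have one row per MMSE coefficient")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lin = config.mmse_intercept + np.asarray(config.mmse_coeffs) @ X
    noisy = lin + config.mmse_noise_sd * rng.standard_normal(X.shape[1])
    return np.clip(np.rint(noisy), 0, 30).astype(int)


#: Fixed zero-mean unit-population-SD base pattern used to back-construct
#: four gene values with a prescribed (sum, SD).
_BASE_PATTERN = (np.array([1.0, 2.0, 3.0, 4.0]) - 2.5) / np.std([1.0, 2.0, 3.0, 4.0])


@dataclass
class ClassificationSim:
    expression: ExpressionMatrix  # raw scale, 4 genes
    labels: np.ndarray  # 0 = control, 1 = patient
    features: np.ndarray  # planted (sum, SD) per sample
    metadata: pd.DataFrame


def simulate_classification_cohort(
    config: CohortSimConfig | None = None,
    seed: int | None = None,
    n_control: int | None = None,
    n_patient: int | None = None,
) -> ClassificationSim:
    """Two classes separable in (sum, SD) feature space.

    Features are drawn from axis-aligned bivariate normals; the patient mean
    is shifted by ``delta`` standard deviations along each feature (so the
    Mahalanobis distance between the class means is delta * sqrt(2), and the
    Bayes-optimal AUC is Phi(delta)).  Panel values are back-constructed so
    each sample's sum and population SD match its planted features exactly
    (a fixed zero-mean pattern, randomly permuted per sample, scaled by the
    SD around sum/4).
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n0 = config.n_control if n_control is None else n_control
    n1 = config.n_patient if n_patient is None else n_patient
    m0 = np.asarray(config.feature_mean, dtype=float)
    sd = np.asarray(config.feature_sd, dtype=float)
    shift = config.delta * sd
    F0 = m0 + sd * rng.standard_normal((n0, 2))
    F1 = m0 + shift + sd * rng.standard_normal((n1, 2))
    F = np.vstack([F0, F1])
    F[:, 1] = np.clip(F[:, 1], 1e-3, None)  # SD must stay positive
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
    X = np.empty((4, len(F)))
    for i, (ssum, ssd) in enumerate(F):
        X[:, i] = ssum / 4.0 + ssd * rng.permutation(_BASE_PATTERN)
    X = np.clip(X, 0.0, None)
    sample_ids = [f"s{i + 1}" for i in range(len(F))]
    raw = np.power(10.0, X) - 1.0
    expr = ExpressionMatrix(list(DEFAULT_PANEL), sample_ids, raw, Scale.RAW)
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "group": np.where(labels == 0, 1, 4), "label": labels}
    )
    return ClassificationSim(expression=expr, labels=labels, features=F, metadata=meta)


@dataclass
class ModuleTruth:
    labels: dict[str, str]  # gene -> module_k / "noise"
    factors: np.ndarray  # latent factor per module (K x n_samples)


@dataclass
class ModuleSim:
    expression: ExpressionMatrix  # log10 scale (synthetic)
    truth: ModuleTruth


def simulate_background_modules(
    config: CohortSimConfig | None = None,
    seed: int | None = None,
    trait: np.ndarray | None = None,
) -> ModuleSim:
    """K planted modules of correlated genes plus independent noise genes.

    Gene g in module m is f_m + sigma * eps with sigma chosen so the
    within-module gene-gene correlation equals ``within_corr``
    (sigma^2 = 1/rho - 1).  When ``trait`` is given, the first module's
    latent factor is the standardized trait (plus a little noise), so
    module-trait correlation should rank that module first.  Values are
    emitted on a plausible log10 scale.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples if trait is None else len(trait)
    sigma = np.sqrt(1.0 / config.within_corr - 1.0)
    factors = rng.standard_normal((config.n_modules, n))
    if trait is not None:
        t = np.asarray(trait, dtype=float)
        t = (t - t.mean()) / (t.std() or 1.0)
        factors[0] = t + 0.1 * rng.standard_normal(n)
    gene_ids, rows, labels = [], [], {}
    for m in range(config.n_modules):
        for g in range(config.genes_per_module):
            gid = f"mod{m + 1}_g{g + 1}"
            gene_ids.append(gid)
            labels[gid] = f"module_{m + 1}"
            rows.append(factors[m] + sigma * rng.standard_normal(n))
    for g in range(config.n_noise_genes):
        gid = f"noise_g{g + 1}"
        gene_ids.append(gid)
        labels[gid] = "noise"
        rows.append(rng.standard_normal(n) * (1.0 + sigma))
    X = 2.5 + 0.3 * np.asarray(rows)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    expr = ExpressionMatrix(gene_ids, sample_ids, X, Scale.LOG10)
    return ModuleSim(expression=expr, truth=ModuleTruth(labels=labels, factors=factors))
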