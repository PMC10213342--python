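"""From-scratch max-margin disease classifier over (sum, SD) panel features.

Each sample is summarized by two numbers: the sum of its four panel
log-expression values and their standard deviation (population denominator
by default).  Features are z-scored with training-set statistics, then
mapped to Gaussian similarities exp(-||x - l||^2 / (2 sigma^2)) against a
landmark set (default: all training samples; sigma^2 = 0.5).  A soft-margin
linear separator on the mapped features is found by seeded stochastic
subgradient descent on the hinge objective 0.5 ||w||^2 + C sum hinge_i
(Pegasos-style steps with iterate averaging), and performance is summarized
with sensitivity/specificity confusion counts, the ROC curve and its
trapezoid-rule area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "SampleFeatures",
    "FeatureScaler",
    "SVMModel",
    "ConfusionCounts",
    "ROCCurve",
    "extract_features",
    "rbf_similarity",
    "rbf_map",
    "svm_train",
    "hinge_objective",
    "decision_function",
    "confusion_counts",
    "roc_curve",
    "RBFMaxMarginClassifier",
]


@dataclass
class SampleFeatures:
    sample_id: str
    sum_expr: float
    sd_expr: float
    label: int | None = None  # 0 = control, 1 = patient


def extract_features(panel: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Per-sample (sum, SD) of the four panel genes -> (n, 2) array.

    ``ddof=0`` (population SD, divide by 4) is the default; both statistics
    are symmetric in the genes, so gene order does not matter.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2 or panel.shape[0] < 4:
        raise ValueError("panel must be a (>=4 genes) x samples matrix")
    return np.column_stack([panel.sum(axis=0), panel.std(axis=0, ddof=ddof)])


@dataclass
class FeatureScaler:
    """z-scoring with training-set statistics (RBF distances are
    scale-sensitive)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, F: np.ndarray) -> "FeatureScaler":
        F = np.asarray(F, dtype=float)
        sd = F.std(axis=0, ddof=0)
        return cls(mean=F.mean(axis=0), sd=np.where(sd == 0, 1.0, sd))

    def transform(self, F: np.ndarray) -> np.ndarray:
        return (np.asarray(F, dtype=float) - self.mean) / self.sd


def rbf_similarity(x: np.ndarray, l: np.ndarray, sigma2: float = 0.5) -> float:
    """exp(-||x - l||^2 / (2 sigma^2)); in (0, 1], equal to 1 iff x == l."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = np.asarray(x, dtype=float)
    l = np.asarray(l, dtype=float)
    if x.shape != l.shape:
        raise ValueError("feature vectors have different dimensions")
    return float(np.exp(-np.sum((x - l) ** 2) / (2.0 * sigma2)))


def rbf_map(F: np.ndarray, landmarks: np.ndarray, sigma2: float = 0.5) -> np.ndarray:
    """Map each sample to its vector of similarities to all landmarks."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    landmarks = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if landmarks.shape[0] == 0:
        raise ValueError("landmark set is empty")
    D2 = cdist(np.atleast_2d(np.asarray(F, dtype=float)), landmarks, metric="sqeuclidean")
    return np.exp(-D2 / (2.0 * sigma2))


@dataclass
class SVMModel:
    w: np.ndarray
    b: float
    C: float
    n_iter: int
    objective: float

    @property
    def margin(self) -> float:
        """Geometric margin 1 / ||w||^2 as tracked during training."""
        nrm2 = float(self.w @ self.w)
        return np.inf if nrm2 == 0 else 1.0 / nrm2


def hinge_objective(w: np.ndarray, b: float, Y: np.ndarray, labels: np.ndarray, C: float) -> float:
    """0.5 ||w||^2 + C * sum_i max(0, 1 - y_i (w . Y_i + b))."""
    margins = labels * (Y @ w + b)
    return float(0.5 * w @ w + C * np.clip(1.0 - margins, 0.0, None).sum())


def svm_train(
    Y: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    n_iter: int = 100_000,
    seed: int = 0,
    bias_scale: float = 5.0,
) -> SVMModel:
    """Seeded stochastic subgradient descent on the hinge objective.

    Labels must contain both classes (coded +1 / -1, or 0/1 which is
    recoded).  Pegasos step sizes on the equivalent scaled objective
    (lambda = 1 / (C n)) with projection and averaging of the second half of
    the iterates.  The bias is folded into the weights through a constant
    feature of value ``bias_scale``, so it is only lightly regularized (the
    extra penalty is b^2 / (2 bias_scale^2), negligible for the default
    scale); the reported objective is the plain hinge objective of (w, b).
    """
    Y = np.asarray(Y, dtype=float)
    y = np.asarray(labels, dtype=float).copy()
    uniq = set(np.unique(y))
    if uniq == {0.0, 1.0}:
        y = 2.0 * y - 1.0
    elif not uniq <= {-1.0, 1.0}:
        raise ValueError("labels must be coded 0/1 or -1/+1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("training requires both classes")
    if C <= 0:
        raise ValueError("C must be positive")
    n, d = Y.shape
    Z = np.column_stack([Y, np.full(n, bias_scale)])
    lam = 1.0 / (C * n)
    rng = np.random.default_rng(seed)
    w = np.zeros(d + 1)
    w_sum = np.zeros(d + 1)
    n_avg = 0
    half = n_iter // 2
    radius = 1.0 / np.sqrt(lam)
    for t in range(1, n_iter + 1):
        i = int(rng.integers(n))
        eta = 1.0 / (lam * t)
        margin = y[i] * (w @ Z[i])
        w *= 1.0 - eta * lam
        if margin < 1.0:
            w += eta * y[i] * Z[i]
        nrm = np.linalg.norm(w)
        if nrm > radius:
            w *= radius / nrm
        if t > half:
            w_sum += w
            n_avg += 1
    w_avg = w_sum / n_avg
    w_out, b_out = w_avg[:-1], float(bias_scale * w_avg[-1])
    obj = hinge_objective(w_out, b_out, Y, y, C)
    logger.info("SVM trained: %d iters, objective %.6g", n_iter, obj)
    return SVMModel(w=w_out, b=b_out, C=C, n_iter=n_iter, objective=obj)


def decision_function(model: SVMModel, Y: np.ndarray) -> np.ndarray:
    return np.asarray(Y, dtype=float) @ model.w + model.b


@dataclass
class ConfusionCounts:
    """Confusion counts at a threshold: p = TP, n = FN, t = TN, f = FP."""

    p: int
    n: int
    t: int
    f: int

    @property
    def sensitivity(self) -> float:
        return self.p / (self.p + self.n) if (self.p + self.n) else 0.0

    @property
    def specificity(self) -> float:
        return self.t / (self.f + self.t) if (self.f + self.t) else 0.0


def confusion_counts(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) > 0
    pred = scores >= threshold
    return ConfusionCounts(
        p=int(np.sum(pred & pos)),
        n=int(np.sum(~pred & pos)),
        t=int(np.sum(~pred & ~pos)),
        f=int(np.sum(pred & ~pos)),
    )


@dataclass
class ROCCurve:
    """Ordered ROC points (1 - specificity, sensitivity) and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Threshold sweep over the sorted unique decision values.

    Tied scores collapse into a single threshold step; the curve starts at
    (0, 0), ends at (1, 1) and is monotone nondecreasing in both
    coordinates.  AUC is computed by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    pos = (np.asarray(labels) > 0).astype(float)
    P = pos.sum()
    N = len(pos) - P
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # last index of each tied block
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1.0 - y)[distinct]
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


@dataclass
class RBFMaxMarginClassifier:
    """Convenience wrapper: scale -> RBF-map -> max-margin training.

    Landmarks default to the (scaled) training samples, the standard
    landmark construction.
    """

    sigma2: float = 0.5
    C: float = 1.0
    n_iter: int = 100_000
    seed: int = 0
    scaler: FeatureScaler | None = None
    landmarks: np.ndarray | None = None
    model: SVMModel | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "RBFMaxMarginClassifier":
        self.scaler = FeatureScaler.fit(features)
        Fs = self.scaler.transform(features)
        if self.landmarks is None:
            self.landmarks = Fs
        Y = rbf_map(Fs, self.landmarks, self.sigma2)
        self.model = svm_train(Y, labels, C=self.C, n_iter=self.n_iter, seed=self.seed)
        return self

    def decision(self, features: np.ndarray) -> np.ndarray:
        if self.model is None or self.scaler is None:
            raise RuntimeError("classifier is not fitted")
        Y = rbf_map(self.scaler.transform(features), self.landmarks, self.sigma2)
        return decision_function(self.model, Y)
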