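"""Gene-wise two-sample differential-expression screening.

Independent two-sample t-tests between a case and a control matrix at a raw
significance threshold (default alpha = 0.05, no multiple-testing
correction, mirroring the original screen that yielded 16 up- / 14
down-regulated genes).  Welch's unequal-variance variant is the default —
the safe choice for the 7-9 samples per group of this design; the pooled
Student variant is available for sensitivity checks.  An optional
Benjamini-Hochberg column is provided as a clearly labelled extension.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "two_sample_ttest", "screen_genes"]


@dataclass
class DEResult:
    gene_id: str
    t_statistic: float
    p_value: float
    direction: str  # up / down / unchanged (case relative to control)
    mean_case: float
    mean_control: float


def two_sample_ttest(
    x: np.ndarray, y: np.ndarray, variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided independent t-test; ``welch`` or ``student`` (pooled).

    Degenerate zero-variance inputs: equal means -> (0, 1); unequal means ->
    (signed inf, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in t-test input")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (extension, not used for
    the default screen)."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def screen_genes(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    alpha: float = 0.05,
    variant: str = "welch",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test and up/down call at strict p < alpha.

    Returns a DataFrame with columns gene_id, t, p, direction, mean_case,
    mean_control (and adj_p when ``bh_adjust``).  Directions are relative to
    control: "up" means case mean > control mean with p < alpha.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    if set(case.gene_ids) != set(control.gene_ids):
        raise ValueError("case and control matrices have different gene sets")
    control = control.subset_genes(case.gene_ids)
    X, Y = case.values, control.values
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(X, Y, axis=1, equal_var=(variant == "student"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate rows: both groups constant
    both_const = (X.var(axis=1, ddof=1) == 0) & (Y.var(axis=1, ddof=1) == 0)
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    eq = both_const & (mx == my)
    ne = both_const & (mx != my)
    t[eq], p[eq] = 0.0, 1.0
    t[ne], p[ne] = np.sign(mx[ne] - my[ne]) * np.inf, 0.0
    if ne.any():
        warnings.warn(f"{int(ne.sum())} gene(s) with zero variance and unequal means; p -> 0")
    sig = p < alpha
    direction = np.where(sig & (mx > my), "up", np.where(sig & (mx < my), "down", "unchanged"))
    out = pd.DataFrame(
        {
            "gene_id": case.gene_ids,
            "t": t,
            "p": p,
            "direction": direction,
            "mean_case": mx,
            "mean_control": my,
        }
    )
    if bh_adjust:
        out["adj_p"] = _bh_adjust(p)
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    logger.info("DE screen (%s, alpha=%g): %d up, %d down of %d genes", variant, alpha, n_up, n_down, len(out))
    return out
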