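"""Log transform and severity-group partition of expression matrices.

The pipeline works on x = log10(g + 1) values; the transform removes the
magnitude differences between microarray samples.  The matrix is then split
into one genes x n_g submatrix per severity group (the GSE1297 design has
groups of 9 / 7 / 8 / 7 samples for control / incipient / moderate / severe),
and the four-gene panel is extracted in fixed panel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenePanel,
    GROUP_NAMES,
    Scale,
    align_metadata,
    validate_metadata,
)

__all__ = ["log_transform", "partition_by_group", "extract_panel", "GroupedPanel", "grouped_panel"]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise x = log10(g + 1); refuses to run twice (scale flag only)."""
    if m.scale is Scale.LOG10:
        raise ValueError("matrix is already on the log10 scale; refusing to transform again")
    neg = np.argwhere(m.values < 0)
    if len(neg):
        i, j = neg[0]
        raise ValueError(
            f"negative expression value at gene {m.gene_ids[i]!r}, sample {m.sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), np.log10(m.values + 1.0), Scale.LOG10
    )


def partition_by_group(m: ExpressionMatrix, meta: pd.DataFrame) -> dict[int, ExpressionMatrix]:
    """Split columns by severity group code, preserving original sample order.

    Every matrix sample must appear in the metadata; a group code present in
    the metadata but matching no matrix sample is an error.
    """
    meta = validate_metadata(meta)
    aligned = align_metadata(m, meta)
    present = set(aligned["sample_id"])
    missing = [s for s in m.sample_ids if s not in present]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    group_of = dict(zip(aligned["sample_id"], aligned["group"]))
    out: dict[int, ExpressionMatrix] = {}
    for code in sorted({int(g) for g in group_of.values()}):
        cols = [s for s in m.sample_ids if group_of[s] == code]
        out[code] = m.subset_samples(cols)
    empty = {int(g) for g in meta["group"]} - set(out)
    if empty:
        names = [GROUP_NAMES.get(c, str(c)) for c in sorted(empty)]
        raise ValueError(f"group(s) with zero samples in the matrix: {names}")
    return out


def extract_panel(m: ExpressionMatrix, panel: GenePanel | None = None) -> np.ndarray:
    """Return the panel submatrix (rows in panel order) as a plain array."""
    panel = panel or GenePanel()
    sub = m.subset_genes(list(panel.symbols))
    if not np.all(np.isfinite(sub.values)):
        i, j = np.argwhere(~np.isfinite(sub.values))[0]
        raise ValueError(
            f"missing/non-finite panel value at gene {sub.gene_ids[i]!r}, "
            f"sample {sub.sample_ids[j]!r}"
        )
    return sub.values


@dataclass
class GroupedPanel:
    """Per-group panel matrices (each s x n_g, log10 scale, rows in panel order)."""

    panel: GenePanel
    matrices: dict[int, np.ndarray]
    sample_ids: dict[int, list[str]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        return {g: x.shape[1] for g, x in self.matrices.items()}


def grouped_panel(
    m: ExpressionMatrix, meta: pd.DataFrame, panel: GenePanel | None = None
) -> GroupedPanel:
    """Log-check, partition by group and extract the panel in one step."""
    if m.scale is not Scale.LOG10:
        raise ValueError("grouped_panel expects a log10-scale matrix; apply log_transform first")
    panel = panel or GenePanel()
    parts = partition_by_group(m, meta)
    return GroupedPanel(
        panel,
        {g: extract_panel(sub, panel) for g, sub in parts.items()},
        {g: list(sub.sample_ids) for g, sub in parts.items()},
    )
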