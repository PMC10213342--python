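"""Domain types and readers/writers for expression matrices and sample metadata.

The package operates on hippocampal microarray expression tables (genes x
samples) together with a per-sample clinical table giving the dementia
severity group (control / incipient / moderate / severe), the MMSE cognitive
score (0-30, lower = more impaired) and optional covariates (NFT burden,
Braak stage, age, sex, post-mortem interval).

Two text dialects are supported: a plain TSV with a ``gene_id`` first column,
and the GEO series-matrix layout (the table between the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers of a
series-matrix file, e.g. for accession GSE1297).
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "GenePanel",
    "DEFAULT_PANEL",
    "GENE_ALIASES",
    "GROUP_CODES",
    "GROUP_NAMES",
    "read_expression",
    "write_expression",
    "write_series_matrix",
    "read_metadata",
    "validate_metadata",
    "align_metadata",
    "map_probes_to_genes",
]


class Scale(str, Enum):
    """Whether expression values are raw intensities or log10(g+1) values."""

    RAW = "raw"
    LOG10 = "log10"


#: Panel order is fixed; eigenvector components are always reported in this order.
DEFAULT_PANEL: tuple[str, ...] = ("BAG2", "HSC70", "STUB1", "MAPT")

#: Protein-name aliases accepted when matching mapping tables (HSC70 is the
#: protein encoded by HSPA8).
GENE_ALIASES: dict[str, str] = {"HSC70": "HSPA8"}

#: Severity-group numeric coding used throughout (control=1 ... severe=4).
GROUP_CODES: dict[str, int] = {
    "control": 1,
    "incipient": 2,
    "incipient ad": 2,
    "moderate": 3,
    "severe": 4,
}
GROUP_NAMES: dict[int, str] = {1: "control", 2: "incipient", 3: "moderate", 4: "severe"}

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(dups)}")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with an explicit scale flag.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique row/column identifiers (probe IDs or gene symbols).
    values
        Numeric matrix of shape ``(len(gene_ids), len(sample_ids))``.  NaN is
        tolerated in the full matrix but rejected in panel submatrices.
    scale
        ``Scale.RAW`` for nonnegative intensities, ``Scale.LOG10`` after the
        x = log10(g + 1) transform.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        self.scale = Scale(self.scale)
        if self.scale is Scale.RAW:
            with np.errstate(invalid="ignore"):
                if np.nanmin(self.values) < 0:
                    i, j = np.argwhere(self.values < 0)[0]
                    raise ValueError(
                        "raw expression values must be nonnegative; first "
                        f"negative cell at gene {self.gene_ids[i]!r}, "
                        f"sample {self.sample_ids[j]!r}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: Scale = Scale.RAW) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.scale
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[idx, :], self.scale
        )


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene panel; defaults to the chaperone/tau four-gene set."""

    symbols: tuple[str, ...] = DEFAULT_PANEL
    probe_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.symbols, "panel symbols")

    def __len__(self) -> int:
        return len(self.symbols)


def _frame_to_matrix(df: pd.DataFrame, path: str) -> ExpressionMatrix:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    _check_unique([str(i) for i in df.index], "gene IDs")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    as_str = df.astype(str).apply(lambda c: c.str.strip().str.lower())
    bad = numeric.isna() & ~as_str.isin(_MISSING_TOKENS)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    m = ExpressionMatrix.from_frame(numeric, Scale.RAW)
    logger.info("read %d genes x %d samples from %s", m.n_genes, m.n_samples, path)
    return m


def read_expression(path: str | Path, dialect: str = "plain_tsv") -> ExpressionMatrix:
    """Read a raw-scale expression matrix from a TSV or GEO series-matrix file.

    ``plain_tsv``: header row of sample IDs, first column gene IDs.
    ``geo_series_matrix``: the tab-separated table between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers;
    all other ``!`` metadata lines are ignored and quoted IDs are unquoted.
    """
    path = Path(path)
    if dialect == "plain_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "geo_series_matrix":
        lines = path.read_text().splitlines()
        try:
            lo = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
            hi = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
        except StopIteration:
            raise ValueError(f"{path}: series-matrix table markers not found") from None
        block = "\n".join(lines[lo + 1 : hi])
        df = pd.read_csv(_io.StringIO(block), sep="\t", index_col=0, dtype=str)
        df.index = [re.sub(r'^"|"$', "", str(i)) for i in df.index]
        df.columns = [re.sub(r'^"|"$', "", str(c)) for c in df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = [str(i) for i in df.index]
    return _frame_to_matrix(df, str(path))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as plain TSV (first column header ``gene_id``)."""
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_series_matrix(m: ExpressionMatrix, path: str | Path, title: str = "synthetic series") -> None:
    """Write a minimal GEO-series-matrix-style file (synthetic fixture writer)."""
    with open(path, "w") as fh:
        fh.write(f'!Series_title\t"{title}"\n')
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s}"' for s in m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(f'"{g}"\t' + "\t".join(repr(float(v)) for v in row) + "\n")
        fh.write("!series_matrix_table_end\n")


def _code_group(label: object) -> int:
    s = str(label).strip().lower()
    if s in GROUP_CODES:
        return GROUP_CODES[s]
    try:
        code = int(float(s))
    except ValueError:
        code = -1
    if code in GROUP_NAMES:
        return code
    raise ValueError(
        f"unknown group label {label!r}; allowed: "
        f"{sorted(set(GROUP_CODES))} or codes 1-4"
    )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize a metadata table: unique sample_id, group coded 1-4,
    MMSE (when present) in [0, 30]."""
    meta = meta.copy()
    meta.columns = [str(c).strip().lower() for c in meta.columns]
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    _check_unique(list(meta["sample_id"]), "sample IDs")
    meta["group"] = [_code_group(g) for g in meta["group"]]
    if "mmse" in meta.columns:
        meta["mmse"] = pd.to_numeric(meta["mmse"], errors="coerce")
        bad = meta["mmse"].dropna()
        out = bad[(bad < 0) | (bad > 30)]
        if len(out):
            raise ValueError(
                f"MMSE outside [0, 30] for samples "
                f"{list(meta.loc[out.index, 'sample_id'])}: {list(out)}"
            )
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV with at least ``sample_id`` and ``group``."""
    return validate_metadata(pd.read_csv(path, sep="\t"))


def align_metadata(m: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Inner-join metadata to the matrix, preserving the matrix sample order."""
    meta = validate_metadata(meta)
    by_id = meta.set_index("sample_id")
    shared = [s for s in m.sample_ids if s in by_id.index]
    dropped_meta = len(by_id) - len(shared)
    dropped_expr = m.n_samples - len(shared)
    if dropped_expr or dropped_meta:
        logger.warning(
            "metadata join dropped %d expression samples and %d metadata rows",
            dropped_expr,
            dropped_meta,
        )
    return by_id.loc[shared].reset_index()


def _canonical(symbol: str) -> set[str]:
    s = symbol.upper()
    names = {s}
    if s in GENE_ALIASES:
        names.add(GENE_ALIASES[s].upper())
    for alias, target in GENE_ALIASES.items():
        if target.upper() == s:
            names.add(alias.upper())
    return names


def map_probes_to_genes(
    m: ExpressionMatrix,
    mapping: Mapping[str, str] | pd.DataFrame,
    policy: str = "max_mean",
    listed: Mapping[str, str] | None = None,
    symbols: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Collapse probe-level rows to one row per gene symbol.

    Policies: ``max_mean`` keeps the probe with the highest mean expression;
    ``listed_probe`` keeps the probe given in ``listed[symbol]``;
    ``mean_collapse`` averages all mapped probes.  Protein-name aliases
    (HSC70 -> HSPA8) are honoured on both sides.  Returns the collapsed
    matrix and the probes chosen per symbol (provenance).
    """
    if isinstance(mapping, pd.DataFrame):
        cols = [c.lower() for c in mapping.columns]
        mapping = dict(
            zip(
                mapping.iloc[:, cols.index("probe")].astype(str),
                mapping.iloc[:, cols.index("symbol")].astype(str),
            )
        )
    by_symbol: dict[str, list[str]] = {}
    probe_pos = {p: i for i, p in enumerate(m.gene_ids)}
    for probe, symbol in mapping.items():
        if probe in probe_pos:
            by_symbol.setdefault(str(symbol).upper(), []).append(probe)
    if symbols is None:
        symbols = sorted(by_symbol)
    rows, chosen = [], {}
    for sym in symbols:
        probes: list[str] = []
        for name in _canonical(sym):
            probes.extend(by_symbol.get(name, []))
        if not probes:
            raise ValueError(f"no probe in the matrix maps to gene symbol {sym!r}")
        probes = sorted(set(probes), key=lambda p: probe_pos[p])
        if policy == "max_mean":
            means = [np.nanmean(m.values[probe_pos[p]]) for p in probes]
            pick = probes[int(np.argmax(means))]
            rows.append(m.values[probe_pos[pick]])
            chosen[sym] = [pick]
        elif policy == "listed_probe":
            if listed is None or sym not in listed:
                raise ValueError(f"policy 'listed_probe' requires an explicit probe for {sym!r}")
            pick = listed[sym]
            if pick not in probe_pos:
                raise ValueError(f"listed probe {pick!r} for {sym!r} not in matrix")
            rows.append(m.values[probe_pos[pick]])
            chosen[sym] = [pick]
        elif policy == "mean_collapse":
            rows.append(np.mean([m.values[probe_pos[p]] for p in probes], axis=0))
            chosen[sym] = probes
        else:
            raise ValueError(f"unknown probe policy {policy!r}")
    logger.info("probe collapse (%s): %s", policy, chosen)
    out = ExpressionMatrix(list(symbols), list(m.sample_ids), np.vstack(rows), m.scale)
    return out, chosen
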