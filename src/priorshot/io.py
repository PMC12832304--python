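"""Reading, writing and aligning expression matrices, priors, labels.

Conventions
-----------
* Expression and loading matrices live in pandas DataFrames with gene
  symbols as the index.  Expression columns are sample ids; loading columns
  are latent-variable (LV) ids.  Values are log2-scale expression and real
  loadings respectively.
* Labels are a pandas Series of {0 = control, 1 = case} indexed by sample id.
* Gene symbols are matched case-sensitively and never alias-resolved.

Duplicate gene symbols in an expression file (e.g. multiple microarray
probes collapsed to one symbol) are reduced to a single row by the
element-wise median; for an even number of duplicates the median is the
mean of the two central values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_ALIASES = {"0": 0, "1": 1, "control": 0, "case": 1}


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentError(ValueError):
    """Gene spaces cannot be aligned (empty intersection)."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _validate_matrix(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{what} has duplicate row ids, e.g. {dupes}")
    if df.columns.has_duplicates:
        raise FormatError(f"{what} has duplicate column ids")
    if not np.all(np.isfinite(df.to_numpy())):
        bad = df.index[~np.isfinite(df.to_numpy()).all(axis=1)][:5].tolist()
        raise FormatError(f"{what} has non-finite values in rows {bad}")
    return df


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{what} file {path} is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{what} file {path} has no data rows/columns")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[:1]
            raise FormatError(
                f"non-numeric value in {what} file {path}, "
                f"row {bad.tolist()}, column {col!r}"
            )
    return df.astype(float)


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows to their element-wise median.

    Idempotent: a matrix without duplicate symbols is returned unchanged
    (same row order).
    """
    if not df.index.has_duplicates:
        return df
    collapsed = df.groupby(level=0, sort=False).median()
    return collapsed


def read_expression(path: str | Path, collapse: str = "median") -> pd.DataFrame:
    """Read a genes x samples expression table (TSV/CSV, symbols in column 1).

    Parameters
    ----------
    collapse : {"median"}
        How duplicate gene symbols are merged.  Only the element-wise
        median is supported.
    """
    if collapse != "median":
        raise ValueError(f"unsupported collapse rule {collapse!r}")
    df = _read_table(path, "expression")
    df = collapse_duplicate_genes(df)
    return _validate_matrix(df, "expression matrix")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    """Write genes x samples expression; full float precision round-trips."""
    df.to_csv(Path(path), sep=_sep_for(path), index_label="gene",
              float_format="%.17g")


def read_loadings(path: str | Path) -> pd.DataFrame:
    """Read a fixed genes x LVs loading matrix.  Treated as read-only."""
    df = _read_table(path, "loadings")
    return _validate_matrix(df, "loading matrix")


def write_loadings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep=_sep_for(path), index_label="gene",
              float_format="%.17g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample_id / label table; labels {0,1} or {control,case}."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"label table {path} must have two columns")
    sample_ids = df.iloc[:, 0].astype(str)
    if sample_ids.duplicated().any():
        raise FormatError(f"duplicate sample ids in label table {path}")
    raw = df.iloc[:, 1].str.strip().str.lower()
    unknown = sorted(set(raw) - set(LABEL_ALIASES))
    if unknown:
        raise FormatError(f"unrecognised labels {unknown} in {path}")
    labels = raw.map(LABEL_ALIASES).astype(int)
    labels.index = pd.Index(sample_ids.to_numpy(), name=None)
    labels.name = "label"
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()}).to_csv(
        Path(path), sep=_sep_for(path), index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line; '#' starts a comment."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def align_to_prior(
    X: pd.DataFrame, Z: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict expression and prior to their common genes, same row order.

    The intersection keeps the expression matrix's gene order.  Counts of
    genes dropped on each side are logged.
    """
    common = X.index.intersection(Z.index)
    if len(common) == 0:
        raise AlignmentError("expression and loading matrices share no genes")
    logger.info(
        "gene alignment: %d common; dropped %d from expression, %d from prior",
        len(common), X.shape[0] - len(common), Z.shape[0] - len(common),
    )
    return X.loc[common], Z.loc[common]


@dataclass
class StandardizationParams:
    """Training-derived per-gene location/scale (population-SD convention)."""

    mean: pd.Series
    sd: pd.Series
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.sd <= 0).any():
            raise ValueError("stored standard deviations must be positive")


def standardize_genes(
    X: pd.DataFrame, params: StandardizationParams | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each gene row.

    Fit mode (``params is None``): mean/SD are computed from ``X`` with the
    population (1/n) convention; zero-variance genes are dropped and recorded.
    Apply mode: the stored training statistics are used unchanged, so query
    samples leak nothing into the scaling.
    """
    if params is None:
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=0)
        keep = sd > 0
        dropped = X.index[~keep].tolist()
        if dropped:
            logger.warning("dropping %d zero-variance genes", len(dropped))
        params = StandardizationParams(mean=mean[keep], sd=sd[keep],
                                       dropped_genes=dropped)
    missing = params.mean.index.difference(X.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} genes in standardization params missing from input, "
            f"e.g. {missing[:5].tolist()}"
        )
    Xs = X.loc[params.mean.index]
    out = Xs.sub(params.mean, axis=0).div(params.sd, axis=0)
    return out, params
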