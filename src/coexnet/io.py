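"""Readers and writers for the pipeline's tabular formats.

All expression data is handled as a pandas DataFrame with genes in rows and
samples in columns (log-scale normalized intensities).  Trait and covariate
tables are samples x variables DataFrames.  Missing values use the token
``NA`` on disk and ``NaN`` in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "load_probe_map",
    "load_trait_table",
    "load_module_assignment",
    "load_gmt",
    "write_module_assignment",
    "collapse_probes",
    "validate_expression",
]


def validate_expression(expr: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Check the invariants of a genes x samples expression matrix.

    Raises ``ValueError`` on duplicate gene or sample identifiers, non-finite
    values, or fewer than ``min_samples`` samples.  Returns the frame
    unchanged so the call can be chained.
    """
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:10]}")
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )
    if expr.shape[1] < min_samples:
        raise ValueError(
            f"expression matrix has {expr.shape[1]} samples; "
            f"at least {min_samples} required"
        )
    return expr


def load_expression(path: str | Path, orientation: str = "genes_in_rows") -> pd.DataFrame:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path
        TSV with one header row of identifiers and one leading identifier
        column.
    orientation
        ``genes_in_rows`` (default) or ``samples_in_rows``; the result is
        always returned genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty expression file: {path}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value {df[col].iloc[i]!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
        df = df.apply(pd.to_numeric)
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return validate_expression(df, min_samples=1)


def load_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column ``probe_id<TAB>gene_id`` map (header auto-detected).

    Returns a probe -> gene Series.  A first line is treated as a header when
    its probe id reappears nowhere else and the file parses either way; the
    practical rule used here: if the first row's fields equal common header
    words ("probe", "gene", ...) case-insensitively, it is skipped.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two tab-separated columns")
    first = [str(x).strip().lower() for x in raw.iloc[0, :2]]
    header_words = {"probe", "probe_id", "probeid", "gene", "gene_id", "geneid", "symbol"}
    if first[0] in header_words or first[1] in header_words:
        raw = raw.iloc[1:]
    mapping = pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values, dtype=str)
    if mapping.index.duplicated().any():
        dups = mapping.index[mapping.index.duplicated()].unique().tolist()
        raise ValueError(f"probes mapped more than once: {dups[:10]}")
    return mapping


def load_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x variables table (traits or covariates); 'NA' = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:10]}")
    return df.astype(float)


def load_module_assignment(path: str | Path) -> pd.Series:
    """Read a ``gene_id<TAB>module_label`` partition ('grey' = unassigned)."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] < 2:
        raise ValueError(f"module assignment {path} needs two columns")
    first = [str(x).strip().lower() for x in raw.iloc[0, :2]]
    if first[0] in {"gene", "gene_id", "geneid"} or first[1] in {"module", "module_label", "color"}:
        raw = raw.iloc[1:]
    assign = pd.Series(raw.iloc[:, 1].values, index=raw.iloc[:, 0].values, dtype=str)
    if assign.index.duplicated().any():
        raise ValueError("duplicate gene identifiers in module assignment")
    return assign


def write_module_assignment(assign: pd.Series, path: str | Path) -> None:
    assign.rename("module").rename_axis("gene_id").to_csv(path, sep="\t", header=False)


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: ``term<TAB>description<TAB>gene1...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def collapse_probes(expr: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Merge probe-level rows to gene level by averaging.

    Probes absent from the map are dropped (count logged).  Multiple probes
    of one gene are summarized by the arithmetic mean per sample.
    """
    shared = expr.index.intersection(probe_map.index)
    if len(shared) == 0:
        raise ValueError("no probes in the expression matrix appear in the probe map")
    dropped = expr.shape[0] - len(shared)
    if dropped:
        logger.info("collapse_probes: dropped %d probes absent from the map", dropped)
    sub = expr.loc[shared]
    genes = probe_map.loc[shared]
    collapsed = sub.groupby(genes.values).mean()
    collapsed.index = collapsed.index.astype(str)
    collapsed.index.name = expr.index.name
    return collapsed
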