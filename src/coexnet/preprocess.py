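"""Sample quality control and cell-type deconvolution.

Outlier samples are flagged by standardized sample network connectivity:
pairwise sample distances are turned into a sample adjacency
``A_ij = 1 - d_ij / max(d)``, each sample's connectivity ``k_i`` is the sum
of its adjacencies to the other samples, and ``Z_k = (k - mean k) / sd k``.
Samples with ``Z_k`` below a threshold (default -5) are removed.

Cell-type fractions are estimated per sample by nonnegative least squares of
the expression profile on a genes x cell-types reference signature matrix,
renormalized to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = ["SampleQC", "sample_connectivity_z", "remove_outlier_samples", "estimate_cell_fractions"]


@dataclass
class SampleQC:
    """Standardized sample connectivity and the outlier call derived from it."""

    z_k: pd.Series                      # per-sample standardized connectivity
    threshold: float = -5.0
    distance: str = "euclidean"
    outliers: pd.Index = field(init=False)

    def __post_init__(self) -> None:
        self.outliers = self.z_k.index[self.z_k < self.threshold]


def sample_connectivity_z(
    expr: pd.DataFrame, distance: str = "euclidean", threshold: float = -5.0
) -> SampleQC:
    """Standardized sample network connectivity Z_k.

    Parameters
    ----------
    expr
        genes x samples expression matrix (>= 3 samples).
    distance
        ``euclidean`` (on per-gene standardized expression, the default) or
        ``correlation`` (d = 1 - r between sample profiles).
    threshold
        Z_k below this marks an outlier sample.

    Notes
    -----
    If all samples are equidistant (sd of connectivity is zero) every Z_k is
    defined as 0 and no sample is an outlier.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"sample QC requires >= 3 samples, got {n}")
    x = expr.to_numpy(dtype=float)
    if distance == "euclidean":
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=1, keepdims=True)) / sd
        g = z.T @ z                                  # samples x samples Gram
        sq = np.diag(g)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0)
        d = np.sqrt(d2)
    elif distance == "correlation":
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x.T)
        r = np.nan_to_num(r, nan=0.0)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    dmax = d.max()
    if dmax == 0:
        z_k = np.zeros(n)
    else:
        adj = 1.0 - d / dmax
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        s = k.std(ddof=0)
        z_k = np.zeros(n) if s == 0 else (k - k.mean()) / s
    return SampleQC(pd.Series(z_k, index=expr.columns, name="Z.k"),
                    threshold=threshold, distance=distance)


def remove_outlier_samples(
    expr: pd.DataFrame, qc: SampleQC, threshold: float | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples whose standardized connectivity falls below the threshold.

    Returns the filtered matrix (column order preserved) and the list of
    removed sample ids.  Raises if removal would leave fewer than 3 samples.
    """
    if not qc.z_k.index.equals(expr.columns):
        raise ValueError("QC was computed on different samples than the expression matrix")
    thr = qc.threshold if threshold is None else threshold
    removed = [s for s in expr.columns if qc.z_k[s] < thr]
    kept = [s for s in expr.columns if s not in removed]
    if len(kept) < 3:
        raise ValueError(
            f"outlier removal would leave {len(kept)} samples (< 3); "
            f"threshold {thr} removed {len(removed)}"
        )
    if removed:
        logger.info("removed %d outlier samples: %s", len(removed), removed)
    return expr[kept], removed


def estimate_cell_fractions(expr: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Constrained least-squares deconvolution against a reference signature.

    For each sample, solves ``min ||R f - x||`` subject to ``f >= 0`` over the
    genes shared between ``expr`` and ``reference`` and rescales the solution
    to sum to one.  A sample with an all-zero solution receives uniform
    fractions (with a warning).

    Returns a samples x cell-types DataFrame; rows sum to 1.
    """
    if reference.shape[1] < 2:
        raise ValueError("reference signature needs at least 2 cell types")
    shared = expr.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between expression matrix and reference")
    R = reference.loc[shared].to_numpy(dtype=float)
    X = expr.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        warnings.warn("reference signature matrix is rank deficient; "
                      "fractions may not be identifiable", UserWarning, stacklevel=2)
    n_types = R.shape[1]
    out = np.empty((expr.shape[1], n_types))
    for j in range(expr.shape[1]):
        f, _ = nnls(R, X[:, j])
        total = f.sum()
        if total <= 0:
            warnings.warn(f"all-zero deconvolution solution for sample "
                          f"{expr.columns[j]!r}; using uniform fractions",
                          UserWarning, stacklevel=2)
            f = np.full(n_types, 1.0 / n_types)
        else:
            f = f / total
        out[j] = f
    return pd.DataFrame(out, index=expr.columns, columns=reference.columns)
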