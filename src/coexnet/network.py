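"""Weighted co-expression network construction and module detection.

The chain implemented here is the classic weighted gene co-expression
recipe: Pearson correlation between all gene pairs, soft-thresholding to a
weighted adjacency (``a_ij = |r_ij|^beta`` unsigned, or
``((1 + r_ij)/2)^beta`` signed), the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu a_uj,      k_i = sum_{u != i} a_iu,

average-linkage hierarchical clustering of ``1 - TOM``, an adaptive
(dynamic) cut of the dendrogram into modules of at least ``min_module_size``
genes, module eigengenes (first principal component of the standardized
module submatrix), and iterative merging of modules whose eigengenes are
correlated above ``1 - merge_cut_height``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .treecut import cut_dendrogram_dynamic

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "correlation_matrix",
    "adjacency_from_correlation",
    "scale_free_fit",
    "tom_similarity",
    "cluster_genes",
    "cut_dendrogram_dynamic",
    "compute_eigengenes",
    "merge_modules",
    "label_modules_by_size",
    "MODULE_COLORS",
    "GREY",
]

GREY = "grey"

#: Canonical module color sequence, assigned to modules in decreasing size
#: order ("grey" is reserved for unassigned genes).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class NetworkParams:
    """Tuning parameters of network construction and module detection.

    power
        Soft-thresholding exponent beta (default 6).
    adjacency_type
        ``unsigned`` (|r|^beta, default) or ``signed`` (((1+r)/2)^beta).
    min_module_size
        Smallest allowed module (default 30).
    deep_split
        Split sensitivity 0-4 of the dynamic cut; larger values produce
        more, smaller modules (default 2).
    merge_cut_height
        Modules whose eigengene dissimilarity 1 - cor falls below this are
        merged (default 0.25).
    reassign_threshold
        p-value threshold for post-hoc reassignment of genes between modules;
        0 (the default) disables the step.
    """

    power: int = 6
    adjacency_type: str = "unsigned"
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    reassign_threshold: float = 0.0
    pam_stage: bool = True

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.adjacency_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown adjacency_type {self.adjacency_type!r}")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all gene pairs across samples.

    Raises on constant gene rows (undefined correlation) and on fewer than
    3 samples; the diagonal is exactly 1.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation requires >= 3 samples")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"constant gene rows have undefined correlation: {bad[:10]}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def adjacency_from_correlation(corr: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Soft-thresholded adjacency; entries in [0, 1] with unit diagonal."""
    r = corr.to_numpy(dtype=float)
    if params.adjacency_type == "unsigned":
        a = np.abs(r) ** params.power
    else:
        a = ((1.0 + r) / 2.0) ** params.power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def scale_free_fit(
    expr: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    adjacency_type: str = "unsigned",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scale-free topology fit index across candidate soft powers.

    For each power the network connectivity ``k_i`` is computed and split
    into ``n_bins`` equal-width bins; log10 of each bin's frequency is
    regressed on log10 of its mean connectivity.  The fit R^2 is reported
    with the usual sign convention: negated when the log-log slope is
    positive (a scale-free topology requires a decreasing frequency in k).

    Returns a DataFrame with columns ``power``, ``r_squared``,
    ``mean_connectivity``.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 11)) + [12, 14, 16, 18, 20]
    if any(p < 1 for p in candidate_powers):
        raise ValueError("candidate powers must be >= 1")
    corr = correlation_matrix(expr)
    rows = []
    for p in candidate_powers:
        params = NetworkParams(power=int(p), adjacency_type=adjacency_type)
        a = adjacency_from_correlation(corr, params).to_numpy()
        k = a.sum(axis=1) - 1.0  # exclude the unit diagonal
        rows.append((int(p), _scale_free_r2(k, n_bins), float(k.mean())))
    return pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"])


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.allclose(k, k[0]):
        warnings.warn("all connectivities identical; scale-free R^2 undefined, "
                      "reported as 0", UserWarning, stacklevel=3)
        return 0.0
    n_bins = min(n_bins, max(2, k.size // 2))
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.size < 3 or np.allclose(xs, xs[0]):
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = float(((ys - fitted) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.  The dissimilarity used for clustering is 1 - TOM.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # l_ij over all u then remove the u in {i, j} contributions
    l_full = a @ a
    l = l_full - 0.0  # a_ii = a_jj = 0 already excludes u in {i, j}
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    assert np.all(den > 0), "TOM denominator must be positive"
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_genes(diss: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) hierarchical clustering of a dissimilarity.

    Returns a scipy linkage matrix.  Input must be symmetric with a zero
    diagonal and no NaN.
    """
    d = diss.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def compute_eigengenes(
    expr: pd.DataFrame, assign: pd.Series, exclude_grey: bool = True
) -> pd.DataFrame:
    """Module eigengenes: first principal component of each module.

    Member gene rows are standardized across samples; the first right
    singular vector over samples is the eigengene, standardized to mean 0 /
    sd 1 and signed so that its mean correlation with the member genes is
    nonnegative.  Returns a samples x modules DataFrame with columns named
    ``ME<label>``; the grey (unassigned) pool is excluded by default.
    """
    assign = assign.loc[expr.index]
    labels = [m for m in pd.unique(assign) if not (exclude_grey and m == GREY)]
    if not labels:
        raise ValueError("no modules to compute eigengenes for")
    n = expr.shape[1]
    out = {}
    for m in sorted(labels):
        genes = assign.index[assign == m]
        sub = expr.loc[genes].to_numpy(dtype=float)
        if sub.shape[0] == 1:
            warnings.warn(f"module {m!r} has a single gene; its eigengene is "
                          f"that gene standardized", UserWarning, stacklevel=2)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        # first right singular vector across samples
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = (me - me.mean()) / me.std(ddof=0)
        if (z @ me).mean() < 0:  # mean cor(gene, ME) ~ z @ me / n
            me = -me
        out[f"ME{m}"] = me
    return pd.DataFrame(out, index=expr.columns)


def merge_modules(
    expr: pd.DataFrame, assign: pd.Series, params: NetworkParams
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge modules with highly correlated eigengenes.

    Eigengenes are clustered by average linkage on ``1 - cor``; every group
    of modules joined below ``merge_cut_height`` is merged (the merged module
    takes the label of its largest member) and eigengenes are recomputed.
    The procedure iterates until no further merge occurs.
    """
    assign = assign.copy()
    while True:
        me = compute_eigengenes(expr, assign)
        labels = [c[2:] for c in me.columns]
        if len(labels) < 2:
            return assign, me
        r = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - r
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        lk = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(lk, t=params.merge_cut_height, criterion="distance")
        if len(set(groups)) == len(labels):
            return assign, me
        sizes = assign.value_counts()
        for g in set(groups):
            members = [labels[i] for i in range(len(labels)) if groups[i] == g]
            if len(members) < 2:
                continue
            keep = max(members, key=lambda m: (sizes[m], m))
            logger.info("merging modules %s into %s", members, keep)
            assign[assign.isin(members)] = keep


def detect_modules(
    expr: pd.DataFrame, params: NetworkParams | None = None, merge: bool = True
) -> pd.Series:
    """Run the full module-detection chain on an expression matrix.

    correlation -> soft-threshold adjacency -> TOM -> 1 - TOM dissimilarity
    -> average linkage -> dynamic cut -> (optionally) eigengene-based merge.
    Returns a gene -> module label Series (``M1, M2, ...`` plus "grey").
    """
    params = params or NetworkParams()
    corr = correlation_matrix(expr)
    adj = adjacency_from_correlation(corr, params)
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    link = cluster_genes(diss)
    assign = cut_dendrogram_dynamic(
        link, diss,
        min_module_size=params.min_module_size,
        deep_split=params.deep_split,
        pam_stage=params.pam_stage,
    )
    if merge and (assign != GREY).any():
        assign, _ = merge_modules(expr, assign, params)
    return assign


def label_modules_by_size(assign: pd.Series) -> pd.Series:
    """Relabel modules with canonical colors in decreasing size order.

    The largest module becomes "turquoise", the second "blue", and so on;
    "grey" is untouched.  Ties are broken toward the module containing the
    lexicographically smallest gene id.  If the color list is exhausted the
    remaining modules are labeled ``module_<k>`` (with a warning).
    """
    labels = [m for m in pd.unique(assign) if m != GREY]
    keyed = sorted(
        labels,
        key=lambda m: (-int((assign == m).sum()), min(assign.index[assign == m])),
    )
    if len(keyed) > len(MODULE_COLORS):
        warnings.warn(f"{len(keyed)} modules exceed the color list "
                      f"({len(MODULE_COLORS)}); using module_<k> labels",
                      UserWarning, stacklevel=2)
    mapping = {GREY: GREY}
    for i, m in enumerate(keyed):
        mapping[m] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i + 1}"
    return assign.map(mapping)
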