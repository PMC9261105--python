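"""Module eigengene-trait association and hub-gene selection.

Associations are Pearson partial correlations: both variables are
residualized on the covariates (sex, age, age at onset, ethnicity, cell
fractions) plus an intercept by least squares, and the residuals are
correlated.  The p-value uses the t transform with ``df = n - 2 - q`` for
``q`` covariates.  Multiple testing over the module x trait family is
controlled by Benjamini-Hochberg FDR, and percentile bootstrap confidence
intervals (resampling samples with replacement) quantify uncertainty.

Gene significance (GS) is the absolute partial correlation of a gene with
a trait; module membership (MM) is the signed correlation of a gene with a
module eigengene.  Hub genes satisfy ``|MM| > 0.8`` and ``GS > 0.3``.
Significant modules are clustered by their trait-correlation profiles
(Euclidean distance, average linkage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "partial_pearson",
    "benjamini_hochberg",
    "bootstrap_correlation_ci",
    "module_trait_table",
    "gene_significance",
    "module_membership",
    "gs_mm_test",
    "select_hub_genes",
    "HubGeneSet",
    "cluster_modules_by_trait_profile",
    "ModuleClusterTree",
]


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def _complete_mask(x, y, c):
    m = np.isfinite(x) & np.isfinite(y)
    if c is not None:
        m &= np.all(np.isfinite(c), axis=1)
    return m


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Pearson partial correlation of x and y given covariates.

    Uses pairwise-complete observations.  With no covariates this reduces
    exactly to the plain Pearson correlation and its p-value.

    Returns ``(r, p, n)`` where ``n`` is the number of complete samples.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if c is not None and c.shape[0] != x.size:
        c = c.T
    mask = _complete_mask(x, y, c)
    n = int(mask.sum())
    q = 0 if c is None else c.shape[1]
    if n < q + 3:
        raise ValueError(f"need at least q + 3 = {q + 3} complete samples, got {n}")
    xm, ym = x[mask], y[mask]
    if c is not None:
        cm = c[mask]
        design = np.column_stack([np.ones(n), cm])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient (collinear columns)")
        xm = _residualize(xm, design)
        ym = _residualize(ym, design)
    else:
        xm = xm - xm.mean()
        ym = ym - ym.mean()
    sx, sy = np.sqrt((xm ** 2).sum()), np.sqrt((ym ** 2).sum())
    # relative tolerance: residuals that are pure rounding noise count as zero
    tol_x = 1e-8 * max(np.abs(x[mask]).max(), 1.0) * np.sqrt(n)
    tol_y = 1e-8 * max(np.abs(y[mask]).max(), 1.0) * np.sqrt(n)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((xm @ ym) / (sx * sy), -1.0, 1.0))
    df = n - 2 - q
    if df <= 0:
        raise ValueError("no degrees of freedom left after adjustment")
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    return r, p, n


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_correlation_ci(
    x, y, covariates=None, B: int = 1000, seed: int | None = None,
    level: float = 0.95, max_degenerate_fraction: float = 0.5,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the (partial) Pearson correlation.

    Samples are resampled with replacement ``B`` times; degenerate
    resamples (zero residual variance or a rank-deficient covariate draw)
    are redrawn, with an error once they exceed half of all draws.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if c is not None and c.shape[0] != x.size:
        c = c.T
    mask = _complete_mask(x, y, c)
    xm, ym = x[mask], y[mask]
    cm = None if c is None else c[mask]
    n = xm.size
    rng = np.random.default_rng(seed)
    rs = np.empty(B)
    degenerate = 0
    i = 0
    while i < B:
        idx = rng.integers(0, n, size=n)
        try:
            r, _, _ = partial_pearson(xm[idx], ym[idx],
                                      None if cm is None else cm[idx])
        except ValueError:
            degenerate += 1
            if degenerate > max_degenerate_fraction * B:
                raise ValueError(
                    f"more than {max_degenerate_fraction:.0%} of bootstrap "
                    f"resamples were degenerate") from None
            continue
        rs[i] = r
        i += 1
    if degenerate:
        logger.info("bootstrap: redrew %d degenerate resamples", degenerate)
    alpha = 1.0 - level
    lo, hi = np.quantile(rs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _align(me: pd.DataFrame, traits: pd.DataFrame, covars: pd.DataFrame | None):
    samples = me.index.intersection(traits.index)
    if covars is not None:
        samples = samples.intersection(covars.index)
    if len(samples) < 3:
        raise ValueError("fewer than 3 samples shared across tables")
    return samples


def module_trait_table(
    me: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    bootstrap_B: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Module eigengene x clinical trait partial-correlation table.

    One row per (module, trait) with the partial correlation ``r``, the
    sample count used, raw and BH-adjusted p-values over the whole family,
    the significance flag at FDR ``alpha``, and (when ``bootstrap_B`` > 0)
    a percentile bootstrap confidence interval.  Cells whose trait has too
    few complete observations are reported with NaN statistics.
    """
    samples = _align(me, traits, covariates)
    me = me.loc[samples]
    traits = traits.loc[samples]
    cov = None
    if covariates is not None:
        cov = covariates.loc[samples]
        dropped = cov.index[cov.isna().any(axis=1)]
        if len(dropped):
            logger.info("dropping %d samples with missing covariates", len(dropped))
            keep = cov.index.difference(dropped)
            me, traits, cov = me.loc[keep], traits.loc[keep], cov.loc[keep]
    rows = []
    rng = np.random.default_rng(seed)
    for mod in me.columns:
        for trait in traits.columns:
            x = me[mod].to_numpy()
            y = traits[trait].to_numpy()
            cv = None if cov is None else cov.to_numpy()
            try:
                r, p, n = partial_pearson(x, y, cv)
            except ValueError as exc:
                warnings.warn(f"module {mod} x trait {trait}: {exc}; "
                              f"reported as missing", UserWarning, stacklevel=2)
                rows.append((mod, trait, np.nan, 0, np.nan, np.nan, np.nan))
                continue
            if bootstrap_B > 0:
                lo, hi = bootstrap_correlation_ci(
                    x, y, cv, B=bootstrap_B,
                    seed=int(rng.integers(0, 2 ** 31 - 1)))
            else:
                lo = hi = np.nan
            rows.append((mod, trait, r, n, p, lo, hi))
    table = pd.DataFrame(rows, columns=["module", "trait", "r", "n",
                                        "p", "ci_low", "ci_high"])
    ok = table["p"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = benjamini_hochberg(table.loc[ok, "p"])
    table["p_adj"] = adj
    table["significant"] = table["p_adj"] < alpha
    # data-dependent raw-p cutoff implied by the BH decision at alpha
    sig_raw = table.loc[table["significant"], "p"]
    table.attrs["raw_p_cutoff"] = float(sig_raw.max()) if len(sig_raw) else 0.0
    table.attrs["alpha"] = alpha
    return table


def gene_significance(
    expr: pd.DataFrame, trait: pd.Series, covariates: pd.DataFrame | None = None
) -> pd.Series:
    """GS: absolute (partial) Pearson correlation of each gene with a trait."""
    samples = expr.columns.intersection(trait.index)
    if covariates is not None:
        samples = samples.intersection(covariates.index)
    x = expr[samples].to_numpy(dtype=float)
    y = trait.loc[samples].to_numpy(dtype=float)
    cv = None if covariates is None else covariates.loc[samples].to_numpy(dtype=float)
    out = np.empty(expr.shape[0])
    for i in range(expr.shape[0]):
        r, _, _ = partial_pearson(x[i], y, cv)
        out[i] = abs(r)
    return pd.Series(out, index=expr.index, name=f"GS_{trait.name}")


def module_membership(expr: pd.DataFrame, me: pd.DataFrame) -> pd.DataFrame:
    """MM (kME): signed Pearson correlation of each gene with each eigengene."""
    samples = expr.columns.intersection(me.index)
    x = expr[samples].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = expr.index[sd == 0].tolist()
        raise ValueError(f"constant genes have undefined membership: {bad[:10]}")
    zx = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    m = me.loc[samples].to_numpy(dtype=float)
    zm = (m - m.mean(axis=0)) / m.std(axis=0, ddof=0)
    mm = zx @ zm / len(samples)
    return pd.DataFrame(np.clip(mm, -1, 1), index=expr.index, columns=me.columns)


def _bare_label(label: str, assign: pd.Series) -> str:
    """Resolve a module label that may carry the eigengene 'ME' prefix."""
    if (assign == label).any():
        return label
    if label.startswith("ME") and (assign == label[2:]).any():
        return label[2:]
    raise KeyError(f"unknown module label {label!r}")


def gs_mm_test(
    gs: pd.Series, mm: pd.DataFrame, assign: pd.Series, module: str
) -> tuple[float, float]:
    """Correlation between GS and |MM| over one module's genes, with p-value."""
    module = _bare_label(module, assign)
    col = f"ME{module}" if f"ME{module}" in mm.columns else module
    if col not in mm.columns:
        raise KeyError(f"module {module!r} has no membership column")
    genes = assign.index[assign == module]
    if len(genes) < 3:
        raise ValueError(f"module {module!r} has {len(genes)} genes; need >= 3")
    g = gs.loc[genes].to_numpy()
    k = mm.loc[genes, col].abs().to_numpy()
    if np.std(g) == 0 or np.std(k) == 0:
        raise ValueError("GS or |MM| constant within the module; test undefined")
    r, p = stats.pearsonr(g, k)
    return float(r), float(p)


@dataclass
class HubGeneSet:
    """Hub genes of one module cluster: |MM| > mm_min and GS > gs_min."""

    cluster_id: int | str
    modules: list[str]
    trait: str | dict[str, str]
    gs_min: float
    mm_min: float
    table: pd.DataFrame          # gene, module, MM, GS

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())


def select_hub_genes(
    gs: pd.Series | pd.DataFrame,
    mm: pd.DataFrame,
    assign: pd.Series,
    modules: list[str],
    trait: str | dict[str, str] | None = None,
    gs_min: float = 0.3,
    mm_min: float = 0.8,
    cluster_id: int | str = 1,
) -> HubGeneSet:
    """Hub genes across a list of modules.

    ``gs`` is either a single GS vector or a genes x traits frame; in the
    latter case ``trait`` selects the column, per module when a dict
    (module -> trait of interest).  A gene is a hub of its own module when
    ``|MM|`` with that module's eigengene exceeds ``mm_min`` and its GS
    exceeds ``gs_min``.
    """
    modules = [_bare_label(m, assign) for m in modules]
    rows = []
    for m in modules:
        col = f"ME{m}" if f"ME{m}" in mm.columns else m
        genes = assign.index[assign == m]
        if isinstance(gs, pd.DataFrame):
            tname = trait[m] if isinstance(trait, dict) else trait
            gvec = gs.loc[genes, tname]
        else:
            gvec = gs.loc[genes]
        kvec = mm.loc[genes, col].abs()
        hubs = genes[(kvec > mm_min) & (gvec > gs_min)]
        for g in hubs:
            rows.append((g, m, float(mm.loc[g, col]), float(gvec.loc[g])))
    table = pd.DataFrame(rows, columns=["gene", "module", "MM", "GS"])
    table = table.drop_duplicates("gene").sort_values("gene").reset_index(drop=True)
    return HubGeneSet(cluster_id=cluster_id, modules=list(modules),
                      trait=trait if trait is not None else "",
                      gs_min=gs_min, mm_min=mm_min, table=table)


@dataclass
class ModuleClusterTree:
    """Hierarchical grouping of modules by their trait-correlation profiles."""

    modules: list[str]
    profile: pd.DataFrame        # modules x traits correlation matrix
    linkage_matrix: np.ndarray
    clusters: pd.Series          # module -> flat cluster id


def cluster_modules_by_trait_profile(
    results: pd.DataFrame, k: int = 2, only_significant: bool = True
) -> ModuleClusterTree:
    """Cluster modules by their vectors of trait correlations.

    ``results`` is a ``module_trait_table`` output.  Modules with at least
    one significant cell (default) form a modules x traits matrix of r
    values, clustered by Euclidean distance and average linkage; flat
    clusters are read at ``k`` groups.
    """
    if only_significant:
        keep = results.groupby("module")["significant"].any()
        modules = sorted(keep.index[keep])
    else:
        modules = sorted(results["module"].unique())
    if len(modules) < 2:
        raise ValueError(f"need >= 2 modules to cluster, got {len(modules)}")
    profile = results.pivot(index="module", columns="trait", values="r").loc[modules]
    k = min(k, len(modules))
    lk = linkage(pdist(profile.to_numpy(), metric="euclidean"), method="average")
    flat = fcluster(lk, t=k, criterion="maxclust")
    # renumber clusters deterministically by first module name
    order: dict[int, int] = {}
    for lab, m in zip(flat, modules):
        order.setdefault(int(lab), len(order) + 1)
    clusters = pd.Series([order[int(c)] for c in flat], index=modules, name="cluster")
    return ModuleClusterTree(modules=modules, profile=profile,
                             linkage_matrix=lk, clusters=clusters)
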