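"""Model/Results front end for the co-expression analysis.

Two estimators cover the analysis:

``CoexpressionNetwork``
    Unsupervised network model of a genes x samples expression matrix.
    ``fit()`` runs QC, soft-thresholded adjacency, topological overlap,
    average-linkage clustering, the dynamic cut, eigengene-based merging
    and size-ordered color labeling, returning ``CoexpressionResults``.

``ModuleTraitModel``
    Association model of the fitted eigengenes against clinical traits
    under covariate adjustment.  ``fit()`` returns ``AssociationResults``
    holding the module x trait partial-correlation table with BH-FDR,
    bootstrap intervals, GS/MM statistics, hub-gene sets and the module
    clustering by trait profile.

Example
-------
>>> from coexnet import simulate_study, CoexpressionNetwork, ModuleTraitModel
>>> study = simulate_study(seed=1)
>>> net = CoexpressionNetwork(study.expression).fit()
>>> assoc = ModuleTraitModel(net, study.traits, study.covariates).fit()
>>> print(assoc.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import network as net_mod
from . import preprocess, validation
from .network import GREY, NetworkParams

__all__ = ["CoexpressionNetwork", "CoexpressionResults",
           "ModuleTraitModel", "AssociationResults"]


class CoexpressionNetwork:
    """Weighted co-expression network model of an expression matrix.

    Parameters
    ----------
    expr
        genes x samples normalized expression (log scale).
    params
        :class:`~coexnet.network.NetworkParams`; defaults are beta = 6,
        unsigned adjacency, min module size 30, merge cut height 0.25.
    remove_outliers
        Apply the standardized-connectivity sample filter (Z_k < -5)
        before network construction.
    """

    def __init__(self, expr: pd.DataFrame, params: NetworkParams | None = None,
                 remove_outliers: bool = True, outlier_threshold: float = -5.0):
        self.expr = expr
        self.params = params or NetworkParams()
        self.remove_outliers = remove_outliers
        self.outlier_threshold = outlier_threshold

    def pick_soft_power(self, candidate_powers=None, r2_target: float = 0.8):
        """Scale-free fit table plus the smallest power reaching the target R^2."""
        table = net_mod.scale_free_fit(self.expr, candidate_powers,
                                       adjacency_type=self.params.adjacency_type)
        ok = table[table["r_squared"] >= r2_target]
        chosen = int(ok["power"].iloc[0]) if len(ok) else None
        return table, chosen

    def fit(self) -> "CoexpressionResults":
        expr = self.expr
        qc = None
        removed: list[str] = []
        if self.remove_outliers:
            qc = preprocess.sample_connectivity_z(
                expr, threshold=self.outlier_threshold)
            expr, removed = preprocess.remove_outlier_samples(expr, qc)
        corr = net_mod.correlation_matrix(expr)
        adj = net_mod.adjacency_from_correlation(corr, self.params)
        tom = net_mod.tom_similarity(adj)
        diss = 1.0 - tom
        np.fill_diagonal(diss.values, 0.0)
        link = net_mod.cluster_genes(diss)
        raw_assign = net_mod.cut_dendrogram_dynamic(
            link, diss,
            min_module_size=self.params.min_module_size,
            deep_split=self.params.deep_split,
            pam_stage=self.params.pam_stage,
        )
        if (raw_assign != GREY).any():
            merged, _ = net_mod.merge_modules(expr, raw_assign, self.params)
        else:
            merged = raw_assign
        assign = net_mod.label_modules_by_size(merged)
        if (assign != GREY).any():
            me = net_mod.compute_eigengenes(expr, assign)
        else:
            me = pd.DataFrame(index=expr.columns)
        return CoexpressionResults(
            model=self, expr=expr, qc=qc, removed_samples=removed,
            linkage_matrix=link, dissimilarity=diss, assignment=assign,
            eigengenes=me,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: modules, eigengenes, diagnostics."""

    model: CoexpressionNetwork
    expr: pd.DataFrame              # after outlier removal
    qc: preprocess.SampleQC | None
    removed_samples: list[str]
    linkage_matrix: np.ndarray
    dissimilarity: pd.DataFrame     # 1 - TOM
    assignment: pd.Series           # gene -> color label
    eigengenes: pd.DataFrame        # samples x MEs
    _mm: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.assignment.value_counts()
        non_grey = sizes[sizes.index != GREY].sort_values(ascending=False)
        if GREY in sizes.index:
            non_grey[GREY] = sizes[GREY]
        return non_grey

    @property
    def n_modules(self) -> int:
        return int((self.assignment.unique() != GREY).sum())

    def module_membership(self) -> pd.DataFrame:
        if self._mm is None:
            self._mm = assoc_mod.module_membership(self.expr, self.eigengenes)
        return self._mm

    def stability(self, n_iter: int = 50, sample_fraction: float = 0.8,
                  seed: int | None = None) -> validation.StabilityResult:
        """Subsampling consistency of the fitted partition."""
        return validation.module_stability(
            self.expr, self.assignment, self.model.params,
            n_iter=n_iter, sample_fraction=sample_fraction, seed=seed)

    def external_overlap(self, external: pd.Series,
                         correction: str = "bonferroni") -> pd.DataFrame:
        """Hypergeometric overlap with an external module partition."""
        return validation.cross_study_module_overlap(
            self.assignment, external, correction=correction)

    def summary(self) -> str:
        p = self.model.params
        sizes = self.module_sizes
        grey = int(sizes.get(GREY, 0))
        lines = [
            "Weighted co-expression network",
            "=" * 46,
            f"genes: {self.expr.shape[0]}   samples: {self.expr.shape[1]}"
            f"   outliers removed: {len(self.removed_samples)}",
            f"power: {p.power} ({p.adjacency_type})   min module size: "
            f"{p.min_module_size}   merge height: {p.merge_cut_height}",
            f"modules: {self.n_modules}   unassigned (grey): {grey}",
            "",
            "module sizes:",
        ]
        for m, s in sizes.items():
            if m != GREY:
                lines.append(f"  {m:<16s}{int(s):>6d}")
        return "\n".join(lines)


class ModuleTraitModel:
    """Covariate-adjusted association of module eigengenes with traits.

    Parameters
    ----------
    network
        A fitted :class:`CoexpressionResults` (or a samples x MEs frame).
    traits
        samples x clinical traits (missing values allowed).
    covariates
        samples x covariates used for partial correlation (sex, age, age at
        onset, ethnicity, cell fractions); ``None`` gives plain Pearson.
    adjusted
        Master switch: ``False`` ignores the covariates everywhere.
    """

    def __init__(self, network: CoexpressionResults | pd.DataFrame,
                 traits: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 adjusted: bool = True):
        if isinstance(network, CoexpressionResults):
            self.network = network
            self.eigengenes = network.eigengenes
        else:
            self.network = None
            self.eigengenes = network
        self.traits = traits
        self.covariates = covariates if adjusted else None

    def fit(self, alpha: float = 0.05, bootstrap_B: int = 1000,
            seed: int | None = None, gs_min: float = 0.3,
            mm_min: float = 0.8, cluster_k: int = 2) -> "AssociationResults":
        table = assoc_mod.module_trait_table(
            self.eigengenes, self.traits, self.covariates,
            alpha=alpha, bootstrap_B=bootstrap_B, seed=seed)
        return AssociationResults(
            model=self, table=table, alpha=alpha, gs_min=gs_min,
            mm_min=mm_min, cluster_k=cluster_k)


@dataclass
class AssociationResults:
    """Module x trait association results and downstream gene statistics."""

    model: ModuleTraitModel
    table: pd.DataFrame             # long module x trait table
    alpha: float
    gs_min: float
    mm_min: float
    cluster_k: int

    @property
    def significant_modules(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return sorted(sig["module"].unique())

    def correlation_matrix(self) -> pd.DataFrame:
        """Wide module x trait matrix of partial correlations."""
        return self.table.pivot(index="module", columns="trait", values="r")

    def trait_of_interest(self) -> dict[str, str]:
        """Per significant module, the trait with the largest |r|."""
        out = {}
        for m in self.significant_modules:
            sub = self.table[self.table["module"] == m]
            out[m] = sub.loc[sub["r"].abs().idxmax(), "trait"]
        return out

    def cluster_modules(self, k: int | None = None) -> assoc_mod.ModuleClusterTree:
        return assoc_mod.cluster_modules_by_trait_profile(
            self.table, k=k if k is not None else self.cluster_k)

    def gene_statistics(self, trait: str):
        """(GS vector for the trait, MM matrix) on the network's genes."""
        if self.network() is None:
            raise ValueError("gene statistics require a fitted network")
        net = self.network()
        gs = assoc_mod.gene_significance(
            net.expr, self.model.traits[trait], self.model.covariates)
        return gs, net.module_membership()

    def network(self) -> CoexpressionResults | None:
        return self.model.network

    def hub_gene_sets(self, k: int | None = None) -> list[assoc_mod.HubGeneSet]:
        """Hub genes per module cluster (|MM| > mm_min, GS > gs_min).

        Each significant module contributes hubs selected against its trait
        of interest; hubs are pooled over the modules of each trait-profile
        cluster.
        """
        net = self.network()
        if net is None:
            raise ValueError("hub selection requires a fitted network")
        tree = self.cluster_modules(k)
        interest = self.trait_of_interest()
        mm = net.module_membership()
        gs_cache: dict[str, pd.Series] = {}
        out = []
        for cid in sorted(tree.clusters.unique()):
            mods = sorted(tree.clusters.index[tree.clusters == cid])
            rows = []
            for m in mods:
                t = interest[m]
                if t not in gs_cache:
                    gs_cache[t] = assoc_mod.gene_significance(
                        net.expr, self.model.traits[t], self.model.covariates)
                hub = assoc_mod.select_hub_genes(
                    gs_cache[t], mm, net.assignment, [m], trait=None,
                    gs_min=self.gs_min, mm_min=self.mm_min, cluster_id=cid)
                tab = hub.table.copy()
                tab["trait"] = t
                rows.append(tab)
            table = (pd.concat(rows, ignore_index=True)
                     .drop_duplicates("gene").sort_values("gene")
                     .reset_index(drop=True)) if rows else \
                pd.DataFrame(columns=["gene", "module", "MM", "GS", "trait"])
            out.append(assoc_mod.HubGeneSet(
                cluster_id=cid, modules=mods, trait=interest,
                gs_min=self.gs_min, mm_min=self.mm_min, table=table))
        return out

    def summary(self) -> str:
        wide = self.correlation_matrix().round(3)
        sig = self.table[self.table["significant"]]
        lines = [
            "Module eigengene - trait association",
            "=" * 46,
            f"modules: {self.table['module'].nunique()}   traits: "
            f"{self.table['trait'].nunique()}   FDR alpha: {self.alpha}",
            f"significant cells: {len(sig)}   significant modules: "
            f"{', '.join(self.significant_modules) or 'none'}",
            f"raw-p cutoff at the BH decision: "
            f"{self.table.attrs.get('raw_p_cutoff', float('nan')):.4g}",
            "",
            "partial correlations (r):",
            wide.to_string(),
        ]
        return "\n".join(lines)
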