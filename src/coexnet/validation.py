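"""Robustness and external validation of a module partition.

Stability is assessed by subsampling: the whole network construction and
module detection chain is rerun on randomly drawn subsets of samples
(default 80% without replacement, 50 iterations); each resampled module is
identified with the reference module of maximal Jaccard overlap, and a
gene's consistency is the percentage of iterations in which it returned to
its reference module.  A module's stability is the mean consistency of its
member genes.

External validation uses the upper-tail hypergeometric test: the overlap
of each of our modules with each module of an independently derived
partition, over the universe of genes present in both, corrected for the
number of tested pairs (Bonferroni by default).  The same test drives
over-representation analysis of gene sets against GMT annotations with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import benjamini_hochberg
from .network import GREY, NetworkParams, detect_modules

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityResult",
    "module_stability",
    "match_modules_by_jaccard",
    "hypergeometric_overlap",
    "cross_study_module_overlap",
    "ora_enrichment",
]


@dataclass
class StabilityResult:
    """Gene- and module-level subsampling consistency."""

    gene_consistency: pd.Series     # per gene, percentage in [0, 100]
    module_stability: pd.Series     # per non-grey reference module
    n_iterations: int
    sample_fraction: float
    seed: int | None


def match_modules_by_jaccard(
    reference: pd.Series, other: pd.Series, unassigned: str = GREY
) -> dict[str, str]:
    """Map each module of ``other`` to the reference module of maximal
    Jaccard overlap (ties broken toward the larger reference module, then
    by label)."""
    ref_sets = {m: set(reference.index[reference == m])
                for m in reference.unique() if m != unassigned}
    mapping: dict[str, str] = {}
    for m in other.unique():
        if m == unassigned:
            continue
        o = set(other.index[other == m])
        best = None
        best_key = (-1.0, -1, "")
        for rm, rs in ref_sets.items():
            inter = len(o & rs)
            j = inter / len(o | rs) if (o or rs) else 0.0
            key = (j, len(rs), rm)
            if key > best_key:
                best_key, best = key, rm
        if best is not None and best_key[0] > 0:
            mapping[m] = best
    return mapping


def module_stability(
    expr: pd.DataFrame,
    reference_assign: pd.Series,
    params: NetworkParams | None = None,
    n_iter: int = 50,
    sample_fraction: float = 0.8,
    seed: int | None = None,
) -> StabilityResult:
    """Subsampling consistency of a module partition.

    Reruns network construction and module detection ``n_iter`` times on
    random subsets of samples and scores, per gene, the percentage of
    iterations in which it was assigned to its reference module (after
    Jaccard matching of resampled to reference modules).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    params = params or NetworkParams()
    n = expr.shape[1]
    n_draw = max(int(round(sample_fraction * n)), 3)
    if n_draw < 3:
        raise ValueError("resampled sample count must be >= 3")
    rng = np.random.default_rng(seed)
    reference_assign = reference_assign.loc[expr.index]
    hits = np.zeros(expr.shape[0])
    for it in range(n_iter):
        cols = rng.choice(n, size=n_draw, replace=False)
        sub = expr.iloc[:, np.sort(cols)]
        assign = detect_modules(sub, params)
        mapping = match_modules_by_jaccard(reference_assign, assign)
        if not mapping:
            logger.warning("stability iteration %d produced no non-grey "
                           "modules; counted as all-mismatch", it)
            continue
        mapped = assign.map(lambda m: mapping.get(m, GREY))
        hits += (mapped.values == reference_assign.values) & \
                (reference_assign.values != GREY)
    consistency = pd.Series(100.0 * hits / n_iter, index=expr.index,
                            name="consistency")
    stab = {}
    for m in reference_assign.unique():
        if m == GREY:
            continue
        stab[m] = float(consistency[reference_assign == m].mean())
    return StabilityResult(
        gene_consistency=consistency,
        module_stability=pd.Series(stab, name="stability").sort_index(),
        n_iterations=n_iter,
        sample_fraction=sample_fraction,
        seed=seed,
    )


def hypergeometric_overlap(set_a, set_b, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test.

    Returns ``(k, p)`` where ``k = |a ∩ b|`` and ``p = P(X >= k)`` for X
    hypergeometric with population ``|universe|``, ``|a|`` successes and
    ``|b|`` draws.  Both sets must be contained in the universe.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if len(u) < 1:
        raise ValueError("universe must be non-empty")
    stray = (a | b) - u
    if stray:
        raise ValueError(f"sets contain genes outside the universe: "
                         f"{sorted(stray)[:10]}")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return k, min(p, 1.0)


def cross_study_module_overlap(
    ours: pd.Series, external: pd.Series, correction: str = "bonferroni",
    alpha: float = 0.05, unassigned: str = GREY,
) -> pd.DataFrame:
    """Hypergeometric overlap of every (our module, external module) pair.

    The universe is the set of genes present in both partitions; grey is
    excluded from testing on both sides.  ``correction`` is ``bonferroni``
    (over all tested pairs, the default) or ``bh``.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    universe = set(ours.index) & set(external.index)
    if not universe:
        raise ValueError("no genes shared between the two partitions")
    ours = ours.loc[ours.index.isin(universe)]
    external = external.loc[external.index.isin(universe)]
    our_mods = sorted(m for m in ours.unique() if m != unassigned)
    ext_mods = sorted(m for m in external.unique() if m != unassigned)
    rows = []
    for om in our_mods:
        a = set(ours.index[ours == om])
        for em in ext_mods:
            b = set(external.index[external == em])
            k, p = hypergeometric_overlap(a, b, universe)
            rows.append((om, em, k, len(a), len(b), p))
    table = pd.DataFrame(rows, columns=["module", "external_module", "overlap",
                                        "module_size", "external_size", "p"])
    m = len(table)
    if correction == "bonferroni":
        table["p_corrected"] = np.minimum(table["p"] * m, 1.0)
    else:
        table["p_corrected"] = benjamini_hochberg(table["p"])
    table["significant"] = table["p_corrected"] < alpha
    table.attrs["universe_size"] = len(universe)
    table.attrs["correction"] = correction
    return table


def ora_enrichment(
    genes, annotation: dict[str, set[str]], universe,
    min_term_size: int = 3, alpha: float = 0.05, two_sided: bool = False,
) -> pd.DataFrame:
    """Over-representation of a gene set against GMT annotations.

    Per term (restricted to the universe, terms smaller than
    ``min_term_size`` skipped): upper-tail hypergeometric p of the overlap,
    BH-adjusted across tested terms; only terms with at least one
    overlapping gene are reported.  ``two_sided`` doubles the smaller tail
    (capped at 1) for a two-sided reading of the test.
    """
    g = set(genes)
    u = set(universe)
    if not g:
        raise ValueError("empty gene set")
    if not g <= u:
        raise ValueError("gene set not contained in the universe")
    rows = []
    for term, members in annotation.items():
        t = members & u
        if len(t) < min_term_size:
            continue
        k = len(g & t)
        p = float(hypergeom.sf(k - 1, len(u), len(t), len(g)))
        if two_sided:
            lower = float(hypergeom.cdf(k, len(u), len(t), len(g)))
            p = min(1.0, 2.0 * min(p, lower))
        rows.append((term, len(t), k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p"])
    else:
        table["p_adj"] = pd.Series(dtype=float)
    table = table[table["overlap"] >= 1].reset_index(drop=True)
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p", "term"]).reset_index(drop=True)
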