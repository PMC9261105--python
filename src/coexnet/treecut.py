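"""Adaptive (dynamic hybrid) cutting of a dendrogram into modules.

Fixed-height cuts of a co-expression dendrogram either fragment large
modules or swallow distinct ones.  The dynamic hybrid cut instead walks the
merge tree and accepts a branch as a module when it is simultaneously

* large enough (``min_module_size`` leaves),
* internally tight — the scatter of its core (the mean pairwise
  dissimilarity of the first ``min_module_size`` leaves that assemble
  inside it) stays below a threshold, and
* clearly separated — the gap between the height at which the branch joins
  the rest of the tree and its core scatter exceeds a minimum.

Both thresholds are expressed relative to the height range between the 5th
percentile of all merge heights and the cut height (99% of the total height
range by default), and are controlled by the integer ``deep_split`` in
0..4: deeper splits tolerate looser cores and smaller gaps, yielding more
and smaller modules.

Leaves on no accepted branch are left unassigned ("grey").  An optional
PAM-like refinement then attaches an unassigned gene to the closest module
(by average dissimilarity to the module's genes) provided that distance is
below the height at which the module branch joined the tree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["cut_dendrogram_dynamic"]

GREY = "grey"

# deep_split 0..4 -> maximum relative core scatter; the minimum relative gap
# is (1 - scatter) * 3/4
_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


class _Tree:
    """Light adapter over a scipy linkage matrix with lazy subtree queries."""

    def __init__(self, link: np.ndarray):
        self.link = link
        self.n_leaves = link.shape[0] + 1
        self._leaves: dict[int, np.ndarray] = {}

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def children(self, node: int) -> tuple[int, int]:
        row = self.link[node - self.n_leaves]
        return int(row[0]), int(row[1])

    def height(self, node: int) -> float:
        return 0.0 if self.is_leaf(node) else float(self.link[node - self.n_leaves, 2])

    def size(self, node: int) -> int:
        return 1 if self.is_leaf(node) else int(self.link[node - self.n_leaves, 3])

    def leaves(self, node: int) -> np.ndarray:
        if node in self._leaves:
            return self._leaves[node]
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            elif v in self._leaves:
                out.extend(self._leaves[v].tolist())
            else:
                stack.extend(self.children(v))
        arr = np.asarray(sorted(out), dtype=int)
        self._leaves[node] = arr
        return arr



def cut_dendrogram_dynamic(
    link: np.ndarray,
    diss: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
) -> pd.Series:
    """Cut an average-linkage dendrogram into modules of variable height.

    Parameters
    ----------
    link
        scipy linkage matrix built from ``diss``.
    diss
        The gene x gene dissimilarity the tree was built on (used by the
        PAM refinement and for labeling).
    min_module_size
        Smallest branch accepted as a module.
    deep_split
        Split sensitivity 0..4 (see module docstring).
    cut_height
        Merges above this height are never considered joins; default is 99%
        of the height range above the minimum merge height.
    pam_stage
        Attach unassigned genes to sufficiently close modules afterwards.

    Returns
    -------
    pandas.Series mapping gene id -> module label ``M1, M2, ...`` in
    decreasing size order, with ``"grey"`` for unassigned genes.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    tree = _Tree(np.asarray(link, dtype=float))
    n = tree.n_leaves
    gene_ids = diss.index
    if len(gene_ids) != n:
        raise ValueError("dissimilarity and linkage disagree on gene count")
    if min_module_size > n:
        warnings.warn("min_module_size exceeds the number of genes; "
                      "all genes labeled grey", UserWarning, stacklevel=2)
        return pd.Series(GREY, index=gene_ids)

    heights = tree.link[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    if cut_height is None:
        cut_height = h_min + 0.99 * (h_max - h_min)
    ref = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref, 1e-12)
    max_scatter = ref + _CORE_SCATTER[deep_split] * span
    min_gap = (1.0 - _CORE_SCATTER[deep_split]) * 0.75 * span

    d_mat = diss.to_numpy(dtype=float)
    scatter_cache: dict[int, float] = {}

    def core_scatter(node: int) -> float:
        """Mean pairwise dissimilarity of the branch's earliest-assembled
        core: the leaves of the lowest subtree node reaching core size."""
        if node in scatter_cache:
            return scatter_cache[node]
        target = min(min_module_size, tree.size(node))
        best, best_h = node, tree.height(node)
        stack = [node]
        while stack:
            v = stack.pop()
            if tree.is_leaf(v) or tree.size(v) < target:
                continue  # descendants of too-small nodes cannot reach target
            if tree.height(v) < best_h:
                best, best_h = v, tree.height(v)
            stack.extend(tree.children(v))
        lv = tree.leaves(best)
        if lv.size > 3 * min_module_size:
            lv = lv[: 3 * min_module_size]
        sub = d_mat[np.ix_(lv, lv)]
        m = lv.size
        scatter = float(sub.sum() / (m * (m - 1))) if m > 1 else 0.0
        scatter_cache[node] = scatter
        return scatter

    def qualifies(node: int, attach: float) -> bool:
        if tree.size(node) < min_module_size:
            return False
        scatter = core_scatter(node)
        return scatter <= max_scatter and (attach - scatter) >= min_gap

    modules: list[np.ndarray] = []
    attach_heights: list[float] = []
    unassigned: list[int] = []
    root = 2 * n - 2
    stack: list[tuple[int, float]] = [(root, cut_height)]
    while stack:
        node, attach = stack.pop()
        if tree.is_leaf(node):
            unassigned.append(node)
            continue
        h = tree.height(node)
        left, right = tree.children(node)
        if h > cut_height:
            # not a join: the two subtrees are unrelated at this scale
            stack.append((left, cut_height))
            stack.append((right, cut_height))
            continue
        q_left = qualifies(left, h)
        q_right = qualifies(right, h)
        if q_left and q_right:
            # two distinct sub-branches: split
            stack.append((left, h))
            stack.append((right, h))
        elif qualifies(node, attach):
            # the branch as a whole is one tight, separated cluster
            modules.append(tree.leaves(node))
            attach_heights.append(attach)
        elif q_left or q_right:
            # a distinct cluster plus loose material: descend, the loose
            # side ends up unassigned (PAM may re-attach it)
            stack.append((left, h))
            stack.append((right, h))
        else:
            unassigned.extend(tree.leaves(node).tolist())

    labels = np.full(n, -1, dtype=int)
    for i, leaves in enumerate(modules):
        labels[leaves] = i

    if pam_stage and modules and unassigned:
        d = diss.to_numpy(dtype=float)
        un = np.asarray(sorted(unassigned), dtype=int)
        # average dissimilarity of each unassigned gene to each module
        avg = np.column_stack([d[np.ix_(un, lv)].mean(axis=1) for lv in modules])
        best = np.argmin(avg, axis=1)
        best_d = avg[np.arange(len(un)), best]
        limits = np.asarray(attach_heights)[best]
        accept = best_d < limits
        labels[un[accept]] = best[accept]

    # relabel in decreasing size order (ties by smallest member gene id)
    out = pd.Series(GREY, index=gene_ids, name="module")
    order = sorted(
        range(len(modules)),
        key=lambda i: (-(labels == i).sum(), str(gene_ids[labels == i].min())),
    )
    for rank, i in enumerate(order, start=1):
        out.iloc[labels == i] = f"M{rank}"
    return out
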