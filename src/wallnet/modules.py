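"""Module detection on the TOM dissimilarity and module summarisation.

Genes are clustered by average-linkage hierarchical clustering of 1 - TOM;
the dendrogram is cut at a high quantile of its merge heights and branches
with at least ``min_module_size`` leaves become modules (label 0 is reserved
for unassigned genes). Each module is summarised by its eigengene — the
first principal component of its standardised member profiles — and modules
whose eigengenes are nearly collinear are merged. Connectivity statistics
(kTotal, kWithin, kOut, kME) rank genes within and across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .network import GeneMatrix

__all__ = [
    "Dendrogram",
    "ModuleResult",
    "cluster_genes",
    "cut_tree",
    "module_eigengene",
    "merge_modules",
    "filter_incoherent_modules",
    "reassign_by_kme",
    "connectivity",
    "kme",
    "cluster_eigengenes",
    "module_meta_network",
]


@dataclass
class Dendrogram:
    """A scipy linkage matrix together with its leaf identifiers."""

    Z: np.ndarray
    ids: pd.Index

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class ModuleResult:
    """Detected modules: labels (0 = unassigned), eigengenes and parameters."""

    labels: pd.Series
    eigengenes: pd.DataFrame  # modules x samples, rows 'ME<k>', unit norm
    var_explained: pd.Series
    min_module_size: int
    merge_cut_height: float


def cluster_genes(diss: GeneMatrix, method: str = "average") -> Dendrogram:
    """Agglomeratively cluster genes on a dissimilarity matrix."""
    if diss.kind != "dissimilarity":
        raise ValueError(f"expected a dissimilarity matrix, got kind={diss.kind!r}")
    v = diss.values
    if np.isnan(v).any():
        raise ValueError("dissimilarity contains NaN")
    Z = linkage(squareform(v, checks=False), method=method)
    return Dendrogram(Z, diss.gene_ids)


def cut_tree(
    dendro: Dendrogram,
    min_module_size: int = 50,
    cut_quantile: float = 0.9,
    recursive: bool = True,
) -> pd.Series:
    """Quantile-height cut of the gene dendrogram into modules.

    The tree is first cut at the ``cut_quantile`` quantile of all merge
    heights; components below the cut with at least ``min_module_size``
    leaves become module candidates, all other genes get label 0. With
    ``recursive`` (the default) each candidate is then re-examined at the
    same quantile of its own subtree's merge heights and split whenever
    that yields two or more sufficiently large children — this separates
    modules whose branches happen to join below the global cut, which a
    single static threshold cannot resolve. Modules are numbered 1..M in
    descending size order.
    """
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    n = len(dendro.ids)
    if n == 1:
        lab = 1 if min_module_size <= 1 else 0
        return pd.Series([lab], index=dendro.ids, name="module")
    Z = dendro.Z
    if not recursive:
        h = float(np.quantile(dendro.heights, cut_quantile))
        raw = fcluster(Z, t=h, criterion="distance")
        return _sizes_to_labels(pd.Series(raw, index=dendro.ids), min_module_size)

    height = {n + t: Z[t, 2] for t in range(n - 1)}
    children = {n + t: (int(Z[t, 0]), int(Z[t, 1])) for t in range(n - 1)}

    leaves_memo: dict[int, list[int]] = {}

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        if node not in leaves_memo:
            # iterative post-order to avoid deep recursion on chained trees
            stack, order = [node], []
            while stack:
                x = stack.pop()
                order.append(x)
                if x >= n:
                    stack.extend(children[x])
            for x in reversed(order):
                if x >= n and x not in leaves_memo:
                    a, b = children[x]
                    leaves_memo[x] = (
                        (leaves_memo[a] if a >= n else [a])
                        + (leaves_memo[b] if b >= n else [b])
                    )
        return leaves_memo[node]

    def maximal_below(node: int, h: float) -> list[int]:
        out, stack = [], [node]
        while stack:
            x = stack.pop()
            if x < n or height[x] <= h:
                out.append(x)
            else:
                stack.extend(children[x])
        return out

    def subtree_heights(node: int) -> list[float]:
        out, stack = [], [node]
        while stack:
            x = stack.pop()
            if x >= n:
                out.append(height[x])
                stack.extend(children[x])
        return out

    h_global = float(np.quantile(Z[:, 2], cut_quantile))
    modules: list[list[int]] = []
    work = [c for c in maximal_below(2 * n - 2, h_global)]
    while work:
        node = work.pop()
        lv = leaves(node)
        if len(lv) < min_module_size:
            continue
        hs = subtree_heights(node)
        if not hs:
            modules.append(lv)
            continue
        h_sub = float(np.quantile(hs, cut_quantile))
        if h_sub >= height.get(node, np.inf):
            modules.append(lv)
            continue
        comps = maximal_below(node, h_sub)
        big = [c for c in comps if len(leaves(c)) >= min_module_size]
        if len(big) >= 2:
            work.extend(comps)
        elif len(big) == 1 and len(leaves(big[0])) <= len(lv) // 2:
            # a coherent minority branch inside a diffuse cluster: keep the
            # branch, let the shreddable remainder fall back to unassigned
            work.extend(comps)
        else:
            modules.append(lv)

    lab = np.zeros(n, dtype=int)
    for i, mod in enumerate(modules, 1):
        lab[mod] = i
    return _sizes_to_labels(pd.Series(lab, index=dendro.ids), min_module_size)


def _sizes_to_labels(raw: pd.Series, min_module_size: int) -> pd.Series:
    """Renumber raw cluster assignments: big clusters 1..M by size, rest 0."""
    counts = raw.value_counts()
    big = counts[counts >= min_module_size]
    # descending size; ties broken by smallest member ID for determinism
    first_member = {c: raw.index[raw == c].min() for c in big.index}
    order = sorted(big.index, key=lambda c: (-big[c], str(first_member[c])))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return raw.map(lambda c: remap.get(c, 0)).rename("module")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene encountered while standardizing a module")
    return (x - mu) / sd


def _single_eigengene(member_expr: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First right-singular vector of the standardised member matrix.

    Returns the unit-norm eigengene over samples and the variance fraction it
    explains. Sign: mean correlation with the member genes must be >= 0; an
    exactly balanced module falls back to positive correlation with the
    first member by ID.
    """
    g = _standardize_rows(member_expr.to_numpy())
    _, s, vt = np.linalg.svd(g, full_matrices=False)
    v = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    corrs = _row_corr_with(g, v)
    mean_c = corrs.mean()
    if abs(mean_c) < 1e-12:
        first = member_expr.index.argsort()[0]
        if corrs[first] < 0:
            v = -v
    elif mean_c < 0:
        v = -v
    return v, var_explained


def _row_corr_with(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    return (rc @ vc) / denom


def module_eigengene(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (first PC over samples) for every module label >= 1.

    Returns (eigengenes modules x samples with rows 'ME<k>' of unit Euclidean
    norm, variance-explained per module).
    """
    labels = labels.reindex(expr.index)
    if labels.isna().any():
        raise ValueError("labels do not cover every gene in the expression matrix")
    mods = sorted(int(m) for m in labels.unique() if m >= 1)
    if not mods:
        raise ValueError("no modules (all labels 0)")
    rows, ve = {}, {}
    for m in mods:
        members = expr.loc[labels[labels == m].index]
        v, var = _single_eigengene(members)
        rows[f"ME{m}"] = v
        ve[f"ME{m}"] = var
    me = pd.DataFrame(rows, index=expr.columns).T
    return me, pd.Series(ve, name="var_explained")


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float = 0.20
) -> pd.Series:
    """Iteratively merge the closest module pair by eigengene dissimilarity.

    The pair with the smallest d = 1 - PCC(ME_a, ME_b) is merged while
    d < merge_cut_height; eigengenes are recomputed after every merge.
    Labels are finally renumbered 1..M by descending size.
    """
    labels = labels.copy()
    while True:
        mods = sorted(int(m) for m in labels.unique() if m >= 1)
        if len(mods) < 2:
            break
        me, _ = module_eigengene(expr, labels)
        d = 1.0 - np.corrcoef(me.to_numpy())
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= merge_cut_height:
            break
        a, b = mods[i], mods[j]
        labels[labels == max(a, b)] = min(a, b)
    # renumber contiguously, descending size; 0 stays unassigned
    assigned = labels[labels >= 1]
    out = labels.copy()
    if len(assigned):
        out.loc[assigned.index] = _sizes_to_labels(assigned, 1)
    return out.rename("module")


def filter_incoherent_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    min_var_explained: float = 0.2,
) -> pd.Series:
    """Dissolve modules whose eigengene explains too little variance.

    A branch of mutually uncorrelated genes can satisfy the size rule without
    being a co-expression module; its eigengene variance fraction stays near
    the random-matrix baseline (~1/min(genes, samples)) whereas genuinely
    co-regulated modules score far higher. Modules below
    ``min_var_explained`` are returned to label 0 and the rest renumbered.
    """
    labels = labels.copy()
    if labels.max() < 1:
        return labels
    _, ve = module_eigengene(expr, labels)
    for name, frac in ve.items():
        if frac < min_var_explained:
            labels[labels == int(str(name)[2:])] = 0
    assigned = labels[labels >= 1]
    if len(assigned):
        labels.loc[assigned.index] = _sizes_to_labels(assigned, 1)
    return labels.rename("module")


def reassign_by_kme(
    expr: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.3,
) -> pd.Series:
    """Assign unlabelled genes to the module whose eigengene they track best.

    A gene with label 0 joins the module maximising kME when that kME reaches
    ``threshold``; otherwise it stays unassigned. Off by default in the
    pipeline.
    """
    me, _ = module_eigengene(expr, labels)
    out = labels.copy()
    free = labels[labels == 0].index
    if len(free) == 0:
        return out
    km = kme(expr.loc[free], me)
    best = km.idxmax(axis=1)
    best_val = km.max(axis=1)
    for g in free:
        if best_val[g] >= threshold:
            out[g] = int(str(best[g])[2:])
    return out


def connectivity(A: GeneMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-gene connectivity split into within- and out-of-module weight.

    kTotal_i sums all off-diagonal adjacency weights of gene i, kWithin_i the
    weights to genes sharing its module, and kOut = kTotal - kWithin (exact by
    construction).
    """
    if not A.gene_ids.isin(labels.index).all():
        missing = A.gene_ids[~A.gene_ids.isin(labels.index)]
        raise ValueError(f"labels missing for genes: {list(missing[:5])}")
    lab = labels.reindex(A.gene_ids).to_numpy()
    a = A.values.copy()
    np.fill_diagonal(a, 0.0)
    same = lab[:, None] == lab[None, :]
    k_within = (a * same).sum(axis=1)
    k_out = (a * ~same).sum(axis=1)
    # summing the two groups separately keeps kTotal = kWithin + kOut exact
    out = pd.DataFrame(
        {
            "module": lab,
            "kTotal": k_within + k_out,
            "kWithin": k_within,
            "kOut": k_out,
        },
        index=A.gene_ids,
    )
    return out


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Signed eigengene-based connectivity: PCC of each gene with each ME."""
    if not expr.columns.equals(eigengenes.columns):
        raise ValueError("expression and eigengenes must share the sample axis")
    if (expr.std(axis=1, ddof=0) == 0).any():
        flat = expr.index[expr.std(axis=1, ddof=0) == 0]
        raise ValueError(f"zero-variance genes: {list(flat[:5])}")
    x = expr.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    xc /= np.linalg.norm(xc, axis=1, keepdims=True)
    e = eigengenes.to_numpy()
    ec = e - e.mean(axis=1, keepdims=True)
    ec /= np.linalg.norm(ec, axis=1, keepdims=True)
    km = np.clip(xc @ ec.T, -1.0, 1.0)
    return pd.DataFrame(km, index=expr.index, columns=eigengenes.index)


def cluster_eigengenes(eigengenes: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Complete-linkage dendrogram of eigengenes on dissimilarity 1 - PCC."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 eigengenes to cluster")
    d = 1.0 - np.corrcoef(eigengenes.to_numpy())
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    Z = linkage(squareform(d, checks=False), method=method)
    return Dendrogram(Z, eigengenes.index)


def module_meta_network(eigengenes: pd.DataFrame, threshold: float = 0.5) -> nx.Graph:
    """Module-level graph: edge between modules with |PCC(ME_a, ME_b)| >= threshold."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 eigengenes")
    r = np.corrcoef(eigengenes.to_numpy())
    g = nx.Graph()
    names = list(eigengenes.index)
    g.add_nodes_from((n, {"kind": "module"}) for n in names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(r[i, j]) >= threshold:
                g.add_edge(names[i], names[j], weight=float(r[i, j]))
    return g
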