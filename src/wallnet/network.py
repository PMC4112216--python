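"""Weighted co-expression network construction.

Similarity is the absolute Pearson correlation between gene expression
profiles; a soft threshold raises it to a power β chosen so the resulting
weighted network approximates scale-free topology; the topological overlap
measure (TOM) then augments direct adjacency with shared-neighbour weight,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with l_ij the summed two-step adjacency through common neighbours and k_i the
node connectivity. 1 - TOM is the dissimilarity used for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneMatrix",
    "SoftThresholdScan",
    "similarity",
    "adjacency",
    "connectivity_vector",
    "scale_free_fit",
    "fit_scale_free",
    "pick_soft_threshold",
    "tom",
    "tom_dissimilarity",
]

_SYM_TOL = 1e-10


@dataclass
class GeneMatrix:
    """A square symmetric gene x gene matrix with its semantic kind.

    kind is one of 'similarity', 'adjacency', 'tom', 'dissimilarity'.
    Values lie in [0, 1]; the diagonal is 1 for similarity/adjacency/tom
    and 0 for dissimilarity.
    """

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        v = self.df.to_numpy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GeneMatrix must be square")
        if np.isnan(v).any():
            raise ValueError("GeneMatrix contains NaN values")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("GeneMatrix must be symmetric")
        if self.kind not in ("similarity", "adjacency", "tom", "dissimilarity"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclass
class SoftThresholdScan:
    """Scale-free fit scan over candidate soft-threshold powers."""

    betas: list[float]
    r_squared: list[float]
    mean_connectivity: list[float]
    selected: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.betas, "signed_r2": self.r_squared, "mean_k": self.mean_connectivity}
        )


def similarity(expr: pd.DataFrame) -> GeneMatrix:
    """Absolute Pearson correlation between all gene pairs; diagonal 1."""
    if expr.shape[1] < 3:
        raise ValueError("similarity needs at least 3 samples")
    var = expr.var(axis=1, ddof=0)
    flat = var[var == 0].index
    if len(flat):
        raise ValueError(f"zero-variance rows: {list(flat[:5])}")
    s = np.abs(np.corrcoef(expr.to_numpy()))
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    s = (s + s.T) / 2
    return GeneMatrix(pd.DataFrame(s, index=expr.index, columns=expr.index), "similarity")


def adjacency(S: GeneMatrix, beta: float) -> GeneMatrix:
    """Soft-threshold the similarity: A_ij = S_ij ** beta off-diagonal, diagonal 1."""
    if S.kind != "similarity":
        raise ValueError(f"adjacency expects a similarity matrix, got kind={S.kind!r}")
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    a = S.values ** beta
    np.fill_diagonal(a, 1.0)
    return GeneMatrix(pd.DataFrame(a, index=S.gene_ids, columns=S.gene_ids), "adjacency")


def connectivity_vector(A: GeneMatrix) -> pd.Series:
    """Node connectivity k_i = sum of off-diagonal adjacency weights."""
    v = A.values
    k = v.sum(axis=1) - np.diag(v)
    return pd.Series(k, index=A.gene_ids, name="k")


def scale_free_fit(A: GeneMatrix, n_bins: int = 10) -> float:
    """Signed R² of the log-log connectivity-distribution fit for a network.

    See :func:`fit_scale_free` for the fit recipe.
    """
    return fit_scale_free(connectivity_vector(A).to_numpy(), n_bins=n_bins)


def fit_scale_free(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log fit to a connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; a line is
    fitted to log10(frequency) against log10(mean connectivity) over the
    non-empty bins, and -sign(slope)·R² is returned so that a decaying
    (scale-free-like) distribution scores positively. Degenerate inputs
    (all connectivities equal, or fewer than two usable bins) return 0 with
    a warning.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined, returning 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        freqs.append(mask.sum())
        means.append(mk)
    if len(freqs) < 2:
        warnings.warn("fewer than two usable connectivity bins; returning 0")
        return 0.0
    res = stats.linregress(np.log10(means), np.log10(freqs))
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas: Sequence[float] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers and select the soft threshold.

    The selected β is the smallest candidate whose signed scale-free fit R²
    reaches ``r2_cut``; if none does, the β maximising the fit is taken with
    a warning.
    """
    S = similarity(expr)
    r2s, mean_ks = [], []
    for b in betas:
        A = adjacency(S, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2s.append(scale_free_fit(A, n_bins=n_bins))
        mean_ks.append(float(connectivity_vector(A).mean()))
    passing = [b for b, r2 in zip(betas, r2s) if r2 >= r2_cut]
    if passing:
        selected = min(passing)
    else:
        selected = betas[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate beta reached signed R^2 >= {r2_cut}; "
            f"taking the maximiser beta={selected}"
        )
    return SoftThresholdScan(list(betas), r2s, mean_ks, float(selected))


def tom(A: GeneMatrix) -> GeneMatrix:
    """Topological overlap matrix of a weighted adjacency; diagonal 1."""
    if A.kind != "adjacency":
        raise ValueError(f"tom expects an adjacency matrix, got kind={A.kind!r}")
    a = A.values.copy()
    if not np.allclose(a, a.T, atol=_SYM_TOL):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    l = a @ a  # zero diagonal makes this exactly sum over u != i, j
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    np.clip(t, 0.0, 1.0, out=t)
    t = (t + t.T) / 2
    return GeneMatrix(pd.DataFrame(t, index=A.gene_ids, columns=A.gene_ids), "tom")


def tom_dissimilarity(T: GeneMatrix) -> GeneMatrix:
    """1 - TOM, the clustering dissimilarity; diagonal 0."""
    if T.kind != "tom":
        raise ValueError(f"expected a tom matrix, got kind={T.kind!r}")
    d = 1.0 - T.values
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return GeneMatrix(pd.DataFrame(d, index=T.gene_ids, columns=T.gene_ids), "dissimilarity")
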