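"""Regularized canonical correlation analysis and the trait-module relevance network.

CCA finds paired linear combinations of two variable blocks — here the cell
wall trait matrix X (samples x traits) and the module eigengene matrix Y
(samples x eigengenes) — whose correlation is maximal. With more eigengenes
than samples the classical problem is degenerate (every canonical correlation
is 1), so ridge penalties λ_X, λ_Y are added to the within-block covariances.
Canonical structure correlations (correlations of the original variables with
the canonical variates) give each trait and eigengene a coordinate per
component; their cross-block inner products are the signed similarity scores
whose thresholding at τ yields the bipartite relevance network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import linalg

__all__ = [
    "CCAResult",
    "rcca",
    "structure_correlations",
    "similarity_scores",
    "relevance_network",
]


@dataclass
class CCAResult:
    """Fitted (regularized) CCA: basis vectors, variates and correlations."""

    x_weights: pd.DataFrame  # traits x components
    y_weights: pd.DataFrame  # eigengenes x components
    x_scores: pd.DataFrame  # samples x components (U)
    y_scores: pd.DataFrame  # samples x components (V)
    correlations: np.ndarray  # non-increasing, in [0, 1]
    lambda_x: float
    lambda_y: float

    @property
    def n_components(self) -> int:
        return len(self.correlations)


def _standardize(m: pd.DataFrame) -> np.ndarray:
    v = m.to_numpy(dtype=float)
    mu = v.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, ddof=1, keepdims=True)
    if (sd == 0).any():
        bad = list(m.columns[(sd == 0).ravel()])
        raise ValueError(f"constant columns cannot enter CCA: {bad[:5]}")
    return (v - mu) / sd


def _inv_sqrt(c: np.ndarray, ridge: float, block: str) -> np.ndarray:
    c = c + ridge * np.eye(c.shape[0])
    w, v = linalg.eigh(c)
    tol = 1e-10 * w.max()
    if w.min() < tol:
        raise np.linalg.LinAlgError(
            f"{block}-block covariance is rank deficient with lambda=0; "
            "more variables than samples requires ridge regularization "
            "(set lambda_x/lambda_y > 0)"
        )
    return v @ np.diag(w**-0.5) @ v.T


def rcca(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda_x: float = 0.0,
    lambda_y: float = 0.0,
    n_components: int | None = None,
) -> CCAResult:
    """Ridge-regularized CCA between two samples x variables blocks.

    Columns are standardized to zero mean and unit variance; the canonical
    system is solved on (Σ_XX + λ_X I, Σ_YY + λ_Y I) by whitening and SVD of
    the cross-covariance. Canonical correlations are clipped to [0, 1] and
    returned non-increasing.
    """
    if list(X.index) != list(Y.index):
        raise ValueError("X and Y must share the sample axis (same order)")
    n = X.shape[0]
    max_comp = min(X.shape[1], Y.shape[1], n - 1)
    k = max_comp if n_components is None else n_components
    if not (1 <= k <= max_comp):
        raise ValueError(f"n_components must lie in 1..{max_comp}")
    if lambda_x < 0 or lambda_y < 0:
        raise ValueError("ridge penalties must be >= 0")

    xs = _standardize(X)
    ys = _standardize(Y)
    cxx = xs.T @ xs / (n - 1)
    cyy = ys.T @ ys / (n - 1)
    cxy = xs.T @ ys / (n - 1)

    wx = _inv_sqrt(cxx, lambda_x, "X")
    wy = _inv_sqrt(cyy, lambda_y, "Y")
    u, s, vt = np.linalg.svd(wx @ cxy @ wy)
    rho = np.clip(s[:k], 0.0, 1.0)
    a = wx @ u[:, :k]
    b = wy @ vt[:k].T

    comp = [f"C{i + 1}" for i in range(k)]
    return CCAResult(
        x_weights=pd.DataFrame(a, index=X.columns, columns=comp),
        y_weights=pd.DataFrame(b, index=Y.columns, columns=comp),
        x_scores=pd.DataFrame(xs @ a, index=X.index, columns=comp),
        y_scores=pd.DataFrame(ys @ b, index=Y.index, columns=comp),
        correlations=rho,
        lambda_x=lambda_x,
        lambda_y=lambda_y,
    )


def _corr_cols_with(block: np.ndarray, variates: np.ndarray) -> np.ndarray:
    bc = block - block.mean(axis=0, keepdims=True)
    vc = variates - variates.mean(axis=0, keepdims=True)
    bn = np.linalg.norm(bc, axis=0)
    vn = np.linalg.norm(vc, axis=0)
    return np.clip((bc.T @ vc) / np.outer(bn, vn), -1.0, 1.0)


def structure_correlations(
    result: CCAResult,
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int = 3,
    variates: str = "average",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations of the original variables with the canonical variates.

    ``variates`` selects the representation the variables are correlated
    against: the X-block scores, the Y-block scores, or their per-component
    average (U^k + V^k)/2 — the relevance-network convention and the default.
    Returns (traits x components, eigengenes x components) tables.
    """
    k = min(n_components, result.n_components)
    if variates == "average":
        z = (result.x_scores.to_numpy()[:, :k] + result.y_scores.to_numpy()[:, :k]) / 2
    elif variates == "x":
        z = result.x_scores.to_numpy()[:, :k]
    elif variates == "y":
        z = result.y_scores.to_numpy()[:, :k]
    else:
        raise ValueError("variates must be 'average', 'x' or 'y'")
    comp = list(result.x_scores.columns[:k])
    sx = pd.DataFrame(_corr_cols_with(X.to_numpy(dtype=float), z), index=X.columns, columns=comp)
    sy = pd.DataFrame(_corr_cols_with(Y.to_numpy(dtype=float), z), index=Y.columns, columns=comp)
    return sx, sy


def similarity_scores(struct_x: pd.DataFrame, struct_y: pd.DataFrame) -> pd.DataFrame:
    """Trait x eigengene signed similarity: inner product in structure space.

    score(t, g) = Σ_k struct_x(t, k) · struct_y(g, k), clipped to [-1, 1].
    """
    if list(struct_x.columns) != list(struct_y.columns):
        raise ValueError(
            f"component mismatch: {list(struct_x.columns)} vs {list(struct_y.columns)}"
        )
    s = np.clip(struct_x.to_numpy() @ struct_y.to_numpy().T, -1.0, 1.0)
    return pd.DataFrame(s, index=struct_x.index, columns=struct_y.index)


def relevance_network(
    scores: pd.DataFrame,
    tau: float = 0.5,
    rescue_isolated_traits: bool = False,
) -> nx.Graph:
    """Bipartite trait-eigengene graph thresholded at |score| >= tau.

    Edges carry the signed score (``weight``), a ``sign`` label matching the
    conventional red/blue colouring, and a ``rescued`` flag. With rescue on, a
    trait whose every score falls below tau receives its single strongest
    edge, flagged; otherwise isolation triggers a warning only.
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores contain non-finite values")
    g = nx.Graph()
    g.add_nodes_from((t, {"kind": "trait"}) for t in scores.index)
    g.add_nodes_from((m, {"kind": "module"}) for m in scores.columns)
    for t in scores.index:
        row = scores.loc[t]
        hits = row[row.abs() >= tau]
        for m, s in hits.items():
            g.add_edge(t, m, weight=float(s), sign="positive" if s >= 0 else "negative", rescued=False)
        if len(hits) == 0:
            if rescue_isolated_traits:
                m = row.abs().idxmax()
                s = float(row[m])
                g.add_edge(t, m, weight=s, sign="positive" if s >= 0 else "negative", rescued=True)
            else:
                warnings.warn(f"trait {t!r} is isolated at tau={tau}")
    return g
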