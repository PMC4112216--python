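"""Model/Results front-end over the network and CCA machinery.

Two fitted-model entry points mirror the usual estimator convention:

* :class:`CoexpressionNetwork` — built from an expression matrix; ``fit()``
  selects (or accepts) the soft-threshold power, builds adjacency and TOM,
  detects and merges modules, and returns a :class:`NetworkResults` carrying
  labels, eigengenes, variance explained, connectivity and a ``summary()``
  table.
* :class:`TraitCCA` — built from a trait table and an eigengene matrix;
  ``fit()`` runs ridge-regularized CCA and returns :class:`CCAResults` with
  canonical correlations, structure correlations, similarity scores and the
  thresholded relevance network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from . import network as net
from . import modules as mod
from . import traits as tr
from . import cca as cc

__all__ = ["CoexpressionNetwork", "NetworkResults", "TraitCCA", "CCAResults"]


class CoexpressionNetwork:
    """Weighted gene co-expression network model over an expression matrix.

    Parameters
    ----------
    expr : DataFrame, genes x samples, log-scale intensities. Every row must
        have nonzero variance.
    """

    def __init__(self, expr: pd.DataFrame):
        if expr.index.has_duplicates or expr.columns.has_duplicates:
            raise ValueError("duplicate gene or sample IDs")
        self.expr = expr

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame) -> "CoexpressionNetwork":
        return cls(expr)

    def fit(
        self,
        beta: float | None = None,
        betas=tuple(range(1, 21)),
        r2_cut: float = 0.8,
        min_module_size: int = 50,
        cut_quantile: float = 0.9,
        merge_cut_height: float = 0.20,
        coherence_min: float | None = 0.2,
        reassign_kme: float | None = None,
    ) -> "NetworkResults":
        """Build the network and detect modules.

        When ``beta`` is None the soft threshold is chosen by the scale-free
        fit scan. ``reassign_kme`` (off when None) joins unassigned genes to
        the module whose eigengene they track with at least that correlation.
        """
        scan = None
        if beta is None:
            scan = net.pick_soft_threshold(self.expr, betas=betas, r2_cut=r2_cut)
            beta = scan.selected
        S = net.similarity(self.expr)
        A = net.adjacency(S, beta)
        T = net.tom(A)
        dendro = mod.cluster_genes(net.tom_dissimilarity(T))
        labels = mod.cut_tree(dendro, min_module_size=min_module_size, cut_quantile=cut_quantile)
        if labels.max() >= 1 and coherence_min is not None:
            labels = mod.filter_incoherent_modules(self.expr, labels, coherence_min)
        if labels.max() >= 1:
            labels = mod.merge_modules(self.expr, labels, merge_cut_height=merge_cut_height)
        if labels.max() >= 1:
            if reassign_kme is not None:
                labels = mod.reassign_by_kme(self.expr, labels, threshold=reassign_kme)
            me, ve = mod.module_eigengene(self.expr, labels)
            km = mod.kme(self.expr, me)
        else:
            me = pd.DataFrame(columns=self.expr.columns)
            ve = pd.Series(dtype=float)
            km = pd.DataFrame(index=self.expr.index)
        conn = mod.connectivity(A, labels)
        return NetworkResults(
            model=self,
            beta=float(beta),
            scan=scan,
            adjacency=A,
            tom=T,
            dendrogram=dendro,
            labels=labels,
            eigengenes=me,
            var_explained=ve,
            connectivity=conn,
            kme=km,
            params={
                "beta": float(beta),
                "min_module_size": min_module_size,
                "cut_quantile": cut_quantile,
                "merge_cut_height": merge_cut_height,
                "coherence_min": coherence_min,
                "reassign_kme": reassign_kme,
            },
        )


@dataclass
class NetworkResults:
    """Fitted co-expression network: modules, eigengenes and connectivity."""

    model: CoexpressionNetwork
    beta: float
    scan: net.SoftThresholdScan | None
    adjacency: net.GeneMatrix
    tom: net.GeneMatrix
    dendrogram: mod.Dendrogram
    labels: pd.Series
    eigengenes: pd.DataFrame
    var_explained: pd.Series
    connectivity: pd.DataFrame
    kme: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() >= 1).sum())

    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels >= 1].value_counts().sort_index()
        sizes.index = [f"ME{m}" for m in sizes.index]
        return sizes.rename("size")

    def trait_correlations(self, traits: pd.DataFrame) -> tr.CorrelationReport:
        """Modules x traits grid of eigengene-trait (r, p)."""
        return tr.module_trait_matrix(self.eigengenes, traits)

    def meta_network(self, threshold: float = 0.5) -> nx.Graph:
        return mod.module_meta_network(self.eigengenes, threshold=threshold)

    def summary(self) -> str:
        sizes = self.module_sizes()
        lines = [
            "Co-expression network results",
            "=" * 31,
            f"genes: {self.model.expr.shape[0]}   samples: {self.model.expr.shape[1]}",
            f"soft threshold beta: {self.beta:g}"
            + ("" if self.scan is None else f" (scan max signed R2 = {max(self.scan.r_squared):.3f})"),
            f"modules: {self.n_modules}   unassigned genes: {int((self.labels == 0).sum())}",
            "",
            "module  size  var_explained",
        ]
        for m in sizes.index:
            lines.append(f"{m:>6}  {sizes[m]:>4}  {self.var_explained.get(m, float('nan')):.3f}")
        return "\n".join(lines)


class TraitCCA:
    """Regularized CCA between a trait block and an eigengene block.

    Parameters
    ----------
    traits : DataFrame, samples x traits.
    eigengenes : DataFrame, modules x samples (as produced by
        :class:`NetworkResults`); transposed internally to samples x modules.
    """

    def __init__(self, traits: pd.DataFrame, eigengenes: pd.DataFrame):
        y = eigengenes.T
        if list(traits.index) != list(y.index):
            raise ValueError("traits and eigengenes must share the sample axis")
        self.X = traits
        self.Y = y

    def fit(
        self,
        lambda_x: float = 0.1,
        lambda_y: float = 0.1,
        n_components: int = 3,
        tau: float = 0.5,
        variates: str = "average",
        rescue_isolated_traits: bool = False,
    ) -> "CCAResults":
        k_fit = min(self.X.shape[1], self.Y.shape[1], self.X.shape[0] - 1)
        res = cc.rcca(self.X, self.Y, lambda_x=lambda_x, lambda_y=lambda_y, n_components=k_fit)
        sx, sy = cc.structure_correlations(res, self.X, self.Y, n_components=n_components, variates=variates)
        scores = cc.similarity_scores(sx, sy)
        graph = cc.relevance_network(scores, tau=tau, rescue_isolated_traits=rescue_isolated_traits)
        return CCAResults(
            model=self,
            cca=res,
            struct_x=sx,
            struct_y=sy,
            scores=scores,
            network=graph,
            tau=tau,
        )


@dataclass
class CCAResults:
    """Fitted trait-eigengene CCA with the derived relevance network."""

    model: TraitCCA
    cca: cc.CCAResult
    struct_x: pd.DataFrame
    struct_y: pd.DataFrame
    scores: pd.DataFrame
    network: nx.Graph
    tau: float

    @property
    def correlations(self) -> np.ndarray:
        return self.cca.correlations

    def summary(self) -> str:
        rho = ", ".join(f"{r:.3f}" for r in self.correlations[:5])
        edges = self.network.number_of_edges()
        lines = [
            "Regularized CCA results",
            "=" * 25,
            f"traits: {self.model.X.shape[1]}   eigengenes: {self.model.Y.shape[1]}   "
            f"samples: {self.model.X.shape[0]}",
            f"lambda_x={self.cca.lambda_x:g}  lambda_y={self.cca.lambda_y:g}",
            f"canonical correlations (first 5): {rho}",
            f"structure components retained: {self.struct_x.shape[1]}",
            f"relevance network: {edges} edges at tau={self.tau:g}",
        ]
        iso = [t for t in self.scores.index if self.network.degree(t) == 0]
        if iso:
            lines.append(f"isolated traits: {iso}")
        return "\n".join(lines)
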