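"""Eigengene- and gene-level correlation with compositional traits.

Pearson correlations carry two-sided Student asymptotic p-values,
t = r sqrt(n-2) / sqrt(1-r^2) against t(n-2). Candidate genes within a module
are screened by the percentile rule: a gene survives for a trait when its
p-value falls strictly below the 25th percentile of all p-values computed for
that module-trait pairing, and survivors are classified by the combination of
traits whose screens they pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import pdist

from .modules import Dendrogram

__all__ = [
    "CorrelationReport",
    "corr_with_p",
    "pearson_pvalue",
    "module_trait_matrix",
    "trait_correlation_matrix",
    "percentile_cutoff",
    "screen_candidates",
    "classify_candidates",
    "cluster_modules_by_trait_profile",
    "TRAIT_ABBREVIATIONS",
]

# canonical abbreviation table used for subgroup naming
TRAIT_ABBREVIATIONS: dict[str, str] = {
    "cellulose": "Cel",
    "xylose": "Xyl",
    "arabinose": "Ara",
    "galactose": "Gal",
    "p-hydroxyphenyl": "H",
    "guaiacyl": "G",
    "syringyl": "S",
}


@dataclass
class CorrelationReport:
    """Paired correlation and p-value grids over (entity, trait) pairs."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_long(self) -> pd.DataFrame:
        long = self.r.stack().rename("r").to_frame()
        long["p"] = self.p.stack()
        long.index.names = ["entity", "trait"]
        return long.reset_index()


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided Student asymptotic p-value for a Pearson correlation."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def corr_with_p(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> tuple[float, float]:
    """Pearson correlation with its two-sided Student asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.clip(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)), -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:
        r = float(np.sign(r))
    return r, pearson_pvalue(r, n)


def _corr_grid(rows: pd.DataFrame, cols: pd.DataFrame) -> CorrelationReport:
    """(r, p) grid between the rows of ``rows`` and columns of ``cols``."""
    n = rows.shape[1]
    a = rows.to_numpy()
    b = cols.to_numpy().T
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    if (an == 0).any() or (bn == 0).any():
        raise ValueError("constant vector: correlation undefined")
    r = np.clip((ac @ bc.T) / np.outer(an, bn), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return CorrelationReport(
        r=pd.DataFrame(r, index=rows.index, columns=cols.columns),
        p=pd.DataFrame(p, index=rows.index, columns=cols.columns),
        n=n,
    )


def _check_samples(sample_like: pd.Index, traits: pd.DataFrame) -> None:
    if list(sample_like) != list(traits.index):
        missing = [s for s in sample_like if s not in traits.index]
        extra = [s for s in traits.index if s not in sample_like]
        raise ValueError(
            f"sample mismatch between expression and traits; "
            f"missing from traits: {missing[:5]}, extra in traits: {extra[:5]}"
        )


def module_trait_matrix(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> CorrelationReport:
    """Full modules x traits grid of (r, p) between eigengenes and traits."""
    _check_samples(eigengenes.columns, traits)
    return _corr_grid(eigengenes, traits)


def trait_correlation_matrix(traits: pd.DataFrame) -> CorrelationReport:
    """Symmetric trait x trait (r, p) grid."""
    if traits.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    return _corr_grid(traits.T, traits)


def percentile_cutoff(pvalues: np.ndarray | Sequence[float], percentile: float = 25.0) -> float:
    """Linear-interpolation percentile of a p-value population.

    The screening threshold: a candidate must fall strictly below this value,
    i.e. its p-value must be lower than (100 - percentile)% of the population.
    """
    return float(np.percentile(np.asarray(pvalues, dtype=float), percentile, method="linear"))


def screen_candidates(
    expr_subset: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    percentile: float = 25.0,
    population_p: np.ndarray | Sequence[float] | None = None,
) -> list[str]:
    """Percentile screen: genes whose trait p-value beats most of the module.

    Computes a p-value per gene against the trait and returns the genes whose
    p-value is strictly below the ``percentile`` percentile (linear
    interpolation) of all p-values in the subset — by default the bottom
    quarter of the distribution. ``population_p`` substitutes an external
    p-value population for the threshold (the pooled-across-modules mode);
    the genes returned are still those of ``expr_subset``.
    """
    if expr_subset.shape[0] == 0:
        raise ValueError("empty module passed to screen")
    trait = np.asarray(trait, dtype=float)
    ps = pd.Series(
        [corr_with_p(expr_subset.loc[g], trait)[1] for g in expr_subset.index],
        index=expr_subset.index,
    )
    pop = ps.to_numpy() if population_p is None else np.asarray(population_p, dtype=float)
    q = percentile_cutoff(pop, percentile)
    return list(ps.index[ps < q])


def classify_candidates(
    candidate_sets: Mapping[str, Sequence[str]],
    trait_order: Sequence[str] | None = None,
    abbreviations: Mapping[str, str] | None = None,
) -> pd.Series:
    """Label genes by the combination of trait screens they pass.

    A gene passing exactly one screen gets that trait's abbreviation, exactly
    two gets "A + B" (in canonical trait-list order), and three or more gets
    "Multi". Genes passing no screen are excluded.
    """
    abbrev = dict(TRAIT_ABBREVIATIONS) if abbreviations is None else dict(abbreviations)
    order = list(trait_order) if trait_order is not None else list(candidate_sets)
    hits: dict[str, list[str]] = {}
    for trait in order:
        for g in candidate_sets.get(trait, ()):
            hits.setdefault(g, []).append(trait)
    labels = {}
    for g, ts in hits.items():
        names = [abbrev.get(t, t) for t in ts]
        if len(names) == 1:
            labels[g] = names[0]
        elif len(names) == 2:
            labels[g] = f"{names[0]} + {names[1]}"
        else:
            labels[g] = "Multi"
    return pd.Series(labels, name="subgroup").sort_index()


def cluster_modules_by_trait_profile(
    report: CorrelationReport,
    method: str = "complete",
    cut_height: float | None = None,
) -> tuple[Dendrogram, pd.Series | None]:
    """Complete-linkage clustering of module rows of the correlation grid.

    Modules are clustered by the Euclidean distance between their trait
    correlation profiles; when ``cut_height`` is given, clade assignments for
    colour-coding are returned as well.
    """
    if report.r.shape[0] < 2:
        raise ValueError("need at least 2 modules")
    Z = linkage(pdist(report.r.to_numpy(), metric="euclidean"), method=method)
    dendro = Dendrogram(Z, report.r.index)
    clades = None
    if cut_height is not None:
        clades = pd.Series(
            fcluster(Z, t=cut_height, criterion="distance"),
            index=report.r.index,
            name="clade",
        )
    return dendro, clades
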