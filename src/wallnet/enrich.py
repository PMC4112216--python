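"""Term over-representation tests for gene modules.

Classic per-term one-sided tests against user-supplied annotation maps
(GO-BP-like, KEGG-Orthology-like, MapMan-like): the hypergeometric upper tail
P(X >= k) for k annotated genes in a module of size n drawn from a universe of
N genes of which K carry the term, and the numerically identical one-sided
(greater) Fisher's exact test on the corresponding 2x2 table. Reports are
labeled "classic"; no graph-based decorrelation across terms is attempted.
No multiple-testing correction is applied by default; a Benjamini-Hochberg
column is available on request.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "read_gmt",
    "read_term_table",
    "hypergeom_enrichment",
    "fisher_enrichment",
]


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file: term, description, then member gene IDs per line."""
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need term, description, genes): {line[:60]!r}")
        terms[parts[0]] = set(parts[2:])
        descriptions[parts[0]] = parts[1]
    return terms, descriptions


def read_term_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, term) into term -> gene-set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term"):
        out[str(term)] = set(grp["gene_id"])
    return out


def _prepare(
    module_genes: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
) -> tuple[set[str], set[str], dict[str, set[str]]]:
    module = set(module_genes)
    uni = set(universe)
    outside = module - uni
    if outside:
        raise ValueError(f"module genes outside the universe: {sorted(outside)[:5]}")
    restricted = {t: gs & uni for t, gs in annotation.items()}
    restricted = {t: gs for t, gs in restricted.items() if gs}
    return module, uni, restricted


def _enrichment(
    module_genes: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    pfunc,
    fdr: bool,
    descriptions: Mapping[str, str] | None,
) -> pd.DataFrame:
    module, uni, restricted = _prepare(module_genes, annotation, universe)
    N, n = len(uni), len(module)
    rows = []
    for term, genes in sorted(restricted.items()):
        K = len(genes)
        k = len(genes & module)
        rows.append(
            {
                "term": term,
                "description": (descriptions or {}).get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": pfunc(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "description", "k", "n", "K", "N", "p"])
    if len(df):
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
        if fdr:
            df["p_bh"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df.attrs["method"] = "classic"
    return df


def _hyper_p(k: int, n: int, K: int, N: int) -> float:
    # upper tail P(X >= k); sf(k-1) handles k = 0 -> 1 exactly
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _fisher_p(k: int, n: int, K: int, N: int) -> float:
    table = [[k, n - k], [K - k, N - n - K + k]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def hypergeom_enrichment(
    module_genes: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    fdr: bool = False,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term hypergeometric upper-tail enrichment, sorted ascending by p."""
    return _enrichment(module_genes, annotation, universe, _hyper_p, fdr, descriptions)


def fisher_enrichment(
    module_genes: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    fdr: bool = False,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term one-sided (greater) Fisher's exact enrichment.

    Mathematically identical to the hypergeometric upper tail; kept as a
    separately-exercised code path so the identity can be asserted.
    """
    return _enrichment(module_genes, annotation, universe, _fisher_p, fdr, descriptions)
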