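"""Probe-level preprocessing: background filtering and probe-to-gene collapse.

Array probes whose intensities do not rise above the negative-control
background are treated as noise and removed; genes measured by several probes
are summarised by a single representative probe row.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["filter_probes", "collapse_probes", "drop_zero_variance"]


def filter_probes(
    probes: pd.DataFrame,
    negative_control_ids: Iterable[str],
    fraction: float = 0.8,
    mode: str = "any",
) -> pd.DataFrame:
    """Remove probes that fall below the negative-control background.

    Per sample ``s`` the threshold ``T_s`` is the ``fraction`` quantile
    (linear interpolation between order statistics) of the negative-control
    intensities in that sample. Under mode ``"any"`` a probe is removed if its
    value is below ``T_s`` in at least one sample; under ``"all"`` only if it
    is below threshold in every sample. Control rows never appear in the
    output.
    """
    controls = [c for c in negative_control_ids]
    if not controls:
        raise ValueError("negative control set is empty")
    missing = [c for c in controls if c not in probes.index]
    if missing:
        raise ValueError(f"negative control IDs absent from matrix: {missing[:5]}")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")

    ctrl = probes.loc[controls]
    thresholds = ctrl.quantile(fraction, interpolation="linear")  # per sample
    logger.debug("background thresholds per sample: %s", thresholds.to_dict())

    rest = probes.drop(index=controls)
    below = rest.lt(thresholds, axis=1)
    removed = below.any(axis=1) if mode == "any" else below.all(axis=1)
    return rest.loc[~removed]


def collapse_probes(
    probes: pd.DataFrame,
    probe_to_gene: Mapping[str, str] | pd.Series | pd.DataFrame,
    method: str = "max_mean",
) -> pd.DataFrame:
    """Collapse multiple probes per gene to one expression row per gene.

    ``max_mean`` keeps, per gene, the probe with the highest mean intensity
    across samples (ties broken by lexicographically smallest probe ID);
    ``mean`` averages a gene's probes. Probes absent from the map pass
    through under their probe IDs.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        if probe_to_gene.shape[1] < 2:
            raise ValueError("probe map table needs two columns (probe_id, gene_id)")
        pairs = probe_to_gene.iloc[:, :2]
        pairs.columns = ["probe_id", "gene_id"]
        if pairs.groupby("probe_id")["gene_id"].nunique().gt(1).any():
            bad = pairs.groupby("probe_id")["gene_id"].nunique()
            raise ValueError(
                "ambiguous mapping: probes mapped to multiple genes: "
                f"{list(bad[bad > 1].index[:5])}"
            )
        mapping = dict(zip(pairs["probe_id"], pairs["gene_id"]))
    elif isinstance(probe_to_gene, pd.Series):
        if probe_to_gene.index.has_duplicates:
            dup = probe_to_gene.index[probe_to_gene.index.duplicated()].unique()
            amb = [p for p in dup if probe_to_gene.loc[[p]].nunique() > 1]
            if amb:
                raise ValueError(f"ambiguous mapping: probes mapped to multiple genes: {amb[:5]}")
        mapping = probe_to_gene.to_dict()
    else:
        mapping = dict(probe_to_gene)
    if method not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse method {method!r}")

    mapped = probes.index.to_series().map(mapping)
    unmapped = probes.loc[mapped.isna()]
    grouped = probes.loc[mapped.notna()].copy()
    genes = mapped.dropna()

    if method == "mean":
        collapsed = grouped.groupby(genes).mean()
    else:
        means = grouped.mean(axis=1)
        # sort so idxmax lands on the lexicographically smallest probe on ties
        order = means.to_frame("m").assign(pid=grouped.index).sort_values(["m", "pid"], ascending=[False, True])
        keep = order.assign(gene=genes.loc[order.index]).drop_duplicates("gene")
        collapsed = grouped.loc[keep.index]
        collapsed.index = keep["gene"].to_numpy()
    out = pd.concat([collapsed, unmapped])
    out = out.sort_index()
    out.index.name = "gene_id"
    if out.index.has_duplicates:
        raise ValueError("collapse produced duplicate row IDs (gene ID collides with probe ID)")
    return out


def drop_zero_variance(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with zero variance across samples, warning with the count.

    Correlation is undefined for constant rows, so the network stage requires
    every entering row to vary.
    """
    var = expr.var(axis=1, ddof=0)
    flat = var[var == 0].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance rows (e.g. {list(flat[:3])})")
        return expr.drop(index=flat)
    return expr
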