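"""Configuration and end-to-end pipeline driver.

Stage order: simulate? -> preprocess -> network -> modules -> traits -> cca
-> enrich?. Every stage persists its outputs under the run directory and the
run finishes with a machine-readable ``summary.json``. Reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, preprocess, io as wio, traits as tr, enrich as en
from .model import CoexpressionNetwork, TraitCCA

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; round-trips losslessly through YAML."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    # inputs (ignored when simulate=True)
    expr_path: str | None = None
    probe_map_path: str | None = None
    controls_path: str | None = None
    traits_path: str | None = None
    annotation_gmt: str | None = None
    # simulation
    simulate: bool = True
    seed: int = 0
    n_samples: int = 29
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    n_noise_genes: int = 200
    noise_sd: float = 0.5
    simulate_probes: bool = False
    max_probes_per_gene: int = 3
    n_negative_controls: int = 50
    # preprocess
    background_fraction: float = 0.8
    background_mode: str = "any"
    collapse_method: str = "max_mean"
    # network
    beta: float | None = None
    betas: tuple[float, ...] = tuple(range(1, 21))
    r2_cut: float = 0.8
    max_block_size: int | None = None  # accepted but ignored; blocks exist only for memory
    # modules
    min_module_size: int = 50
    cut_quantile: float = 0.9
    merge_cut_height: float = 0.20
    coherence_min: float | None = 0.2
    reassign_kme: float | None = None
    meta_threshold: float = 0.5
    # trait link
    screen_percentile: float = 25.0
    screen_scope: str = "module"  # or "global": pool p-values across modules
    # cca
    lambda_x: float = 0.1
    lambda_y: float = 0.1
    n_cca_components: int = 3
    tau_cca: float = 0.5
    variate_convention: str = "average"
    rescue_isolated_traits: bool = False
    # stage toggles
    run_cca: bool = True
    run_enrich: bool = False

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["betas"] = [float(b) for b in self.betas]
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("schema_version", 1) != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {d.get('schema_version')}")
        d["module_sizes"] = tuple(d.get("module_sizes", ()))
        d["betas"] = tuple(d.get("betas", ()))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every enabled stage, persisting intermediates and a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    t0 = time.time()
    summary: dict = {"config": yaml.safe_load((out / "config.yaml").read_text())}
    stage = "simulate"
    try:
        if config.max_block_size is not None:
            warnings.warn("max_block_size is accepted but ignored: computation is single-block")
        if config.simulate:
            design = datasets.PlantedDesign(
                n_samples=config.n_samples,
                module_sizes=tuple(config.module_sizes),
                n_noise_genes=config.n_noise_genes,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            expr, truth = datasets.generate_expression(design)
            trait_table = datasets.generate_traits(truth, design)
            if config.simulate_probes:
                probes, p2g, ctrl = datasets.generate_probe_level(
                    expr,
                    config.max_probes_per_gene,
                    config.n_negative_controls,
                    seed=config.seed,
                )
                datasets.write_design_outputs(
                    out / "simulated", design, expr, truth, trait_table, probes, p2g, ctrl
                )
            else:
                probes = p2g = ctrl = None
                datasets.write_design_outputs(out / "simulated", design, expr, truth, trait_table)
        else:
            if config.expr_path is None:
                raise ValueError("expr_path is required when simulate is off")
            probes = wio.read_matrix(config.expr_path)
            p2g = (
                pd.read_csv(config.probe_map_path, sep="\t", index_col=0).iloc[:, 0]
                if config.probe_map_path
                else None
            )
            ctrl = wio.read_id_list(config.controls_path) if config.controls_path else None
            trait_table = wio.read_trait_table(config.traits_path) if config.traits_path else None
            expr = probes if p2g is None and ctrl is None else None

        stage = "preprocess"
        if probes is not None and (p2g is not None or ctrl is not None):
            if ctrl is not None:
                probes = preprocess.filter_probes(
                    probes, ctrl, fraction=config.background_fraction, mode=config.background_mode
                )
            if p2g is not None:
                probes = preprocess.collapse_probes(probes, p2g, method=config.collapse_method)
            expr = probes
        expr = preprocess.drop_zero_variance(expr)
        expr = expr.sort_index()
        wio.write_matrix(expr, out / "expression_preprocessed.tsv")
        logger.info("preprocess: %d genes x %d samples", *expr.shape)

        stage = "network+modules"
        model = CoexpressionNetwork(expr)
        res = model.fit(
            beta=config.beta,
            betas=config.betas,
            r2_cut=config.r2_cut,
            min_module_size=config.min_module_size,
            cut_quantile=config.cut_quantile,
            merge_cut_height=config.merge_cut_height,
            coherence_min=config.coherence_min,
            reassign_kme=config.reassign_kme,
        )
        res.labels.sort_index().to_csv(out / "module_labels.tsv", sep="\t")
        wio.write_matrix(res.eigengenes, out / "eigengenes.tsv")
        conn = res.connectivity.sort_index().copy()
        if res.n_modules:
            own = [
                res.kme.loc[g, f"ME{m}"] if m >= 1 else np.nan
                for g, m in conn["module"].items()
            ]
            conn["kME_own"] = own
        conn.to_csv(out / "connectivity.tsv", sep="\t")
        summary["n_genes"] = int(expr.shape[0])
        summary["n_samples"] = int(expr.shape[1])
        summary["beta"] = res.beta
        summary["n_modules"] = res.n_modules
        summary["module_sizes"] = {k: int(v) for k, v in res.module_sizes().items()}
        if res.n_modules >= 2:
            meta = res.meta_network(threshold=config.meta_threshold)
            wio.write_network(meta, out / "module_meta_network.graphml")
            wio.write_network(meta, out / "module_meta_network.tsv", format="edgelist")
        logger.info("modules: %d (beta=%g)", res.n_modules, res.beta)

        stage = "traits"
        if trait_table is not None and res.n_modules:
            trait_table = trait_table.loc[expr.columns]
            report = res.trait_correlations(trait_table)
            report.to_long().to_csv(out / "module_trait_correlations.tsv", sep="\t", index=False)
            summary["module_trait_r"] = _round_floats(report.r.round(6).to_dict())
            summary["module_trait_p"] = _round_floats(report.p.round(8).to_dict())
            # per-module, per-trait candidate screen (optionally pooling the
            # p-value population across all assigned genes per trait)
            pooled: dict[str, np.ndarray] = {}
            if config.screen_scope == "global":
                assigned = res.labels[res.labels >= 1].index
                for t in trait_table.columns:
                    y = trait_table[t].to_numpy()
                    pooled[t] = np.array(
                        [tr.corr_with_p(expr.loc[g], y)[1] for g in assigned]
                    )
            counts = {}
            for m in sorted(set(res.labels) - {0}):
                genes = res.labels[res.labels == m].index
                sets = {
                    t: tr.screen_candidates(
                        expr.loc[genes],
                        trait_table[t],
                        percentile=config.screen_percentile,
                        population_p=pooled.get(t),
                    )
                    for t in trait_table.columns
                }
                sub = tr.classify_candidates(sets, trait_order=list(trait_table.columns))
                sub.to_csv(out / f"candidates_module{m}.tsv", sep="\t")
                counts[str(m)] = {t: len(s) for t, s in sets.items()}
            summary["candidate_counts"] = counts

            stage = "cca"
            if config.run_cca and res.n_modules >= 2:
                cres = TraitCCA(trait_table, res.eigengenes).fit(
                    lambda_x=config.lambda_x,
                    lambda_y=config.lambda_y,
                    n_components=config.n_cca_components,
                    tau=config.tau_cca,
                    variates=config.variate_convention,
                    rescue_isolated_traits=config.rescue_isolated_traits,
                )
                wio.write_network(cres.network, out / "relevance_network.graphml")
                wio.write_network(cres.network, out / "relevance_network.tsv", format="edgelist")
                summary["canonical_correlations"] = [
                    round(float(r), 10) for r in cres.correlations
                ]
                summary["relevance_edges"] = sorted(
                    [str(u), str(v), round(float(d["weight"]), 10)]
                    for u, v, d in cres.network.edges(data=True)
                )

        stage = "enrich"
        if config.run_enrich and config.annotation_gmt and res.n_modules:
            terms, desc = en.read_gmt(config.annotation_gmt)
            universe = list(expr.index)
            frames = []
            for m in sorted(set(res.labels) - {0}):
                genes = res.labels[res.labels == m].index
                df = en.fisher_enrichment(genes, terms, universe, descriptions=desc)
                df.insert(0, "module", m)
                frames.append(df)
            pd.concat(frames).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["n_enrichment_rows"] = int(sum(len(f) for f in frames))
    except Exception as exc:  # pragma: no cover - error path formatting
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["elapsed_reported"] = "see log"
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return out
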